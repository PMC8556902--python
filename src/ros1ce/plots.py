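"""Cost-effectiveness plane, CEAC and tornado figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_ce_plane(psa_result, path, wtp: float = 100_000.0) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    d = psa_result.draws
    ax.scatter(d["delta_qaly"], d["delta_cost"], s=4, alpha=0.3, color="steelblue")
    lim = max(abs(d["delta_qaly"]).max() * 1.1, 0.1)
    ax.plot([-lim, lim], [-lim * wtp, lim * wtp], "k--", lw=1,
            label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (CAD)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ceac(psa_result, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(psa_result.ceac["wtp"], psa_result.ceac["probability"], lw=1.5)
    ax.set_xlabel("Willingness to pay (CAD/QALY)")
    ax.set_ylabel("P(crizotinib cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tornado(tornado, path, top: int = 12) -> None:
    df = tornado.head(top).iloc[::-1]
    base = tornado.attrs.get("base_icer_qaly")
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    y = range(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = sorted([row["icer_low"], row["icer_high"]])
        ax.barh(i, hi - lo, left=lo, color="steelblue", alpha=0.8)
    ax.set_yticks(list(y))
    ax.set_yticklabels(df["parameter"])
    if base is not None:
        ax.axvline(base, color="k", lw=1, ls="--", label="base ICER")
        ax.legend()
    ax.set_xlabel("ICER (CAD/QALY)")
    ax.set_title("One-way sensitivity (tornado)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
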