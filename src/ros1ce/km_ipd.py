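"""Reconstruction of individual patient data (IPD) from digitized Kaplan-Meier curves.

Published survival figures can be inverted back to a pseudo patient-level
dataset: the curve coordinates fix where events happened, and the
numbers-at-risk table fixes how many subjects were lost to censoring in
between.  Two reconstruction routes are provided:

* :func:`replicate_small_study` — for small studies whose every step and
  censor tick is individually resolvable on the plot, events and censorings
  are read off exactly.
* :func:`reconstruct_ipd` — for larger studies, the iterative inversion of
  the product-limit construction (the Guyot algorithm) distributes censoring
  within risk-table intervals and solves for integer event counts so the
  reconstructed KM curve passes through the digitized coordinates.

Times are in months throughout this layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidCurveError, ValidationError

ARMS = ("crizotinib", "chemotherapy")

__all__ = [
    "DigitizedCurve",
    "IPDRecord",
    "IPDSet",
    "KMCurve",
    "clean_digitized_curve",
    "replicate_small_study",
    "reconstruct_ipd",
    "km_estimate",
    "pool_ipd",
    "read_curve_csv",
    "read_risk_csv",
    "write_ipd_csv",
    "read_ipd_csv",
]


@dataclass(frozen=True)
class IPDRecord:
    """One subject's right-censored observation."""

    time: float  # months, > 0
    event: bool  # True = progression/death, False = censored
    arm: str
    study_id: str

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValidationError(f"IPD time must be finite and positive, got {self.time}")
        if not self.arm or not self.study_id:
            raise ValidationError("arm and study_id must be non-empty")


@dataclass
class IPDSet:
    """A collection of IPD records with per-study reconstruction provenance."""

    records: list[IPDRecord]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def arm_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.arm] = counts.get(r.arm, 0) + 1
        return counts

    def subset(self, arm: str) -> "IPDSet":
        recs = [r for r in self.records if r.arm == arm]
        return IPDSet(recs, dict(self.provenance))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": [r.study_id for r in self.records],
                "arm": [r.arm for r in self.records],
                "time_months": [r.time for r in self.records],
                "event": [int(r.event) for r in self.records],
            }
        )


@dataclass
class DigitizedCurve:
    """Digitizer output for one study arm: (time, survival) clicks plus risk table.

    ``points`` are ordered (time, survival) pairs; ``risk_table`` is an
    optional list of (time, n_at_risk); ``total_events`` optionally pins the
    total number of events when no risk table is available; ``n_subjects``
    gives the initial sample size when it cannot be read from the risk table.
    """

    study_id: str
    arm: str
    points: list[tuple[float, float]]
    risk_table: list[tuple[float, int]] | None = None
    total_events: int | None = None
    n_subjects: int | None = None

    @property
    def n0(self) -> int | None:
        if self.risk_table:
            return int(self.risk_table[0][1])
        return self.n_subjects

    def times(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    def survival(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass
class KMCurve:
    """Product-limit estimate as a right-continuous step function."""

    times: np.ndarray  # event times where S drops (sorted)
    survival: np.ndarray  # S immediately after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n_events: np.ndarray  # events at each drop
    n0: int

    def evaluate(self, t) -> np.ndarray:
        """S(t) for scalar or array t (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        surv = np.concatenate([[1.0], self.survival])
        return surv[idx]

    def n_at_risk(self, t) -> np.ndarray:
        """Number of subjects still under observation at time t (from stored data)."""
        # reconstructed from drops only; callers needing exact censoring-aware
        # counts should use km_estimate's ``risk_fn``
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left")
        ar = np.concatenate([[self.n0], self.at_risk - self.n_events])
        return ar[np.minimum(idx, len(self.times))]

    @property
    def median(self) -> float:
        """Earliest time with S(t) <= 0.5 (nan if never reached)."""
        below = np.nonzero(self.survival <= 0.5)[0]
        if len(below) == 0:
            return float("nan")
        return float(self.times[below[0]])

    def step_points(self) -> list[tuple[float, float]]:
        """Exact step coordinates (time, survival) including the origin."""
        pts = [(0.0, 1.0)]
        pts += [(float(t), float(s)) for t, s in zip(self.times, self.survival)]
        return pts


# ---------------------------------------------------------------------------
# cleaning


def clean_digitized_curve(raw: DigitizedCurve) -> DigitizedCurve:
    """Make digitizer clicks monotone and well-formed.

    Sorts by time, collapses duplicate times to the last click, clips survival
    to [0, 1], clamps to a running minimum (survival cannot increase), and
    prepends the origin (0, 1) if absent.  Survival outside [-0.02, 1.02]
    before clipping is treated as a digitization failure rather than jitter.
    """
    if len(raw.points) < 2:
        raise InvalidCurveError(f"{raw.study_id}: need at least 2 digitized points")
    t = raw.times()
    s = raw.survival()
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(s)):
        raise InvalidCurveError(f"{raw.study_id}: non-finite coordinates")
    if np.any(s < -0.02) or np.any(s > 1.02):
        raise InvalidCurveError(
            f"{raw.study_id}: survival outside [-0.02, 1.02]; not plausible digitizer jitter"
        )
    if np.any(t < 0):
        raise InvalidCurveError(f"{raw.study_id}: negative times")
    order = np.argsort(t, kind="stable")
    t, s = t[order], s[order]
    # collapse duplicate times -> keep last click
    keep = np.append(t[1:] != t[:-1], True)
    t, s = t[keep], s[keep]
    s = np.clip(s, 0.0, 1.0)
    s = np.minimum.accumulate(s)
    if t[0] != 0.0:
        t = np.insert(t, 0, 0.0)
        s = np.insert(s, 0, 1.0)
    else:
        s[0] = 1.0
    cleaned = replace(raw, points=[(float(a), float(b)) for a, b in zip(t, s)])
    _validate_risk_table(cleaned)
    return cleaned


def _validate_risk_table(curve: DigitizedCurve) -> None:
    if not curve.risk_table:
        return
    rt = np.array([n for _, n in curve.risk_table], dtype=float)
    tt = np.array([t for t, _ in curve.risk_table], dtype=float)
    if np.any(np.diff(tt) <= 0):
        raise ValidationError(f"{curve.study_id}: risk-table times must be increasing")
    if np.any(np.diff(rt) > 0):
        raise ValidationError(f"{curve.study_id}: n_at_risk must be non-increasing")
    if np.any(rt < 0):
        raise ValidationError(f"{curve.study_id}: negative n_at_risk")


# ---------------------------------------------------------------------------
# Kaplan-Meier estimation


def km_estimate(records: list[IPDRecord] | IPDSet) -> KMCurve:
    """Product-limit estimator with events-before-censorings tie handling."""
    if isinstance(records, IPDSet):
        records = records.records
    if not records:
        raise ValidationError("km_estimate needs at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    n0 = len(times)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    ev_times = np.unique(times[events])
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for te in ev_times:
        # ties: events at te counted while censorings at te are still at risk
        n_risk = int(np.sum((times > te) | (times == te)))
        d = int(np.sum(events & (times == te)))
        at_risk.append(n_risk)
        n_ev.append(d)
        s *= 1.0 - d / n_risk
        surv.append(s)
    return KMCurve(
        times=np.asarray(ev_times, dtype=float),
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
        n0=n0,
    )


# ---------------------------------------------------------------------------
# exact replication (small studies)


def replicate_small_study(
    curve: DigitizedCurve, *, integer_tol: float = 0.2, max_n: int | None = None
) -> list[IPDRecord]:
    """Read each event and censor tick off an exactly-digitized small-study curve.

    A click with a survival drop encodes events (multiplicity = drop x number
    at risk / previous survival); a click at an unchanged survival level is a
    censor tick for one subject.  Subjects left at the final click with no
    tick are censored there.  Event multiplicities further than
    ``integer_tol`` subjects from an integer raise :class:`ValidationError`.
    """
    curve = clean_digitized_curve(curve)
    n0 = curve.n0
    if n0 is None:
        raise ValidationError(f"{curve.study_id}: sample size unknown (no risk table or n_subjects)")
    if max_n is not None and n0 > max_n:
        raise ValidationError(f"{curve.study_id}: n={n0} exceeds exact-replication threshold {max_n}")
    t = curve.times()
    s = curve.survival()
    records: list[IPDRecord] = []
    n_remaining = n0
    s_prev = 1.0
    for k in range(1, len(t)):
        if s[k] < s_prev:
            if s_prev <= 0:
                raise ValidationError(f"{curve.study_id}: drop after curve reached zero")
            d_float = n_remaining * (1.0 - s[k] / s_prev)
            d = int(round(d_float))
            if abs(d_float - d) > integer_tol:
                raise ValidationError(
                    f"{curve.study_id}: drop at t={t[k]} implies {d_float:.2f} events "
                    f"(not integer within {integer_tol})"
                )
            if d < 1:
                raise ValidationError(f"{curve.study_id}: vanishing drop at t={t[k]}")
            records += [IPDRecord(t[k], True, curve.arm, curve.study_id)] * d
            n_remaining -= d
            s_prev = s[k]
        else:
            # unchanged level: a censor tick for one subject
            records.append(IPDRecord(t[k], False, curve.arm, curve.study_id))
            n_remaining -= 1
        if n_remaining < 0:
            raise ValidationError(f"{curve.study_id}: marks imply more subjects than n={n0}")
    # anyone unaccounted for is administratively censored at last follow-up
    records += [IPDRecord(t[-1], False, curve.arm, curve.study_id)] * n_remaining
    return records


# ---------------------------------------------------------------------------
# Guyot reconstruction


def reconstruct_ipd(
    curve: DigitizedCurve, *, max_iter: int = 50, censor_placement: str = "uniform"
) -> list[IPDRecord]:
    """Invert a digitized KM curve into pseudo-IPD (Guyot algorithm).

    With a risk table, censoring counts inside each risk interval are solved
    iteratively so that the implied number at risk matches the table at the
    next interval start, censor times spread uniformly within the interval,
    and event counts are chosen so the reconstructed product-limit curve
    passes through the digitized coordinates.  Without a risk table, the total
    event count (if supplied) or a censoring-only-at-last-follow-up
    assumption anchors the inversion.

    ``censor_placement='clicks'`` snaps censor times onto zero-drop clicks
    inside each interval (the censor ticks of an exactly-digitized curve), so
    that on a one-click-per-subject curve the output coincides with
    :func:`replicate_small_study`; the default keeps the canonical uniform
    spread.
    """
    if censor_placement not in ("uniform", "clicks"):
        raise ValidationError(f"censor_placement must be 'uniform' or 'clicks'")
    curve = clean_digitized_curve(curve)
    t = curve.times()
    s = curve.survival()
    K = len(t)

    if curve.risk_table:
        trisk = [float(x) for x, _ in curve.risk_table]
        nrisk = [int(n) for _, n in curve.risk_table]
    else:
        n0 = curve.n0
        if n0 is None:
            raise ValidationError(
                f"{curve.study_id}: reconstruction needs a risk table or n_subjects"
            )
        trisk, nrisk = [0.0], [n0]

    if trisk[0] > 0.0:
        trisk.insert(0, 0.0)
        nrisk.insert(0, nrisk[0])

    # klick index ranges per risk interval
    I = len(trisk)
    lower = [int(np.searchsorted(t, trisk[i], side="left")) for i in range(I)]
    upper = [
        (int(np.searchsorted(t, trisk[i + 1], side="left")) - 1) if i < I - 1 else K - 1
        for i in range(I)
    ]
    interval_end = [trisk[i + 1] if i < I - 1 else t[-1] for i in range(I)]

    d = np.zeros(K, dtype=int)  # events at each klick
    cens_times: list[list[float]] = [[] for _ in range(I)]

    n_start = nrisk[0]
    for i in range(I):
        if lower[i] > upper[i]:
            # no klicks in this interval; censor the full decrement mid-interval
            if i < I - 1:
                ncen = n_start - nrisk[i + 1]
                cens_times[i] = [0.5 * (trisk[i] + interval_end[i])] * max(ncen, 0)
                n_start = nrisk[i + 1]
            continue
        if i < I - 1:
            s_lo = s[lower[i]]
            s_next = s[lower[i + 1]] if lower[i + 1] < K else s[-1]
            guess = int(round(n_start * (s_next / s_lo))) - nrisk[i + 1] if s_lo > 0 else 0
            ncen = max(guess, 0)
            for _ in range(max_iter):
                ct, dk, n_end = _process_interval(
                    t, s, lower[i], upper[i], trisk[i], interval_end[i], n_start, ncen, d
                )
                diff = n_end - nrisk[i + 1]
                if diff == 0:
                    break
                ncen += diff
                if ncen < 0:
                    ncen = 0
                    ct, dk, n_end = _process_interval(
                        t, s, lower[i], upper[i], trisk[i], interval_end[i], n_start, ncen, d
                    )
                    break
            cens_times[i] = ct
            d[lower[i] : upper[i] + 1] = dk
            n_start = n_end
        else:
            # last interval: anchor on total_events when available, else assume
            # no censoring before the last follow-up time
            ncen = 0
            target = curve.total_events
            for _ in range(max_iter):
                ct, dk, n_end = _process_interval(
                    t, s, lower[i], upper[i], trisk[i], interval_end[i], n_start, ncen, d
                )
                if target is None:
                    break
                total_d = int(np.sum(d[: lower[i]]) + np.sum(dk))
                diff = total_d - target
                if diff == 0 or ncen + diff < 0 or ncen + diff > n_start:
                    break
                ncen += diff
            cens_times[i] = ct
            d[lower[i] : upper[i] + 1] = dk
            n_start = n_end

    if censor_placement == "clicks":
        # subjects still at risk at the end are censor ticks too on an
        # exactly-digitized curve; let them snap to their clicks
        cens_times[I - 1] = list(cens_times[I - 1]) + [t[-1]] * int(n_start)
        n_start = 0
        for i in range(I):
            if not cens_times[i] or lower[i] > upper[i]:
                continue
            flats = [
                t[k]
                for k in range(max(lower[i], 1), upper[i] + 1)
                if d[k] == 0
            ]
            m = min(len(flats), len(cens_times[i]))
            cens_times[i] = flats[:m] + cens_times[i][m:]

    records: list[IPDRecord] = []
    for k in range(K):
        if d[k] > 0:
            records += [IPDRecord(t[k], True, curve.arm, curve.study_id)] * int(d[k])
    for i in range(I):
        for ct in cens_times[i]:
            records.append(IPDRecord(max(ct, 1e-9), False, curve.arm, curve.study_id))
    # subjects still at risk after the final klick: administratively censored there
    records += [IPDRecord(t[-1], False, curve.arm, curve.study_id)] * int(n_start)
    return records


def _process_interval(t, s, lo, up, t_start, t_end, n_start, ncen, d_prev):
    """Distribute ``ncen`` censorings uniformly over [t_start, t_end] and solve
    integer event counts at each klick so the running KM matches ``s``.

    Returns (censor_times, events_per_klick, n_at_risk_at_interval_end).
    """
    width = t_end - t_start
    if ncen > 0 and width > 0:
        ct = [t_start + width * (j - 0.5) / ncen for j in range(1, ncen + 1)]
    elif ncen > 0:
        ct = [t_start] * ncen
    else:
        ct = []
    # censorings falling within [t[k], t[k+1]) leave the risk set after klick k
    c = np.zeros(up - lo + 1, dtype=int)
    for x in ct:
        k = int(np.searchsorted(t[lo : up + 1], x, side="right")) - 1
        k = min(max(k, 0), up - lo)
        c[k] += 1

    # digitized value just before the interval is the running product baseline
    km_prod = s[lo - 1] if lo > 0 else 1.0

    dk = np.zeros(up - lo + 1, dtype=int)
    n_hat = n_start
    for k in range(lo, up + 1):
        if n_hat > 0 and km_prod > 0:
            d_f = n_hat * (1.0 - s[k] / km_prod)
            dd = int(round(d_f))
            dd = min(max(dd, 0), n_hat)
        else:
            dd = 0
        if dd > 0:
            km_prod *= 1.0 - dd / n_hat
        dk[k - lo] = dd
        n_hat -= dd + c[k - lo]
        if n_hat < 0:
            n_hat = 0
    return ct, dk, n_hat


# ---------------------------------------------------------------------------
# pooling and I/O


def pool_ipd(studies: list[IPDSet]) -> IPDSet:
    """Concatenate per-study IPD, preserving labels; validates arm consistency."""
    if not studies:
        raise ValidationError("pool_ipd needs at least one study")
    arm_by_study: dict[str, str] = {}
    records: list[IPDRecord] = []
    provenance: dict[str, str] = {}
    for st in studies:
        for r in st.records:
            prev = arm_by_study.get(r.study_id)
            if prev is not None and prev != r.arm:
                raise ValidationError(f"study {r.study_id} appears in conflicting arms")
            arm_by_study[r.study_id] = r.arm
            records.append(r)
        provenance.update(st.provenance)
    return IPDSet(records, provenance)


def read_curve_csv(path) -> list[DigitizedCurve]:
    """Read digitized coordinates: columns study_id, arm, time_months, survival."""
    df = pd.read_csv(path)
    required = {"study_id", "arm", "time_months", "survival"}
    if not required.issubset(df.columns):
        raise ValidationError(f"curve CSV must have columns {sorted(required)}")
    curves = []
    for (sid, arm), g in df.groupby(["study_id", "arm"], sort=False):
        pts = list(zip(g["time_months"].astype(float), g["survival"].astype(float)))
        curves.append(DigitizedCurve(str(sid), str(arm), pts))
    return curves


def read_risk_csv(path, curves: list[DigitizedCurve]) -> list[DigitizedCurve]:
    """Attach risk tables (columns study_id, arm, time_months, n_at_risk) to curves."""
    df = pd.read_csv(path)
    required = {"study_id", "arm", "time_months", "n_at_risk"}
    if not required.issubset(df.columns):
        raise ValidationError(f"risk CSV must have columns {sorted(required)}")
    by_key = {(c.study_id, c.arm): c for c in curves}
    for (sid, arm), g in df.groupby(["study_id", "arm"], sort=False):
        key = (str(sid), str(arm))
        if key in by_key:
            by_key[key].risk_table = list(
                zip(g["time_months"].astype(float), g["n_at_risk"].astype(int))
            )
    return curves


def write_ipd_csv(ipd: IPDSet, path) -> None:
    ipd.to_dataframe().to_csv(path, index=False)


def read_ipd_csv(path) -> IPDSet:
    df = pd.read_csv(path)
    records = [
        IPDRecord(float(r.time_months), bool(r.event), str(r.arm), str(r.study_id))
        for r in df.itertuples()
    ]
    return IPDSet(records)
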