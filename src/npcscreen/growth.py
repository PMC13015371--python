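"""Growth-kinetics analysis for live-cell imaging well traces.

The measured quantity is the total fluorescent-nucleus area per well
("object sum area"), a proxy for live-cell number.  Cell growth is modelled
as exponential, ``N(t) = N0 * exp(k t)``; the growth rate ``k`` is the
ordinary-least-squares slope of ``ln N`` against time, and the doubling
time is ``DT = ln(2) / k``.

The replicate-level quality-control pipeline applies three rules, in order:

1. drop wells that never show continuous (weakly monotone) growth spanning
   at least 48 h;
2. drop doubling times outside the Tukey fences
   ``[q1 - 1.5*IQR, q3 + 1.5*IQR]`` of their replicate set, with quartiles
   computed by linear interpolation between order statistics;
3. mark the replicate set invalid when fewer than 3 doubling times remain.

Treated and untreated replicate sets from the same plate and cell line are
compared by the doubling-time change and ratio, by a two-sided Mann-Whitney
U test, and by a two-way (treatment x time) ANOVA on the raw curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    DesignError,
    DomainError,
    MatchingError,
    UndefinedStatisticError,
    ValidityError,
)

LN2 = math.log(2.0)

#: QC flag names attached to fits / recorded as removal reasons.
FLAG_NO_CONTINUOUS_GROWTH = "no_continuous_growth_48h"
FLAG_NONPOSITIVE_RATE = "nonpositive_rate"
FLAG_TOO_FEW_POINTS = "too_few_points"
REASON_IQR = "iqr_outlier"

TRACE_COLUMNS = [
    "plate_id",
    "well_id",
    "line_id",
    "genotype",
    "molecule",
    "concentration_uM",
    "condition",
    "time_h",
    "value",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WellTrace:
    """One well's time series plus plate/line/condition metadata.

    ``times`` are hours from assay start, strictly increasing, with at least
    two points.  ``values`` may be negative only for derived
    (subtractively normalized) traces; raw traces are non-negative.
    """

    plate_id: str
    well_id: str
    line_id: str
    genotype: str
    condition: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    molecule: str = ""
    concentration_uM: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size < 2:
            raise ValueError(f"well {self.well_id}: need >= 2 time points, got {t.size}")
        if v.size != t.size:
            raise ValueError(
                f"well {self.well_id}: times ({t.size}) and values ({v.size}) differ in length"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"well {self.well_id}: times must be strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @property
    def time_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def value_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class GrowthCurveFit:
    """Results of fitting the exponential growth model to one well.

    ``k`` is the OLS slope of ln(value) on time [1/h]; ``dt`` is the doubling
    time ln(2)/k [h], absent when k <= 0 or the fit failed.  ``qc_flags``
    records quality problems; the replicate pipeline uses them as removal
    reasons.
    """

    well_id: str
    plate_id: str
    line_id: str
    genotype: str
    condition: str
    molecule: str
    k: float | None
    dt: float | None
    log_n0: float | None
    n_points_used: int
    fit_window: tuple[float, float] | None
    qc_flags: frozenset[str] = frozenset()
    r_squared: float | None = None
    k_stderr: float | None = None

    @property
    def usable(self) -> bool:
        """True when the well produced a positive growth rate and passes QC."""
        return self.dt is not None and not self.qc_flags

    def summary(self) -> str:
        lines = [
            f"Exponential growth fit: well {self.well_id} "
            f"({self.line_id} {self.genotype}, {self.condition})",
            f"  points used : {self.n_points_used}"
            + (f" over {self.fit_window[0]:g}-{self.fit_window[1]:g} h" if self.fit_window else ""),
        ]
        if self.k is not None:
            se = f" (SE {self.k_stderr:.3g})" if self.k_stderr is not None else ""
            lines.append(f"  growth rate : k = {self.k:.6g} /h{se}")
        if self.dt is not None:
            lines.append(f"  doubling    : DT = {self.dt:.4g} h")
        if self.r_squared is not None:
            lines.append(f"  R-squared   : {self.r_squared:.4f}")
        if self.qc_flags:
            lines.append(f"  QC flags    : {', '.join(sorted(self.qc_flags))}")
        return "\n".join(lines)


class GrowthCurveModel:
    """Log-linear exponential growth model for a single well trace.

    Parameters
    ----------
    trace
        The well trace to fit.
    window
        Optional ``(start_h, end_h)`` restricting the points used.
    min_span_h
        Span of weakly monotone growth required by QC rule 1 (default 48 h).
    """

    def __init__(
        self,
        trace: WellTrace,
        window: tuple[float, float] | None = None,
        min_span_h: float = 48.0,
    ) -> None:
        self.trace = trace
        self.window = window
        self.min_span_h = min_span_h
        if window is not None:
            lo, hi = window
            if lo > hi:
                raise ValueError(f"window start {lo} exceeds end {hi}")
            if lo < trace.times[0] or hi > trace.times[-1]:
                raise ValueError(
                    f"window {window} outside trace span "
                    f"({trace.times[0]}, {trace.times[-1]})"
                )

    def fit(self) -> GrowthCurveFit:
        tr = self.trace
        t = tr.time_array
        v = tr.value_array
        mask = np.ones(t.size, dtype=bool)
        if self.window is not None:
            lo, hi = self.window
            mask &= (t >= lo) & (t <= hi)
        # non-positive values are dropped before the log transform, not floored
        mask &= v > 0
        qc: set[str] = set()
        if not has_continuous_growth(tr, self.min_span_h):
            qc.add(FLAG_NO_CONTINUOUS_GROWTH)

        meta = dict(
            well_id=tr.well_id,
            plate_id=tr.plate_id,
            line_id=tr.line_id,
            genotype=tr.genotype,
            condition=tr.condition,
            molecule=tr.molecule,
        )
        n_used = int(mask.sum())
        if n_used < 2:
            qc.add(FLAG_TOO_FEW_POINTS)
            return GrowthCurveFit(
                **meta,
                k=None,
                dt=None,
                log_n0=None,
                n_points_used=n_used,
                fit_window=self.window,
                qc_flags=frozenset(qc),
            )
        tt = t[mask]
        ln_v = np.log(v[mask])
        window = self.window or (float(tt[0]), float(tt[-1]))
        if np.all(v[mask] == v[mask][0]):
            # flat trace: slope is exactly zero, not a float-noise residue
            k, intercept = 0.0, float(ln_v[0])
            r2: float | None = None
            k_se: float | None = None
        else:
            k, intercept = (float(c) for c in np.polyfit(tt, ln_v, 1))
            resid = ln_v - (k * tt + intercept)
            ss_res = float(resid @ resid)
            ss_tot = float(((ln_v - ln_v.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
            sxx = float(((tt - tt.mean()) ** 2).sum())
            k_se = (
                math.sqrt(ss_res / (n_used - 2) / sxx) if n_used > 2 and sxx > 0 else None
            )
        if k <= 0:
            qc.add(FLAG_NONPOSITIVE_RATE)
            dt = None
        else:
            dt = LN2 / k
        return GrowthCurveFit(
            **meta,
            k=k,
            dt=dt,
            log_n0=intercept,
            n_points_used=n_used,
            fit_window=window,
            qc_flags=frozenset(qc),
            r_squared=r2,
            k_stderr=k_se,
        )


@dataclass
class ReplicateSummary:
    """Doubling times for one plate x line x condition replicate set after QC.

    ``removed`` pairs each removed well id with the rule that removed it;
    ``valid`` is True iff at least ``min_replicates`` doubling times survive.
    """

    plate_id: str
    line_id: str
    condition: str
    molecule: str
    dts_raw: list[float]
    dts_kept: list[float]
    kept_ids: list[str]
    removed: list[tuple[str, str]]
    valid: bool
    genotype: str = ""

    @property
    def mean_dt(self) -> float | None:
        return float(np.mean(self.dts_kept)) if self.dts_kept else None


@dataclass(frozen=True)
class DtComparison:
    """Within-plate treated-vs-untreated doubling-time contrast for one line."""

    line_id: str
    plate_id: str
    genotype: str
    molecule: str
    dt_change: float  # treated mean - untreated mean, hours
    dt_ratio: float  # treated mean / untreated mean
    untreated_dt: float
    treated_dt: float


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def doubling_time(k: float) -> float:
    """Doubling time ln(2)/k for a positive exponential growth rate ``k`` [1/h]."""
    if k <= 0:
        raise DomainError(f"doubling time undefined for non-positive growth rate k={k}")
    return LN2 / k


def fit_growth_rate(
    trace: WellTrace,
    window: tuple[float, float] | None = None,
    min_span_h: float = 48.0,
) -> GrowthCurveFit:
    """Fit the log-linear growth model to one trace (see GrowthCurveModel)."""
    return GrowthCurveModel(trace, window=window, min_span_h=min_span_h).fit()


def has_continuous_growth(trace: WellTrace, min_span_h: float = 48.0) -> bool:
    """True iff some contiguous weakly increasing run spans >= ``min_span_h``.

    A run is a maximal stretch of consecutive time points in which each
    successive value is >= the previous one; the span is measured between the
    run's first and last time points, bound inclusive.
    """
    t = trace.time_array
    v = trace.value_array
    start = 0
    for i in range(1, v.size):
        if v[i] < v[i - 1]:
            start = i
        if t[i] - t[start] >= min_span_h:
            return True
    return False


def iqr_outlier_filter(dts: Sequence[float]) -> tuple[list[float], list[float]]:
    """Tukey fence filter with linear-interpolation sample quartiles.

    Values strictly below ``q1 - 1.5*IQR`` or strictly above ``q3 + 1.5*IQR``
    are removed; values exactly at a fence are kept.  Input order of the kept
    values is preserved.
    """
    arr = np.asarray(list(dts), dtype=float)
    if arr.size == 0:
        raise ValueError("iqr_outlier_filter requires a non-empty input")
    q1, q3 = np.percentile(arr, [25.0, 75.0])  # linear interpolation (default)
    iqr = q3 - q1
    lo = q1 - 1.5 * iqr
    hi = q3 + 1.5 * iqr
    kept = [float(x) for x in arr if lo <= x <= hi]
    removed = [float(x) for x in arr if x < lo or x > hi]
    return kept, removed


def normalize_subtractive(
    treated: Iterable[WellTrace], untreated: Iterable[WellTrace]
) -> list[WellTrace]:
    """Per-timepoint subtraction of the matched untreated mean from treated wells.

    Each treated well is matched to the untreated wells that share its plate
    and cell line; the derived trace's value at time t is the treated value
    minus the mean untreated value at t.  Original traces are not modified.
    """
    groups: dict[tuple[str, str], list[WellTrace]] = {}
    for tr in untreated:
        groups.setdefault((tr.plate_id, tr.line_id), []).append(tr)
    out: list[WellTrace] = []
    for tr in treated:
        key = (tr.plate_id, tr.line_id)
        if key not in groups:
            raise MatchingError(
                f"no untreated wells for plate={tr.plate_id!r} line={tr.line_id!r}"
            )
        ref = groups[key]
        for u in ref:
            if u.times != tr.times:
                raise AlignmentError(
                    f"time grids differ between treated well {tr.well_id} "
                    f"and untreated well {u.well_id}"
                )
        ref_mean = np.mean([u.value_array for u in ref], axis=0)
        out.append(
            replace(
                tr,
                well_id=f"{tr.well_id}__norm",
                values=tuple(tr.value_array - ref_mean),
            )
        )
    return out


def apply_outlier_pipeline(
    fits: Iterable[GrowthCurveFit], min_replicates: int = 3
) -> list[ReplicateSummary]:
    """Apply the three QC rules, in order, within each replicate set.

    Replicate sets are plate x line x condition x molecule groups.  Rule 1
    removes wells flagged ``no_continuous_growth_48h`` (wells with no usable
    doubling time — too few positive points or a non-positive rate — are
    likewise removed here, recorded under their own flag).  Rule 2 applies
    the Tukey IQR filter to the surviving doubling times.  Rule 3 marks the
    summary invalid when fewer than ``min_replicates`` doubling times remain.
    """
    grouped: dict[tuple[str, str, str, str], list[GrowthCurveFit]] = {}
    for f in fits:
        grouped.setdefault((f.plate_id, f.line_id, f.condition, f.molecule), []).append(f)
    summaries: list[ReplicateSummary] = []
    for (plate, line, condition, molecule), group in grouped.items():
        dts_raw = [f.dt for f in group if f.dt is not None]
        removed: list[tuple[str, str]] = []
        survivors: list[GrowthCurveFit] = []
        for f in group:  # rule 1 (+ wells with no doubling time)
            if FLAG_NO_CONTINUOUS_GROWTH in f.qc_flags:
                removed.append((f.well_id, FLAG_NO_CONTINUOUS_GROWTH))
            elif FLAG_TOO_FEW_POINTS in f.qc_flags or f.dt is None:
                reason = (
                    FLAG_TOO_FEW_POINTS
                    if FLAG_TOO_FEW_POINTS in f.qc_flags
                    else FLAG_NONPOSITIVE_RATE
                )
                removed.append((f.well_id, reason))
            else:
                survivors.append(f)
        if survivors:  # rule 2
            kept_dts, _ = iqr_outlier_filter([f.dt for f in survivors])
            kept: list[GrowthCurveFit] = []
            budget = list(kept_dts)
            for f in survivors:
                if f.dt in budget:
                    budget.remove(f.dt)
                    kept.append(f)
                else:
                    removed.append((f.well_id, REASON_IQR))
        else:
            kept = []
        valid = len(kept) >= min_replicates  # rule 3
        summaries.append(
            ReplicateSummary(
                plate_id=plate,
                line_id=line,
                condition=condition,
                molecule=molecule,
                genotype=group[0].genotype if group else "",
                dts_raw=[float(d) for d in dts_raw],
                dts_kept=[float(f.dt) for f in kept],
                kept_ids=[f.well_id for f in kept],
                removed=removed,
                valid=valid,
            )
        )
    return summaries


def dt_comparison(treated: ReplicateSummary, untreated: ReplicateSummary) -> DtComparison:
    """Doubling-time change and ratio between matched replicate summaries.

    Both summaries must be valid and come from the same plate and line
    (within-plate comparison); otherwise the comparison is refused.
    """
    if not treated.valid or not untreated.valid:
        bad = treated if not treated.valid else untreated
        raise ValidityError(
            f"replicate summary {bad.plate_id}/{bad.line_id}/{bad.condition} is invalid "
            f"(fewer than the minimum kept doubling times)"
        )
    if (treated.plate_id, treated.line_id) != (untreated.plate_id, untreated.line_id):
        raise ValidityError(
            "dt_comparison requires summaries from the same plate and line; got "
            f"{treated.plate_id}/{treated.line_id} vs {untreated.plate_id}/{untreated.line_id}"
        )
    mt = treated.mean_dt
    mu = untreated.mean_dt
    assert mt is not None and mu is not None
    return DtComparison(
        line_id=treated.line_id,
        plate_id=treated.plate_id,
        genotype=treated.genotype or untreated.genotype,
        molecule=treated.molecule,
        dt_change=mt - mu,
        dt_ratio=mt / mu,
        untreated_dt=mu,
        treated_dt=mt,
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def mann_whitney_two_sided(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    The p-value is exact (full enumeration) when both samples have at most
    8 observations and there are no ties; otherwise it comes from the
    tie-corrected normal approximation with a continuity correction that
    shrinks |U - mean| toward zero (so identical samples give p = 1).
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise DomainError("Mann-Whitney test requires two non-empty samples")
    combined = np.concatenate([xa, ya])
    no_ties = np.unique(combined).size == combined.size
    if no_ties and xa.size <= 8 and ya.size <= 8:
        res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    n, m = xa.size, ya.size
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    mu = n * m / 2.0
    nn = n + m
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (nn * (nn - 1)))
    sigma2 = n * m / 12.0 * ((nn + 1) - tie_term)
    if sigma2 <= 0:
        return u1, 1.0  # all observations identical
    num = u1 - mu
    num = math.copysign(max(abs(num) - 0.5, 0.0), num)  # continuity correction
    z = num / math.sqrt(sigma2)
    return u1, min(1.0, 2.0 * float(stats.norm.sf(abs(z))))


def ratio_vs_untreated_correlation(
    comparisons: Sequence[DtComparison],
) -> tuple[float, float, float]:
    """Pearson correlation of the treated/untreated DT ratio against untreated DT.

    Returns (r, r^2, two-sided p from the t distribution with n-2 df).  A
    negative r means treatment shortens doubling times more in slower-growing
    lines.
    """
    if len(comparisons) < 3:
        raise DesignError("correlation requires at least 3 comparisons")
    xs = np.array([c.untreated_dt for c in comparisons], dtype=float)
    ys = np.array([c.dt_ratio for c in comparisons], dtype=float)
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise UndefinedStatisticError("correlation undefined: a variable has zero variance")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(r) ** 2, float(p)


def growth_curve_anova(traces: Sequence[WellTrace]) -> tuple[float, float]:
    """Two-way fixed-effects ANOVA (treatment x time) on well values.

    All traces must come from one line/plate replicate set with a shared
    time grid and at least two wells per condition.  Returns the F statistic
    and p-value of the treatment main effect (type II sums of squares).
    """
    import statsmodels.api as sm  # deferred: heavy import
    import statsmodels.formula.api as smf

    conditions = {tr.condition for tr in traces}
    if len(conditions) < 2:
        raise DesignError(f"two-way ANOVA needs both conditions; got {sorted(conditions)}")
    counts = {c: sum(1 for tr in traces if tr.condition == c) for c in conditions}
    if min(counts.values()) < 2:
        raise DesignError(f"need >= 2 wells per condition; got {counts}")
    grids = {tr.times for tr in traces}
    if len(grids) != 1:
        raise AlignmentError("traces must share one time grid for the ANOVA")
    rows = [
        {"value": val, "condition": tr.condition, "time_h": t}
        for tr in traces
        for t, val in zip(tr.times, tr.values)
    ]
    df = pd.DataFrame(rows)
    fit = smf.ols("value ~ C(condition) * C(time_h)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(condition)"]
    return float(row["F"]), float(row["PR(>F)"])


def passage_recovery_ratio(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> list[float]:
    """Elementwise ratio of per-day cell counts under two passaging protocols."""
    a = np.asarray(list(counts_a), dtype=float)
    b = np.asarray(list(counts_b), dtype=float)
    if a.size != b.size:
        raise DomainError(f"count vectors differ in length: {a.size} vs {b.size}")
    if np.any(b <= 0):
        raise DomainError("denominator counts must be strictly positive")
    return [float(r) for r in a / b]


# ---------------------------------------------------------------------------
# experiment-level model
# ---------------------------------------------------------------------------


@dataclass
class GrowthExperimentResults:
    """Fits, replicate summaries and treated-vs-untreated contrasts for a run."""

    fits: list[GrowthCurveFit]
    summaries: list[ReplicateSummary]
    comparisons: list[DtComparison]
    skipped_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def mean_dt_change(self, genotype: str | None = None) -> float | None:
        vals = [
            c.dt_change for c in self.comparisons if genotype is None or c.genotype == genotype
        ]
        return float(np.mean(vals)) if vals else None

    def dt_changes(self, genotype: str) -> list[float]:
        return [c.dt_change for c in self.comparisons if c.genotype == genotype]

    def mann_whitney_by_genotype(
        self, genotype_a: str = "T21", genotype_b: str = "Eup"
    ) -> tuple[float, float]:
        """Compare DT changes between genotypes (e.g. trisomic vs euploid)."""
        return mann_whitney_two_sided(self.dt_changes(genotype_a), self.dt_changes(genotype_b))

    def ratio_correlation(self, genotype: str) -> tuple[float, float, float]:
        comps = [c for c in self.comparisons if c.genotype == genotype]
        return ratio_vs_untreated_correlation(comps)

    def fits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well_id": f.well_id,
                    "plate_id": f.plate_id,
                    "line_id": f.line_id,
                    "genotype": f.genotype,
                    "condition": f.condition,
                    "molecule": f.molecule,
                    "k_per_h": f.k,
                    "dt_h": f.dt,
                    "n_points_used": f.n_points_used,
                    "r_squared": f.r_squared,
                    "qc_flags": ";".join(sorted(f.qc_flags)),
                }
                for f in self.fits
            ]
        )

    def summaries_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plate_id": s.plate_id,
                    "line_id": s.line_id,
                    "genotype": s.genotype,
                    "condition": s.condition,
                    "molecule": s.molecule,
                    "n_raw": len(s.dts_raw),
                    "n_kept": len(s.dts_kept),
                    "mean_dt_h": s.mean_dt,
                    "removed": ";".join(f"{w}:{r}" for w, r in s.removed),
                    "valid": s.valid,
                }
                for s in self.summaries
            ]
        )

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "line_id": c.line_id,
                    "plate_id": c.plate_id,
                    "genotype": c.genotype,
                    "molecule": c.molecule,
                    "untreated_dt_h": c.untreated_dt,
                    "treated_dt_h": c.treated_dt,
                    "dt_change_h": c.dt_change,
                    "dt_ratio": c.dt_ratio,
                }
                for c in self.comparisons
            ]
        )

    def summary(self) -> str:
        lines = [
            "Growth experiment summary",
            f"  wells fitted        : {len(self.fits)}",
            f"  replicate sets      : {len(self.summaries)} "
            f"({sum(s.valid for s in self.summaries)} valid)",
            f"  paired comparisons  : {len(self.comparisons)}",
        ]
        for gt in sorted({c.genotype for c in self.comparisons}):
            changes = self.dt_changes(gt)
            lines.append(
                f"  {gt:>4}: mean DT change {np.mean(changes):+.2f} h "
                f"(SD {np.std(changes, ddof=1) if len(changes) > 1 else 0.0:.2f}, "
                f"n={len(changes)})"
            )
        return "\n".join(lines)


class GrowthExperiment:
    """Whole-plate growth analysis: fit wells, apply QC, pair the conditions.

    Built from well traces (or a long-format DataFrame); ``fit()`` runs the
    per-well model, the three-rule outlier pipeline and the within-plate
    treated-vs-untreated doubling-time comparisons, and returns a
    :class:`GrowthExperimentResults`.
    """

    def __init__(
        self,
        traces: Sequence[WellTrace],
        min_span_h: float = 48.0,
        min_replicates: int = 3,
        fit_start_h: float = 0.0,
    ) -> None:
        if not traces:
            raise ValueError("GrowthExperiment needs at least one trace")
        self.traces = list(traces)
        self.min_span_h = float(min_span_h)
        self.min_replicates = int(min_replicates)
        self.fit_start_h = float(fit_start_h)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GrowthExperiment":
        return cls(traces_from_dataframe(df), **kwargs)

    def fit(self) -> GrowthExperimentResults:
        fits = []
        for tr in self.traces:
            window = None
            if self.fit_start_h > tr.times[0]:
                window = (self.fit_start_h, tr.times[-1])
            fits.append(fit_growth_rate(tr, window=window, min_span_h=self.min_span_h))
        summaries = apply_outlier_pipeline(fits, min_replicates=self.min_replicates)
        by_key = {
            (s.plate_id, s.line_id, s.condition): s for s in summaries
        }
        comparisons: list[DtComparison] = []
        skipped: list[tuple[str, str, str]] = []
        for (plate, line, condition), s in sorted(by_key.items()):
            if condition != "treated":
                continue
            u = by_key.get((plate, line, "untreated"))
            if u is None:
                skipped.append((plate, line, "no untreated summary"))
                continue
            if not (s.valid and u.valid):
                skipped.append((plate, line, "invalid replicate summary"))
                continue
            comparisons.append(dt_comparison(s, u))
        return GrowthExperimentResults(
            fits=fits, summaries=summaries, comparisons=comparisons, skipped_pairs=skipped
        )


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------


def traces_from_dataframe(
    df: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> list[WellTrace]:
    """Build WellTrace objects from a long-format table.

    Expected columns: plate_id, well_id, line_id, genotype, molecule,
    concentration_uM, condition, time_h, value (rename via ``column_map``,
    mapping canonical name -> actual column).  Raw values must be
    non-negative.
    """
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in TRACE_COLUMNS if c not in df.columns and c not in ("molecule", "concentration_uM")]
    if missing:
        raise AlignmentError(
            f"trace table is missing columns {missing}; available: {list(df.columns)}"
        )
    traces: list[WellTrace] = []
    keys = ["plate_id", "well_id", "line_id", "genotype", "condition"]
    for meta, sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("time_h")
        values = sub["value"].to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError(f"well {meta[1]}: raw trace values must be non-negative")
        molecule = str(sub["molecule"].iloc[0]) if "molecule" in sub else ""
        if molecule in ("nan", "None"):
            molecule = ""
        conc = None
        if "concentration_uM" in sub:
            raw = sub["concentration_uM"].iloc[0]
            conc = None if pd.isna(raw) or raw == "" else float(raw)
        traces.append(
            WellTrace(
                plate_id=str(meta[0]),
                well_id=str(meta[1]),
                line_id=str(meta[2]),
                genotype=str(meta[3]),
                condition=str(meta[4]),
                times=tuple(sub["time_h"].to_numpy(dtype=float)),
                values=tuple(values),
                molecule=molecule,
                concentration_uM=conc,
            )
        )
    return traces


def traces_to_dataframe(traces: Iterable[WellTrace]) -> pd.DataFrame:
    rows = [
        {
            "plate_id": tr.plate_id,
            "well_id": tr.well_id,
            "line_id": tr.line_id,
            "genotype": tr.genotype,
            "molecule": tr.molecule,
            "concentration_uM": "" if tr.concentration_uM is None else tr.concentration_uM,
            "condition": tr.condition,
            "time_h": t,
            "value": v,
        }
        for tr in traces
        for t, v in zip(tr.times, tr.values)
    ]
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def read_traces_csv(path, column_map: Mapping[str, str] | None = None) -> list[WellTrace]:
    return traces_from_dataframe(pd.read_csv(path), column_map=column_map)


def write_traces_csv(traces: Iterable[WellTrace], path) -> None:
    traces_to_dataframe(traces).to_csv(path, index=False)


def plot_growth_curves(traces: Sequence[WellTrace], ax=None, log_scale: bool = True):
    """Plot well traces (treated solid, untreated dashed); returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for tr in traces:
        style = "-" if tr.condition == "treated" else "--"
        ax.plot(tr.times, tr.values, style, alpha=0.7, label=f"{tr.well_id}")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("object sum area (a.u.)")
    if log_scale:
        ax.set_yscale("log")
    return ax
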