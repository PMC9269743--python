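"""Statistical certification of a synthetic day-set against its real
counterpart.

A generated cohort is accepted only when its per-day clinical outcome
distributions are indistinguishable from the real patient's: the time spent
in the standard glycemic bands (level-2 hypoglycemia below 54 mg/dL,
level-1 in [54, 70), time-in-range [70, 180), hyperglycemia at or above
180) and the per-day mean glucose are each compared with a Wilcoxon
rank-sum test, and the model is accepted when every p-value is at or above
the significance level (default 0.05), i.e. when no metric shows a
detectable difference.

The battery also reports the Jensen-Shannon distance between the pooled
glucose histograms,

    JSd(P, Q) = sqrt((D(P||M) + D(Q||M)) / 2),   M = (P + Q) / 2,

with base-2 logarithms so the distance lies in [0, 1]; per-day JS heatmaps
(to show the generator does not copy training days); and a two-sample
Z statistic on per-day means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cgm_io import GLUCOSE_MAX, GLUCOSE_MIN, DayMatrix

__all__ = [
    "RangeThresholds",
    "GlycemicSummary",
    "ProbabilityHistogram",
    "ComparisonReport",
    "range_fractions",
    "summary_stats",
    "glucose_histogram",
    "js_distance",
    "js_heatmap",
    "wilcoxon_acceptance",
    "z_test",
    "METRIC_NAMES",
]

METRIC_NAMES = ("hyper", "tir", "l1", "l2", "mean")


@dataclass(frozen=True)
class RangeThresholds:
    """Glycemic band boundaries (mg/dL); bands are half-open.

    L2 hypo = [40, 54), L1 hypo = [54, 70), TIR = [70, 180),
    hyperglycemia = [180, 400].
    """

    l2_upper: float = 54.0
    l1_upper: float = 70.0
    tir_upper: float = 180.0

    def __post_init__(self):
        if not (self.l2_upper < self.l1_upper < self.tir_upper):
            raise ValueError("thresholds must satisfy l2 < l1 < tir")


@dataclass
class GlycemicSummary:
    """Per-day-set clinical summary: band percentages and glucose moments."""

    hyper_pct: float
    tir_pct: float
    l1_pct: float
    l2_pct: float
    mean: float
    sd: float
    variance: float


@dataclass
class ProbabilityHistogram:
    bin_edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.bin_edges) != len(self.masses) + 1:
            raise ValueError("need len(bin_edges) == len(masses) + 1")
        if (self.masses < 0).any():
            raise ValueError("masses must be non-negative")
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise ValueError("masses must sum to 1")


@dataclass
class ComparisonReport:
    p_values: dict
    js: float
    z_value: float
    variance_real: float
    variance_synth: float
    accepted: bool
    alpha: float = 0.05
    n_days: int = 0
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "js_distance": float(self.js),
            "z_value": float(self.z_value),
            "variance_real": float(self.variance_real),
            "variance_synth": float(self.variance_synth),
            "accepted": bool(self.accepted),
            "alpha": float(self.alpha),
            "n_days": int(self.n_days),
        }


def _require_nonempty(days: DayMatrix) -> np.ndarray:
    rows = days.rows
    if rows.size == 0:
        raise ValueError("day matrix is empty: metrics undefined")
    return rows


def range_fractions(days: DayMatrix,
                    thresholds: RangeThresholds = RangeThresholds()
                    ) -> tuple[float, float, float, float]:
    """Percent of all samples in (hyper, TIR, L1, L2); sums to 100."""
    x = _require_nonempty(days).ravel()
    t = thresholds
    l2 = float(np.mean(x < t.l2_upper)) * 100.0
    l1 = float(np.mean((x >= t.l2_upper) & (x < t.l1_upper))) * 100.0
    tir = float(np.mean((x >= t.l1_upper) & (x < t.tir_upper))) * 100.0
    hyper = float(np.mean(x >= t.tir_upper)) * 100.0
    return hyper, tir, l1, l2


def summary_stats(days: DayMatrix,
                  thresholds: RangeThresholds = RangeThresholds()) -> GlycemicSummary:
    """Band percentages plus mean/SD/variance over all samples.

    SD uses the population convention (ddof=0) so sd**2 == variance exactly.
    """
    x = _require_nonempty(days).ravel()
    hyper, tir, l1, l2 = range_fractions(days, thresholds)
    var = float(np.var(x))
    return GlycemicSummary(hyper, tir, l1, l2, float(np.mean(x)),
                           float(np.sqrt(var)), var)


def glucose_histogram(days: DayMatrix, bin_width: float = 10.0) -> ProbabilityHistogram:
    """Normalized histogram of all samples over the fixed support [40, 400]."""
    return _histogram_of(_require_nonempty(days).ravel(), bin_width)


def _histogram_of(values: np.ndarray, bin_width: float) -> ProbabilityHistogram:
    span = GLUCOSE_MAX - GLUCOSE_MIN
    n_bins = span / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide the support {span}")
    edges = GLUCOSE_MIN + bin_width * np.arange(int(round(n_bins)) + 1)
    counts, _ = np.histogram(values, bins=edges)
    return ProbabilityHistogram(edges, counts / counts.sum())


def js_distance(p: ProbabilityHistogram, q: ProbabilityHistogram) -> float:
    """Jensen-Shannon distance (base 2) between two aligned histograms.

    Zero-mass bins contribute nothing to their own KL sum; the mixture is
    positive wherever either input is, so every term is finite.
    """
    if p.bin_edges.shape != q.bin_edges.shape or not np.allclose(p.bin_edges, q.bin_edges):
        raise ValueError("histograms must share bin edges")
    return _js_from_masses(p.masses, q.masses)


def _js_from_masses(pm: np.ndarray, qm: np.ndarray) -> float:
    m = 0.5 * (pm + qm)
    div = 0.0
    for a in (pm, qm):
        nz = a > 0
        div += 0.5 * float(np.sum(a[nz] * np.log2(a[nz] / m[nz])))
    # guard tiny negative round-off
    return float(np.sqrt(max(div, 0.0)))


def js_heatmap(set_a: DayMatrix, set_b: DayMatrix, bin_width: float = 10.0) -> np.ndarray:
    """Pairwise day-vs-day JS distances; entry (i, j) compares a-day i with b-day j."""
    a = _require_nonempty(set_a)
    b = _require_nonempty(set_b)
    ha = np.vstack([_histogram_of(row, bin_width).masses for row in a])
    hb = np.vstack([_histogram_of(row, bin_width).masses for row in b])
    out = np.empty((len(ha), len(hb)))
    for i in range(len(ha)):
        for j in range(len(hb)):
            out[i, j] = _js_from_masses(ha[i], hb[j])
    return out


def per_day_metrics(days: DayMatrix,
                    thresholds: RangeThresholds = RangeThresholds()) -> dict:
    """Per-day metric vectors: band fractions (of the day's 288 samples) and day mean."""
    rows = _require_nonempty(days)
    t = thresholds
    return {
        "hyper": np.mean(rows >= t.tir_upper, axis=1),
        "tir": np.mean((rows >= t.l1_upper) & (rows < t.tir_upper), axis=1),
        "l1": np.mean((rows >= t.l2_upper) & (rows < t.l1_upper), axis=1),
        "l2": np.mean(rows < t.l2_upper, axis=1),
        "mean": rows.mean(axis=1),
    }


def z_test(real: DayMatrix, synth: DayMatrix) -> float:
    """Two-sample Z statistic on per-day mean glucose (absolute value)."""
    mr = _require_nonempty(real).mean(axis=1)
    ms = _require_nonempty(synth).mean(axis=1)
    if len(mr) < 2 or len(ms) < 2:
        raise ValueError("z_test needs at least two days per set")
    se = np.sqrt(mr.var(ddof=1) / len(mr) + ms.var(ddof=1) / len(ms))
    if se == 0.0:
        return 0.0
    return float(abs(mr.mean() - ms.mean()) / se)


def wilcoxon_acceptance(real: DayMatrix, synth: DayMatrix, alpha: float = 0.05,
                        seed: int = 0, bin_width: float = 10.0,
                        thresholds: RangeThresholds = RangeThresholds(),
                        paired: bool = False) -> ComparisonReport:
    """Accept the synthetic day-set when no per-day metric differs.

    ``len(real)`` synthetic rows are subsampled (seeded, without
    replacement) so both groups have equal size; for each of the five
    per-day metrics a Wilcoxon test yields a p-value, and the set is
    accepted iff every p-value is at or above ``alpha``.  The default is
    the unpaired rank-sum test — real and synthetic days have no natural
    pairing; ``paired=True`` switches to the signed-rank test on
    order-statistics-matched samples.
    """
    r = _require_nonempty(real)
    s = _require_nonempty(synth)
    if len(s) < len(r):
        raise ValueError(f"need at least {len(r)} synthetic rows, got {len(s)}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(s), size=len(r), replace=False)
    sub = DayMatrix(synth.patient_id, s[pick], anchor_hour=synth.anchor_hour,
                    provenance=synth.provenance)

    mr = per_day_metrics(real, thresholds)
    ms = per_day_metrics(sub, thresholds)
    p_values = {}
    for name in METRIC_NAMES:
        a, b = mr[name], ms[name]
        if np.array_equal(a, b):
            p = 1.0
        elif paired:
            diff = np.sort(a) - np.sort(b)
            p = 1.0 if not diff.any() else float(stats.wilcoxon(diff).pvalue)
        else:
            p = float(stats.ranksums(a, b).pvalue)
        p_values[name] = p

    js = js_distance(glucose_histogram(real, bin_width),
                     glucose_histogram(sub, bin_width))
    accepted = all(p >= alpha for p in p_values.values())
    return ComparisonReport(
        p_values=p_values, js=js, z_value=z_test(real, sub),
        variance_real=float(r.var()), variance_synth=float(sub.rows.var()),
        accepted=accepted, alpha=alpha, n_days=len(r),
    )
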