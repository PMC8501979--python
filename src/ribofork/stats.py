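"""Incorporation-rate statistics.

Core model: for libraries i = 1..N sharing a genotype and capture
technique, the leading- and lagging-strand rNMP tallies are

    X_i ~ Poisson(r_i * a * L),    Y_i ~ Poisson(r_i * b * L)

with per-nucleotide incorporation rates a (leading) and b (lagging),
library capture rates r_i and genome length L.  The maximum-likelihood
estimate of the leading/lagging ratio theta = a/b is the closed form
sum(X_i) / sum(Y_i), independent of the (unknown) r_i.

Also here: RPB/PPB rate measures, the binned ratio series and its
"changing phase" (the extent of the Pol delta -> Pol epsilon handoff,
read off as the bin of extreme slope from the origin), log-ratio
regressions against firing time or efficiency, and the one-sided
Mann-Whitney U test used for leading-vs-lagging comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .ars import ARSRecord, FlankConfig, FlankRegion, bin_flank, pair_flanks
from .io import LAGGING, LEADING, RNMPLibrary, count_sites

PHASE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class RateMeasure:
    """rNMPs-per-base (RPB) and probability-per-base (PPB) of a region."""

    count: int
    region_size: int
    library_total: int
    rpb: float
    ppb: float


@dataclass
class RatioEstimate:
    """MLE of the leading/lagging incorporation ratio from pooled counts."""

    leading_counts: list[int]
    lagging_counts: list[int]
    theta: float  # inf when lagging total is 0; nan when both are 0
    rate_leading: float | None = None  # a, per nt (needs r_i and L)
    rate_lagging: float | None = None  # b, per nt
    capture_rates: list[float] | None = None
    genome_length: int | None = None

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.theta)


@dataclass
class ChangingPhase:
    """Extent of the ratio's initial rise/fall out from the origin."""

    bin_series: list[tuple[int, float]]
    baseline: float
    end_bin: int
    extent: int  # nt; end_bin * bin_size
    direction: str  # "increase" | "decrease" | "none"


@dataclass
class RegressionResult:
    """OLS fit of per-origin log ratios on firing time or efficiency."""

    slope: float
    intercept: float
    n_points: int
    predictor: str
    stderr: float
    r_value: float
    n_excluded: int = 0
    log_base: float = math.e


# ---------------------------------------------------------------------------
# rates


def compute_ppb(count: int, region_size: int, library_total: int) -> RateMeasure:
    """RPB = count / region size; PPB = RPB / library total."""
    if region_size <= 0:
        raise ValueError("region_size must be > 0")
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    rpb = count / region_size
    return RateMeasure(count, region_size, library_total, rpb, rpb / library_total)


# ---------------------------------------------------------------------------
# ratio estimation


def estimate_ratio(
    X: Sequence[int],
    Y: Sequence[int],
    capture_rates: Sequence[float] | None = None,
    genome_length: int | None = None,
) -> RatioEstimate:
    """Pooled-count MLE theta = sum(X)/sum(Y).

    With known capture rates and genome length (synthetic data) the
    absolute rates a = sum(X)/(L sum(r)) and b = sum(Y)/(L sum(r)) are
    also filled in.
    """
    if len(X) != len(Y) or len(X) == 0:
        raise ValueError("X and Y must be non-empty and of equal length")
    sx, sy = int(sum(X)), int(sum(Y))
    if sy > 0:
        theta = sx / sy
    elif sx > 0:
        theta = math.inf
    else:
        theta = math.nan
    a = b = None
    if capture_rates is not None and genome_length is not None:
        denom = genome_length * float(sum(capture_rates))
        a, b = sx / denom, sy / denom
    return RatioEstimate(list(X), list(Y), theta, a, b,
                         list(capture_rates) if capture_rates else None,
                         genome_length)


def theta_standard_error(estimate: RatioEstimate) -> float:
    """Delta-method SE of theta under the Poisson model."""
    sx, sy = sum(estimate.leading_counts), sum(estimate.lagging_counts)
    if sx == 0 or sy == 0:
        return math.nan
    return estimate.theta * math.sqrt(1.0 / sx + 1.0 / sy)


def _flank_role_counts(
    library: RNMPLibrary, up: FlankRegion | None, down: FlankRegion | None
) -> tuple[int, int]:
    """(leading, lagging) counts of one library over one origin's flanks."""
    lead = lag = 0
    for region in (up, down):
        if region is None or region.length == 0:
            continue
        lead += count_sites(library, region, strand_role=LEADING)
        lag += count_sites(library, region, strand_role=LAGGING)
    return lead, lag


def pooled_flank_counts(
    libraries: Sequence[RNMPLibrary],
    flanks: Sequence[FlankRegion],
    ars_names: set[str] | None = None,
) -> tuple[list[int], list[int]]:
    """Per-library leading/lagging totals over a set of origin flanks."""
    paired = pair_flanks(flanks)
    X, Y = [], []
    for lib in libraries:
        lead = lag = 0
        for name, sides in paired.items():
            if ars_names is not None and name not in ars_names:
                continue
            l_, g_ = _flank_role_counts(lib, sides.get("upstream"),
                                        sides.get("downstream"))
            lead += l_
            lag += g_
        X.append(lead)
        Y.append(lag)
    return X, Y


def leading_percentage(
    library: RNMPLibrary, flanks: Sequence[FlankRegion]
) -> float:
    """Percent of flank rNMPs on the leading strand: 100 X / (X + Y)."""
    if not flanks:
        raise ValueError("flank set is empty")
    X, Y = pooled_flank_counts([library], flanks)
    total = X[0] + Y[0]
    if total == 0:
        return math.nan
    return 100.0 * X[0] / total


def mean_library_ratio(
    libraries: Sequence[RNMPLibrary], flanks: Sequence[FlankRegion]
) -> tuple[float, tuple[float, float], list[float]]:
    """Arithmetic mean of per-library theta with 1.5-IQR whiskers.

    Libraries with zero lagging counts are excluded (with a warning via
    the count: they simply do not appear in the returned per-library
    list).  Returns (mean, (low whisker, high whisker), per-library thetas).
    """
    X, Y = pooled_flank_counts(libraries, flanks)
    thetas = [x / y for x, y in zip(X, Y) if y > 0]
    if not thetas:
        raise ValueError("no library has lagging-strand counts")
    arr = np.asarray(thetas)
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    return float(arr.mean()), (float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)), thetas


# ---------------------------------------------------------------------------
# binned series and changing phase


def binned_ratio_series(
    libraries: Sequence[RNMPLibrary],
    flanks: Sequence[FlankRegion],
    config: FlankConfig = FlankConfig(),
    ars_names: set[str] | None = None,
) -> list[tuple[int, float, float]]:
    """Per-bin pooled theta moving outward from the origin.

    For each bin index k the leading counts of bin k of every flank of
    every origin in the group are pooled across libraries (likewise
    lagging), and theta_k = X_k / Y_k.  The third element is the standard
    deviation of per-library theta_k (nan where undefined).  Bins whose
    pooled lagging count is zero get theta = inf/nan and are skipped by
    phase detection.
    """
    if not libraries:
        raise ValueError("need at least one library")
    paired = pair_flanks(flanks)
    n_bins = math.ceil(config.flank_length / config.bin_size)
    # per-library per-bin tallies
    lead = np.zeros((len(libraries), n_bins), dtype=float)
    lag = np.zeros((len(libraries), n_bins), dtype=float)
    for name, sides in paired.items():
        if ars_names is not None and name not in ars_names:
            continue
        for side_region in sides.values():
            for k, (s, e), _size in bin_flank(side_region, config.bin_size):
                for li, lib in enumerate(libraries):
                    sub = FlankRegion(name, side_region.chrom, side_region.side,
                                      s, e, side_region.anchor)
                    lead[li, k - 1] += count_sites(lib, sub, strand_role=LEADING)
                    lag[li, k - 1] += count_sites(lib, sub, strand_role=LAGGING)
    series: list[tuple[int, float, float]] = []
    for k in range(n_bins):
        sx, sy = lead[:, k].sum(), lag[:, k].sum()
        if sx == 0 and sy == 0:
            continue  # bin beyond every truncated flank
        theta = sx / sy if sy > 0 else math.inf
        per_lib = [
            lead[li, k] / lag[li, k]
            for li in range(len(libraries))
            if lag[li, k] > 0
        ]
        sd = float(np.std(per_lib)) if len(per_lib) > 1 else math.nan
        series.append((k + 1, float(theta), sd))
    return series


def detect_changing_phase(
    series: Sequence[tuple[int, float] | tuple[int, float, float]],
    bin_size: int = 500,
    tolerance: float = PHASE_TOLERANCE,
) -> ChangingPhase:
    """Find the extent of the initial ratio change out from the origin.

    For each bin k >= 2 the slope of the chord from the first bin,
    slope_k = (theta_k - theta_1) / ((k - 1) * bin_size), is computed;
    the phase ends at the *largest* k attaining the extreme slope
    (maximum for a rise, minimum for a fall).  A series whose slopes all
    sit within ``tolerance`` of zero has no phase (extent 0).
    """
    pts = [(int(p[0]), float(p[1])) for p in series if math.isfinite(p[1])]
    if len(pts) < 2:
        raise ValueError("need at least 2 finite bins to detect a phase")
    k1, theta1 = pts[0]
    slopes: list[tuple[int, float]] = []
    for k, theta in pts[1:]:
        slopes.append((k, (theta - theta1) / ((k - k1) * bin_size)))
    max_slope = max(s for _, s in slopes)
    min_slope = min(s for _, s in slopes)
    if max_slope <= tolerance and -min_slope <= tolerance:
        return ChangingPhase([(k, t) for k, t in pts], theta1, 0, 0, "none")
    if -min_slope > max_slope:
        direction, extreme = "decrease", min_slope
    else:
        direction, extreme = "increase", max_slope
    # slopes within the tolerance of the extreme tie; the phase covers the
    # full rise/fall, so the largest such bin wins
    end_bin = max(k for k, s in slopes if abs(s - extreme) <= tolerance)
    return ChangingPhase([(k, t) for k, t in pts], theta1, end_bin,
                         end_bin * bin_size, direction)


# ---------------------------------------------------------------------------
# per-origin log ratios and regression


def per_ars_log_ratio(
    libraries: Sequence[RNMPLibrary],
    flanks: Sequence[FlankRegion],
    ars_name: str,
    log_base: float = math.e,
) -> float | None:
    """log(theta) of one origin from counts pooled across libraries.

    Returns ``None`` (excluded) when either strand has zero pooled
    counts; a log of 0 or infinity would be meaningless in the
    regressions downstream.
    """
    X, Y = pooled_flank_counts(libraries, flanks, ars_names={ars_name})
    sx, sy = sum(X), sum(Y)
    if sx == 0 or sy == 0:
        return None
    return math.log(sx / sy) / math.log(log_base)


def regress_log_ratio(
    points: Sequence[tuple[float, float]],
    predictor: str = "firing_time",
    n_excluded: int = 0,
    log_base: float = math.e,
) -> RegressionResult:
    """Ordinary least squares of per-origin log ratio on a predictor."""
    if len(points) < 2:
        raise ValueError("need at least 2 points for regression")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression design is degenerate")
    fit = sps.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept), len(points),
                            predictor, float(fit.stderr), float(fit.rvalue),
                            n_excluded, log_base)


def slope_confidence_interval(
    result: RegressionResult, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided t confidence interval on the fitted slope."""
    dof = result.n_points - 2
    if dof <= 0:
        return (-math.inf, math.inf)
    tcrit = sps.t.ppf(0.5 + level / 2.0, dof)
    return (result.slope - tcrit * result.stderr,
            result.slope + tcrit * result.stderr)


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney_one_sided(
    xs: Sequence[float], ys: Sequence[float], alternative: str = "less"
) -> float:
    """One-sided Mann-Whitney U p-value.

    ``alternative="less"`` tests whether ``xs`` is shifted lower than
    ``ys``; ``"greater"`` the opposite.  The exact null distribution is
    enumerated for small (n_x + n_y <= 12) tie-free samples; larger or
    tied samples use the tie-corrected normal approximation with
    continuity correction.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    xs = list(xs)
    ys = list(ys)
    if not xs or not ys:
        raise ValueError("both samples must be non-empty")
    if len(set(xs) | set(ys)) == 1:
        # every observation identical: U is degenerate at its mean
        return 0.5
    has_ties = len(set(xs) | set(ys)) < len(xs) + len(ys)
    if len(xs) + len(ys) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(xs, ys, alternative=alternative, method=method,
                           use_continuity=True)
    return float(res.pvalue)
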