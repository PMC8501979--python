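"""Replication-fork rNTP-incorporation rate simulator.

Models the expected per-nucleotide probability of ribonucleotide
incorporation on the nascent leading and lagging strands as a function
of distance from the replication origin, given the division of labor of
the three replicative polymerases:

* leading strand: primed upstream of the origin by Pol alpha, a short
  initial tract synthesized by Pol delta, then bulk synthesis by
  Pol epsilon.  Measured from the origin anchor only the delta and
  epsilon phases are visible.
* lagging strand: Okazaki fragments, each ~10 nt of Pol alpha followed
  by ~160 nt of Pol delta, repeating.

Wild-type incorporation rates are 1/625 (alpha), 1/5000 (delta) and
1/1250 (epsilon) rNMPs per nt; steric-gate mutants multiply their
polymerase's rate (~5x for pol2/epsilon, ~10x for pol3/delta; the pol1
fold change is not established and must be supplied).

Single-origin profiles are deterministic piecewise-constant functions.
The combined profile averages many origins, each with a Normal
annotation jitter of the origin position, a Uniform leading-strand delta
tract length, and a random Okazaki phase, reproducing the smoothed
ramps seen in averaged data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

RATE_ALPHA = 1.0 / 625.0
RATE_DELTA = 1.0 / 5000.0
RATE_EPSILON = 1.0 / 1250.0

GENOTYPES = ("WT", "pol2-M644G", "pol3-L612M", "pol3-L612G",
             "pol1-L868M", "pol1-Y869A")


@dataclass(frozen=True)
class PolymeraseRates:
    """Per-nt rNTP incorporation probabilities of Pol alpha/delta/epsilon."""

    rate_alpha: float = RATE_ALPHA
    rate_delta: float = RATE_DELTA
    rate_epsilon: float = RATE_EPSILON
    pol2_multiplier: float = 5.0   # epsilon steric-gate mutants
    pol3_multiplier: float = 10.0  # delta steric-gate mutants
    pol1_multiplier: float | None = None  # alpha mutants: no published fold

    def __post_init__(self) -> None:
        for r in (self.rate_alpha, self.rate_delta, self.rate_epsilon):
            if not (0.0 < r < 1.0):
                raise ValueError("polymerase rates must lie in (0, 1)")

    def for_genotype(self, genotype: str) -> tuple[float, float, float]:
        """(alpha, delta, epsilon) rates after the genotype multiplier."""
        a, d, e = self.rate_alpha, self.rate_delta, self.rate_epsilon
        if genotype == "WT":
            return a, d, e
        if genotype.startswith("pol2"):
            return a, d, e * self.pol2_multiplier
        if genotype.startswith("pol3"):
            return a, d * self.pol3_multiplier, e
        if genotype.startswith("pol1"):
            if self.pol1_multiplier is None:
                raise ValueError(
                    "pol1 genotypes require an explicit pol1_multiplier"
                )
            return a * self.pol1_multiplier, d, e
        raise ValueError(f"unknown genotype '{genotype}'")


@dataclass(frozen=True)
class TractModel:
    """Lengths of the polymerase synthesis tracts, in nt.

    ``leading_delta_tract`` is the Pol delta segment visible on the
    leading strand downstream of the origin anchor; in combined-origin
    mode it is re-drawn per origin.  The Okazaki period is the alpha
    primer plus the delta extension (10 + 160 = 170 nt by default).
    """

    alpha_tract: int = 10
    delta_okazaki_tract: int = 160
    leading_start_offset: int = 100  # where leading synthesis starts, upstream
    leading_delta_tract: int = 160

    def __post_init__(self) -> None:
        for v in (self.alpha_tract, self.delta_okazaki_tract,
                  self.leading_start_offset, self.leading_delta_tract):
            if v <= 0:
                raise ValueError("tract lengths must be positive")

    @property
    def okazaki_period(self) -> int:
        return self.alpha_tract + self.delta_okazaki_tract


@dataclass(frozen=True)
class CombinedConfig:
    """Monte-Carlo settings for the combined (averaged) origin profile."""

    n_ars: int = 400
    anchor_jitter_sd: float = 1000.0
    delta_tract_range: tuple[float, float] = (500.0, 4000.0)
    seed: int = 0
    randomize_phase: bool = True  # Okazaki phase per origin

    def __post_init__(self) -> None:
        if self.n_ars < 1:
            raise ValueError("n_ars must be >= 1")
        if self.anchor_jitter_sd < 0:
            raise ValueError("anchor_jitter_sd must be >= 0")
        lo, hi = self.delta_tract_range
        if not lo <= hi:
            raise ValueError("delta_tract_range must satisfy low <= high")


@dataclass
class RateProfile:
    """Expected incorporation probability per nt at offsets from the anchor."""

    positions: np.ndarray
    leading_rate: np.ndarray
    lagging_rate: np.ndarray
    genotype: str = "WT"

    def __len__(self) -> int:
        return len(self.positions)


def _leading_piecewise(positions: np.ndarray, delta_rate: float,
                       epsilon_rate: float, delta_end: float) -> np.ndarray:
    """Pol delta rate out to ``delta_end``, Pol epsilon beyond.

    Positions upstream of the (possibly jittered) origin keep the delta
    rate: the initial leading tract there has not yet handed off.
    """
    return np.where(positions < delta_end, delta_rate, epsilon_rate)


def _lagging_periodic(positions: np.ndarray, alpha_rate: float,
                      delta_rate: float, tracts: TractModel,
                      phase: int = 0) -> np.ndarray:
    offset = np.mod(positions + phase, tracts.okazaki_period)
    return np.where(offset < tracts.alpha_tract, alpha_rate, delta_rate)


def single_ars_profile(
    rates: PolymeraseRates = PolymeraseRates(),
    tracts: TractModel = TractModel(),
    genotype: str = "WT",
    extent: int = 15_000,
) -> RateProfile:
    """Deterministic expected-rate profile of one origin.

    Leading strand (measured from the anchor): the Pol delta rate over
    the visible delta tract, the Pol epsilon rate beyond -- two phases
    only, because the Pol alpha primer lies upstream of the anchor.
    Lagging strand: the Okazaki-periodic alpha/delta pattern.
    """
    if extent <= 0:
        raise ValueError("extent must be > 0")
    a, d, e = rates.for_genotype(genotype)
    pos = np.arange(extent)
    leading = _leading_piecewise(pos, d, e, tracts.leading_delta_tract)
    lagging = _lagging_periodic(pos, a, d, tracts)
    return RateProfile(pos, leading, lagging, genotype)


def combined_ars_profile(
    rates: PolymeraseRates = PolymeraseRates(),
    tracts: TractModel = TractModel(),
    genotype: str = "WT",
    combined: CombinedConfig = CombinedConfig(),
    extent: int = 15_000,
) -> RateProfile:
    """Monte-Carlo average profile over many annotated origins.

    Each origin draws an annotation jitter ~ Normal(0, sd), a leading
    delta-tract length ~ Uniform(range) and a uniform Okazaki phase; the
    returned profile is the arithmetic mean of the per-origin piecewise
    profiles, deterministic for a fixed seed.  With sd = 0 and a
    degenerate tract the result equals the single-origin profile.
    """
    if extent <= 0:
        raise ValueError("extent must be > 0")
    a, d, e = rates.for_genotype(genotype)
    rng = np.random.default_rng(combined.seed)
    pos = np.arange(extent)
    leading_sum = np.zeros(extent)
    lagging_sum = np.zeros(extent)
    lo, hi = combined.delta_tract_range
    for _ in range(combined.n_ars):
        jitter = rng.normal(0.0, combined.anchor_jitter_sd) \
            if combined.anchor_jitter_sd > 0 else 0.0
        tract = rng.uniform(lo, hi) if lo < hi else lo
        phase = int(rng.integers(0, tracts.okazaki_period)) \
            if combined.randomize_phase else 0
        leading_sum += _leading_piecewise(pos, d, e, jitter + tract)
        lagging_sum += _lagging_periodic(pos, a, d, tracts, phase)
    return RateProfile(pos, leading_sum / combined.n_ars,
                       lagging_sum / combined.n_ars, genotype)


def fixed_tract_combined(
    rates: PolymeraseRates,
    tracts: TractModel,
    genotype: str,
    combined: CombinedConfig,
    extent: int,
    tract: float,
) -> RateProfile:
    """Combined profile with a single fixed delta tract (degeneracy checks)."""
    cfg = replace(combined, delta_tract_range=(tract, tract))
    return combined_ars_profile(rates, tracts, genotype, cfg, extent)


def profile_ratio(
    profile: RateProfile, bin_size: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position leading/lagging ratio with bin-averaged lagging rate.

    The lagging strand's Okazaki periodicity is removed by averaging the
    lagging rate within ``bin_size`` windows before dividing, mirroring
    how binned empirical ratios are computed.  Returns (positions, ratio).
    """
    n = len(profile)
    ratio = np.empty(n)
    for start in range(0, n, bin_size):
        stop = min(start + bin_size, n)
        mean_lag = profile.lagging_rate[start:stop].mean()
        if mean_lag == 0:
            raise ZeroDivisionError("lagging rate is zero in a bin")
        ratio[start:stop] = profile.leading_rate[start:stop] / mean_lag
    return profile.positions, ratio


def mean_lagging_rate(rates: PolymeraseRates = PolymeraseRates(),
                      tracts: TractModel = TractModel(),
                      genotype: str = "WT") -> float:
    """Okazaki-period-averaged lagging rate (the ratio's denominator)."""
    a, d, _ = rates.for_genotype(genotype)
    period = tracts.okazaki_period
    return (tracts.alpha_tract * a + tracts.delta_okazaki_tract * d) / period
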