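"""Synthetic genomes, origin tables and rNMP libraries with known truth.

The generator realizes the same Poisson model the estimator assumes:
around every origin, each nucleotide of each nascent strand carries an
embedded ribonucleotide with expectation

    r_i * rate(role) * context_weight(5' neighbour, rNMP base, role)

where ``r_i`` is the library capture rate, ``rate`` is the per-nt
incorporation rate of the strand role (leading a, lagging b -- flat, or
position-dependent via a simulator profile), and the context weight
produces dinucleotide signatures (e.g. the dA-before-rNMP preference of
Pol epsilon on the leading strand).  Counts are Poisson draws per
position and strand; every random choice flows from one seed, so a
(config, seed) pair reproduces its outputs byte for byte.

A :class:`GroundTruthManifest` written alongside the data records the
true rates, ratios and capture rates needed to score recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ars import ARSRecord, FlankConfig, FlankRegion, build_flanks
from .io import LAGGING, LEADING, RNMPLibrary, RNMPSite

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


class SyntheticConfigError(ValueError):
    """Raised when a generator configuration is invalid."""


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the real-data setting scaled to a desk-size genome:
    a single 500-kb chromosome carrying 10 origins at least 40 kb apart
    (so 15-kb flanks never collide), firing times Uniform(10, 45) min,
    efficiencies Uniform(0.3, 0.9), flat leading/lagging rates a = 2e-3
    and b = 1e-3 per nt, and one library with unit capture rate.
    """

    chrom_lengths: Sequence[int] = (500_000,)
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25)  # A C G T
    ars_count: int = 10
    min_spacing: int = 40_000
    firing_time_range: tuple[float, float] = (10.0, 45.0)
    efficiency_range: tuple[float, float] = (0.3, 0.9)
    genotype: str = "WT"
    capture_rates: Sequence[float] = (1.0,)
    rate_leading: float = 2e-3
    rate_lagging: float = 1e-3
    context_weights: Mapping[tuple[str, str, str], float] = field(
        default_factory=dict
    )  # (5' neighbour, rNMP base or 'N', role) -> multiplicative weight
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise SyntheticConfigError(
                "base_composition must be 4 non-negative probabilities summing to 1"
            )
        if any(r < 0 for r in self.capture_rates):
            raise SyntheticConfigError("capture rates must be >= 0")
        if any(w <= 0 for w in self.context_weights.values()):
            raise SyntheticConfigError("context weights must be > 0")


@dataclass
class GroundTruthManifest:
    """True parameters behind a generated dataset, for recovery scoring."""

    rate_leading: float
    rate_lagging: float
    theta: float
    capture_rates: list[float]
    genotype: str
    seed: int
    context_weights: dict[str, float] = field(default_factory=dict)
    per_ars_theta: dict[str, float] = field(default_factory=dict)
    generator_version: str = "1"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# genome and origins


def generate_genome(config: SyntheticConfig,
                    rng: np.random.Generator | None = None) -> dict[str, str]:
    """I.i.d. random genome at the configured base composition."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genome: dict[str, str] = {}
    bases = np.frombuffer(BASES.encode(), dtype="S1")
    for i, length in enumerate(config.chrom_lengths, start=1):
        draws = rng.choice(bases, size=length, p=list(config.base_composition))
        genome[f"chr{i}"] = draws.tobytes().decode()
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def generate_ars_table(config: SyntheticConfig, genome: Mapping[str, str],
                       rng: np.random.Generator | None = None
                       ) -> list[ARSRecord]:
    """Evenly spaced origins with jitter, respecting the minimum spacing."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    chroms = list(genome)
    per_chrom = _split_counts(config.ars_count, [len(genome[c]) for c in chroms])
    records: list[ARSRecord] = []
    idx = 1
    for chrom, n in zip(chroms, per_chrom):
        length = len(genome[chrom])
        if n == 0:
            continue
        slot = length / (n + 1)
        if slot < config.min_spacing:
            raise SyntheticConfigError(
                f"{chrom} ({length} nt) too short for {n} origins at "
                f"spacing {config.min_spacing}"
            )
        jitter_max = max(0.0, (slot - config.min_spacing) / 2.0)
        for j in range(1, n + 1):
            anchor = int(j * slot + rng.uniform(-jitter_max, jitter_max))
            anchor = min(max(anchor, 200), length - 200)
            t = float(rng.uniform(*config.firing_time_range))
            eff = float(rng.uniform(*config.efficiency_range))
            records.append(ARSRecord(
                name=f"synARS{idx:03d}", chrom=chrom,
                start=anchor - 100, end=anchor + 100, anchor=anchor,
                firing_time=round(t, 2), efficiency=round(eff, 3),
                status="confirmed",
            ))
            idx += 1
    return records


def _split_counts(total: int, weights: Sequence[int]) -> list[int]:
    w = np.asarray(weights, dtype=float)
    raw = w / w.sum() * total
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def write_ars_table(records: Sequence[ARSRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstart\tend\tfiring_time\tefficiency\tstatus\n")
        for r in records:
            t = "NA" if r.firing_time is None else f"{r.firing_time}"
            e = "NA" if r.efficiency is None else f"{r.efficiency}"
            fh.write(f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{t}\t{e}\t"
                     f"{r.status}\n")


# ---------------------------------------------------------------------------
# rNMP libraries


def _context_weight(weights: Mapping[tuple[str, str, str], float],
                    neighbor: str, base: str, role: str) -> float:
    return weights.get((neighbor, base, role),
                       weights.get((neighbor, "N", role), 1.0))


def _sample_region(seq: str, start: int, end: int, strand: str, role: str,
                   rate: float, r_i: float,
                   weights: Mapping[tuple[str, str, str], float],
                   rng: np.random.Generator,
                   chrom: str) -> list[RNMPSite]:
    """Poisson-sample sites of one (region, strand, role) combination."""
    sites: list[RNMPSite] = []
    start = max(start, 1)
    end = min(end, len(seq) - 1)  # keep both genomic neighbours readable
    if start >= end:
        return sites
    probs = np.empty(end - start)
    if weights:
        for k, pos in enumerate(range(start, end)):
            if strand == "+":
                base, nb = seq[pos], seq[pos - 1]
            else:
                base = seq[pos].translate(_COMP)
                nb = seq[pos + 1].translate(_COMP)
            probs[k] = rate * r_i * _context_weight(weights, nb, base, role)
        if (probs >= 1.0).any():
            raise SyntheticConfigError(
                "per-position incorporation probability reaches 1"
            )
    else:
        p = rate * r_i
        if p >= 1.0:
            raise SyntheticConfigError(
                "per-position incorporation probability reaches 1"
            )
        probs.fill(p)
    counts = rng.poisson(probs)
    for k in np.flatnonzero(counts):
        sites.append(RNMPSite(chrom, start + int(k), strand, int(counts[k])))
    return sites


def generate_rnmp_library(
    genome: Mapping[str, str],
    records: Sequence[ARSRecord],
    config: SyntheticConfig,
    library_index: int = 0,
    rng: np.random.Generator | None = None,
    flank_config: FlankConfig = FlankConfig(),
    per_ars_leading_rate: Mapping[str, float] | None = None,
    name: str | None = None,
) -> RNMPLibrary:
    """Sample one rNMP library over every origin flank.

    Both reference strands of both flanks are sampled: downstream the
    plus strand carries the leading role and the minus strand the
    lagging role, upstream the reverse.  ``per_ars_leading_rate``
    overrides the flat leading rate origin by origin (used to build
    firing-time-dependent ratios with a known regression slope).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 100 + library_index)
    r_i = config.capture_rates[library_index]
    lengths = {c: len(s) for c, s in genome.items()}
    flanks = build_flanks(records, lengths, flank_config)
    sites: list[RNMPSite] = []
    for region in flanks:
        seq = genome[region.chrom]
        a = config.rate_leading
        if per_ars_leading_rate is not None:
            a = per_ars_leading_rate.get(region.ars_name, a)
        b = config.rate_lagging
        if region.side == "downstream":
            role_of = {"+": (LEADING, a), "-": (LAGGING, b)}
        else:
            role_of = {"+": (LAGGING, b), "-": (LEADING, a)}
        for strand, (role, rate) in role_of.items():
            sites.extend(_sample_region(
                seq, region.start, region.end, strand, role, rate, r_i,
                config.context_weights, rng, region.chrom,
            ))
    lib_name = name or f"synthetic_{library_index}"
    return RNMPLibrary(name=lib_name, technique="synthetic",
                       rnase_h2="rnh201-null", pol_allele=config.genotype,
                       sites=sorted(sites, key=lambda s: (s.chrom, s.pos,
                                                          s.strand)))


def generate_dataset(
    config: SyntheticConfig,
    flank_config: FlankConfig = FlankConfig(),
) -> tuple[dict[str, str], list[ARSRecord], list[RNMPLibrary],
           GroundTruthManifest]:
    """Genome + origin table + one library per capture rate + manifest."""
    genome = generate_genome(config)
    records = generate_ars_table(config, genome)
    libraries = [
        generate_rnmp_library(genome, records, config, i,
                              flank_config=flank_config)
        for i in range(len(config.capture_rates))
    ]
    manifest = GroundTruthManifest(
        rate_leading=config.rate_leading,
        rate_lagging=config.rate_lagging,
        theta=config.rate_leading / config.rate_lagging,
        capture_rates=list(config.capture_rates),
        genotype=config.genotype,
        seed=config.seed,
        context_weights={"|".join(k): v
                         for k, v in config.context_weights.items()},
        per_ars_theta={r.name: config.rate_leading / config.rate_lagging
                       for r in records},
    )
    return genome, records, libraries, manifest


def sample_poisson_counts(
    rate_leading: float,
    rate_lagging: float,
    capture_rates: Sequence[float],
    genome_length: int,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """Draw (X_i, Y_i) directly from the closed-form Poisson count model."""
    X = [int(rng.poisson(r * rate_leading * genome_length))
         for r in capture_rates]
    Y = [int(rng.poisson(r * rate_lagging * genome_length))
         for r in capture_rates]
    return X, Y
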