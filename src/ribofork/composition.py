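"""Background-normalized rNMP composition analysis.

For a set of strand-role-specific windows around origins (or around
fork-collision points), counts the embedded rNMP bases and their
NR/RN dinucleotide contexts in nascent-strand orientation, divides by
the background (di)nucleotide frequencies of the reference sequence in
the same windows, and renormalizes so each group of four sums to 1 --
so 0.25 everywhere means no incorporation preference.

Libraries contributing fewer than 100 rNMPs to a window group are
excluded from mononucleotide tables, fewer than 400 from dinucleotide
tables, to avoid small-count artefacts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .ars import ARSRecord, FlankConfig, collision_point
from .io import LAGGING, LEADING, RNMPLibrary
from .stats import mann_whitney_one_sided

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

MONO_MIN_COUNT = 100
DINUC_MIN_COUNT = 400

#: named window presets, nt offsets from the anchor along the role's direction
WINDOW_PRESETS: dict[str, tuple[int, int]] = {
    "0-100": (0, 100),
    "0-200": (0, 200),
    "0-500": (0, 500),
    "4000-10000": (4000, 10_000),
}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class WindowSpec:
    """Offsets (nt) from the anchor, measured outward along the role."""

    name: str
    start_offset: int
    end_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_offset < self.end_offset):
            raise ValueError("window offsets must satisfy 0 <= start < end")

    @classmethod
    def preset(cls, name: str) -> "WindowSpec":
        return cls(name, *WINDOW_PRESETS[name])


@dataclass(frozen=True)
class ResolvedWindow:
    """A genomic interval with the nascent-strand orientation of a role.

    ``strand`` is the reference strand carrying the nascent strand of
    interest in this interval; sequence is read reverse-complemented
    when it is "-".
    """

    chrom: str
    start: int
    end: int
    strand: str  # "+" | "-"
    role: str  # leading | lagging
    ars_name: str
    truncated: bool = False


@dataclass
class BackgroundFreqs:
    """Reference (di)nucleotide frequencies pooled over a window group."""

    mono: dict[str, float]
    dinuc: dict[str, float]  # 16 keys "NR" in nascent orientation


@dataclass
class CompositionTable:
    """Normalized rNMP (di)nucleotide frequencies for one library/group.

    For ``kind="mono"``, ``values`` maps each rNMP base to its
    normalized frequency (the four sum to 1).  For ``kind="NR"`` or
    ``"RN"``, ``values`` maps dinucleotides "NR" to frequencies that sum
    to 1 within each fixed rNMP base R.
    """

    library: str
    kind: str  # "mono" | "NR" | "RN"
    role: str
    window: str
    values: dict[str, float] = field(default_factory=dict)
    raw_counts: dict[str, int] = field(default_factory=dict)
    total_sites: int = 0
    skipped_edge_sites: int = 0
    excluded_reason: str | None = None

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not None


# ---------------------------------------------------------------------------
# window resolution


def resolve_windows(
    records: Sequence[ARSRecord],
    window: WindowSpec,
    role: str,
    genome_lengths: Mapping[str, int],
) -> list[ResolvedWindow]:
    """Map a role-directed window onto genomic intervals for every origin.

    The leading role of an origin lives on the plus strand downstream of
    the anchor and on the minus strand upstream; the lagging role the
    reverse.  Each origin therefore contributes two intervals per
    window, clipped at chromosome ends.
    """
    if role not in (LEADING, LAGGING):
        raise ValueError(f"unknown role '{role}'")
    out: list[ResolvedWindow] = []
    for r in records:
        chrom_len = genome_lengths[r.chrom]
        down = (r.anchor + window.start_offset,
                min(r.anchor + window.end_offset, chrom_len))
        up = (max(r.anchor - window.end_offset, 0),
              r.anchor - window.start_offset)
        down_strand = "+" if role == LEADING else "-"
        up_strand = "-" if role == LEADING else "+"
        if down[0] < down[1]:
            out.append(ResolvedWindow(r.chrom, down[0], down[1], down_strand,
                                      role, r.name))
        if up[0] < up[1]:
            out.append(ResolvedWindow(r.chrom, up[0], up[1], up_strand,
                                      role, r.name))
    return out


def termination_zone_windows(
    records: Sequence[ARSRecord],
    genome_lengths: Mapping[str, int],
    width: int = 200,
    fork_speed: float = 1600.0,
    max_distance: int = 30_000,
) -> dict[str, list[ResolvedWindow]]:
    """Windows of ``width`` nt flanking each fork-collision point.

    For neighbouring origins closer than ``max_distance``, the collision
    point is computed from their firing times; on its left side the
    approaching fork came from the left origin, so leading is the plus
    strand, while on the right side leading is the minus strand.
    Windows squeezed against an anchor are truncated and flagged.
    Returns ``{"leading": [...], "lagging": [...]}``.
    """
    out: dict[str, list[ResolvedWindow]] = {LEADING: [], LAGGING: []}
    by_chrom: dict[str, list[ARSRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda r: r.anchor)
        for left, right in itertools.pairwise(group):
            if right.anchor - left.anchor >= max_distance:
                continue
            cpoint, _ = collision_point(left, right, fork_speed)
            name = f"{left.name}|{right.name}"
            lstart = max(cpoint - width, left.anchor)
            rend = min(cpoint + width, right.anchor)
            left_trunc = lstart > cpoint - width
            right_trunc = rend < cpoint + width
            # left of the collision: fork from the left origin
            if lstart < cpoint or left_trunc:
                out[LEADING].append(ResolvedWindow(
                    chrom, lstart, cpoint, "+", LEADING, name, left_trunc))
                out[LAGGING].append(ResolvedWindow(
                    chrom, lstart, cpoint, "-", LAGGING, name, left_trunc))
            # right of the collision: fork from the right origin
            if cpoint < rend or right_trunc:
                out[LEADING].append(ResolvedWindow(
                    chrom, cpoint, rend, "-", LEADING, name, right_trunc))
                out[LAGGING].append(ResolvedWindow(
                    chrom, cpoint, rend, "+", LAGGING, name, right_trunc))
    return out


# ---------------------------------------------------------------------------
# background


def compute_background(
    genome: Mapping[str, str], windows: Sequence[ResolvedWindow]
) -> BackgroundFreqs:
    """Pooled (di)nucleotide frequencies of the nascent-oriented reference."""
    if not windows:
        raise ValueError("empty window set")
    mono = {b: 0 for b in BASES}
    dinuc = {a + b: 0 for a in BASES for b in BASES}
    for w in windows:
        seq = genome[w.chrom][w.start:w.end].upper()
        if w.strand == "-":
            seq = _revcomp(seq)
        for b in seq:
            if b in mono:
                mono[b] += 1
        for i in range(len(seq) - 1):
            pair = seq[i:i + 2]
            if pair in dinuc:
                dinuc[pair] += 1
    mtot = sum(mono.values())
    dtot = sum(dinuc.values())
    if mtot == 0:
        raise ValueError("windows contain no sequence")
    return BackgroundFreqs(
        {b: c / mtot for b, c in mono.items()},
        {k: c / dtot if dtot else 0.0 for k, c in dinuc.items()},
    )


# ---------------------------------------------------------------------------
# site context extraction


def _sites_in_windows(library: RNMPLibrary, windows: Sequence[ResolvedWindow]):
    for w in windows:
        for s in library.sites:
            if s.chrom == w.chrom and s.strand == w.strand and \
                    w.start <= s.pos < w.end:
                yield w, s


def _site_base(genome: Mapping[str, str], site) -> str:
    b = genome[site.chrom][site.pos].upper()
    return b.translate(_COMP) if site.strand == "-" else b


def _neighbor_base(genome: Mapping[str, str], site, side: str) -> str | None:
    """5' (side="NR") or 3' (side="RN") neighbour in nascent orientation."""
    seq = genome[site.chrom]
    if (side == "NR") == (site.strand == "+"):
        npos = site.pos - 1
    else:
        npos = site.pos + 1
    if not (0 <= npos < len(seq)):
        return None
    b = seq[npos].upper()
    return b.translate(_COMP) if site.strand == "-" else b


# ---------------------------------------------------------------------------
# composition tables


def mono_composition(
    library: RNMPLibrary,
    windows: Sequence[ResolvedWindow],
    genome: Mapping[str, str],
    background: BackgroundFreqs,
    min_count: int = MONO_MIN_COUNT,
    window_name: str = "",
    role: str = "",
) -> CompositionTable:
    """Background-normalized frequency of each embedded rNMP base."""
    counts = {b: 0 for b in BASES}
    total = 0
    for _w, s in _sites_in_windows(library, windows):
        b = _site_base(genome, s)
        if b in counts:
            counts[b] += s.count
            total += s.count
    table = CompositionTable(library.name, "mono", role, window_name,
                             raw_counts=counts, total_sites=total)
    if total < min_count:
        table.excluded_reason = (
            f"only {total} rNMPs in window group (< {min_count})"
        )
        return table
    norm: dict[str, float] = {}
    for b in BASES:
        g = background.mono[b]
        if g == 0:
            if counts[b] > 0:
                raise ValueError(
                    f"zero background frequency for {b} with nonzero count"
                )
            norm[b] = 0.0
        else:
            norm[b] = counts[b] / g
    z = sum(norm.values())
    table.values = {b: v / z for b, v in norm.items()}
    return table


def dinucleotide_composition(
    library: RNMPLibrary,
    windows: Sequence[ResolvedWindow],
    genome: Mapping[str, str],
    background: BackgroundFreqs,
    side: str = "NR",
    min_count: int = DINUC_MIN_COUNT,
    window_name: str = "",
    role: str = "",
) -> CompositionTable:
    """Normalized NR (or RN) dinucleotide frequencies, per rNMP base row.

    The neighbour is read genomically even when it falls just outside
    the window; sites whose neighbour falls off the chromosome are
    skipped and tallied.  Within each rNMP base R the four normalized
    frequencies sum to 1.
    """
    if side not in ("NR", "RN"):
        raise ValueError("side must be 'NR' or 'RN'")
    counts = {a + b: 0 for a in BASES for b in BASES}
    total = 0
    skipped = 0
    for _w, s in _sites_in_windows(library, windows):
        r = _site_base(genome, s)
        n = _neighbor_base(genome, s, side)
        if n is None:
            skipped += s.count
            continue
        key = n + r if side == "NR" else r + n
        if key in counts:
            counts[key] += s.count
            total += s.count
    table = CompositionTable(library.name, side, role, window_name,
                             raw_counts=counts, total_sites=total,
                             skipped_edge_sites=skipped)
    if total < min_count:
        table.excluded_reason = (
            f"only {total} rNMPs in window group (< {min_count})"
        )
        return table
    values: dict[str, float] = {}
    for r in BASES:  # one row per rNMP base
        row: dict[str, float] = {}
        for n in BASES:
            key = n + r if side == "NR" else r + n
            g = background.dinuc[key]
            if g == 0:
                if counts[key] > 0:
                    raise ValueError(
                        f"zero background frequency for {key} with count > 0"
                    )
                row[key] = 0.0
            else:
                row[key] = counts[key] / g
        z = sum(row.values())
        for key, v in row.items():
            values[key] = v / z if z > 0 else math.nan
    table.values = values
    return table


def compare_roles(
    tables_leading: Sequence[CompositionTable],
    tables_lagging: Sequence[CompositionTable],
    pattern: str,
    alternative: str = "greater",
) -> float:
    """One-sided Mann-Whitney p for a pattern's frequency, leading vs lagging.

    ``pattern`` is a base ("A") for mono tables or a dinucleotide ("AA"
    for dArA) for NR/RN tables.  ``alternative="greater"`` tests whether
    the pattern is more frequent on the leading strand.
    """
    lead = [t.values[pattern] for t in tables_leading if not t.excluded]
    lag = [t.values[pattern] for t in tables_lagging if not t.excluded]
    if len(lead) < 2 or len(lag) < 2:
        raise ValueError("need >= 2 non-excluded libraries per strand role")
    return mann_whitney_one_sided(lead, lag, alternative=alternative)
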