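"""Reading and writing rNMP site data.

An rNMP site is a single genomic nucleotide position on one strand where
an embedded ribonucleotide was captured, with a count of captured
molecules.  Sites arrive either as BED6 (one 1-nt interval per record,
duplicates aggregated) or as a plus/minus bedGraph pair with per-position
counts.

The strand *role* of a site relative to a replication origin follows the
bidirectional-fork convention: downstream of the anchor the plus strand
is the nascent leading strand, upstream of the anchor the minus strand
is; the complementary strand at each position is the lagging strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .ars import FlankRegion

logger = logging.getLogger(__name__)

LEADING = "leading"
LAGGING = "lagging"

TECHNIQUES = {"ribose-seq", "emRiboSeq", "RHII-HydEn-seq", "synthetic"}


class RNMPFormatError(ValueError):
    """Raised on malformed rNMP site files."""


@dataclass(frozen=True)
class RNMPSite:
    chrom: str
    pos: int  # 0-based single-nucleotide coordinate
    strand: str  # "+" | "-"
    count: int = 1


@dataclass
class RNMPLibrary:
    """One rNMP sequencing library: metadata plus its stranded sites."""

    name: str
    technique: str = "synthetic"
    rnase_h2: str = "rnh201-null"
    pol_allele: str = "WT"
    sites: list[RNMPSite] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(s.count for s in self.sites)

    def sites_on(self, chrom: str) -> list[RNMPSite]:
        return [s for s in self.sites if s.chrom == chrom]


def _aggregate(raw: Iterable[tuple[str, int, str, int]]) -> list[RNMPSite]:
    counts: dict[tuple[str, int, str], int] = {}
    for chrom, pos, strand, count in raw:
        key = (chrom, pos, strand)
        counts[key] = counts.get(key, 0) + count
    return [
        RNMPSite(chrom, pos, strand, c)
        for (chrom, pos, strand), c in sorted(counts.items())
    ]


def read_rnmp_bed(path, name: str | None = None, offset: int = 0,
                  dedup: bool = False, **metadata) -> RNMPLibrary:
    """Read a BED6 file of single-nucleotide rNMP records.

    Each record must span exactly one nucleotide (end = start + 1) with
    strand ``+`` or ``-``.  Duplicate (chrom, pos, strand) records are
    aggregated into a count; ``dedup=True`` collapses counts to
    presence/absence instead.  ``offset`` shifts every position by a
    signed integer, for input conventions that mark the neighbour of the
    embedded ribonucleotide rather than the ribonucleotide itself.
    """
    raw: list[tuple[str, int, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise RNMPFormatError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start, end, _, score, strand = fields[:6]
            start, end = int(start), int(end)
            if end != start + 1:
                raise RNMPFormatError(
                    f"{path}:{lineno}: rNMP record must be 1 nt (got {end - start})"
                )
            if strand not in ("+", "-"):
                raise RNMPFormatError(f"{path}:{lineno}: bad strand '{strand}'")
            raw.append((chrom, start + offset, strand, 1))
    sites = _aggregate(raw)
    if dedup:
        sites = [RNMPSite(s.chrom, s.pos, s.strand, 1) for s in sites]
    lib_name = name if name is not None else str(path)
    return RNMPLibrary(name=lib_name, sites=sites, **metadata)


def read_rnmp_bedgraph_pair(plus_path, minus_path, name: str | None = None,
                            **metadata) -> RNMPLibrary:
    """Read a plus/minus bedGraph pair of per-position rNMP counts.

    Each covered position in an interval becomes one site with the
    interval's value as its count; zero-value intervals are skipped.
    """
    raw: list[tuple[str, int, str, int]] = []
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise RNMPFormatError(
                        f"{path}:{lineno}: expected 4 bedGraph columns"
                    )
                chrom, start, end, value = fields[:4]
                start, end, value = int(start), int(end), float(value)
                if value < 0:
                    raise RNMPFormatError(f"{path}:{lineno}: negative value")
                count = int(round(value))
                if count == 0:
                    continue
                for pos in range(start, end):
                    raw.append((chrom, pos, strand, count))
    lib_name = name if name is not None else f"{plus_path}|{minus_path}"
    return RNMPLibrary(name=lib_name, sites=_aggregate(raw), **metadata)


def write_rnmp_bed(library: RNMPLibrary, path) -> None:
    """Write sites as BED6; a site with count c becomes c identical lines."""
    with open(path, "w") as fh:
        for s in sorted(library.sites, key=lambda s: (s.chrom, s.pos, s.strand)):
            line = f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{library.name}\t1\t{s.strand}\n"
            fh.write(line * s.count)


def assign_strand_role(site: RNMPSite, anchor: int) -> str | None:
    """Leading/lagging role of a site relative to an origin anchor.

    Returns ``None`` for a site exactly at the anchor, where the
    convention is undefined; such sites are excluded from strand tallies.
    """
    if site.pos == anchor:
        logger.warning("site at %s:%d coincides with the ARS anchor; excluded",
                       site.chrom, site.pos)
        return None
    downstream = site.pos > anchor
    if site.strand == "+":
        return LEADING if downstream else LAGGING
    return LAGGING if downstream else LEADING


def count_sites(
    library: RNMPLibrary,
    region: FlankRegion | tuple[str, int, int],
    strand: str | None = None,
    strand_role: str | None = None,
    anchor: int | None = None,
) -> int:
    """Total count of sites inside a half-open region, optionally filtered.

    ``strand`` filters on the reference strand; ``strand_role`` filters on
    leading/lagging relative to ``anchor`` (taken from the region when it
    is a :class:`FlankRegion`).
    """
    if isinstance(region, FlankRegion):
        chrom, start, end = region.chrom, region.start, region.end
        if anchor is None:
            anchor = region.anchor
    else:
        chrom, start, end = region
    if strand_role is not None and anchor is None:
        raise ValueError("strand_role filtering requires an anchor")
    total = 0
    for s in library.sites:
        if s.chrom != chrom or not (start <= s.pos < end):
            continue
        if strand is not None and s.strand != strand:
            continue
        if strand_role is not None and assign_strand_role(s, anchor) != strand_role:
            continue
        total += s.count
    return total


def read_library_metadata(path) -> dict[str, dict[str, str]]:
    """Read a ``name technique rnase_h2 pol_allele`` TSV sidecar."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("name", "technique", "rnase_h2", "pol_allele"):
        if col not in df.columns:
            raise RNMPFormatError(f"library metadata missing column '{col}'")
    return {row["name"]: dict(row) for _, row in df.iterrows()}
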