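"""Replication-origin (ARS) annotation handling.

Parses ARS tables, classifies origins by firing time and efficiency,
builds the 15-kb leading/lagging flank regions with fork-collision
truncation, and cuts flanks into 500-nt bins.

Coordinates are 0-based half-open throughout; 1-based input tables are
converted at the reader boundary.  The ARS *anchor* -- the point from
which bidirectional replication is measured -- is the integer midpoint
of the annotated interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STATUS = {"confirmed", "likely", "dubious", "unknown"}

DEFAULT_FLANK_LENGTH = 15_000
DEFAULT_FORK_SPEED = 1_600  # nt per minute
DEFAULT_BIN_SIZE = 500

EFFICIENCY_HIGH = 0.7
EFFICIENCY_LOW = 0.5


class ARSFormatError(ValueError):
    """Raised when an ARS table violates the expected format."""


class ARSValidationError(ValueError):
    """Raised when a record fails its invariants."""


@dataclass(frozen=True)
class ARSRecord:
    """One replication origin.

    ``firing_time`` is the trep-style activation time in minutes into S
    phase; ``efficiency`` is the fraction of cells in which the origin
    fires.  Either may be ``None`` when unannotated.
    """

    name: str
    chrom: str
    start: int
    end: int
    anchor: int
    firing_time: float | None = None
    efficiency: float | None = None
    status: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ARSValidationError(
                f"{self.name}: start ({self.start}) must be < end ({self.end})"
            )
        if not (self.start <= self.anchor < self.end):
            raise ARSValidationError(f"{self.name}: anchor outside [start, end)")
        if self.efficiency is not None and not (0.0 <= self.efficiency <= 1.0):
            raise ARSValidationError(
                f"{self.name}: efficiency {self.efficiency} outside [0, 1]"
            )
        if self.firing_time is not None and self.firing_time <= 0:
            raise ARSValidationError(
                f"{self.name}: firing time {self.firing_time} must be > 0"
            )


@dataclass(frozen=True)
class FlankConfig:
    """Geometry of the origin flanks.

    ``fork_speed`` is the average replication-fork speed used to place
    collision points between neighbouring origins (default 1.6 kb/min).
    """

    flank_length: int = DEFAULT_FLANK_LENGTH
    fork_speed: float = DEFAULT_FORK_SPEED
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if self.flank_length <= 0 or self.fork_speed <= 0 or self.bin_size <= 0:
            raise ValueError("flank_length, fork_speed and bin_size must be > 0")


@dataclass(frozen=True)
class FlankRegion:
    """One side of an origin's flank, possibly truncated.

    ``truncated_by`` is ``"none"``, ``"chromosome_end"`` or
    ``"collision:<name>"`` naming the converging neighbour.
    """

    ars_name: str
    chrom: str
    side: str  # "upstream" | "downstream"
    start: int
    end: int
    anchor: int
    truncated_by: str = "none"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ARSGrouping:
    """Class labels per origin plus the thresholds that produced them."""

    firing_class: dict[str, str] = field(default_factory=dict)
    efficiency_class: dict[str, str] = field(default_factory=dict)
    firing_threshold: float | None = None
    efficiency_high: float = EFFICIENCY_HIGH
    efficiency_low: float = EFFICIENCY_LOW

    def names_in_firing_class(self, label: str) -> list[str]:
        return [n for n, c in self.firing_class.items() if c == label]

    def names_in_efficiency_class(self, label: str) -> list[str]:
        return [n for n, c in self.efficiency_class.items() if c == label]


# ---------------------------------------------------------------------------
# readers


def _parse_optional_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text in ("", "NA", "NaN", "nan", "."):
        return None
    return float(text)


def load_ars_table(
    path,
    status_filter: set[str] | None = frozenset({"confirmed"}),
    one_based: bool = False,
    genome_lengths: Mapping[str, int] | None = None,
) -> list[ARSRecord]:
    """Read a TSV of origins into validated :class:`ARSRecord` objects.

    Required columns: ``name chrom start end``; optional ``firing_time``,
    ``efficiency``, ``status`` (``NA`` for missing).  Records whose status
    is not in ``status_filter`` are dropped (pass ``None`` to keep all).
    ``one_based=True`` converts inclusive 1-based intervals to the
    internal 0-based half-open convention.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("name", "chrom", "start", "end"):
        if col not in df.columns:
            raise ARSFormatError(f"ARS table is missing required column '{col}'")

    records: list[ARSRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        start = int(row.start)
        end = int(row.end)
        if one_based:
            start -= 1
        status = getattr(row, "status", "unknown")
        if status is None or (isinstance(status, float) and math.isnan(status)):
            status = "unknown"
        status = str(status).strip() or "unknown"
        if status_filter is not None and status not in status_filter:
            continue
        if start >= end:
            raise ARSValidationError(
                f"line {lineno}: start ({start}) >= end ({end}) for {row.name}"
            )
        anchor = (start + end) // 2
        if genome_lengths is not None:
            chrom_len = genome_lengths.get(str(row.chrom))
            if chrom_len is None:
                raise ARSValidationError(
                    f"line {lineno}: unknown chromosome '{row.chrom}'"
                )
            if end > chrom_len:
                raise ARSValidationError(
                    f"line {lineno}: interval end {end} exceeds length of "
                    f"{row.chrom} ({chrom_len})"
                )
        records.append(
            ARSRecord(
                name=str(row.name),
                chrom=str(row.chrom),
                start=start,
                end=end,
                anchor=anchor,
                firing_time=_parse_optional_float(getattr(row, "firing_time", None)),
                efficiency=_parse_optional_float(getattr(row, "efficiency", None)),
                status=status,
            )
        )
    return records


def read_genome_lengths(path) -> dict[str, int]:
    """Read a two-column ``chrom length`` TSV (faidx style)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["chrom", "length"], dtype={0: str, 1: int})
    return dict(zip(df["chrom"], df["length"]))


# ---------------------------------------------------------------------------
# classification


def classify_firing(records: Sequence[ARSRecord]) -> ARSGrouping:
    """Split origins into early/late halves at the median firing time.

    Origins with T equal to the median are classified early (T <= threshold).
    Origins without a firing time are labelled ``unknown``.
    """
    times = [r.firing_time for r in records if r.firing_time is not None]
    if not times:
        raise ARSValidationError("no record has a firing time; cannot classify")
    threshold = float(np.median(times))
    grouping = ARSGrouping(firing_threshold=threshold)
    for r in records:
        if r.firing_time is None:
            grouping.firing_class[r.name] = "unknown"
        elif r.firing_time <= threshold:
            grouping.firing_class[r.name] = "early"
        else:
            grouping.firing_class[r.name] = "late"
    return grouping


def classify_efficiency(
    records: Sequence[ARSRecord],
    high: float = EFFICIENCY_HIGH,
    low: float = EFFICIENCY_LOW,
) -> ARSGrouping:
    """Label origins high (eff >= 0.7), low (eff <= 0.5) or mid efficiency."""
    grouping = ARSGrouping(efficiency_high=high, efficiency_low=low)
    for r in records:
        if r.efficiency is None:
            grouping.efficiency_class[r.name] = "unknown"
        elif r.efficiency >= high:
            grouping.efficiency_class[r.name] = "high"
        elif r.efficiency <= low:
            grouping.efficiency_class[r.name] = "low"
        else:
            grouping.efficiency_class[r.name] = "mid"
    return grouping


# ---------------------------------------------------------------------------
# flank geometry


def collision_point(
    ars_a: ARSRecord,
    ars_b: ARSRecord,
    fork_speed: float = DEFAULT_FORK_SPEED,
) -> tuple[int, bool]:
    """Meeting point of the converging forks fired from two neighbours.

    A fork leaving ``ars_a`` (left) at time t_A moves right at speed v and
    one leaving ``ars_b`` (right) at t_B moves left; they meet at
    x = (anchorA + anchorB)/2 + v (t_B - t_A)/2, clamped into
    [anchorA, anchorB].  When either firing time is missing the
    inter-anchor midpoint is used and the fallback flagged (second
    element of the returned tuple).
    """
    if ars_a.chrom != ars_b.chrom:
        raise ValueError("collision_point requires ARSs on the same chromosome")
    if ars_a.anchor >= ars_b.anchor:
        raise ValueError("ars_a must lie upstream of ars_b (anchorA < anchorB)")
    mid = (ars_a.anchor + ars_b.anchor) / 2.0
    if ars_a.firing_time is None or ars_b.firing_time is None:
        logger.warning(
            "missing firing time for %s/%s; collision point falls back to midpoint",
            ars_a.name, ars_b.name,
        )
        return int(round(mid)), True
    x = mid + fork_speed * (ars_b.firing_time - ars_a.firing_time) / 2.0
    x = min(max(x, ars_a.anchor), ars_b.anchor)
    return int(round(x)), False


def build_flanks(
    records: Sequence[ARSRecord],
    genome_lengths: Mapping[str, int],
    config: FlankConfig = FlankConfig(),
) -> list[FlankRegion]:
    """Build the upstream/downstream flank of every origin.

    Flanks extend ``flank_length`` nt from the anchor, truncated at
    chromosome boundaries and, when the neighbouring anchor is closer
    than twice the flank length, at the fork-collision point with that
    neighbour.  Zero-length flanks are kept (and recorded) so that the
    provenance of dense origin clusters stays visible.
    """
    flanks: list[FlankRegion] = []
    by_chrom: dict[str, list[ARSRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda r: r.anchor)
        chrom_len = genome_lengths[chrom]
        for i, r in enumerate(group):
            # upstream side
            up_start = r.anchor - config.flank_length
            up_cause = "none"
            if up_start < 0:
                up_start = 0
                up_cause = "chromosome_end"
            if i > 0:
                left = group[i - 1]
                if r.anchor - left.anchor < 2 * config.flank_length:
                    cpoint, _ = collision_point(left, r, config.fork_speed)
                    if cpoint > up_start:
                        up_start = cpoint
                        up_cause = f"collision:{left.name}"
            flanks.append(
                FlankRegion(r.name, chrom, "upstream",
                            min(up_start, r.anchor), r.anchor, r.anchor, up_cause)
            )
            # downstream side
            down_end = r.anchor + config.flank_length
            down_cause = "none"
            if down_end > chrom_len:
                down_end = chrom_len
                down_cause = "chromosome_end"
            if i + 1 < len(group):
                right = group[i + 1]
                if right.anchor - r.anchor < 2 * config.flank_length:
                    cpoint, _ = collision_point(r, right, config.fork_speed)
                    if cpoint < down_end:
                        down_end = cpoint
                        down_cause = f"collision:{right.name}"
            flanks.append(
                FlankRegion(r.name, chrom, "downstream",
                            r.anchor, max(down_end, r.anchor), r.anchor, down_cause)
            )
    return flanks


def bin_flank(
    region: FlankRegion, bin_size: int = DEFAULT_BIN_SIZE
) -> list[tuple[int, tuple[int, int], int]]:
    """Cut a flank into bins numbered 1..k outward from the anchor.

    The terminal bin of a truncated flank keeps its true (short) size.
    Returns ``(bin_index, (start, end), size)`` triples in bin order.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    bins: list[tuple[int, tuple[int, int], int]] = []
    k = 1
    if region.side == "downstream":
        pos = region.start  # == anchor
        while pos < region.end:
            end = min(pos + bin_size, region.end)
            bins.append((k, (pos, end), end - pos))
            pos = end
            k += 1
    else:
        pos = region.end  # == anchor
        while pos > region.start:
            start = max(pos - bin_size, region.start)
            bins.append((k, (start, pos), pos - start))
            pos = start
            k += 1
    return bins


def pair_flanks(
    flanks: Iterable[FlankRegion],
) -> dict[str, dict[str, FlankRegion]]:
    """Index flanks as ``{ars_name: {"upstream": ..., "downstream": ...}}``."""
    out: dict[str, dict[str, FlankRegion]] = {}
    for f in flanks:
        out.setdefault(f.ars_name, {})[f.side] = f
    return out
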