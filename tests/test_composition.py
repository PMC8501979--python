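"""Background-normalized composition tables and role comparisons."""

import math

import numpy as np
import pytest

from ribofork.ars import ARSRecord
from ribofork.composition import (
    BackgroundFreqs, WindowSpec, compare_roles, compute_background,
    dinucleotide_composition, mono_composition, resolve_windows,
    termination_zone_windows,
)
from ribofork.io import LAGGING, LEADING
from ribofork.synth import SyntheticConfig, generate_dataset
from conftest import make_ars, make_library

UNIFORM_BG = BackgroundFreqs(
    {b: 0.25 for b in "ACGT"},
    {a + b: 0.0625 for a in "ACGT" for b in "ACGT"},
)


def one_ars(anchor=5000):
    return make_ars(anchor=anchor)


class TestWindowResolution:
    def test_leading_role_spans_both_sides(self):
        windows = resolve_windows([one_ars()], WindowSpec("0-200", 0, 200),
                                  LEADING, {"chr1": 100_000})
        assert len(windows) == 2
        down = next(w for w in windows if w.start == 5000)
        up = next(w for w in windows if w.end == 5000)
        assert (down.end, down.strand) == (5200, "+")
        assert (up.start, up.strand) == (4800, "-")

    def test_lagging_role_flips_strands(self):
        windows = resolve_windows([one_ars()], WindowSpec("0-200", 0, 200),
                                  LAGGING, {"chr1": 100_000})
        strands = {(w.start, w.strand) for w in windows}
        assert strands == {(5000, "-"), (4800, "+")}

    def test_offset_window(self):
        (down, up) = resolve_windows(
            [one_ars()], WindowSpec("4000-10000", 4000, 10_000), LEADING,
            {"chr1": 100_000})
        assert (down.start, down.end) == (9000, 15_000)
        assert (up.start, up.end) == (0, 1000)  # clipped at chromosome start


class TestBackground:
    def test_uniform_genome(self):
        genome = {"chr1": "ACGT" * 2500}
        windows = resolve_windows([one_ars()], WindowSpec("0-500", 0, 500),
                                  LEADING, {"chr1": 10_000})
        bg = compute_background(genome, windows)
        for b in "ACGT":
            assert bg.mono[b] == pytest.approx(0.25)
        assert sum(bg.mono.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(bg.dinuc.values()) == pytest.approx(1.0, abs=1e-9)

    def test_minus_orientation_reverse_complements(self):
        genome = {"chr1": "A" * 10_000}
        windows = [w for w in
                   resolve_windows([one_ars()], WindowSpec("0-500", 0, 500),
                                   LEADING, {"chr1": 10_000})
                   if w.strand == "-"]
        bg = compute_background(genome, windows)
        assert bg.mono["T"] == pytest.approx(1.0)
        assert bg.dinuc["TT"] == pytest.approx(1.0)

    def test_pooling_two_windows(self):
        genome = {"chrA": "A" * 1000, "chrC": "C" * 1000}
        wa = resolve_windows([make_ars(chrom="chrA", anchor=500)],
                             WindowSpec("0-100", 0, 100), LEADING,
                             {"chrA": 1000})
        wc = resolve_windows([make_ars(chrom="chrC", anchor=500)],
                             WindowSpec("0-100", 0, 100), LEADING,
                             {"chrC": 1000})
        bg = compute_background(genome, list(wa) + list(wc))
        # each chromosome contributes one + window (all A / all C) and one
        # - window (all T / all G): 25% each
        assert bg.mono == pytest.approx({"A": 0.25, "C": 0.25,
                                         "G": 0.25, "T": 0.25})

    def test_empty_window_set_rejected(self):
        with pytest.raises(ValueError):
            compute_background({"chr1": "ACGT"}, [])


class TestMonoComposition:
    GENOME = {"chr1": "ACGT" * 2500}

    def windows(self, role=LEADING):
        return resolve_windows([one_ars()], WindowSpec("0-500", 0, 500),
                               role, {"chr1": 10_000})

    def lib_from_bases(self, counts_per_base):
        # place sites on the + downstream window at positions with the
        # wanted reference base (period-4 genome makes that easy)
        base_offset = {"A": 0, "C": 1, "G": 2, "T": 3}
        sites = []
        pos = 5000
        for base, n in counts_per_base.items():
            for k in range(n):
                p = 5000 + base_offset[base] + 4 * k
                sites.append(("chr1", p, "+", 1))
        return make_library(sites)

    def test_counts_proportional_to_background_give_quarter(self):
        lib = self.lib_from_bases({"A": 30, "C": 30, "G": 30, "T": 30})
        t = mono_composition(lib, self.windows(), self.GENOME, UNIFORM_BG,
                             min_count=100)
        for b in "ACGT":
            assert t.values[b] == pytest.approx(0.25)
        assert sum(t.values.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_base_concentration(self):
        lib = self.lib_from_bases({"A": 120})
        t = mono_composition(lib, self.windows(), self.GENOME, UNIFORM_BG)
        assert t.values == pytest.approx({"A": 1.0, "C": 0.0, "G": 0.0,
                                          "T": 0.0})

    def test_nonuniform_background_normalization(self):
        # counts (20,10,10,10) against background (0.4,0.2,0.2,0.2):
        # every c/g ratio is 50, so all normalized frequencies are 0.25
        bg = BackgroundFreqs({"A": 0.4, "C": 0.2, "G": 0.2, "T": 0.2},
                             UNIFORM_BG.dinuc)
        lib = self.lib_from_bases({"A": 20, "C": 10, "G": 10, "T": 10})
        t = mono_composition(lib, self.windows(), self.GENOME, bg,
                             min_count=50)
        for b in "ACGT":
            assert t.values[b] == pytest.approx(0.25)

    def test_count_filter_boundary(self):
        t99 = mono_composition(self.lib_from_bases({"A": 99}),
                               self.windows(), self.GENOME, UNIFORM_BG)
        t100 = mono_composition(self.lib_from_bases({"A": 100}),
                                self.windows(), self.GENOME, UNIFORM_BG)
        assert t99.excluded and not t100.excluded

    def test_minus_strand_site_base_complemented(self):
        genome = {"chr1": "A" * 10_000}
        bg = BackgroundFreqs({"A": 0.5, "T": 0.5, "C": 0.0, "G": 0.0},
                             UNIFORM_BG.dinuc)
        # a minus-strand site upstream of the anchor is leading; its rNMP
        # base is the complement of the reference A
        lib = make_library([("chr1", 4600 + k, "-", 1) for k in range(200)])
        t = mono_composition(lib, self.windows(), genome, bg)
        assert t.values["T"] == pytest.approx(1.0)


class TestDinucleotideComposition:
    def test_all_sites_one_context(self):
        genome = {"chr1": ("CG" * 5000)}
        # + sites at odd positions: base G, 5' neighbour C -> all dCrG
        lib = make_library([("chr1", 5001 + 2 * k, "+", 1)
                            for k in range(250)])
        windows = resolve_windows([one_ars()], WindowSpec("0-500", 0, 500),
                                  LEADING, {"chr1": 10_000})
        bg = compute_background(genome, windows)
        t = dinucleotide_composition(lib, windows, genome, bg, side="NR",
                                     min_count=200)
        assert t.values["CG"] == pytest.approx(1.0)
        # rows for rNMP bases with no counts are NaN (0/0), rG row sums to 1
        row_g = sum(v for k, v in t.values.items()
                    if k[1] == "G" and not math.isnan(v))
        assert row_g == pytest.approx(1.0, abs=1e-9)

    def test_count_filter_at_400(self):
        genome = {"chr1": "ACGT" * 2500}
        windows = resolve_windows([one_ars()], WindowSpec("0-500", 0, 500),
                                  LEADING, {"chr1": 10_000})
        bg = compute_background(genome, windows)
        sites = [("chr1", 5000 + k, "+", 1) for k in range(399)]
        t = dinucleotide_composition(make_library(sites), windows, genome, bg)
        assert t.excluded
        sites = [("chr1", 5000 + k, "+", 1) for k in range(400)]
        t = dinucleotide_composition(make_library(sites), windows, genome, bg)
        assert not t.excluded

    def test_rows_sum_to_one(self):
        cfg = SyntheticConfig(seed=31, rate_leading=5e-3, rate_lagging=5e-3)
        genome, records, libs, _ = generate_dataset(cfg)
        lengths = {c: len(s) for c, s in genome.items()}
        windows = resolve_windows(records, WindowSpec("0-10000", 0, 10_000),
                                  LEADING, lengths)
        bg = compute_background(genome, windows)
        t = dinucleotide_composition(libs[0], windows, genome, bg)
        assert not t.excluded
        for r in "ACGT":
            row = sum(t.values[n + r] for n in "ACGT")
            assert row == pytest.approx(1.0, abs=1e-9)
            for n in "ACGT":
                assert 0.0 <= t.values[n + r] <= 1.0


class TestTerminationZones:
    def records(self):
        return [make_ars(name="L", anchor=20_000, firing_time=20),
                make_ars(name="R", anchor=40_000, firing_time=20)]

    def test_symmetric_pair_abuts_midpoint(self):
        zones = termination_zone_windows(self.records(), {"chr1": 100_000},
                                         width=200)
        lead = zones[LEADING]
        assert {(w.start, w.end) for w in lead} == \
            {(29_800, 30_000), (30_000, 30_200)}

    def test_roles_flip_across_collision_point(self):
        zones = termination_zone_windows(self.records(), {"chr1": 100_000},
                                         width=200)
        left = next(w for w in zones[LEADING] if w.end == 30_000)
        right = next(w for w in zones[LEADING] if w.start == 30_000)
        assert left.strand == "+" and right.strand == "-"
        left_lag = next(w for w in zones[LAGGING] if w.end == 30_000)
        assert left_lag.strand == "-"

    def test_clamped_collision_truncates_and_flags(self):
        records = [make_ars(name="L", anchor=20_000, firing_time=1),
                   make_ars(name="R", anchor=21_000, firing_time=100)]
        zones = termination_zone_windows(records, {"chr1": 100_000},
                                         width=200)
        right_side = [w for w in zones[LEADING] if w.start >= 21_000]
        assert right_side
        assert all(w.truncated and w.end - w.start == 0 for w in right_side)

    def test_distant_pair_has_no_zone(self):
        records = [make_ars(name="L", anchor=20_000, firing_time=20),
                   make_ars(name="R", anchor=90_000, firing_time=20)]
        zones = termination_zone_windows(records, {"chr1": 200_000})
        assert zones[LEADING] == [] and zones[LAGGING] == []


class TestCompareRoles:
    def make_tables(self, lead_val, lag_val, n=4, jitter=0.0):
        from ribofork.composition import CompositionTable

        rng = np.random.default_rng(0)
        tables = []
        for role, val in ((LEADING, lead_val), (LAGGING, lag_val)):
            group = []
            for i in range(n):
                v = val + (rng.normal(0, jitter) if jitter else 0.002 * i)
                group.append(CompositionTable(
                    f"lib{i}", "NR", role, "w",
                    values={"AA": v, "CA": 1 - v}))
            tables.append(group)
        return tables

    def test_identical_tables_near_half(self):
        lead, lag = self.make_tables(0.3, 0.3)
        assert compare_roles(lead, lag, "AA") == pytest.approx(0.5, abs=0.2)

    def test_strong_preference_detected(self):
        lead, lag = self.make_tables(0.57, 0.25, n=8)
        assert compare_roles(lead, lag, "AA", "greater") < 0.05

    def test_too_few_libraries_rejected(self):
        lead, lag = self.make_tables(0.3, 0.3, n=1)
        with pytest.raises(ValueError):
            compare_roles(lead, lag, "AA")


class TestOrientationInvariance:
    def test_mirrored_genome_same_tables(self):
        """Reverse-complementing the genome and flipping coordinates and
        strands must leave composition tables unchanged."""
        cfg = SyntheticConfig(chrom_lengths=(100_000,), ars_count=2,
                              min_spacing=30_000, seed=41,
                              rate_leading=5e-3, rate_lagging=5e-3)
        genome, records, libs, _ = generate_dataset(cfg)
        L = len(genome["chr1"])
        comp = str.maketrans("ACGT", "TGCA")
        mirrored_genome = {"chr1": genome["chr1"].translate(comp)[::-1]}
        mirrored_records = [
            ARSRecord(r.name, r.chrom, L - r.end, L - r.start, L - r.anchor,
                      r.firing_time, r.efficiency, r.status)
            for r in records
        ]
        mirrored_sites = [
            ("chr1", L - 1 - s.pos, "-" if s.strand == "+" else "+", s.count)
            for s in libs[0].sites
        ]
        mlib = make_library(mirrored_sites)

        spec = WindowSpec("0-2000", 0, 2000)
        lengths = {"chr1": L}
        w = resolve_windows(records, spec, LEADING, lengths)
        mw = resolve_windows(mirrored_records, spec, LEADING, lengths)
        t = mono_composition(libs[0], w, genome,
                             compute_background(genome, w), min_count=20)
        mt = mono_composition(mlib, mw, mirrored_genome,
                              compute_background(mirrored_genome, mw),
                              min_count=20)
        assert not t.excluded
        for b in "ACGT":
            assert mt.values[b] == pytest.approx(t.values[b], abs=1e-12)
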