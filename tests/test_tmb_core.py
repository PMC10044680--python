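"""Labels and predictors: dinucleotide merge, footprints, per-Mb inputs, cap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmbcal import (
    Consequence,
    CoverageMask,
    InputConfig,
    PanelDefinition,
    SampleProfile,
    cap_training_set,
    exomic_tmb,
    footprint_mb,
    merge_dinucleotides,
    panel_inputs,
    restrict_to_panel,
)


class TestMergeDinucleotides:
    def test_similar_adjacent_pair_merges_to_nonsynonymous(self, variant_factory):
        a = variant_factory(pos=100, alt_count=30, depth=100,
                            consequence=Consequence.SYNONYMOUS)
        b = variant_factory(pos=101, alt_count=28, depth=90)
        (merged,) = merge_dinucleotides([a, b])
        assert merged.pos == 100
        assert merged.consequence is Consequence.NONSYNONYMOUS
        assert merged.alt_count == 29
        assert merged.depth == 95

    def test_dissimilar_counts_stay_separate(self, variant_factory):
        a = variant_factory(pos=100, alt_count=30)
        b = variant_factory(pos=101, alt_count=5)
        assert len(merge_dinucleotides([a, b])) == 2

    def test_non_adjacent_positions_stay_separate(self, variant_factory):
        a = variant_factory(pos=100, alt_count=30)
        b = variant_factory(pos=102, alt_count=30)
        assert len(merge_dinucleotides([a, b])) == 2

    def test_triplet_merges_greedily_left_to_right(self, variant_factory):
        """Three consecutive similar sites: the oracle enumerates greedy
        left-to-right pairing — (100,101) merge, 102 remains."""
        trip = [variant_factory(pos=p, alt_count=30) for p in (100, 101, 102)]
        # independent oracle: simulate greedy pairing on sorted positions
        positions = sorted(v.pos for v in trip)
        expected = []
        i = 0
        while i < len(positions):
            if i + 1 < len(positions) and positions[i + 1] - positions[i] == 1:
                expected.append(positions[i])
                i += 2
            else:
                expected.append(positions[i])
                i += 1
        got = merge_dinucleotides(trip)
        assert [v.pos for v in got] == expected
        assert len(got) == 2

    def test_rel_tol_out_of_range_rejected(self, variant_factory):
        with pytest.raises(ValueError):
            merge_dinucleotides([variant_factory()], rel_tol=1.5)

    @given(st.lists(st.integers(1, 60), min_size=0, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_never_increases_count_and_keeps_nonsyn_floor(self, counts):
        from tests.conftest import make_variant
        variants = [
            make_variant(pos=100 + i, alt_count=c, depth=c + 40,
                         consequence=Consequence.SYNONYMOUS)
            for i, c in enumerate(counts)
        ]
        out = merge_dinucleotides(variants)
        merges = len(variants) - len(out)
        assert merges >= 0
        n_nonsyn_in = sum(
            1 for v in variants if v.consequence is Consequence.NONSYNONYMOUS)
        n_nonsyn_out = sum(
            1 for v in out if v.consequence is Consequence.NONSYNONYMOUS)
        assert n_nonsyn_out >= n_nonsyn_in - merges
        assert n_nonsyn_out == merges  # all-synonymous input: merged only


class TestFootprintAndTmb:
    def test_partial_overlap_is_one_mb(self):
        mask = CoverageMask("S1", [("chr1", 0, 2_000_000)])
        assert footprint_mb(mask, [("chr1", 1_000_000, 3_000_000)]) == 1.0

    def test_identical_mask_and_cds(self):
        ivs = [("chr1", 0, 32_000_000)]
        assert footprint_mb(CoverageMask("S1", list(ivs)), ivs) == 32.0

    def test_disjoint_mask_errors(self):
        mask = CoverageMask("S1", [("chr1", 0, 10)])
        with pytest.raises(ValueError, match="disjoint"):
            footprint_mb(mask, [("chr2", 0, 10)])

    @pytest.mark.parametrize("n_nonsyn,mb,expected", [
        (64, 32.0, 2.0), (0, 32.0, 0.0), (25, 31.25, 0.8),
    ])
    def test_exomic_tmb_values(self, variant_factory, n_nonsyn, mb, expected):
        variants = [variant_factory(pos=i + 1) for i in range(n_nonsyn)]
        variants += [variant_factory(pos=10_000 + i,
                                     consequence=Consequence.SYNONYMOUS)
                     for i in range(7)]  # synonymous never counts
        profile = SampleProfile("S1", variants, exome_footprint_mb=mb)
        assert exomic_tmb(profile) == pytest.approx(expected)


class TestRestrictToPanel:
    panel = PanelDefinition("toy", [("chr1", 100, 200)], cds_mb=0.0001)

    def test_one_based_position_inside_half_open_interval(self, variant_factory):
        # 1-based 150 is 0-based 149, inside [100, 200)
        assert restrict_to_panel([variant_factory(pos=150)], self.panel)

    def test_boundary_position_excluded(self, variant_factory):
        # 1-based 201 is 0-based 200, outside the half-open end
        assert not restrict_to_panel([variant_factory(pos=201)], self.panel)

    def test_interval_start_included(self, variant_factory):
        # 1-based 101 is 0-based 100, the first covered base
        assert restrict_to_panel([variant_factory(pos=101)], self.panel)
        assert not restrict_to_panel([variant_factory(pos=100)], self.panel)

    def test_exome_as_panel_is_identity(self, variant_factory, rng):
        variants = [variant_factory(pos=int(p))
                    for p in rng.integers(1, 10**6, size=50)]
        exome_panel = PanelDefinition("exome", [("chr1", 0, 10**6)], cds_mb=1.0)
        assert restrict_to_panel(variants, exome_panel) == variants


class TestPanelInputs:
    def _variants(self, variant_factory):
        out = []
        for i in range(12):
            out.append(variant_factory(pos=1000 + i, hotspot=i < 2))
        for i in range(4):
            out.append(variant_factory(
                pos=2000 + i, consequence=Consequence.SYNONYMOUS))
        return out

    panel = PanelDefinition("toy", [("chr1", 0, 4_000_000)], cds_mb=4.0)

    def test_nonsyn_only_hotspots_included(self, variant_factory):
        iv = panel_inputs(self._variants(variant_factory), self.panel, "EUR")
        assert iv.nonsyn_per_mb == pytest.approx(3.0)

    def test_nonsyn_only_hotspots_removed(self, variant_factory):
        iv = panel_inputs(
            self._variants(variant_factory), self.panel, "EUR",
            InputConfig(remove_hotspots=True))
        assert iv.nonsyn_per_mb == pytest.approx(2.5)
        assert iv.hotspot_per_mb == 0.0

    def test_full_count_vector(self, variant_factory):
        iv = panel_inputs(
            self._variants(variant_factory), self.panel, "EUR",
            InputConfig(use_all=True, use_hotspot=True))
        assert (iv.nonsyn_per_mb, iv.all_per_mb, iv.hotspot_per_mb) == \
            pytest.approx((3.0, 4.0, 0.5))

    def test_unknown_ancestry_encoded_as_other(self, variant_factory):
        iv = panel_inputs(
            self._variants(variant_factory), self.panel, "MARTIAN",
            InputConfig(use_ancestry=True))
        assert iv.ancestry_onehot[-1] == 1.0
        assert iv.ancestry_onehot.sum() == 1.0

    def test_homogeneous_in_counts(self, variant_factory):
        """Doubling every count at fixed cds_mb doubles every per-Mb field."""
        base = self._variants(variant_factory)
        doubled = base + [
            type(v)(**{**v.__dict__, "pos": v.pos + 500_000}) for v in base
        ]
        cfg = InputConfig(use_all=True, use_hotspot=True)
        iv1 = panel_inputs(base, self.panel, "EUR", cfg)
        iv2 = panel_inputs(doubled, self.panel, "EUR", cfg)
        assert iv2.nonsyn_per_mb == pytest.approx(2 * iv1.nonsyn_per_mb)
        assert iv2.all_per_mb == pytest.approx(2 * iv1.all_per_mb)
        assert iv2.hotspot_per_mb == pytest.approx(2 * iv1.hotspot_per_mb)

    def test_zero_variant_sample_is_legal(self):
        iv = panel_inputs([], self.panel, "EUR")
        assert iv.nonsyn_per_mb == 0.0 and iv.all_per_mb == 0.0


class TestCapTrainingSet:
    @staticmethod
    def _table(values):
        return pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(len(values))],
            "nonsyn_per_mb": values,
        })

    def test_p98_on_1_to_100_keeps_98(self):
        capped = cap_training_set(self._table(list(range(1, 101))))
        assert len(capped) == 98
        assert capped["nonsyn_per_mb"].max() == 98

    def test_identical_inputs_all_retained(self):
        capped = cap_training_set(self._table([5.0] * 40))
        assert len(capped) == 40

    def test_percentile_100_is_identity(self):
        table = self._table([1.0, 2.0, 3.0])
        assert len(cap_training_set(table, percentile=100)) == 3

    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError):
            cap_training_set(self._table([1.0]), percentile=0)

    @given(st.integers(50, 99), st.integers(0, 5))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_percentile(self, p, bump):
        values = list(np.linspace(0, 50, 60))
        lower = cap_training_set(self._table(values), percentile=p)
        higher = cap_training_set(self._table(values),
                                  percentile=min(p + bump, 100))
        assert set(lower["sample_id"]) <= set(higher["sample_id"])
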