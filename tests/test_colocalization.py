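"""Pairwise and any-of-many colocalization under both overlap definitions."""

import math

import numpy as np
import pytest

from puncta.colocalization import (
    LENIENT_CENTROID,
    PERCENT_OF_PAIR,
    PERCENT_OF_REFERENCE,
    PIXEL_OVERLAP,
    STRINGENT_CENTROID,
    OverlapCriterion,
    colocalized_reference_ids,
    colocalized_with_any,
    pairwise_matrix,
    percent_of_pair,
    percent_of_reference,
)
from puncta.core import RoiSpec
from puncta.synth import uniform_puncta_set

from conftest import make_set


class TestColocalizedIds:
    def test_empty_target_gives_empty_set(self, roi52):
        a = make_set("A", [(10, 10), (20, 20)], roi52)
        b = make_set("B", [], roi52)
        for crit in (LENIENT_CENTROID, STRINGENT_CENTROID, PIXEL_OVERLAP):
            assert colocalized_reference_ids(a, b, crit) == set()

    def test_channel_against_itself_all_colocalized(self, roi52):
        pts = [(5, 5), (15, 25), (40, 10)]
        a = make_set("A", pts, roi52)
        b = make_set("B", pts, roi52)
        for crit in (LENIENT_CENTROID, STRINGENT_CENTROID, PIXEL_OVERLAP):
            assert colocalized_reference_ids(a, b, crit) == {0, 1, 2}

    def test_centroid_inequality_is_strict_at_both_fractions(self, roi52):
        # Feret 0.4 each, centroid distance 0.39: colocalized under the
        # lenient rule (0.39 < 0.99*0.4) but not the stringent (0.39 > 0.20)
        a = make_set("A", [(10.0, 10.0)], roi52, feret=0.4)
        b = make_set("B", [(10.39, 10.0)], roi52, feret=0.4)
        assert colocalized_reference_ids(a, b, LENIENT_CENTROID) == {0}
        assert colocalized_reference_ids(a, b, STRINGENT_CENTROID) == set()

    def test_hub_punctum_counted_once(self, roi52):
        a = make_set("A", [(10, 10)], roi52)
        b = make_set("B", [(10.05, 10), (9.95, 10), (10, 10.05)], roi52)
        assert len(colocalized_reference_ids(a, b, LENIENT_CENTROID)) == 1
        # reverse direction: all three partners count
        assert len(colocalized_reference_ids(b, a, LENIENT_CENTROID)) == 3

    def test_uniform_scene_matches_analytic_probability(self, roi180):
        # CSR closed form 1 - (1 - pi (f(rA+rB))^2 / S)^nB, pooled over seeds
        r, f, n_b, n_a = 0.3, 0.99, 2000, 300
        s_area = roi180.area_um2
        p_pred = 1 - (1 - math.pi * (f * 2 * r) ** 2 / s_area) ** n_b
        hits = total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = uniform_puncta_set("A", n_a, r, roi180, rng)
            b = uniform_puncta_set("B", n_b, r, roi180, rng)
            hits += len(colocalized_reference_ids(a, b, LENIENT_CENTROID))
            total += n_a
        se = math.sqrt(p_pred * (1 - p_pred) / total)
        assert abs(hits / total - p_pred) < 3 * se

    def test_pixel_and_lenient_centroid_agree_on_clear_geometry(self, roi52):
        together = make_set("A", [(10, 10)], roi52)
        partner = make_set("B", [(10.02, 10.0), (40.0, 40.0)], roi52)
        for crit in (PIXEL_OVERLAP, LENIENT_CENTROID):
            assert colocalized_reference_ids(together, partner, crit) == {0}

    def test_missing_feret_raises_with_punctum_name(self, roi52):
        a = make_set("A", [(10, 10)], roi52)
        bad = make_set("B", [(10, 10)], roi52, feret=float("nan"))
        with pytest.raises(ValueError, match="Feret"):
            colocalized_reference_ids(a, bad, LENIENT_CENTROID)

    def test_mismatched_roi_rejected(self, roi52, roi180):
        a = make_set("A", [(10, 10)], roi52)
        b = make_set("B", [(10, 10)], roi180)
        with pytest.raises(ValueError, match="ROI"):
            colocalized_reference_ids(a, b, LENIENT_CENTROID)


class TestPercentages:
    @pytest.mark.parametrize(
        "n_coloc,n_total,expected",
        [(85, 107, 79.4), (33, 107, 30.8), (5, 107, 4.7), (0, 107, 0.0)],
    )
    def test_percent_formula(self, roi52, n_coloc, n_total, expected):
        # reference puncta co-placed with a partner for the first n_coloc
        pts_a = [(0.5 + 0.5 * (i % 100), 0.5 + 0.5 * (i // 100)) for i in range(n_total)]
        a = make_set("A", pts_a, roi52, feret=0.2)
        b = make_set("B", pts_a[:n_coloc], roi52, feret=0.2) if n_coloc else make_set("B", [], roi52)
        if n_coloc == 0:
            b = make_set("B", [(51.0, 51.0)], roi52, feret=0.2)
        got = percent_of_reference(a, b, STRINGENT_CENTROID)
        assert round(got, 1) == expected

    def test_empty_reference_reported_missing(self, roi52):
        a = make_set("A", [], roi52)
        b = make_set("B", [(10, 10)], roi52)
        assert percent_of_reference(a, b, LENIENT_CENTROID) is None

    def test_percent_of_pair_identical_channels_is_100(self, roi52):
        pts = [(5, 5), (20, 20)]
        a = make_set("A", pts, roi52)
        b = make_set("B", pts, roi52)
        assert percent_of_pair(a, b, LENIENT_CENTROID) == 100.0

    def test_percent_of_pair_disjoint_is_0_and_symmetric(self, roi52):
        a = make_set("A", [(5, 5)], roi52)
        b = make_set("B", [(45, 45), (40, 40)], roi52)
        assert percent_of_pair(a, b, LENIENT_CENTROID) == 0.0
        c = make_set("C", [(5.1, 5.0)], roi52)
        assert percent_of_pair(a, c, LENIENT_CENTROID) == pytest.approx(
            percent_of_pair(c, a, LENIENT_CENTROID)
        )

    def test_scale_free_under_duplication(self, roi180):
        # doubling every punctum with an offset copy leaves percentages stable
        rng = np.random.default_rng(3)
        a = uniform_puncta_set("A", 300, 0.3, roi180, rng)
        b = uniform_puncta_set("B", 1500, 0.3, roi180, rng)
        base = percent_of_reference(a, b, LENIENT_CENTROID)

        def duplicate(pset, name):
            # offset copy sits right next to its original, so each pair acts
            # as one effective object and percentages should be preserved
            pts = [(p.centroid_xy[0], p.centroid_xy[1]) for p in pset]
            shifted = [(min(x + 0.05, 180.0), y) for x, y in pts]
            return make_set(name, pts + shifted, roi180, feret=0.6)

        doubled = percent_of_reference(
            duplicate(a, "A2"), duplicate(b, "B2"), LENIENT_CENTROID
        )
        assert abs(doubled - base) < 5.0  # within sampling noise


class TestPairwiseMatrix:
    def test_twelve_channels_give_66_unordered_pairs(self, roi52):
        rng = np.random.default_rng(0)
        sets = [
            uniform_puncta_set(f"ch{i}", 5, 0.2, roi52, rng) for i in range(12)
        ]
        mat = pairwise_matrix(sets, LENIENT_CENTROID)
        off_diag = [(r, t) for r in mat.channels for t in mat.channels if r < t]
        assert len(off_diag) == 66

    def test_identical_channels_100_percent_off_diagonal(self, roi52):
        pts = [(5, 5), (20, 20), (35, 35)]
        mat = pairwise_matrix(
            [make_set("A", pts, roi52), make_set("B", pts, roi52)],
            LENIENT_CENTROID,
        )
        assert mat.percent.loc["A", "B"] == 100.0
        assert mat.percent.loc["B", "A"] == 100.0

    def test_matrix_matches_per_pair_operations(self, roi180):
        rng = np.random.default_rng(7)
        sets = [
            uniform_puncta_set("A", 150, 0.3, roi180, rng),
            uniform_puncta_set("B", 400, 0.3, roi180, rng),
            uniform_puncta_set("C", 80, 0.3, roi180, rng),
        ]
        mat = pairwise_matrix(sets, LENIENT_CENTROID, PERCENT_OF_REFERENCE)
        pair_mat = pairwise_matrix(sets, LENIENT_CENTROID, PERCENT_OF_PAIR)
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                assert mat.percent.loc[a.channel, b.channel] == pytest.approx(
                    percent_of_reference(a, b, LENIENT_CENTROID)
                )
                assert pair_mat.percent.loc[a.channel, b.channel] == pytest.approx(
                    percent_of_pair(a, b, LENIENT_CENTROID)
                )

    def test_pair_normalization_is_symmetric(self, roi180):
        rng = np.random.default_rng(11)
        sets = [
            uniform_puncta_set("A", 100, 0.3, roi180, rng),
            uniform_puncta_set("B", 700, 0.3, roi180, rng),
        ]
        mat = pairwise_matrix(sets, LENIENT_CENTROID, PERCENT_OF_PAIR)
        assert mat.percent.loc["A", "B"] == pytest.approx(mat.percent.loc["B", "A"])

    def test_duplicate_channel_labels_rejected(self, roi52):
        a = make_set("A", [(5, 5)], roi52)
        with pytest.raises(ValueError, match="duplicated"):
            pairwise_matrix([a, a], LENIENT_CENTROID)

    def test_counts_bounded_by_reference_totals(self, roi180):
        rng = np.random.default_rng(5)
        sets = [
            uniform_puncta_set("A", 200, 0.3, roi180, rng),
            uniform_puncta_set("B", 900, 0.3, roi180, rng),
        ]
        mat = pairwise_matrix(sets, LENIENT_CENTROID)
        for ref in mat.channels:
            for tgt in mat.channels:
                assert 0 <= mat.counts.loc[ref, tgt] <= mat.totals[ref]


class TestColocalizedWithAny:
    def test_all_empty_others_gives_empty(self, roi52):
        a = make_set("A", [(5, 5)], roi52)
        others = [make_set("B", [], roi52), make_set("C", [], roi52)]
        assert colocalized_with_any(a, others, LENIENT_CENTROID) == set()

    def test_union_equals_union_of_pairwise(self, roi180):
        rng = np.random.default_rng(9)
        a = uniform_puncta_set("A", 200, 0.3, roi180, rng)
        others = [
            uniform_puncta_set(n, 300, 0.3, roi180, rng) for n in ("B", "C", "D")
        ]
        union = colocalized_with_any(a, others, LENIENT_CENTROID)
        brute = set()
        for b in others:
            brute |= colocalized_reference_ids(a, b, LENIENT_CENTROID)
        assert union == brute

    def test_single_overlap_included_once(self, roi52):
        a = make_set("A", [(10, 10)], roi52)
        others = [
            make_set("B", [(10.05, 10)], roi52),
            make_set("C", [(40, 40)], roi52),
        ]
        assert colocalized_with_any(a, others, LENIENT_CENTROID) == {0}


class TestCriterionValidation:
    def test_bad_mode_and_fraction_rejected(self):
        with pytest.raises(ValueError):
            OverlapCriterion(mode="voxel")
        with pytest.raises(ValueError):
            OverlapCriterion(mode="centroid", fraction=0.0)
        with pytest.raises(ValueError):
            OverlapCriterion(mode="pixel", min_pixels=0)
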