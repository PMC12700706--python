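"""Singleton/dimer/multimer classification and marker gating."""

import numpy as np
import pytest

from puncta.colocalization import LENIENT_CENTROID, PIXEL_OVERLAP
from puncta.composition import (
    MarkerGate,
    classify_composition,
    composition_null,
    gate_by_marker,
)
from puncta.core import BinaryMask, RoiSpec
from puncta.synth import ChannelSpec, GranulePlan, generate_scene, uniform_puncta_set

from conftest import make_set


class TestClassify:
    def test_hand_built_toy_matches_manual_enumeration(self, roi52):
        # focal punctum 0: overlaps special only        -> dimer(special)
        # focal punctum 1: overlaps special + other     -> multimer with
        # focal punctum 2: overlaps other1 + other2     -> multimer without
        # focal punctum 3: overlaps other1 only         -> dimer(other1)
        # focal punctum 4: overlaps nothing             -> singleton
        focal = make_set("F", [(5, 5), (10, 10), (15, 15), (20, 20), (30, 30)], roi52)
        special = make_set("S", [(5.05, 5), (10.05, 10)], roi52)
        other1 = make_set("O1", [(10, 10.05), (15.05, 15), (20, 20.05)], roi52)
        other2 = make_set("O2", [(15, 15.05)], roi52)
        s = classify_composition(focal, [special, other1, other2], "S", LENIENT_CENTROID)
        assert s.singleton == pytest.approx(20.0)
        assert s.dimer_per_partner["S"] == pytest.approx(20.0)
        assert s.dimer_per_partner["O1"] == pytest.approx(20.0)
        assert s.dimer_per_partner["O2"] == pytest.approx(0.0)
        assert s.multimer_with_special == pytest.approx(20.0)
        assert s.multimer_without_special == pytest.approx(20.0)
        assert s.total == pytest.approx(100.0, abs=0.01)

    def test_no_partner_overlap_all_singletons(self, roi52):
        focal = make_set("F", [(5, 5), (10, 10)], roi52)
        partner = make_set("P", [(40, 40)], roi52)
        s = classify_composition(focal, [partner], None, LENIENT_CENTROID)
        assert s.singleton == 100.0
        assert s.colocalized_any == 0.0

    def test_two_partners_same_channel_still_a_dimer(self, roi52):
        # partner multiplicity within one channel is not multimerization
        focal = make_set("F", [(10, 10)], roi52)
        partner = make_set("P", [(10.05, 10), (9.95, 10)], roi52)
        s = classify_composition(focal, [partner], None, LENIENT_CENTROID)
        assert s.dimer_per_partner["P"] == 100.0

    def test_empty_focal_reported_missing(self, roi52):
        focal = make_set("F", [], roi52)
        partner = make_set("P", [(10, 10)], roi52)
        assert classify_composition(focal, [partner], None, LENIENT_CENTROID) is None

    def test_special_must_be_in_panel(self, roi52):
        focal = make_set("F", [(5, 5)], roi52)
        partner = make_set("P", [(6, 6)], roi52)
        with pytest.raises(ValueError, match="panel"):
            classify_composition(focal, [partner], "Q", LENIENT_CENTROID)

    def test_planted_scene_recovers_designed_fractions(self, roi180):
        # 30% of focal co-placed with special only, 20% with special + other
        specs = [
            ChannelSpec("F", 200), ChannelSpec("S", 400), ChannelSpec("O", 100),
        ]
        plans = [GranulePlan(("F", "S"), 0.5)]
        scene = generate_scene(specs, plans, roi180, seed=1, poisson_counts=False)
        # co-place O on 40% of the planted F puncta (=> 20% of F overall)
        planted_f = scene.truth[
            (scene.truth.channel == "F") & (scene.truth.granule_id >= 0)
        ].id.tolist()
        promote = planted_f[: len(planted_f) * 2 // 5]
        from puncta.core import Punctum, PunctaSet

        o_new = list(scene["O"].puncta)
        f_by_id = {p.id: p for p in scene["F"]}
        next_id = max(scene["O"].ids()) + 1
        for fid in promote:
            x, y = f_by_id[fid].centroid_xy
            o_new.append(Punctum(next_id, "O", (x, y), 0.1, 0.4, 10.0, 1.0))
            next_id += 1
        scene.channels["O"] = PunctaSet("O", roi180, o_new)
        s = classify_composition(
            scene["F"], [scene["S"], scene["O"]], "S", LENIENT_CENTROID
        )
        assert s.singleton == pytest.approx(50.0, abs=6.0)
        assert s.dimer_per_partner["S"] == pytest.approx(30.0, abs=6.0)
        assert s.multimer_with_special == pytest.approx(20.0, abs=6.0)

    def test_monotone_under_panel_shrinkage(self, roi180):
        rng = np.random.default_rng(5)
        focal = uniform_puncta_set("F", 200, 0.3, roi180, rng)
        partners = [uniform_puncta_set(n, 800, 0.3, roi180, rng) for n in "ABC"]
        full = classify_composition(focal, partners, "A", LENIENT_CENTROID)
        reduced = classify_composition(focal, partners[:2], "A", LENIENT_CENTROID)
        assert reduced.singleton >= full.singleton
        assert (
            reduced.multimer_with_special + reduced.multimer_without_special
            <= full.multimer_with_special + full.multimer_without_special
        )


class TestCompositionNull:
    def test_sparse_uniform_scene_mostly_singletons_both_ways(self, roi180):
        rng = np.random.default_rng(6)
        focal = uniform_puncta_set("F", 100, 0.2, roi180, rng)
        partners = [uniform_puncta_set(n, 50, 0.2, roi180, rng) for n in "AB"]
        s = classify_composition(focal, partners, "A", LENIENT_CENTROID)
        n = composition_null(focal, partners, "A", LENIENT_CENTROID, angle=90)
        assert s.singleton > 95.0
        assert n.singleton > 95.0

    def test_null_singleton_matches_independence_closed_form(self, roi180):
        # CSR: P(singleton) = prod_channels (1 - p_overlap(channel))
        import math

        r, f = 0.3, 0.99
        s_area = roi180.area_um2
        counts = {"A": 2000, "B": 800}
        singles = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            focal = uniform_puncta_set("F", 200, r, roi180, rng)
            partners = [
                uniform_puncta_set(n, c, r, roi180, rng) for n, c in counts.items()
            ]
            nul = composition_null(focal, partners, "A", LENIENT_CENTROID, 90)
            singles.append(nul.singleton / 100.0)
        p_hit = lambda nb: 1 - (1 - math.pi * (f * 2 * r) ** 2 / s_area) ** nb
        expected = (1 - p_hit(2000)) * (1 - p_hit(800))
        n_total = 200 * 15
        se = math.sqrt(expected * (1 - expected) / n_total)
        assert abs(np.mean(singles) - expected) < 3 * se


class TestMarkerGate:
    def test_marker_covering_roi_is_identity(self, roi52, make_puncta_set):
        sets = [make_puncta_set("A", [(5, 5), (20, 20)], roi52, feret=0.3)]
        full = BinaryMask(np.ones(roi52.shape, bool), roi52)
        out = gate_by_marker(sets, MarkerGate(full, PIXEL_OVERLAP))
        assert out[0].ids() == [0, 1]

    def test_empty_marker_empties_all_channels(self, roi52, make_puncta_set):
        sets = [make_puncta_set("A", [(5, 5)], roi52, feret=0.3)]
        empty = BinaryMask(np.zeros(roi52.shape, bool), roi52)
        out = gate_by_marker(sets, MarkerGate(empty, PIXEL_OVERLAP))
        assert len(out[0]) == 0

    def test_marker_over_granules_enriches_planted_colocalization(self, roi52):
        from puncta.colocalization import percent_of_reference
        from puncta.core import disc_pixels

        specs = [ChannelSpec("A", 150), ChannelSpec("B", 200)]
        scene = generate_scene(
            specs, [GranulePlan(("A", "B"), 0.3)], roi52, seed=2, poisson_counts=False
        )
        grid = np.zeros(roi52.shape, bool)
        planted = scene.truth[
            (scene.truth.channel == "A") & (scene.truth.granule_id >= 0)
        ].id
        by_id = {p.id: p for p in scene["A"]}
        for fid in planted:
            for r, c in disc_pixels(by_id[fid].centroid_xy, 1.0, roi52):
                grid[r, c] = True
        gated = gate_by_marker(
            [scene["A"], scene["B"]], MarkerGate(BinaryMask(grid, roi52))
        )
        ungated_pct = percent_of_reference(scene["A"], scene["B"], LENIENT_CENTROID)
        gated_pct = percent_of_reference(gated[0], gated[1], LENIENT_CENTROID)
        assert gated_pct >= ungated_pct
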