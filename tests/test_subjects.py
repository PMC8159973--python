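"""Subject records and airway-tree morphometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungdose import (
    GenerationRow,
    ValidationError,
    area_profile,
    assemble_lung,
    build_lobe_tree,
    load_subject,
    merge_central_distal,
    scale_to_frc,
    total_volume,
)
from lungdose.subjects import CONDUCTING, DEFAULT_LOBAR_FRACTIONS, RESPIRATORY


class TestLoadSubject:
    def test_infant_record(self):
        s = load_subject("infant")
        assert (s.TV, s.V_FRC, s.RR, s.A_FRC, s.BSA) == (49.0, 81.0, 0.66, 3.2, 0.31)
        assert s.D_trachea == 4.0

    def test_adult_record(self):
        s = load_subject("adult")
        assert (s.TV, s.RR, s.TV_over_TVA) == (500.0, 0.25, 1.0)

    def test_child_record(self):
        s = load_subject("child")
        assert (s.TV, s.RR, s.BSA, s.V_FRC) == (209.0, 0.32, 0.77, 830.0)

    def test_pure_lookup(self):
        assert load_subject("adult") == load_subject("adult")

    def test_unknown_label_names_available(self):
        with pytest.raises(LookupError, match="infant"):
            load_subject("toddler")

    def test_tv_ratio_consistent_with_adult(self):
        adult_tv = load_subject("adult").TV
        for label in ("infant", "child", "adult"):
            s = load_subject(label)
            assert s.TV_over_TVA == pytest.approx(s.TV / adult_tv, abs=0.005)


class TestBuildLobeTree:
    def test_conducting_taper_halves_diameter_every_three_generations(self):
        rows = build_lobe_tree("LI", 20, 16, {"d0": 12.0, "L0": 36.0}, 2 ** (-1 / 3))
        assert rows[3].diameter == pytest.approx(0.5 * rows[0].diameter)

    def test_zone_split_at_generation_16(self):
        rows = build_lobe_tree("LI", 24, 16, {"d0": 12.0, "L0": 36.0})
        for r in rows:
            assert r.zone == (RESPIRATORY if r.generation >= 16 else CONDUCTING)
            assert (r.alveolar_volume > 0) == (r.generation >= 16)

    def test_airway_volume_matches_row_by_row_sum(self):
        rows = build_lobe_tree("RI", 18, 15, {"d0": 10.0, "L0": 30.0})
        oracle = sum(
            r.n_airways * math.pi / 4.0 * r.diameter**2 * r.length / 1e3
            for r in rows
        )
        assert sum(r.airway_volume for r in rows) == pytest.approx(oracle, rel=1e-12)

    def test_counts_double_each_generation(self):
        rows = build_lobe_tree("LS", 10, 8, {"d0": 8.0, "L0": 24.0})
        assert [r.n_airways for r in rows] == [2**k for k in range(10)]

    def test_rejects_nonphysical_inputs(self):
        with pytest.raises(ValidationError):
            build_lobe_tree("LI", 10, 5, {"d0": 8.0, "L0": 24.0}, taper=1.2)
        with pytest.raises(ValidationError):
            build_lobe_tree("LI", 10, 5, {"d0": -1.0, "L0": 24.0})


class TestScaleToFrc:
    def test_identity_when_already_at_target(self):
        rows = build_lobe_tree("LI", 12, 9, {"d0": 8.0, "L0": 24.0})
        scaled = scale_to_frc(rows, total_volume(rows))
        for a, b in zip(rows, scaled):
            assert b.diameter == pytest.approx(a.diameter, rel=1e-12)

    def test_cube_root_scaling_factor(self):
        rows = build_lobe_tree("LI", 12, 9, {"d0": 8.0, "L0": 24.0})
        scaled = scale_to_frc(rows, 8.0 * total_volume(rows))
        assert scaled[0].diameter == pytest.approx(2.0 * rows[0].diameter)

    def test_rejects_nonpositive_target(self):
        rows = build_lobe_tree("LI", 12, 9, {"d0": 8.0, "L0": 24.0})
        with pytest.raises(ValidationError):
            scale_to_frc(rows, 0.0)

    @settings(max_examples=100, deadline=None)
    @given(
        d0=st.floats(2.0, 20.0),
        ld=st.floats(2.0, 4.0),
        n=st.integers(8, 24),
        target=st.floats(10.0, 5000.0),
    )
    def test_volume_hits_target_for_random_trees(self, d0, ld, n, target):
        rows = build_lobe_tree("RM", n, max(n - 6, 1), {"d0": d0, "L0": ld * d0})
        scaled = scale_to_frc(rows, target)
        assert total_volume(scaled) == pytest.approx(target, rel=1e-3)


class TestMergeCentralDistal:
    @staticmethod
    def _path(gens, d0, lobe="LI"):
        return [
            GenerationRow(lobe, z, 2**z, d0 * 0.8**i, 3 * d0 * 0.8**i, 0.0, CONDUCTING)
            for i, z in enumerate(gens)
        ]

    def test_continuous_trees_need_no_rescale(self):
        central = self._path(range(0, 4), 10.0)
        # distal seeded so its gen-4 area exactly continues the central path
        a_end = sum(r.airway_area for r in central if r.generation == 3)
        d_next = math.sqrt(a_end / (2**4 * math.pi / 4.0)) * 10.0  # cm -> mm
        distal = self._path(range(4, 8), d_next)
        merged = merge_central_distal(central, distal)
        a4 = sum(r.airway_area for r in merged if r.generation == 4)
        assert a4 == pytest.approx(a_end, rel=1e-9)

    def test_rescale_factor_is_sqrt_area_ratio(self):
        central = self._path(range(0, 4), 10.0)
        distal = self._path(range(4, 8), 25.0)
        a_end = sum(r.airway_area for r in central if r.generation == 3)
        a_start = sum(r.airway_area for r in distal if r.generation == 4)
        factor = math.sqrt(a_end / a_start)
        merged = merge_central_distal(central, distal)
        assert merged[4].diameter == pytest.approx(distal[0].diameter * factor, rel=1e-12)

    def test_area_quadruple_gives_half_diameter(self):
        central = self._path(range(0, 2), 10.0)
        distal = self._path([2, 3], 10.0)
        a_end = sum(r.airway_area for r in central if r.generation == 1)
        a_start = sum(r.airway_area for r in distal if r.generation == 2)
        # rescale the distal seed so its entry area is exactly 4x the
        # central end area; the merge must then halve every distal diameter
        wide = [
            GenerationRow(r.lobe, r.generation, r.n_airways,
                          r.diameter * math.sqrt(4.0 * a_end / a_start),
                          r.length, 0.0, CONDUCTING)
            for r in distal
        ]
        merged = merge_central_distal(central, wide)
        assert merged[2].diameter == pytest.approx(0.5 * wide[0].diameter, rel=1e-12)

    def test_generation_gap_is_structural_error(self):
        from lungdose import StructuralError

        with pytest.raises(StructuralError):
            merge_central_distal(self._path(range(0, 3), 10.0),
                                 self._path(range(5, 8), 5.0))


class TestAssembleLung:
    def test_default_fractions_sum_to_one(self):
        assert sum(DEFAULT_LOBAR_FRACTIONS) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("label", ["infant", "child", "adult"])
    def test_model_volume_matches_frc(self, label, lungs):
        lung = lungs[label]
        assert lung.V_FRC_model == pytest.approx(lung.subject.V_FRC, rel=1e-3)

    def test_assembly_is_deterministic(self):
        s = load_subject("child")
        a, b = assemble_lung(s), assemble_lung(s)
        assert [r.diameter for r in a.rows] == [r.diameter for r in b.rows]

    def test_bad_fractions_rejected(self):
        s = load_subject("adult")
        with pytest.raises(ValidationError):
            assemble_lung(s, lobar_fractions=(0.3, 0.3, 0.3, 0.3, 0.3))

    def test_infant_left_inferior_alveolates_one_generation_later(self, lungs):
        li = [r for r in lungs["infant"].lobe_rows("LI") if r.zone == RESPIRATORY]
        rs = [r for r in lungs["infant"].lobe_rows("RS") if r.zone == RESPIRATORY]
        assert min(r.generation for r in li) == 17
        assert min(r.generation for r in rs) == 16

    @pytest.mark.parametrize("label", ["infant", "child", "adult"])
    def test_trumpet_area_nondecreasing_beyond_generation_five(self, label, lungs):
        profile = area_profile(lungs[label], lungs[label].subject.V_FRC)
        gens = sorted(g for g in profile if g >= 5)
        areas = [profile[g]["A_airway"] for g in gens]
        assert all(b >= a * (1 - 1e-12) for a, b in zip(areas, areas[1:]))


class TestAreaProfile:
    def test_baseline_total_equals_frc_area(self, lungs):
        lung = lungs["adult"]
        prof = area_profile(lung, lung.subject.V_FRC)
        # at FRC the inflation factor is 1: A_total from the raw alveolar volumes
        for g, rec in prof.items():
            assert rec["A_total"] >= rec["A_airway"] - 1e-12

    def test_conducting_area_volume_independent(self, lungs):
        lung = lungs["infant"]
        lo = area_profile(lung, lung.subject.V_FRC)
        hi = area_profile(lung, lung.subject.V_FRC + lung.subject.TV)
        for g in range(0, 10):  # purely conducting generations
            assert hi[g]["A_total"] == pytest.approx(lo[g]["A_total"], rel=1e-12)

    def test_respiratory_area_follows_linear_deformation_rule(self, lungs):
        lung = lungs["child"]
        s = lung.subject
        hi = area_profile(lung, s.V_FRC + s.TV)
        infl = 1.0 + s.TV / lung.V_alveolar
        g = 20
        oracle = sum(
            r.airway_area + r.alveolar_volume * infl / (r.length / 10.0)
            for r in lung.rows
            if r.generation == g
        )
        assert hi[g]["A_total"] == pytest.approx(oracle, rel=1e-12)

    def test_volume_out_of_range_rejected(self, lungs):
        lung = lungs["adult"]
        with pytest.raises(ValidationError):
            area_profile(lung, lung.subject.V_FRC - 50.0)
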