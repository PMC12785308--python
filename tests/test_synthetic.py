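"""Synthetic image and response generators: determinism, oracles, margins."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.special import expit

from trichostudy.synthetic import (ImageSpec, ResponseModel, StudyDesign,
                                   generate_scalp_image, matrix_from_margins,
                                   simulate_paired_matrices, simulate_responses)

EIGHT_CONN = np.ones((3, 3), dtype=int)


class TestScalpImages:
    def test_empty_spec_gives_pure_background(self):
        spec = ImageSpec(n_hairs=0, n_follicular_dots=0)
        img, structures = generate_scalp_image(spec, seed=3)
        assert img.shape == (spec.height, spec.width, 3)
        assert (img == np.array(spec.background_color, np.uint8)).all()
        assert structures == []

    def test_same_seed_identical_bytes(self):
        spec = ImageSpec(n_hairs=12, n_follicular_dots=5)
        a, sa = generate_scalp_image(spec, seed=7)
        b, sb = generate_scalp_image(spec, seed=7)
        assert np.array_equal(a, b)
        assert sa == sb

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_hair_stroke_component_count(self, seed):
        # brute-force oracle: dark 8-connected components; strokes may merge
        # by intersection, never split, so 1 <= components <= n_hairs
        spec = ImageSpec(n_hairs=20, n_follicular_dots=0)
        img, structures = generate_scalp_image(spec, seed)
        delta = np.abs(img.astype(int)
                       - np.array(spec.background_color)).max(axis=2)
        dark = delta > spec.hair_darkness_range[0] // 2
        _, n = ndimage.label(dark, structure=EIGHT_CONN)
        assert 1 <= n <= spec.n_hairs
        assert sum(s["type"] == "hair" for s in structures) == spec.n_hairs

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError, match="64"):
            ImageSpec(height=32)
        with pytest.raises(ValueError, match="min <= max"):
            ImageSpec(hair_thickness_range=(4, 2))


class TestStudyDesign:
    def test_default_matches_reference_roster(self):
        d = StudyDesign()
        assert len(d.rater_ids()) == 19  # 15 dermatologists + 4 AI models
        assert d.n_cases == 25
        mask = d.present_mask()
        assert int(mask.to_numpy().sum()) == 19 * 25 - 1

    def test_missing_cell_validation(self):
        with pytest.raises(ValueError, match="unknown rater"):
            StudyDesign(missing_cells=(("nobody", "case_1"),))
        with pytest.raises(ValueError, match="unknown case"):
            StudyDesign(missing_cells=(("gemini", "case_99"),))


class TestSimulateResponses:
    def test_saturated_logits(self):
        design = StudyDesign(groups=(("g", 3),), n_cases=10, missing_cells=())
        hi = simulate_responses(design, ResponseModel(
            group_logits={"g": np.inf}, case_difficulty_sd=0.0, seed=1))
        assert hi.counts() == (30, 30)
        lo = simulate_responses(design, ResponseModel(
            group_logits={"g": -np.inf}, case_difficulty_sd=0.0, seed=1))
        assert lo.counts() == (0, 30)

    def test_missing_cells_stay_missing(self):
        design = StudyDesign()
        m = simulate_responses(design, ResponseModel(seed=5))
        assert np.isnan(m.values.loc["gemini", "case_25"])
        assert np.isfinite(m.values.drop(index="gemini").to_numpy()).all()

    def test_monte_carlo_proportion(self):
        # 50 raters x 200 cases at p = 0.6: binomial SE ~ 0.005
        design = StudyDesign(groups=(("g", 50),), n_cases=200, missing_cells=())
        m = simulate_responses(design, ResponseModel(
            group_logits={"g": float(np.log(0.6 / 0.4))},
            case_difficulty_sd=0.0, seed=42))
        k, n = m.counts()
        assert n == 10_000
        assert abs(k / n - 0.6) < 0.02

    def test_parameter_recovery(self):
        # empirical group proportions recover expit(logit) within 3 MC SEs
        logits = {"low": -1.0, "mid": 0.0, "high": 1.5}
        design = StudyDesign(groups=tuple((g, 60) for g in logits),
                             n_cases=200, missing_cells=())
        m = simulate_responses(design, ResponseModel(
            group_logits=logits, case_difficulty_sd=0.0, seed=9))
        for g, logit in logits.items():
            k, n = m.counts(m.raters_in(g))
            p = expit(logit)
            assert n >= 10_000
            assert abs(k / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_determinism(self):
        design = StudyDesign()
        model = ResponseModel(seed=3)
        a = simulate_responses(design, model)
        b = simulate_responses(design, model)
        assert a.values.equals(b.values)

    def test_paired_matrices_dominance(self):
        pair = simulate_paired_matrices(StudyDesign(), ResponseModel(seed=17))
        sd = pair["SD"].values.to_numpy()
        sddd = pair["SD_DD"].values.to_numpy()
        both = np.isfinite(sd) & np.isfinite(sddd)
        assert (sddd[both] >= sd[both]).all()
        assert (np.isnan(sd) == np.isnan(sddd)).all()


class TestMatrixFromMargins:
    def test_group_count_placement(self):
        design = StudyDesign(groups=(("expert", 6),), n_cases=25, missing_cells=())
        m = matrix_from_margins(design, {"expert": 106})
        k, n = m.counts()
        assert (k, n) == (106, 150)

    def test_zero_and_full_counts(self):
        design = StudyDesign(groups=(("g", 2),), n_cases=4, missing_cells=())
        zero = matrix_from_margins(design, {"g": 0})
        assert zero.counts() == (0, 8)
        full = matrix_from_margins(design, {"g": 8})
        assert full.counts() == (8, 8)

    def test_count_exceeding_cells_rejected(self):
        design = StudyDesign(groups=(("g", 2),), n_cases=4, missing_cells=())
        with pytest.raises(ValueError, match="exceeds"):
            matrix_from_margins(design, {"g": 9})

    def test_per_rater_margins_respect_missing(self):
        design = StudyDesign()
        m = matrix_from_margins(design, {"gemini": 8, "claude": 2},
                                mode="per_rater")
        assert m.counts(["gemini"]) == (8, 24)
        assert m.counts(["claude"]) == (2, 25)
        # deterministic: correct cells sit at the lowest case indices
        assert m.values.loc["gemini", [f"case_{i}" for i in range(1, 9)]].eq(1).all()

    def test_determinism(self):
        design = StudyDesign()
        a = matrix_from_margins(design, {"expert": 10})
        b = matrix_from_margins(design, {"expert": 10})
        assert a.values.equals(b.values)
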