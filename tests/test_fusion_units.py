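import math

import numpy as np
import pytest

from patchfuse import AtlasLibrary, Template, Volume
from patchfuse.core import EmptyMaskError, LabelSetError
from patchfuse.fusion import (
    FusionParams,
    Patch,
    VoteMap,
    adaptive_h2,
    decide_labels,
    extract_patch,
    multiscale_fuse,
    patch_weight,
    select_templates,
    structural_similarity,
)


def _tpl(data, labels=None, name=""):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = np.zeros(data.shape, dtype=np.int32)
    return Template(Volume(data), Volume(np.asarray(labels, dtype=np.int32)), name=name)


class TestFusionParams:
    def test_defaults_match_tuned_operating_point(self):
        p = FusionParams()
        assert p.n_templates == 25
        assert p.patch_size_1 == 3 and p.patch_size_2 == 5
        assert p.search_radius == 4  # 9x9x9 search volume
        assert p.lam == pytest.approx(0.15)
        assert p.sigma_d == pytest.approx(math.sqrt(2.0))
        assert p.scale_weights == (0.5, 0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"patch_size_1": 4},
            {"block_size": 2},
            {"lam": 0.0},
            {"epsilon": -1.0},
            {"ss_threshold": 1.5},
            {"scale_weights": (0.7, 0.7)},
            {"n_templates": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FusionParams(**kwargs)


class TestSelectTemplates:
    def _subject_and_library(self):
        subj = Volume(np.zeros((4, 4, 4)))
        # masked SSDs: 5, 1, 3 over a 1-voxel mask
        lib = AtlasLibrary(
            [
                _tpl(np.full((4, 4, 4), math.sqrt(5.0)), name="a"),
                _tpl(np.full((4, 4, 4), 1.0), name="b"),
                _tpl(np.full((4, 4, 4), math.sqrt(3.0)), name="c"),
            ]
        )
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        return subj, lib, mask

    def test_ranks_by_masked_ssd(self):
        subj, lib, mask = self._subject_and_library()
        out = select_templates(subj, lib, mask, 2)
        assert [t.name for t in out] == ["b", "c"]

    def test_n_at_least_library_returns_all_ranked(self):
        subj, lib, mask = self._subject_and_library()
        out = select_templates(subj, lib, mask, 10)
        assert [t.name for t in out] == ["b", "c", "a"]

    def test_stable_tie_break_by_index(self):
        subj = Volume(np.zeros((2, 2, 2)))
        lib = AtlasLibrary([_tpl(np.ones((2, 2, 2)), name=f"t{i}") for i in range(3)])
        out = select_templates(subj, lib, np.ones((2, 2, 2), dtype=bool), 2)
        assert [t.name for t in out] == ["t0", "t1"]

    def test_empty_mask_raises(self):
        subj, lib, _ = self._subject_and_library()
        with pytest.raises(EmptyMaskError):
            select_templates(subj, lib, np.zeros((4, 4, 4), dtype=bool), 2)


class TestStructuralSimilarity:
    def test_identity_non_constant(self, rng):
        p = rng.normal(100, 10, (3, 3, 3))
        assert structural_similarity(p, p) == pytest.approx(1.0)

    def test_mean_term_direct_arithmetic(self):
        # mu_p=1, mu_q=2, equal sigma -> ss = 2*1*2/(1+4) = 0.8
        p = np.array([0.5, 1.5])
        q = np.array([1.5, 2.5])
        assert structural_similarity(p, q) == pytest.approx(0.8)

    def test_negated_mean_gated_for_any_nonnegative_threshold(self, rng):
        p = rng.normal(5, 1, (3, 3, 3))
        q = -p
        assert structural_similarity(p, q) < 0

    def test_both_constant_equal_means(self):
        p = np.full((3, 3, 3), 7.0)
        assert structural_similarity(p, p.copy()) == pytest.approx(1.0)

    def test_both_constant_different_means_uses_mean_term(self):
        p = np.full((2, 2, 2), 1.0)
        q = np.full((2, 2, 2), 2.0)
        assert structural_similarity(p, q) == pytest.approx(0.8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            structural_similarity(np.ones((2, 2, 2)), np.ones((3, 3, 3)))


class TestAdaptiveH2:
    def _library_with_ssds(self, subj_val, deltas):
        # search_radius=0 -> one candidate per template, SSD = 27*delta^2
        templates = [
            _tpl(np.full((3, 3, 3), subj_val + d), name=f"d{d}") for d in deltas
        ]
        return Volume(np.full((3, 3, 3), subj_val)), AtlasLibrary(templates)

    def test_identical_patch_gives_epsilon(self):
        subj, lib = self._library_with_ssds(100.0, [0.0, 1.0])
        h2 = adaptive_h2(subj, (1, 1, 1), lib, 3, 0, lam=0.15, epsilon=1e-4)
        assert h2 == pytest.approx(1e-4)

    def test_direct_evaluation(self):
        # candidate SSDs {4, 9}: deltas sqrt(4/27), sqrt(9/27)
        subj, lib = self._library_with_ssds(
            100.0, [math.sqrt(4.0 / 27.0), math.sqrt(9.0 / 27.0)]
        )
        h2 = adaptive_h2(subj, (1, 1, 1), lib, 3, 0, lam=0.15, epsilon=1e-4)
        assert h2 == pytest.approx(0.15 * 4.0 + 1e-4)
        assert h2 == pytest.approx(0.6001)

    def test_linear_in_lambda(self):
        subj, lib = self._library_with_ssds(100.0, [0.5])
        h1 = adaptive_h2(subj, (1, 1, 1), lib, 3, 0, lam=0.15, epsilon=1e-4)
        h2 = adaptive_h2(subj, (1, 1, 1), lib, 3, 0, lam=0.30, epsilon=1e-4)
        assert (h2 - 1e-4) == pytest.approx(2.0 * (h1 - 1e-4))

    def test_no_templates_raises(self):
        with pytest.raises(ValueError):
            adaptive_h2(Volume(np.zeros((3, 3, 3))), (1, 1, 1), AtlasLibrary([]), 3, 0)


class TestPatchWeight:
    def _patch(self, data, center=(0, 0, 0)):
        return Patch(np.asarray(data, dtype=float), center)

    def test_identical_patch_zero_offset_weight_one(self, rng):
        p = self._patch(rng.normal(100, 10, (3, 3, 3)))
        assert patch_weight(p, p, h2=1.0, params=FusionParams()) == pytest.approx(1.0)

    def test_ss_gate_forces_zero(self):
        p = self._patch(np.full((3, 3, 3), 1.0))
        q = self._patch(np.full((3, 3, 3), 100.0))  # ss ~ 2*100/10001 << 0.9
        assert patch_weight(p, q, h2=1e6, params=FusionParams()) == 0.0

    def test_ssd_equal_h2_gives_inverse_e(self, rng):
        base = rng.normal(100, 10, (3, 3, 3))
        c = 1.0  # constant shift: SSD = 27, ss ~ 1
        p = self._patch(base)
        q = self._patch(base + c)
        w = patch_weight(p, q, h2=27.0, params=FusionParams())
        assert w == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_spatial_decay(self, rng):
        base = rng.normal(100, 10, (3, 3, 3))
        p = self._patch(base, center=(0, 0, 0))
        q = self._patch(base, center=(1, 0, 0))  # 1 mm offset
        w = patch_weight(p, q, h2=1.0, params=FusionParams())
        # exp(-1 / (2*2)) with sigma_d = sqrt(2)
        assert w == pytest.approx(math.exp(-0.25))

    def test_invalid_h2_rejected(self):
        p = self._patch(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            patch_weight(p, p, h2=0.0, params=FusionParams())


class TestExtractPatch:
    def test_interior_full_cube(self):
        vol = Volume(np.arange(125, dtype=float).reshape(5, 5, 5))
        p = extract_patch(vol, (2, 2, 2), 3)
        assert p.data.shape == (3, 3, 3)
        assert not p.cropped

    def test_border_cropped(self):
        vol = Volume(np.zeros((5, 5, 5)))
        p = extract_patch(vol, (0, 2, 2), 3)
        assert p.data.shape == (2, 3, 3)
        assert p.cropped

    def test_center_outside_raises(self):
        with pytest.raises(IndexError):
            extract_patch(Volume(np.zeros((5, 5, 5))), (5, 0, 0), 3)


def _votemap(values, labels=(0, 1)):
    values = np.asarray(values, dtype=float)
    mask = values.sum(axis=0) > 0
    return VoteMap(values, np.asarray(labels), mask)


class TestMultiscaleFuse:
    def test_idempotent_on_equal_maps(self):
        v = _votemap(np.stack([np.full((2, 2, 2), 0.3), np.full((2, 2, 2), 0.7)]))
        fused = multiscale_fuse(v, v)
        assert np.allclose(fused.votes, v.votes)

    def test_equal_weight_average(self):
        v1 = _votemap(np.stack([np.zeros((1, 1, 1)), np.ones((1, 1, 1))]))
        v0 = _votemap(np.stack([np.ones((1, 1, 1)), np.zeros((1, 1, 1))]))
        fused = multiscale_fuse(v1, v0, (0.5, 0.5))
        assert fused.votes[1, 0, 0, 0] == pytest.approx(0.5)
        assert fused.votes[0, 0, 0, 0] == pytest.approx(0.5)

    def test_label_set_mismatch_rejected(self):
        v1 = _votemap(np.zeros((2, 1, 1, 1)), labels=(0, 1))
        v2 = _votemap(np.zeros((2, 1, 1, 1)), labels=(0, 2))
        with pytest.raises(LabelSetError):
            multiscale_fuse(v1, v2)


class TestDecideLabels:
    def test_binary_threshold_cases(self):
        votes = np.zeros((2, 1, 1, 2))
        votes[:, 0, 0, 0] = [0.4, 0.6]
        votes[:, 0, 0, 1] = [0.6, 0.4]
        out = decide_labels(_votemap(votes))
        assert out.data[0, 0, 0] == 1
        assert out.data[0, 0, 1] == 0

    def test_argmax_over_three_labels(self):
        votes = np.zeros((3, 1, 1, 1))
        votes[:, 0, 0, 0] = [0.2, 0.5, 0.3]
        out = decide_labels(_votemap(votes, labels=(0, 1, 2)))
        assert out.data[0, 0, 0] == 1

    def test_exact_tie_goes_to_smallest_label(self):
        votes = np.zeros((2, 1, 1, 1))
        votes[:, 0, 0, 0] = [0.5, 0.5]
        out = decide_labels(_votemap(votes))
        assert out.data[0, 0, 0] == 0

    def test_tie_break_matches_exhaustive_binary_enumeration(self):
        for v1 in np.linspace(0, 1, 21):
            votes = np.zeros((2, 1, 1, 1))
            votes[:, 0, 0, 0] = [1 - v1, v1]
            out = decide_labels(_votemap(votes))
            expected = 1 if v1 > 0.5 else 0
            assert out.data[0, 0, 0] == expected

    def test_empty_label_set_rejected(self):
        with pytest.raises(ValueError):
            decide_labels(VoteMap(np.zeros((0, 1, 1, 1)), np.array([]), np.ones((1, 1, 1), bool)))
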