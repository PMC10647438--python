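"""Sliding-window inference and segmentation metrics (with brute-force
distance oracles written independently of the implementation)."""

import numpy as np
import pytest
from scipy.special import expit

from mhseg.errors import ValidationError
from mhseg.infer_eval import (InferenceConfig, SegmentationMetrics,
                              compute_metrics, evaluate_masks,
                              sliding_window_predict)

# --------------------------------------------------------------------------
# independent oracle: all-pairs surface distances on small masks


def _oracle_surface(mask):
    """Border voxels by 6-neighborhood check, written longhand."""
    out = []
    X, Y, Z = mask.shape
    for x, y, z in np.argwhere(mask):
        on_border = False
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < X and 0 <= ny < Y and 0 <= nz < Z) or not mask[nx, ny, nz]:
                on_border = True
                break
        if on_border:
            out.append((x, y, z))
    return np.asarray(out, dtype=float)


def _oracle_metrics(p, r, spacing):
    sp = _oracle_surface(p) * spacing
    sr = _oracle_surface(r) * spacing
    d_pr = np.sqrt(((sp[:, None, :] - sr[None, :, :]) ** 2).sum(-1)).min(1)
    d_rp = np.sqrt(((sr[:, None, :] - sp[None, :, :]) ** 2).sum(-1)).min(1)
    pooled = np.concatenate([d_pr, d_rp])
    dsc = 2.0 * np.logical_and(p, r).sum() / (p.sum() + r.sum())
    rvd = 100.0 * (int(p.sum()) - int(r.sum())) / int(r.sum())
    return dsc, np.percentile(pooled, 95), pooled.mean(), rvd


def _random_blob(rng, shape=(9, 8, 7)):
    m = np.zeros(shape, dtype=bool)
    # union of a few random boxes
    for _ in range(rng.integers(1, 4)):
        a = [rng.integers(0, s - 2) for s in shape]
        b = [rng.integers(x + 1, s) for x, s in zip(a, shape)]
        m[a[0]:b[0], a[1]:b[1], a[2]:b[2]] = True
    return m


class TestMetrics:
    def test_identical_masks(self):
        m = np.zeros((6, 6, 4), dtype=bool)
        m[2:4, 2:4, 1:3] = True
        got = compute_metrics(m, m, (0.6, 0.6, 4.0))
        assert (got.dsc, got.hd95_mm, got.msd_mm, got.rvd_percent) == (1, 0, 0, 0)

    def test_hand_arithmetic_dsc_and_rvd(self):
        p = np.zeros((10, 10, 4), dtype=bool)
        r = np.zeros_like(p)
        p[0:2, 0:2, 0:2] = True          # 8 voxels
        r[1:3, 0:2, 0:2] = True          # 8 voxels, overlap 4
        assert compute_metrics(p, r, (1, 1, 1)).dsc == pytest.approx(0.5)
        p2 = np.zeros((10, 10, 10), dtype=bool)
        r2 = np.zeros_like(p2)
        p2.flat[:90] = True
        r2.flat[:100] = True
        assert compute_metrics(p2, r2, (1, 1, 1)).rvd_percent == pytest.approx(-10.0)

    def test_slice_shifted_cube_matches_all_pairs_oracle(self):
        """A cube shifted by one 4 mm slice: distances verified against the
        exhaustive all-pairs oracle to 1e-9."""
        p = np.zeros((8, 8, 8), dtype=bool)
        r = np.zeros_like(p)
        p[2:5, 2:5, 2:5] = True
        r[2:5, 2:5, 3:6] = True
        spacing = (0.6, 0.6, 4.0)
        got = compute_metrics(p, r, spacing)
        dsc, hd95, msd, rvd = _oracle_metrics(p, r, np.array(spacing))
        assert got.dsc == pytest.approx(dsc, abs=1e-12)
        assert got.hd95_mm == pytest.approx(hd95, abs=1e-9)
        assert got.msd_mm == pytest.approx(msd, abs=1e-9)
        assert got.rvd_percent == pytest.approx(rvd, abs=1e-12)

    def test_twenty_random_pairs_match_oracle(self, rng):
        spacing = np.array([1.5, 0.8, 2.0])
        checked = 0
        while checked < 20:
            p, r = _random_blob(rng), _random_blob(rng)
            if not p.any() or not r.any():
                continue
            got = compute_metrics(p, r, spacing)
            dsc, hd95, msd, rvd = _oracle_metrics(p, r, spacing)
            assert got.dsc == pytest.approx(dsc, abs=1e-9)
            assert got.hd95_mm == pytest.approx(hd95, abs=1e-9)
            assert got.msd_mm == pytest.approx(msd, abs=1e-9)
            assert got.rvd_percent == pytest.approx(rvd, abs=1e-9)
            assert got.hd95_mm >= got.msd_mm >= 0
            checked += 1

    def test_dsc_symmetry(self, rng):
        p, r = _random_blob(rng), _random_blob(rng)
        assert compute_metrics(p, r, (1, 1, 1)).dsc == pytest.approx(
            compute_metrics(r, p, (1, 1, 1)).dsc)

    def test_degenerate_cases_flagged(self):
        empty = np.zeros((4, 4, 4), dtype=bool)
        m = empty.copy()
        m[1:3, 1:3, 1:3] = True
        both = compute_metrics(empty, empty, (1, 1, 1))
        assert both.degenerate == "both_empty"
        assert (both.dsc, both.hd95_mm, both.msd_mm) == (1.0, 0.0, 0.0)
        ref_empty = compute_metrics(m, empty, (1, 1, 1))
        assert ref_empty.degenerate == "reference_empty"
        assert np.isnan(ref_empty.hd95_mm)
        pred_empty = compute_metrics(empty, m, (1, 1, 1))
        assert pred_empty.degenerate == "prediction_empty"
        assert pred_empty.dsc == 0.0 and pred_empty.rvd_percent == -100.0


class _ConstStub:
    def __init__(self, logit):
        self.logit = logit

    def predict_logits(self, x):
        return np.full((1,) + x.shape[1:], self.logit)


class TestSlidingWindow:
    def test_constant_stub_gives_uniform_probability(self):
        cfg = InferenceConfig(patch_size=(8, 8, 4), overlap_fraction=0.75)
        x = np.zeros((2, 20, 18, 10))
        probs = sliding_window_predict(_ConstStub(0.7), x, cfg)
        assert probs.shape == (20, 18, 10)
        assert np.allclose(probs, expit(0.7))

    def test_single_patch_volume_equals_direct_forward(self):
        class Echo:
            def predict_logits(self, x):
                return x[:1] * 0.3 - 0.1
        cfg = InferenceConfig(patch_size=(8, 8, 4), overlap_fraction=0.75)
        x = np.random.default_rng(0).normal(size=(2, 8, 8, 4))
        probs = sliding_window_predict(Echo(), x, cfg)
        assert np.allclose(probs, expit(x[0] * 0.3 - 0.1))

    def test_interior_coverage_counts_match_tiling_simulation(self):
        """With 75% overlap, interior voxels are covered by 4 windows per
        in-plane axis; verified by brute-force tiling count."""
        cfg = InferenceConfig(patch_size=(8, 8, 4), overlap_fraction=0.75)
        shape = (24, 24, 4)

        counter = np.zeros(shape)

        class Count:
            def predict_logits(self, x):
                return np.zeros((1,) + x.shape[1:])

        # replicate the implementation's tiling rule independently
        stride = 2
        starts = [s for s in range(0, shape[0] - 8 + 1, stride)]
        if starts[-1] != shape[0] - 8:
            starts.append(shape[0] - 8)
        for sx in starts:
            for sy in starts:
                counter[sx:sx + 8, sy:sy + 8, :] += 1
        assert counter.min() >= 1
        assert counter[12, 12, 0] == 16  # 4 per in-plane axis
        probs = sliding_window_predict(Count(), np.zeros((1,) + shape), cfg)
        assert np.allclose(probs, 0.5)  # mean of identical windows

    def test_rejects_wrong_rank(self):
        cfg = InferenceConfig(patch_size=(8, 8, 4))
        with pytest.raises(ValidationError):
            sliding_window_predict(_ConstStub(0.0), np.zeros((8, 8, 4)), cfg)


class TestEvaluateMasks:
    def _pairs(self, n=5):
        m = np.zeros((6, 6, 4), dtype=bool)
        m[2:4, 2:4, 1:3] = True
        return {f"s{i}": (m, m) for i in range(n)}

    def test_identical_predictions_give_perfect_medians(self):
        per, summary = evaluate_masks(self._pairs(), (1, 1, 1), seed=0)
        med = dict(zip(summary["metric"], summary["median"]))
        assert (med["dsc"], med["hd95_mm"], med["msd_mm"], med["rvd_percent"]) \
            == (1.0, 0.0, 0.0, 0.0)

    def test_single_study_ci_collapses_to_point(self):
        _, summary = evaluate_masks(dict(list(self._pairs(1).items())), (1, 1, 1))
        row = summary[summary.metric == "dsc"].iloc[0]
        assert row.ci_lo == row.ci_hi == row["median"] == 1.0

    def test_bootstrap_is_seed_deterministic(self, rng):
        pairs = {f"s{i}": (_random_blob(rng), _random_blob(rng) | True)
                 for i in range(4)}
        _, s1 = evaluate_masks(pairs, (1, 1, 1), seed=42)
        _, s2 = evaluate_masks(pairs, (1, 1, 1), seed=42)
        assert s1.equals(s2)
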