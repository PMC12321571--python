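import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from arcquant.fishquant import (
    DEFAULT_SUBTYPE_RULES,
    ClusterResult,
    ExpressionMatrix,
    SubtypeRules,
    assign_subtypes,
    build_expression_matrix,
    median_zero,
    normalize_cluster_embed,
    quantify_cell,
    renyi_bin_threshold,
    renyi_threshold,
)

# ---------------------------------------------------------------------------
# Independent exhaustive oracle for the Renyi-entropy threshold
# ---------------------------------------------------------------------------


def renyi_oracle_bin(hist, alphas=(0.5, 1.0, 2.0)):
    """Plain-loop exhaustive search over every candidate bin, combined by
    the three-threshold ordering/weighting rule."""
    total = float(sum(hist))
    p = [h / total for h in hist]
    n = len(p)

    def best_bin(alpha):
        best, best_obj = None, -math.inf
        for t in range(n):
            pb = math.fsum(p[: t + 1])
            pa = 1.0 - pb
            if pb <= 0 or pa <= 0:
                continue
            if alpha == 1.0:
                hb = -math.fsum((q / pb) * math.log(q / pb)
                                for q in p[: t + 1] if q > 0)
                ha = -math.fsum((q / pa) * math.log(q / pa)
                                for q in p[t + 1:] if q > 0)
            else:
                hb = math.log(math.fsum((q / pb) ** alpha
                                        for q in p[: t + 1])) / (1 - alpha)
                ha = math.log(math.fsum((q / pa) ** alpha
                                        for q in p[t + 1:])) / (1 - alpha)
            if hb + ha > best_obj:
                best, best_obj = t, hb + ha
        if best is None:
            raise ValueError("no separable classes")
        return best

    cands = sorted(best_bin(a) for a in alphas)
    if len(cands) != 3:
        return cands[len(cands) // 2]
    t1, t2, t3 = cands
    if abs(t1 - t2) <= 5:
        b1, b2, b3 = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        b1, b2, b3 = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    P = [math.fsum(p[: i + 1]) for i in range(n)]
    omega = P[t3] - P[t1]
    return int(t1 * (P[t1] + 0.25 * omega * b1)
               + 0.25 * t2 * omega * b2
               + t3 * ((1 - P[t3]) + 0.25 * omega * b3))


def mixture_histogram(rng, n_bins=256):
    """Bimodal Gaussian-mixture intensity histogram."""
    lo = rng.normal(rng.uniform(40, 90), rng.uniform(5, 20), 4000)
    hi = rng.normal(rng.uniform(140, 220), rng.uniform(5, 25), rng.integers(200, 3000))
    vals = np.clip(np.concatenate([lo, hi]), 0, n_bins - 1).astype(int)
    return np.bincount(vals, minlength=n_bins)


class TestRenyiThreshold:
    def test_two_valued_image_separates_perfectly(self):
        img = np.zeros((20, 20), dtype=np.uint8)
        img[:5] = 255
        thr = renyi_threshold(img)
        assert 0 < thr < 255
        assert np.array_equal(img > thr, img == 255)

    def test_matches_exhaustive_oracle_on_mixture_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            hist = mixture_histogram(rng)
            assert renyi_bin_threshold(hist) == renyi_oracle_bin(hist)

    def test_single_alpha_matches_oracle(self):
        rng = np.random.default_rng(1)
        hist = mixture_histogram(rng)
        for alpha in (0.5, 1.0, 2.0):
            assert renyi_bin_threshold(hist, (alpha,)) == renyi_oracle_bin(
                hist, (alpha,))

    def test_foreground_invariant_to_constant_offset(self):
        rng = np.random.default_rng(7)
        img = np.where(rng.random((64, 64)) < 0.1, 210.0, 30.0)
        img += rng.normal(0, 3, img.shape)
        base = img > renyi_threshold(img)
        shifted = (img + 1234.5) > renyi_threshold(img + 1234.5)
        assert np.array_equal(base, shifted)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            renyi_threshold(np.full((8, 8), 7.0))


class TestQuantifyCell:
    def test_degenerate_masks(self):
        roi = np.zeros((10, 10), bool)
        roi[:5, :5] = True
        assert quantify_cell(np.zeros_like(roi), roi) == 0.0
        assert quantify_cell(np.ones_like(roi), roi) == 100.0

    def test_counts_thirty_of_hundred(self):
        roi = np.zeros((10, 10), bool)
        roi.flat[:100] = True
        probe = np.zeros_like(roi)
        probe.flat[:30] = True
        assert quantify_cell(probe, roi) == 30.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            quantify_cell(np.ones((4, 4), bool), np.zeros((4, 4), bool))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(hnp.arrays(bool, (12, 12)), hnp.arrays(bool, (12, 12)))
    def test_equals_brute_force_pixel_count(self, probe, roi):
        if not roi.any():
            return
        expected = 100.0 * sum(
            1 for y in range(12) for x in range(12) if probe[y, x] and roi[y, x]
        ) / roi.sum()
        assert quantify_cell(probe, roi) == pytest.approx(expected)

    def test_monotone_in_probe_pixels(self):
        rng = np.random.default_rng(2)
        roi = rng.random((16, 16)) < 0.5
        probe = rng.random((16, 16)) < 0.3
        v0 = quantify_cell(probe, roi)
        grow = probe.copy()
        grow[np.unravel_index(np.flatnonzero(~probe)[:5], probe.shape)] = True
        assert quantify_cell(grow, roi) >= v0


class TestBuildExpressionMatrix:
    def test_recovers_planted_truth_exactly(self, clean_benchmark):
        cells, stack, labels, truth, model = clean_benchmark
        matrix = build_expression_matrix(stack, labels, model.genes)
        assert matrix.stage == "raw"
        assert np.array_equal(matrix.data.to_numpy(), truth.to_numpy())

    def test_probability_one_gives_all_hundred(self):
        cells = pd.DataFrame({"cell_id": [1, 2], "image_id": 0,
                              "x": [10.0, 30.0], "y": [10.0, 10.0],
                              "type": ["A", "A"]})
        from arcquant.synthetic import ExpressionModel, generate_probe_images

        model = ExpressionModel(pd.DataFrame({"g": [1.0]}, index=["A"]),
                                roi_radius=3.0)
        stack, labels, _ = generate_probe_images(cells, model, (40, 40), seed=0)
        matrix = build_expression_matrix(stack, labels, ["g"])
        assert (matrix.data.to_numpy() == 100.0).all()

    def test_small_object_filter_silences_speckle_channel(self):
        # single-pixel speckle everywhere, no real signal
        rng = np.random.default_rng(8)
        channel = np.where(rng.random((80, 80)) < 0.02, 255, 0).astype(np.uint8)
        labels = np.zeros((80, 80), dtype=np.int32)
        labels[10:16, 10:16] = 1
        labels[40:46, 40:46] = 2
        from scipy import ndimage

        objs, _ = ndimage.label(channel > 0, structure=np.ones((3, 3)))
        largest = np.bincount(objs.ravel())[1:].max()
        matrix = build_expression_matrix(channel[None], labels, ["g"],
                                         min_object_px=largest + 1)
        assert (matrix.data.to_numpy() == 0.0).all()

    def test_bad_inputs_rejected(self):
        stack = np.zeros((2, 10, 10), dtype=np.uint8)
        labels = np.ones((10, 10), dtype=np.int32)
        with pytest.raises(ValueError, match="duplicated"):
            build_expression_matrix(stack, labels, ["g", "g"])
        with pytest.raises(ValueError, match="gene name"):
            build_expression_matrix(stack, labels, ["g"])
        with pytest.raises(ValueError, match="no cells"):
            build_expression_matrix(stack, np.zeros((10, 10), np.int32),
                                    ["g1", "g2"])


class TestMedianZero:
    def test_forced_examples(self):
        df = pd.DataFrame({"g": [0.0, 10.0, 20.0, 30.0, 40.0],
                           "h": [5.0, 5.0, 5.0, 5.0, 5.0]})
        out = median_zero(ExpressionMatrix(df))
        assert out.data["g"].tolist() == [0.0, 0.0, 0.0, 30.0, 40.0]
        assert (out.data["h"] == 0.0).all()  # nothing strictly above the median
        assert out.stage == "median_zeroed"

    def test_all_zero_gene_passes_through(self):
        df = pd.DataFrame({"g": [0.0, 0.0, 0.0]})
        assert (median_zero(ExpressionMatrix(df)).data["g"] == 0.0).all()

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_nonzero_count_matches_counting_oracle(self, seed):
        """Per gene, survivors are exactly the values strictly above the
        gene's median."""
        rng = np.random.default_rng(seed)
        vals = np.round(rng.uniform(0, 100, (21, 5)), 1)
        out = median_zero(ExpressionMatrix(pd.DataFrame(vals))).data.to_numpy()
        for j in range(5):
            med = float(np.median(vals[:, j]))
            expected = sum(1 for v in vals[:, j] if v > med)
            assert (out[:, j] > 0).sum() == expected
            # surviving values unchanged
            assert np.array_equal(out[vals[:, j] > med, j],
                                  vals[vals[:, j] > med, j])

    def test_requires_raw_stage(self):
        m = median_zero(ExpressionMatrix(pd.DataFrame({"g": [0.0, 1.0, 2.0]})))
        with pytest.raises(ValueError):
            median_zero(m)


@pytest.fixture(scope="module")
def planted_blocks():
    """Two orthogonal expression blocks: cells 0-29 express genes 0-4,
    cells 30-59 express genes 5-9."""
    rng = np.random.default_rng(12)
    x = np.abs(rng.normal(2, 1, (60, 10)))
    x[:30, :5] += 60
    x[30:, 5:] += 60
    return ExpressionMatrix(pd.DataFrame(np.clip(x, 0, 100)), stage="raw")


class TestClusterAndAssign:
    def test_planted_blocks_recovered_perfectly(self, planted_blocks):
        from sklearn.metrics import adjusted_rand_score

        # resolution low enough to resolve exactly the two planted
        # communities rather than sub-structure within them
        res = normalize_cluster_embed(median_zero(planted_blocks),
                                      resolution=0.25,
                                      n_neighbors=10, seed=3, embed=False)
        truth = np.repeat([0, 1], 30)
        assert res.labels.nunique() == 2
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0

    def test_identical_cells_form_one_cluster(self):
        df = pd.DataFrame(np.tile([5.0, 0.0, 3.0, 7.0], (25, 1)))
        m = ExpressionMatrix(df, stage="median_zeroed")
        res = normalize_cluster_embed(m, n_neighbors=10, seed=0, embed=False)
        assert res.labels.nunique() == 1

    def test_deterministic_given_seed(self, planted_blocks):
        m = median_zero(planted_blocks)
        r1 = normalize_cluster_embed(m, n_neighbors=10, seed=7)
        r2 = normalize_cluster_embed(m, n_neighbors=10, seed=7)
        pd.testing.assert_series_equal(r1.labels, r2.labels)
        pd.testing.assert_frame_equal(r1.embedding, r2.embedding)

    def test_too_few_cells_for_neighbors_errors_with_guidance(self):
        m = ExpressionMatrix(pd.DataFrame(np.zeros((5, 3))),
                             stage="median_zeroed")
        with pytest.raises(ValueError, match="n_neighbors"):
            normalize_cluster_embed(m, n_neighbors=20)

    def test_marker_rule_forces_subtype(self):
        genes = sorted(DEFAULT_SUBTYPE_RULES.required_genes())
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.uniform(0, 2, (20, len(genes))), columns=genes)
        x.loc[:9, ["NKX2.1", "MAF1"]] = 80.0
        x.loc[10:, ["SST", "LHX6"]] = 80.0
        m = ExpressionMatrix(x, stage="median_zeroed")
        clusters = ClusterResult(
            labels=pd.Series(np.repeat([0, 1], 10), index=x.index),
            embedding=None, resolution=1.0, seed=0)
        sub = assign_subtypes(clusters, m)
        assert (sub.iloc[:10] == "NKX2.1+MAF1+").all()
        assert (sub.iloc[10:] == "SST+LHX6+").all()

    def test_score_tie_yields_unassigned(self):
        rules = SubtypeRules((("S1", ("g1",)), ("S2", ("g2",))))
        x = pd.DataFrame({"g1": [50.0] * 10, "g2": [50.0] * 10,
                          "g3": np.linspace(0, 90, 10)})
        m = ExpressionMatrix(x, stage="median_zeroed")
        clusters = ClusterResult(labels=pd.Series(0, index=x.index),
                                 embedding=None, resolution=1.0, seed=0)
        sub = assign_subtypes(clusters, m, rules=rules, margin=0.1)
        assert (sub == "unassigned").all()

    def test_empty_rules_rejected(self):
        with pytest.raises(ValueError):
            SubtypeRules(())
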