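"""TFCE, paired sign-flip permutation, and cluster extraction."""

from collections import deque

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbmasym import (DesignInfo, InferenceConfig, VolumeGrid,
                     extract_clusters, paired_permutation, tfce_enhance)


# ---------------------------------------------------------------------------
# independent TFCE oracle: per-threshold BFS flood fill (no scipy labeling,
# no union-find) — deliberately the slow textbook definition
# ---------------------------------------------------------------------------

def _components_bfs(bw, connectivity):
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                taxi = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and taxi != 1:
                    continue
                if connectivity == 18 and taxi == 3:
                    continue
                offsets.append((dx, dy, dz))
    shape = bw.shape
    seen = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int64)
    nlab = 0
    for start in zip(*np.nonzero(bw)):
        if seen[start]:
            continue
        nlab += 1
        q = deque([start])
        seen[start] = True
        while q:
            x, y, z = q.popleft()
            labels[x, y, z] = nlab
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]
                        and 0 <= p[2] < shape[2]
                        and bw[p] and not seen[p]):
                    seen[p] = True
                    q.append(p)
    return labels, nlab


def tfce_bruteforce(stat, E, H, n_steps, connectivity):
    out = np.zeros_like(stat)
    m = stat.max()
    if m <= 0:
        return out
    dh = m / n_steps
    for k in range(1, n_steps + 1):
        h = k * dh
        bw = stat >= h
        labels, nlab = _components_bfs(bw, connectivity)
        sizes = np.bincount(labels.ravel(), minlength=nlab + 1)
        contrib = sizes[labels] ** E * h ** H * dh
        out[bw] += contrib[bw]
    return out


class TestTFCE:
    def test_single_voxel_closed_form(self):
        h = 2.5
        stat = np.zeros((9, 9, 9))
        stat[4, 4, 4] = h
        cfg = InferenceConfig(tfce_n_steps=400)
        out = tfce_enhance(stat, cfg)
        assert out[4, 4, 4] == pytest.approx(h ** 3 / 3, rel=0.01)

    def test_plateau_closed_form(self):
        h, n = 1.75, 27
        stat = np.zeros((11, 11, 11))
        stat[4:7, 4:7, 4:7] = h  # 27-voxel plateau
        cfg = InferenceConfig(tfce_n_steps=400)
        out = tfce_enhance(stat, cfg)
        assert out[5, 5, 5] == pytest.approx(np.sqrt(n) * h ** 3 / 3, rel=0.01)

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_maps(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        stat = np.maximum(rng.normal(size=(16, 16, 16)), 0.0)
        cfg = InferenceConfig(tfce_n_steps=25, connectivity=connectivity)
        fast = tfce_enhance(stat, cfg)
        slow = tfce_bruteforce(stat, cfg.tfce_E, cfg.tfce_H, 25, connectivity)
        assert np.abs(fast - slow).max() < 1e-8

    def test_negative_tail_enhanced_separately(self):
        stat = np.zeros((9, 9, 9))
        stat[2, 2, 2] = 2.0
        stat[6, 6, 6] = -2.0
        out = tfce_enhance(stat, InferenceConfig(tfce_n_steps=100))
        assert out[2, 2, 2] > 0
        assert out[6, 6, 6] == pytest.approx(-out[2, 2, 2])

    def test_mask_zeroes_outside(self):
        stat = np.ones((6, 6, 6))
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:3] = True
        out = tfce_enhance(stat, InferenceConfig(), mask=mask)
        assert np.all(out[~mask] == 0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_monotone_in_input(self, seed):
        """Pointwise-increasing the input never decreases any TFCE value."""
        rng = np.random.default_rng(seed)
        a = np.maximum(rng.normal(size=(8, 8, 8)), 0.0)
        bump = np.zeros_like(a)
        ix = tuple(rng.integers(0, 8, size=3))
        bump[ix] = 0.5
        cfg = InferenceConfig(tfce_dh=0.05)
        out_a = tfce_enhance(a, cfg)
        out_b = tfce_enhance(a + bump, cfg)
        assert np.all(out_b >= out_a - 1e-12)


def _make_stacks(diffs):
    """One-voxel-signal helper: (n,) diffs -> (n,2,2,2) A/B stacks."""
    n = len(diffs)
    A = np.zeros((n, 2, 2, 2))
    A[:, 0, 0, 0] = diffs
    B = np.zeros((n, 2, 2, 2))
    return A, B


class TestPairedPermutation:
    def test_three_pair_worked_example(self):
        """n=3 pairs, single signal voxel, diffs {+5,+4,+6}: exhaustive 8
        sign patterns, observed statistic uniquely maximal -> corrected
        1-p = 1 - 1/8 = 0.875."""
        A, B = _make_stacks([5.0, 4.0, 6.0])
        design = DesignInfo(pair_ids=[1, 2, 3])
        cfg = InferenceConfig(n_perm=5000, variance_smooth_fwhm_mm=0.0)
        res = paired_permutation(A, B, design, cfg)
        assert res.exhaustive
        assert res.n_perm_effective == 7
        assert res.corrp[0, 0, 0] == pytest.approx(0.875)

    def test_exhaustive_matches_direct_enumeration(self):
        """The exhaustive max-statistic null equals a direct enumeration of
        all sign patterns computed independently with plain numpy."""
        rng = np.random.default_rng(5)
        diffs = rng.normal(0.5, 1.0, size=(4, 3, 3, 3))
        A = diffs.copy()
        B = np.zeros_like(A)
        design = DesignInfo(pair_ids=list(range(4)))
        cfg = InferenceConfig(n_perm=16, variance_smooth_fwhm_mm=0.0,
                              tfce_n_steps=30)
        res = paired_permutation(A, B, design, cfg)
        assert res.exhaustive

        D = diffs.reshape(4, -1)
        n = 4
        t_all = []
        for bits in range(2 ** n):
            s = np.array([1 - 2 * ((bits >> i) & 1) for i in range(n)])
            Ds = s[:, None] * D
            t = Ds.mean(0) / (Ds.std(0, ddof=1) / np.sqrt(n))
            t_all.append(t.reshape(3, 3, 3))
        cfg_t = InferenceConfig(tfce_n_steps=30)
        expected_max = [tfce_enhance(np.maximum(t, 0), cfg_t).max()
                        for t in t_all[1:]]  # bits=0 is the identity
        assert np.allclose(np.sort(res.max_null), np.sort(expected_max),
                           atol=1e-10)

    def test_group_swap_negates_statistic(self, rng):
        A = rng.normal(size=(5, 4, 4, 4))
        B = rng.normal(size=(5, 4, 4, 4))
        design = DesignInfo(pair_ids=list(range(5)))
        cfg = InferenceConfig(n_perm=16, variance_smooth_fwhm_mm=0.0)
        r1 = paired_permutation(A, B, design, cfg)
        r2 = paired_permutation(B, A, design, cfg)
        assert np.allclose(r1.observed_stat, -r2.observed_stat)

    def test_identical_groups_degenerate(self, rng):
        A = rng.normal(size=(4, 3, 3, 3))
        design = DesignInfo(pair_ids=list(range(4)))
        with pytest.raises(ValueError, match="degenerate"):
            paired_permutation(A, A.copy(), design, InferenceConfig(n_perm=8))

    def test_rank_deficient_covariates_rejected(self, rng):
        A = rng.normal(size=(4, 3, 3, 3))
        B = rng.normal(size=(4, 3, 3, 3))
        design = DesignInfo(pair_ids=list(range(4)),
                            covariates=np.ones((4, 2)))  # collinear w/ 1
        with pytest.raises(ValueError, match="rank"):
            paired_permutation(A, B, design, InferenceConfig(n_perm=8))

    def test_covariates_are_demeaned(self):
        d = DesignInfo(pair_ids=[1, 2, 3], covariates=np.array([30., 32., 37.]))
        assert abs(d.covariates.mean()) < 1e-12

    def test_covariate_regression_absorbs_nuisance_variance(self, rng):
        """With an age-driven nuisance on top of a constant effect, the
        Freedman-Lane adjusted statistic recovers the effect with less
        residual variance, hence a larger t, than the unadjusted one."""
        n = 8
        age = np.linspace(-1, 1, n)
        diffs = np.zeros((n, 3, 3, 3))
        diffs[:, 1, 1, 1] = 2.0 + 4.0 * age + rng.normal(0, 0.05, n)
        A = diffs
        B = np.zeros_like(A)
        cfg = InferenceConfig(n_perm=256, variance_smooth_fwhm_mm=0.0, seed=3)
        res_raw = paired_permutation(
            A, B, DesignInfo(pair_ids=list(range(n))), cfg)
        res_with = paired_permutation(
            A, B, DesignInfo(pair_ids=list(range(n)), covariates=age), cfg)
        t_raw = res_raw.observed_stat[1, 1, 1]
        t_adj = res_with.observed_stat[1, 1, 1]
        assert t_adj > t_raw > 0

    def test_corrp_in_unit_interval(self, rng):
        A = rng.normal(0.3, 1.0, size=(6, 4, 4, 4))
        B = rng.normal(size=(6, 4, 4, 4))
        res = paired_permutation(A, B, DesignInfo(pair_ids=list(range(6))),
                                 InferenceConfig(n_perm=64, seed=1))
        assert res.corrp.min() >= 0.0 and res.corrp.max() <= 1.0


class TestExtractClusters:
    def _result(self, corrp, spacing=1.0):
        from dbmasym.inference import PermutationResult
        shape = corrp.shape
        return PermutationResult(
            observed_stat=np.zeros(shape), observed_tfce=np.zeros(shape),
            max_null=np.zeros(1), corrp=corrp,
            mask=np.ones(shape, dtype=bool), exhaustive=True,
            n_perm_effective=1, spacing=np.full(3, spacing))

    def test_single_blob_single_row(self):
        corrp = np.zeros((12, 12, 12))
        corrp[2:4, 2:4, 2:4] = 0.99  # 8 voxels, left of center
        corrp[3, 3, 4] = 0.99
        corrp[3, 4, 4] = 0.99       # 10 total, connected
        res = self._result(corrp)
        jd = np.full((1, 12, 12, 12), 0.5)
        table = extract_clusters(res, {"nonflipped": jd}, InferenceConfig())
        assert len(table) == 1
        row = table.df.iloc[0]
        assert row.size_voxels == 10
        assert row.hemisphere == "L"
        assert row.lowest_p == pytest.approx(0.01)
        assert row.jd_mean == pytest.approx(0.5)

    def test_two_blobs_ordered_by_descending_size(self):
        corrp = np.zeros((16, 16, 16))
        corrp[1:3, 1:3, 1:3] = 0.98          # 8 voxels
        corrp[10:13, 10:13, 10:13] = 0.995   # 27 voxels
        res = self._result(corrp)
        jd = np.zeros((2, 16, 16, 16))
        table = extract_clusters(res, {"nonflipped": jd}, InferenceConfig())
        assert list(table.df.size_voxels) == [27, 8]
        assert list(table.df.cluster_id) == [1, 2]

    def test_empty_table_allowed(self):
        res = self._result(np.zeros((8, 8, 8)))
        table = extract_clusters(res, {}, InferenceConfig())
        assert len(table) == 0

    def test_tsv_roundtrip(self, tmp_path):
        corrp = np.zeros((8, 8, 8))
        corrp[1:3, 1:3, 1:3] = 0.99
        table = extract_clusters(self._result(corrp),
                                 {"nonflipped": np.zeros((1, 8, 8, 8))},
                                 InferenceConfig())
        path = tmp_path / "clusters.tsv"
        table.to_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert back.iloc[0].size_voxels == 8
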