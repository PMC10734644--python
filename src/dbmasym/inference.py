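"""Paired permutation inference with TFCE and cluster reporting.

The paired design is tested by sign-flipping whole-subject difference
maps, the standard randomization scheme under the exchangeability null of
a paired two-group comparison.  Nuisance covariates are handled at the
difference level by Freedman-Lane residualization: the differences are
residualized against the (demeaned) covariates, the residuals are
sign-flipped, the nuisance fit is added back, and the full model is
refitted.  Family-wise error is controlled by the max-statistic of the
TFCE-enhanced maps; p-values use the add-one estimator (1+b)/(1+B), which
is valid and never exactly zero.  When 2^n sign patterns fit in the
permutation budget the null is enumerated exhaustively (identity pattern
= the observed statistic), giving exact p-values with minimum 1/2^n.

Each contrast direction is a one-sided test; callers that need both
directions run the test twice with the groups swapped and report each at
alpha/2 (0.025 for the conventional 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .grid import VolumeGrid


@dataclass
class DesignInfo:
    """Pairing and nuisance structure of a paired two-group comparison."""

    pair_ids: list
    covariates: np.ndarray | None = None   # (n, k), demeaned on init
    covariate_names: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.pair_ids)
        if self.covariates is None or np.size(self.covariates) == 0:
            self.covariates = np.zeros((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=np.float64)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows must match pairs")
        if self.covariates.shape[1]:
            self.covariates = self.covariates - self.covariates.mean(axis=0)


@dataclass
class InferenceConfig:
    n_perm: int = 5000
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_dh: float | None = None       # None: observed max / tfce_n_steps
    tfce_n_steps: int = 100
    connectivity: int = 26
    alpha_threshold: float = 0.975     # corrected 1-p display threshold
    variance_smooth_fwhm_mm: float = 6.0  # 0 disables the pseudo-t
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.tfce_E < 0 or self.tfce_H < 0:
            raise ValueError("TFCE exponents must be >= 0")
        if self.tfce_dh is not None and self.tfce_dh <= 0:
            raise ValueError("tfce_dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


# ---------------------------------------------------------------------------
# TFCE: single pass over voxels sorted by height, incremental union-find
# with lazy per-component accumulation (exactly equivalent to relabeling
# the suprathreshold components at every step h = dh, 2dh, ..., max).
# ---------------------------------------------------------------------------

@njit(cache=True)
def _uf_find(i, parent, val):
    r = i
    acc = 0.0
    while parent[r] != r:
        acc += val[r]
        r = parent[r]
    j = i
    acc2 = acc
    while parent[j] != r:
        nxt = parent[j]
        v = val[j]
        parent[j] = r
        val[j] = acc2
        acc2 -= v
        j = nxt
    return r


@njit(cache=True)
def _tfce_core(stat, E, H, dh, n_steps, connectivity):
    nx, ny, nz = stat.shape
    nv = nx * ny * nz
    flat = stat.ravel()
    order = np.argsort(flat)[::-1]
    parent = np.full(nv, -1, np.int64)
    val = np.zeros(nv)
    size = np.zeros(nv, np.int64)
    stamp = np.full(nv, -1, np.int64)
    active = np.empty(nv, np.int64)
    n_active = 0
    ptr = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        while ptr < nv and flat[order[ptr]] >= h:
            i = order[ptr]
            ptr += 1
            parent[i] = i
            val[i] = 0.0
            size[i] = 1
            active[n_active] = i
            n_active += 1
            z = i % nz
            y = (i // nz) % ny
            x = i // (nz * ny)
            for dx in range(-1, 2):
                xx = x + dx
                if xx < 0 or xx >= nx:
                    continue
                for dy in range(-1, 2):
                    yy = y + dy
                    if yy < 0 or yy >= ny:
                        continue
                    for dz in range(-1, 2):
                        zz = z + dz
                        if zz < 0 or zz >= nz:
                            continue
                        if dx == 0 and dy == 0 and dz == 0:
                            continue
                        ntaxi = abs(dx) + abs(dy) + abs(dz)
                        if connectivity == 6 and ntaxi != 1:
                            continue
                        if connectivity == 18 and ntaxi == 3:
                            continue
                        j = (xx * ny + yy) * nz + zz
                        if parent[j] == -1:
                            continue
                        ri = _uf_find(i, parent, val)
                        rj = _uf_find(j, parent, val)
                        if ri != rj:
                            if size[ri] < size[rj]:
                                ri, rj = rj, ri
                            parent[rj] = ri
                            val[rj] = val[rj] - val[ri]
                            size[ri] += size[rj]
        if n_active == 0:
            continue
        hterm = h ** H * dh
        for a in range(n_active):
            r = _uf_find(active[a], parent, val)
            if stamp[r] != k:
                stamp[r] = k
                val[r] += size[r] ** E * hterm
    out = np.zeros(nv)
    for a in range(n_active):
        i = active[a]
        r = i
        acc = 0.0
        while True:
            acc += val[r]
            if parent[r] == r:
                break
            r = parent[r]
        out[i] = acc
    return out.reshape(stat.shape)


def _tfce_one_tail(stat: np.ndarray, cfg: InferenceConfig) -> np.ndarray:
    m = float(stat.max(initial=0.0))
    if m <= 0:
        return np.zeros_like(stat)
    if cfg.tfce_dh is not None:
        dh = float(cfg.tfce_dh)
        n_steps = max(1, int(np.floor(m / dh + 1e-12)))
    else:
        n_steps = int(cfg.tfce_n_steps)
        dh = m / n_steps
    # crop to the support bounding box for speed
    nz_idx = np.nonzero(stat > 0)
    lo = [int(v.min()) for v in nz_idx]
    hi = [int(v.max()) + 1 for v in nz_idx]
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    out = np.zeros_like(stat)
    out[sl] = _tfce_core(np.ascontiguousarray(stat[sl]), cfg.tfce_E,
                         cfg.tfce_H, dh, n_steps, cfg.connectivity)
    return out


def tfce_enhance(stat: np.ndarray, cfg: InferenceConfig,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed statistic map.

    TFCE(p) = sum_h e_h(p)^E * h^H * dh over h = dh, 2dh, ..., stat(p),
    with e_h(p) the voxel count of p's connected component at threshold h.
    Positive and negative tails are enhanced separately; the result keeps
    the input's sign.
    """
    stat = np.asarray(stat, dtype=np.float64)
    if mask is not None:
        stat = np.where(np.asarray(mask, dtype=bool), stat, 0.0)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map contains non-finite values")
    pos = _tfce_one_tail(np.maximum(stat, 0.0), cfg)
    neg = _tfce_one_tail(np.maximum(-stat, 0.0), cfg)
    return pos - neg


# ---------------------------------------------------------------------------
# paired permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_stat: np.ndarray
    observed_tfce: np.ndarray
    max_null: np.ndarray
    corrp: np.ndarray
    mask: np.ndarray
    exhaustive: bool
    n_perm_effective: int
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def grid(self) -> VolumeGrid:
        return VolumeGrid(np.zeros(self.observed_stat.shape), self.spacing,
                          self.origin)


def _t_intercept(D: np.ndarray, X: np.ndarray, pinvX: np.ndarray,
                 h00: float, var_smoother=None) -> np.ndarray:
    """(Pseudo-)t-statistic for the intercept of D = X beta + eps.

    With ``var_smoother`` set, the voxelwise residual variance is spatially
    smoothed before entering the denominator (the pseudo-t of
    non-parametric mapping): the statistic stays exchangeable under
    sign-flipping because it is recomputed identically for every
    permutation, while spurious near-zero-variance voxels no longer
    produce unbounded t spikes.
    """
    n, p = X.shape
    beta = pinvX @ D
    resid = D - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    if var_smoother is not None:
        sigma2 = var_smoother(sigma2)
    se = np.sqrt(np.maximum(sigma2 * h00, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[0] / se, 0.0)
    return t


def _sign_patterns(n: int, cfg: InferenceConfig):
    """(signs, exhaustive): null sign matrix, one row per permutation."""
    if 2 ** n <= cfg.n_perm:
        bits = np.arange(1, 2 ** n, dtype=np.int64)  # 0 = identity = observed
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)) & 1)
        return signs.astype(np.float64), True
    rng = np.random.default_rng(cfg.seed)
    signs = rng.choice([-1.0, 1.0], size=(cfg.n_perm, n))
    return signs, False


def paired_permutation(maps_A, maps_B, design: DesignInfo,
                       cfg: InferenceConfig,
                       mask: np.ndarray | None = None,
                       reference: VolumeGrid | None = None) -> PermutationResult:
    """One-sided paired test of A > B with TFCE max-statistic FWER control.

    ``maps_A`` / ``maps_B`` are (n, nx, ny, nz) stacks with one map per
    pair and group.  Returns the observed statistic, its TFCE enhancement,
    the permutation null of the TFCE maximum, and the voxelwise corrected
    1-p map.
    """
    A = np.asarray(maps_A, dtype=np.float64)
    B = np.asarray(maps_B, dtype=np.float64)
    if A.shape != B.shape or A.ndim != 4:
        raise ValueError("expected matching (n, nx, ny, nz) stacks")
    n = A.shape[0]
    if n != len(design.pair_ids):
        raise ValueError("design pairs must match the map stacks")
    if n < 2:
        raise ValueError("need at least 2 pairs")
    shape = A.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    D = (A - B).reshape(n, -1)[:, mask.ravel()]
    if not D.any():
        raise ValueError("degenerate design: all paired differences are zero")

    Z = design.covariates
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariates")
    if n - X.shape[1] < 1:
        raise ValueError(
            f"insufficient residual degrees of freedom: {n} pairs with "
            f"{X.shape[1] - 1} covariates")
    pinvX = np.linalg.pinv(X)
    h00 = float(np.linalg.inv(X.T @ X)[0, 0])

    if Z.shape[1]:
        gamma = np.linalg.pinv(Z) @ D      # nuisance-only (reduced) fit
        nuisance = Z @ gamma
        E_resid = D - nuisance
    else:
        nuisance = 0.0
        E_resid = D

    var_smoother = None
    if cfg.variance_smooth_fwhm_mm > 0:
        spacing = reference.spacing if reference is not None else np.ones(3)
        sigma_vox = (cfg.variance_smooth_fwhm_mm
                     / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / spacing
        # smooth only inside the mask bounding box (padded past the kernel
        # truncation radius, so results inside the mask are exact)
        nz = np.nonzero(mask)
        pad = np.ceil(4.0 * sigma_vox + 1).astype(int)
        box = tuple(slice(max(0, int(v.min()) - p),
                          min(s, int(v.max()) + 1 + p))
                    for v, p, s in zip(nz, pad, shape))
        mask_box = mask[box]
        m_sm = ndimage.gaussian_filter(mask_box.astype(np.float64), sigma_vox)

        def var_smoother(s2, _box_shape=mask_box.shape, _m=mask_box,
                         _norm=m_sm):
            vol = np.zeros(_box_shape)
            vol[_m] = s2
            num = ndimage.gaussian_filter(vol, sigma_vox)
            return (num / np.maximum(_norm, 1e-12))[_m]

    def stat_for(signs_row):
        D_star = nuisance + signs_row[:, None] * E_resid
        return _t_intercept(D_star, X, pinvX, h00, var_smoother)

    t_obs = _t_intercept(D, X, pinvX, h00, var_smoother)
    obs_map = np.zeros(shape)
    obs_map[mask] = t_obs
    obs_tfce = _tfce_one_tail(np.maximum(obs_map, 0.0), cfg)

    signs, exhaustive = _sign_patterns(n, cfg)
    max_null = np.empty(len(signs))
    null_map = np.zeros(shape)
    for b, srow in enumerate(signs):
        tb = stat_for(srow)
        null_map[mask] = tb
        enhanced = _tfce_one_tail(np.maximum(null_map, 0.0), cfg)
        max_null[b] = enhanced.max(initial=0.0)

    Bn = len(signs)
    # p(v) = (1 + #{null max >= T(v)}) / (1 + B); corrp = 1 - p
    sorted_null = np.sort(max_null)
    obs_vals = obs_tfce[mask]
    exceed = Bn - np.searchsorted(sorted_null, obs_vals, side="left")
    pvals = (1.0 + exceed) / (1.0 + Bn)
    corrp = np.zeros(shape)
    corrp[mask] = 1.0 - pvals

    ref = reference
    return PermutationResult(
        observed_stat=obs_map, observed_tfce=obs_tfce, max_null=max_null,
        corrp=corrp, mask=mask, exhaustive=exhaustive, n_perm_effective=Bn,
        spacing=(ref.spacing.copy() if ref is not None else np.ones(3)),
        origin=(ref.origin.copy() if ref is not None else np.zeros(3)))


def null_flip_fwer(mask: np.ndarray, cfg: InferenceConfig, n_cohorts: int,
                   n_subjects: int, seed: int,
                   noise_smooth_vox: float = 1.5,
                   reference: VolumeGrid | None = None) -> dict:
    """Empirical family-wise error of the flip-contrast test on null maps.

    Each replicate cohort consists of per-subject spatially smoothed noise
    maps inside a mirror-symmetric mask; the flipped group is each map's
    own midline mirror, so the paired differences are exchangeable in sign
    and exactly null.  Demeaned age covariates are included to exercise the
    Freedman-Lane path.  Returns the rejection fraction at the corrected
    threshold together with its binomial 95% interval.
    """
    from scipy import ndimage as ndi
    root = np.random.SeedSequence(seed)
    alpha = 1.0 - cfg.alpha_threshold
    rejections = 0
    for rep_seq in root.spawn(n_cohorts):
        rng = np.random.default_rng(rep_seq)
        maps = np.stack([
            ndi.gaussian_filter(rng.normal(size=mask.shape), noise_smooth_vox)
            for _ in range(n_subjects)])
        maps *= mask
        design = DesignInfo(
            pair_ids=list(range(n_subjects)),
            covariates=np.column_stack([
                rng.normal(32.4, 1.1, n_subjects),
                rng.normal(41.7, 1.4, n_subjects)]))
        rep_cfg = InferenceConfig(**{**vars(cfg),
                                     "seed": int(rng.integers(2 ** 31))})
        res = paired_permutation(maps, maps[:, ::-1], design, rep_cfg,
                                 mask=mask, reference=reference)
        if res.corrp.max() >= cfg.alpha_threshold:
            rejections += 1
    p_hat = rejections / n_cohorts
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_cohorts)
    return {"fwer": p_hat, "alpha": alpha, "n_cohorts": n_cohorts,
            "rejections": rejections,
            "binomial_95": (max(0.0, alpha - half), alpha + half)}


# ---------------------------------------------------------------------------
# cluster extraction
# ---------------------------------------------------------------------------

_CONN_STRUCTURE = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterTable:
    """Significant-cluster report: one row per suprathreshold component,
    ordered by descending size, with the location, lowest corrected p and
    the log-JD summary of each cluster."""

    df: pd.DataFrame

    def __len__(self):
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "ClusterTable":
        return cls(pd.read_csv(path, sep="\t"))


_BASE_COLUMNS = ["cluster_id", "hemisphere", "size_voxels", "lowest_p",
                 "jd_min", "jd_max", "jd_mean",
                 "centroid_x", "centroid_y", "centroid_z"]


def extract_clusters(result: PermutationResult, jd_groups: dict,
                     cfg: InferenceConfig,
                     midline_x: float | None = None) -> ClusterTable:
    """Connected components of corrp >= alpha_threshold, largest first.

    ``jd_groups`` maps group tags to (n, nx, ny, nz) log-JD stacks; the
    first entry supplies the headline jd_min/jd_max/jd_mean columns
    (cluster statistics of the across-subject mean map) and every group
    gets a ``jd_mean_<tag>`` column.  Hemisphere is decided by the
    centroid's side of ``midline_x`` (defaults to the grid center).
    """
    grid = result.grid()
    midline_x = grid.center[0] if midline_x is None else float(midline_x)
    sup = result.corrp >= cfg.alpha_threshold
    structure = ndimage.generate_binary_structure(
        3, _CONN_STRUCTURE[cfg.connectivity])
    labels, n_clusters = ndimage.label(sup, structure=structure)

    group_means = {tag: np.asarray(stack, dtype=np.float64).mean(axis=0)
                   for tag, stack in jd_groups.items()}
    primary = next(iter(group_means.values())) if group_means else None

    rows = []
    for cid in range(1, n_clusters + 1):
        sel = labels == cid
        size = int(sel.sum())
        idx = np.argwhere(sel)
        centroid = grid.voxel_to_world(idx.mean(axis=0))
        row = {
            "hemisphere": "R" if centroid[0] > midline_x else "L",
            "size_voxels": size,
            "lowest_p": float(1.0 - result.corrp[sel].max()),
            "jd_min": float(primary[sel].min()) if primary is not None else np.nan,
            "jd_max": float(primary[sel].max()) if primary is not None else np.nan,
            "jd_mean": float(primary[sel].mean()) if primary is not None else np.nan,
            "centroid_x": float(centroid[0]),
            "centroid_y": float(centroid[1]),
            "centroid_z": float(centroid[2]),
        }
        for tag, mean_map in group_means.items():
            row[f"jd_mean_{tag}"] = float(mean_map[sel].mean())
        rows.append(row)

    cols = _BASE_COLUMNS + [f"jd_mean_{t}" for t in group_means]
    if not rows:
        return ClusterTable(pd.DataFrame(columns=cols))
    df = pd.DataFrame(rows).sort_values(
        ["size_voxels", "lowest_p", "centroid_x"],
        ascending=[False, True, True], kind="mergesort").reset_index(drop=True)
    df.insert(0, "cluster_id", np.arange(1, len(df) + 1))
    return ClusterTable(df[cols])
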