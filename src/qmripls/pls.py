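"""Multi-condition, multi-group behavioral PLS correlation.

The analysis relates a subject × 16 behavior block (4 nuclei × 4 MPM
parameters) to voxelwise brain matrices, one per condition (NDI, ODI, FW).
Per group and condition the 16 × p Pearson correlation matrix is computed
on z-scored blocks; the per-condition (and per-group) blocks are stacked on
the behavior side and decomposed by SVD into latent variables (LVs), each
carrying behavior saliences, one shared voxel-salience map, and a singular
value.  Inference is by row permutation of the behavior block (LV
significance) and subject bootstrap with orthogonal-procrustes alignment
(voxel bootstrap ratios and behavior-correlation confidence intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svd as _svd
from scipy.ndimage import label as _cc_label


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

def standardize_columns(x: np.ndarray, names=None) -> np.ndarray:
    """Z-score columns (mean 0, SD 1 with denominator n−1)."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows to standardize")
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero):
        idx = np.nonzero(zero)[0]
        labels = [names[i] for i in idx] if names is not None else idx.tolist()
        raise ValueError(f"zero-variance column(s): {labels}")
    return (x - x.mean(axis=0)) / sd


def _group_slices(groups):
    """Ordered (label, row-index array) pairs; single pseudo-group if None."""
    if groups is None:
        return [(None, None)]
    groups = np.asarray(groups)
    return [(g, np.nonzero(groups == g)[0]) for g in np.unique(groups)]


def _standardized_blocks(behavior, brain, groups):
    """Within-group z-scored behavior and brain blocks, plus row labels."""
    behavior = np.asarray(behavior, dtype=float)
    out = []
    for g, rows in _group_slices(groups):
        b = behavior if rows is None else behavior[rows]
        xs = {c: (x if rows is None else np.asarray(x, float)[rows])
              for c, x in brain.items()}
        out.append((g, rows, standardize_columns(b),
                    {c: standardize_columns(np.asarray(x, float)) for c, x in xs.items()}))
    return out


def stack_crossblock(behavior: np.ndarray, brain: dict,
                     groups=None) -> tuple[np.ndarray, list]:
    """Stacked correlation matrix R ((G·C·q) × p) and its row labels.

    For each group g and condition c, R_{g,c} = corr(B_g, X_{c,g})
    (Pearson, q × p), stacked group-major then condition-major.  Any NaN
    correlation raises, naming the first offending (row, voxel).
    """
    blocks, labels = [], []
    q = np.asarray(behavior).shape[1]
    for g, _rows, b_std, x_std in _standardized_blocks(behavior, brain, groups):
        n_g = b_std.shape[0]
        for c, xs in x_std.items():
            r = b_std.T @ xs / (n_g - 1)
            if np.any(~np.isfinite(r)):
                i, j = np.argwhere(~np.isfinite(r))[0]
                raise ValueError(
                    f"NaN correlation at metric {i}, voxel {j} (group {g}, {c})")
            blocks.append(r)
            labels.extend((g, c, m) for m in range(q))
    return np.vstack(blocks), labels


def decompose(r: np.ndarray):
    """Thin SVD of the crossblock matrix into latent variables.

    Returns ``(s, u, v)`` with LVs ordered by singular value descending.
    Sign convention: each (u_l, v_l) pair is flipped jointly so the voxel
    salience of largest magnitude is positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(r)):
        raise ValueError("crossblock matrix must be finite")
    u, s, vt = _svd(r, full_matrices=False)
    v = vt.T
    for l in range(s.size):
        j = np.argmax(np.abs(v[:, l]))
        if v[j, l] < 0:
            v[:, l] *= -1
            u[:, l] *= -1
    return s, u, v


def covariance_fraction(s: np.ndarray) -> np.ndarray:
    """Percent of total crossblock covariance per LV: 100·s_l²/Σ s²."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("no singular values")
    total = np.sum(s ** 2)
    if total == 0:
        raise ValueError("all singular values are zero")
    return 100.0 * s ** 2 / total


def compute_brain_scores(x_std: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Subject brain scores: rows of the z-scored brain block dotted with v."""
    x_std = np.asarray(x_std, dtype=float)
    v = np.asarray(v, dtype=float)
    if x_std.shape[1] != v.shape[0]:
        raise ValueError("voxel dimension mismatch between X and saliences")
    return x_std @ v


def condition_contributions(u: np.ndarray, labels) -> dict:
    """Percent contribution of each condition: sums of |behavior salience|.

    Absolute values are used so opposite-signed saliences within a
    condition cannot cancel; with groups, a condition's rows are pooled
    across groups.
    """
    u = np.abs(np.asarray(u, dtype=float))
    conds = []
    for (_g, c, _m) in labels:
        if c not in conds:
            conds.append(c)
    total = u.sum()
    out = {}
    for c in conds:
        rows = [i for i, (_g, cc, _m) in enumerate(labels) if cc == c]
        out[c] = 100.0 * u[rows].sum() / total
    return out


# --------------------------------------------------------------------------
# permutation test
# --------------------------------------------------------------------------

def permutation_test(behavior, brain, groups=None, n_perm: int = 1000,
                     seed: int = 0, chunk: int = 32) -> np.ndarray:
    """Permutation p-values per LV with the add-one counting rule.

    Subject rows of the behavior block are permuted (within group when
    grouped) jointly against all brain conditions; the full stack/SVD is
    recomputed and p_l = (#{s_l^perm >= s_l^obs} + 1)/(n_perm + 1).
    Permuted singular values are obtained from the eigenvalues of R·Rᵀ,
    which is exact and much cheaper than a full SVD when p >> rows.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    parts = _standardized_blocks(behavior, brain, groups)
    r_obs, _ = stack_crossblock(behavior, brain, groups)
    s_obs = _svd(r_obs, compute_uv=False)
    k = s_obs.size
    counts = np.zeros(k)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        r_rows = []
        for _g, _rows, b_std, x_std in parts:
            n_g = b_std.shape[0]
            perm_idx = np.array([rng.permutation(n_g) for _ in range(m)])
            b_perm = b_std[perm_idx]  # (m, n_g, q)
            for xs in x_std.values():
                r_rows.append(np.einsum("mni,nj->mij", b_perm, xs) / (n_g - 1))
        r_perm = np.concatenate(r_rows, axis=1)  # (m, rows, p)
        gram = np.einsum("mij,mkj->mik", r_perm, r_perm)
        ev = np.linalg.eigvalsh(gram)  # ascending
        s_perm = np.sqrt(np.maximum(ev[:, ::-1], 0.0))[:, :k]
        counts += (s_perm >= s_obs).sum(axis=0)
        done += m
    return (counts + 1.0) / (n_perm + 1.0)


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """Voxel bootstrap ratios and behavior-correlation intervals per LV."""

    bsr: np.ndarray            # (p, n_keep); salience / bootstrap SE
    v_boot_sd: np.ndarray      # (p, n_keep)
    corr_obs: np.ndarray       # (rows, n_keep) observed behavior correlations
    corr_ci_low: np.ndarray    # (rows, n_keep)
    corr_ci_high: np.ndarray   # (rows, n_keep)
    n_boot: int
    n_redrawn: int


def _behavior_correlations(b_std_parts, x_std_parts, v, labels_rows):
    """corr(behavior column, brain score) per stacked (group, cond, metric) row."""
    out = np.empty((labels_rows, v.shape[1]))
    i = 0
    for b_std, x_std in zip(b_std_parts, x_std_parts):
        n_g, q = b_std.shape
        for xs in x_std.values():
            scores = xs @ v  # (n_g, k)
            sc = standardize_columns(scores)
            out[i:i + q] = b_std.T @ sc / (n_g - 1)
            i += q
    return out


def bootstrap(behavior, brain, groups=None, n_boot: int = 1000, seed: int = 0,
              n_keep: int = 4) -> BootstrapSummary:
    """Subject bootstrap of the PLS solution with procrustes alignment.

    Subjects are resampled with replacement (within group when grouped);
    the crossblock matrix and its SVD are recomputed, each bootstrap
    solution is rotated onto the original by the orthogonal procrustes
    solution on U, and voxel saliences v are accumulated.  BSR is the
    original salience divided by the bootstrap SD of the aligned salience
    (±inf where the SD is zero).  Behavior-correlation CIs are 2.5/97.5
    percentiles of corr(behavior, brain score) across resamples.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    behavior = np.asarray(behavior, dtype=float)
    parts = _standardized_blocks(behavior, brain, groups)
    r_obs, labels = stack_crossblock(behavior, brain, groups)
    s, u, v = decompose(r_obs)
    k = min(n_keep, s.size)
    n_rows = r_obs.shape[0]
    p = r_obs.shape[1]

    corr_obs = _behavior_correlations(
        [pt[2] for pt in parts], [pt[3] for pt in parts], v[:, :k], n_rows)

    v_sum = np.zeros((p, k))
    v_sumsq = np.zeros((p, k))
    corr_dist = np.empty((n_boot, n_rows, k))
    n_redrawn = 0
    groups_arr = None if groups is None else np.asarray(groups)

    raw_brain = {c: np.asarray(x, float) for c, x in brain.items()}
    for b_i in range(n_boot):
        while True:
            idx_parts = []
            ok = True
            for g, rows, _b, _x in parts:
                base = np.arange(behavior.shape[0]) if rows is None else rows
                draw = rng.choice(base, size=base.size, replace=True)
                if np.unique(draw).size < 3:
                    ok = False
                idx_parts.append(draw)
            if not ok:
                n_redrawn += 1
                continue
            try:
                b_parts, x_parts, r_rows = [], [], []
                for draw in idx_parts:
                    b_std = standardize_columns(behavior[draw])
                    x_std = {c: standardize_columns(x[draw])
                             for c, x in raw_brain.items()}
                    n_g = draw.size
                    for xs in x_std.values():
                        r_rows.append(b_std.T @ xs / (n_g - 1))
                    b_parts.append(b_std)
                    x_parts.append(x_std)
            except ValueError:
                n_redrawn += 1  # zero-variance column in a resample
                continue
            break
        r_b = np.vstack(r_rows)
        u_b, s_b, vt_b = _svd(r_b, full_matrices=False)
        v_b = vt_b.T
        # orthogonal procrustes rotation aligning bootstrap U onto original U
        w, _sv, zt = _svd(u_b.T @ u, full_matrices=False)
        q_rot = w @ zt
        v_rot = (v_b @ q_rot)[:, :k]
        v_sum += v_rot
        v_sumsq += v_rot ** 2
        corr_dist[b_i] = _behavior_correlations(b_parts, x_parts, v_rot, n_rows)

    var = np.maximum(v_sumsq / n_boot - (v_sum / n_boot) ** 2, 0.0)
    sd = np.sqrt(var * n_boot / (n_boot - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(sd > 0, v[:, :k] / sd,
                       np.sign(v[:, :k]) * np.inf)
    lo, hi = np.percentile(corr_dist, [2.5, 97.5], axis=0)
    return BootstrapSummary(bsr=bsr, v_boot_sd=sd, corr_obs=corr_obs,
                            corr_ci_low=lo, corr_ci_high=hi,
                            n_boot=n_boot, n_redrawn=n_redrawn)


# --------------------------------------------------------------------------
# cluster filtering
# --------------------------------------------------------------------------

def bsr_threshold_clusters(bsr_volume: np.ndarray, bsr_thr: float = 2.0,
                           min_cluster: int = 32,
                           connectivity: int = 26) -> np.ndarray:
    """Reliable-voxel mask: |BSR| > thr, cluster floor, sign-split labeling.

    Positive and negative suprathreshold voxels are labeled as separate
    connected components (touching blobs of opposite sign never merge);
    components smaller than ``min_cluster`` voxels are dropped.
    """
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = None  # ndimage default
    else:
        raise ValueError("connectivity must be 6 or 26")
    bsr = np.asarray(bsr_volume, dtype=float)
    keep = np.zeros(bsr.shape, dtype=bool)
    for sign_mask in (bsr > bsr_thr, bsr < -bsr_thr):
        labels, n = _cc_label(sign_mask, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        good = np.nonzero(sizes >= min_cluster)[0]
        good = good[good != 0]
        keep |= np.isin(labels, good)
    return keep


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

@dataclass
class PlsResult:
    """Full PLS solution with inference summaries."""

    singular_values: np.ndarray
    cov_fraction: np.ndarray
    u: np.ndarray               # (rows, K) behavior saliences
    v: np.ndarray               # (p, K) voxel saliences
    row_labels: list            # (group, condition, metric index) per row
    perm_p: np.ndarray | None
    brain_scores: dict          # condition -> (n, n_keep), original subject order
    contributions: list         # per-LV dict condition -> %
    bootstrap: BootstrapSummary | None
    meta: dict = field(default_factory=dict)


def run_pls(behavior, brain: dict, groups=None, n_perm: int = 1000,
            n_boot: int = 1000, seed: int = 0, n_keep: int = 4) -> PlsResult:
    """Run the complete PLS correlation analysis.

    ``behavior`` is (n, q); ``brain`` maps condition name to (n, p).
    ``groups`` (optional) are per-subject labels (e.g. APOE4 0/1); blocks
    are then standardized, correlated, permuted and resampled within group.
    ``n_perm=0`` / ``n_boot=0`` skip the respective inference step.
    """
    behavior = np.asarray(behavior, dtype=float)
    parts = _standardized_blocks(behavior, brain, groups)
    r, labels = stack_crossblock(behavior, brain, groups)
    s, u, v = decompose(r)
    k = min(n_keep, s.size)
    n = behavior.shape[0]
    scores = {c: np.full((n, k), np.nan) for c in brain}
    for g, rows, _b_std, x_std in parts:
        sel = slice(None) if rows is None else rows
        for c, xs in x_std.items():
            scores[c][sel] = compute_brain_scores(xs, v[:, :k])
    contribs = [condition_contributions(u[:, l], labels) for l in range(k)]
    perm_p = None
    if n_perm:
        perm_p = permutation_test(behavior, brain, groups, n_perm=n_perm,
                                  seed=seed)
    boot = None
    if n_boot:
        boot = bootstrap(behavior, brain, groups, n_boot=n_boot,
                         seed=seed + 1, n_keep=k)
    return PlsResult(
        singular_values=s, cov_fraction=covariance_fraction(s),
        u=u, v=v, row_labels=labels, perm_p=perm_p, brain_scores=scores,
        contributions=contribs, bootstrap=boot,
        meta={"n_perm": n_perm, "n_boot": n_boot, "seed": seed,
              "procrustes_in_permutation": False, "grouped": groups is not None})
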