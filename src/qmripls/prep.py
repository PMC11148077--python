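"""ROI extraction, masking, confound residualization and masked smoothing.

These are the steps that turn fitted parameter maps into the two PLS input
blocks: a subject × 16 table of brainstem/basal-forebrain nucleus means
(4 nuclei × 4 MPM parameters) and, per NODDI condition, a subject × voxel
matrix over the group white-matter mask with age and a pontine control
region regressed out, then lightly smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

# probabilistic-atlas thresholds used for the nucleus masks
ROI_THRESHOLDS = {"LC": 0.10, "DR": 0.10, "VTA": 0.25, "NbM": 0.60,
                  "pontine": 0.50}


def threshold_mask(prob: np.ndarray, thr: float, name: str = "ROI") -> np.ndarray:
    """Binary mask: voxels with probability >= thr (inclusive boundary)."""
    if not 0.0 < thr < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    out = np.asarray(prob, dtype=float) >= thr
    if not np.any(out):
        raise ValueError(f"thresholding {name} at {thr} leaves no voxels")
    return out


def make_dr_sphere(grid_shape, affine, center_mm=(0.0, -30.0, -13.0),
                   radius_mm: float = 3.0) -> np.ndarray:
    """Spherical ROI: voxels whose center lies within radius of center_mm.

    This is the dorsal-raphe definition used when no probabilistic atlas is
    trusted: a 3 mm sphere around MNI (0, −30, −13).
    """
    affine = np.asarray(affine, dtype=float)
    ijk = np.stack(np.meshgrid(*[np.arange(n) for n in grid_shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    xyz = ijk @ affine[:3, :3].T + affine[:3, 3]
    d2 = np.sum((xyz - np.asarray(center_mm, float)) ** 2, axis=1)
    mask = (d2 <= radius_mm ** 2).reshape(tuple(grid_shape))
    if not np.any(mask):
        raise ValueError("sphere lies entirely outside the grid")
    return mask


def extract_roi_mean(volume: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean over in-mask finite voxels."""
    vals = np.asarray(volume, dtype=float)[np.asarray(mask, bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite voxels inside the mask")
    return float(vals.mean())


def build_group_wm_mask(subject_masks: np.ndarray, thr: float = 0.95) -> np.ndarray:
    """Group white-matter mask: voxels present in >= thr of subjects (inclusive)."""
    subject_masks = np.asarray(subject_masks, dtype=float)
    if subject_masks.shape[0] < 2:
        raise ValueError("need at least two subjects")
    mean = subject_masks.mean(axis=0)
    out = mean >= thr
    if not np.any(out):
        raise ValueError("group mask is empty")
    return out


def residualize_voxelwise(x: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Per-column OLS residuals of a subject × voxel matrix on [1, covariates].

    The intercept removes the column mean, so residuals come back centered.
    Raises on a rank-deficient covariate design, naming the offending
    columns.
    """
    x = np.asarray(x, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != x.shape[0]:
        cov = cov.T
    n, k = cov.shape
    if n <= k + 1:
        raise ValueError("need more subjects than regressors")
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariates must be finite")
    design = np.column_stack([np.ones(n), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        for j in range(1, design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(j - 1)
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float = 1.0,
                    voxel_size_mm: float = 1.0,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Separable Gaussian smoothing, sigma = FWHM/sqrt(8 ln 2) per axis.

    With a mask, kernel weights are renormalized over in-mask voxels so a
    constant field stays constant up to the mask edge; out-of-mask voxels
    come back NaN.  fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    if mask is None:
        return gaussian_filter(volume, sigma=sigma_vox, mode="constant")
    m = np.asarray(mask, dtype=bool)
    filled = np.where(m, volume, 0.0)
    num = gaussian_filter(filled, sigma=sigma_vox, mode="constant")
    den = gaussian_filter(m.astype(float), sigma=sigma_vox, mode="constant")
    out = np.full_like(volume, np.nan)
    out[m] = num[m] / den[m]
    return out


@dataclass
class VoxelDataset:
    """Per-condition subject × voxel matrices over a common voxel index."""

    matrices: dict  # condition -> (n_subjects, p)
    voxel_index: np.ndarray  # (p, 3) grid coordinates of the columns
    mask: np.ndarray  # boolean grid mask
    conditions: tuple

    @property
    def n_subjects(self) -> int:
        return next(iter(self.matrices.values())).shape[0]

    @property
    def n_voxels(self) -> int:
        return self.voxel_index.shape[0]


def build_voxel_dataset(condition_maps: dict, wm_mask: np.ndarray,
                        covariates: np.ndarray | None = None,
                        fwhm_mm: float = 1.0,
                        voxel_size_mm: float = 1.0) -> VoxelDataset:
    """Assemble PLS brain blocks: mask → residualize → smooth → matrices.

    ``condition_maps`` maps condition name (NDI/ODI/FW) to a
    (n_subjects, X, Y, Z) stack.  Covariates (age + pontine control means)
    are regressed out voxelwise first; each subject's residual volume is
    then smoothed within the mask, mirroring the order of the processing
    chain this feeds.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    voxel_index = np.argwhere(wm_mask)
    matrices = {}
    for cond, stack in condition_maps.items():
        stack = np.asarray(stack, dtype=float)
        x = stack[:, wm_mask]  # (n, p)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"non-finite voxels inside the mask for {cond}")
        if covariates is not None:
            x = residualize_voxelwise(x, covariates)
        if fwhm_mm > 0:
            sm = np.empty_like(x)
            vol = np.zeros(wm_mask.shape)
            for i in range(x.shape[0]):
                vol[wm_mask] = x[i]
                sm[i] = gaussian_smooth(vol, fwhm_mm, voxel_size_mm,
                                        mask=wm_mask)[wm_mask]
            x = sm
        matrices[cond] = x
    return VoxelDataset(matrices=matrices, voxel_index=voxel_index,
                        mask=wm_mask, conditions=tuple(condition_maps))
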