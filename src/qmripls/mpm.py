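"""Quantitative multiparametric mapping (MPM) from multi-echo FLASH triplets.

Implements the standard hMRI-style processing chain:

* joint multi-contrast log-linear R2* estimation with per-contrast TE=0
  intercepts (ESTATICS), one weighted reweighting pass ("WLS1");
* B1+ transmit-field mapping by the double-angle method with polynomial
  surface smoothing;
* R1 and signal-amplitude maps from the T1w/PDw intercept pair through the
  small-flip-angle rational approximation of the FLASH steady state;
* magnetization-transfer saturation (MTsat) with the empirical B1
  correction;
* proton-density calibration to a white-matter reference mean.

All flip angles are degrees at the interface and radians internally; TR is
seconds, echo times milliseconds, R1 and R2* 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class AcqParams:
    """FLASH acquisition parameters: repetition time (s) and nominal flip (deg)."""

    tr: float
    flip_deg: float

    def __post_init__(self):
        if not 0.0 < self.flip_deg < 90.0:
            raise ValueError("flip angle must lie in (0, 90) degrees")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def flip_rad(self) -> float:
        return float(np.deg2rad(self.flip_deg))


@dataclass
class EchoTrain:
    """One multi-echo FLASH acquisition: contrast weighting, timing, volumes."""

    contrast: str  # "T1w" | "PDw" | "MTw"
    tr: float  # s
    flip_deg: float
    te_ms: np.ndarray
    volumes: np.ndarray  # (..., n_echoes)

    def __post_init__(self):
        if self.contrast not in ("T1w", "PDw", "MTw"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        te = np.asarray(self.te_ms, dtype=float)
        if te.size < 1 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if np.any(te / 1000.0 >= self.tr):
            raise ValueError("TE must lie inside (0, TR)")
        vols = np.asarray(self.volumes, dtype=float)
        if vols.shape[-1] != te.size:
            raise ValueError("last volumes axis must index echoes")
        self.te_ms = te
        self.volumes = vols

    @property
    def acq(self) -> AcqParams:
        return AcqParams(tr=self.tr, flip_deg=self.flip_deg)


# The study protocol: 1 mm FLASH triplet and the 60/120 degree DAM pair.
T1W_ACQ = AcqParams(tr=0.018, flip_deg=20.0)
PDW_ACQ = AcqParams(tr=0.027, flip_deg=6.0)
MTW_ACQ = AcqParams(tr=0.027, flip_deg=6.0)
T1W_TE_MS = np.linspace(2.16, 14.81, 6)
PDW_TE_MS = np.linspace(2.04, 22.20, 8)
MTW_TE_MS = np.linspace(2.04, 14.89, 6)
DAM_ALPHA_DEG = 60.0


@dataclass(frozen=True)
class TransmitFieldMap:
    """Relative B1+ transmit efficiency f (unitless, nominal 1.0)."""

    f: np.ndarray


@dataclass
class MpmMaps:
    """Voxelwise quantitative maps; NaN outside the mask / invalid voxels."""

    r1: np.ndarray       # 1/s
    a: np.ndarray        # signal amplitude at TE=0, flip-normalized
    mtsat: np.ndarray    # percent units
    r2star: np.ndarray   # 1/s
    pd: np.ndarray       # percent units


# --------------------------------------------------------------------------
# ESTATICS
# --------------------------------------------------------------------------

def fit_estatics(trains: Sequence[EchoTrain], mask: np.ndarray):
    """Joint log-linear R2* fit with per-contrast TE=0 intercepts.

    Model: ln S_c(TE) = ln S0_c − R2*·TE, one shared R2* across contrasts.
    First an ordinary least-squares pass, then one reweighted pass with
    weights equal to the squared model-predicted signals (the "WLS1"
    scheme, which restores efficiency lost by the log transform).

    Returns ``(intercepts, r2star)`` where ``intercepts`` maps contrast name
    to the exponentiated TE=0 intercept map.  Voxels with nonpositive
    signal anywhere in the mask are flagged invalid (NaN).
    """
    if len(trains) < 1:
        raise ValueError("need at least one echo train")
    mask = np.asarray(mask, dtype=bool)
    n_c = len(trains)
    te_all, contrast_idx, sig_rows = [], [], []
    for ci, tr in enumerate(trains):
        te_s = tr.te_ms / 1000.0
        te_all.append(te_s)
        contrast_idx.append(np.full(te_s.size, ci))
        sig_rows.append(tr.volumes[mask].T)  # (n_echo, n_vox)
    te_all = np.concatenate(te_all)
    contrast_idx = np.concatenate(contrast_idx)
    if te_all.size < n_c + 1:
        raise ValueError("need at least n_contrasts + 1 echoes in total")
    if np.ptp(te_all) == 0:
        raise ValueError("singular design: all echo times equal")
    signals = np.concatenate(sig_rows, axis=0)  # (n_obs, n_vox)

    design = np.zeros((te_all.size, n_c + 1))
    design[np.arange(te_all.size), contrast_idx] = 1.0
    design[:, -1] = -te_all

    valid = np.all(signals > 0, axis=0)
    beta = np.full((n_c + 1, signals.shape[1]), np.nan)
    if np.any(valid):
        logs = np.log(signals[:, valid])
        b_ols, *_ = np.linalg.lstsq(design, logs, rcond=None)
        # one reweighting pass, w = predicted signal squared
        pred = design @ b_ols
        w = np.exp(2.0 * pred)  # (n_obs, n_vox_valid)
        aw = np.einsum("ov,oi,oj->vij", w, design, design)
        bw = np.einsum("ov,oi,ov->vi", w, design, logs)
        beta[:, valid] = np.linalg.solve(aw, bw[..., None])[..., 0].T

    shape = mask.shape
    r2star = np.full(shape, np.nan)
    r2star[mask] = beta[-1]
    intercepts = {}
    for ci, tr in enumerate(trains):
        s0 = np.full(shape, np.nan)
        s0[mask] = np.exp(beta[ci])
        intercepts[tr.contrast] = s0
    return intercepts, r2star


# --------------------------------------------------------------------------
# B1+ mapping (double-angle method)
# --------------------------------------------------------------------------

def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial design x^i y^j z^k with i+j+k <= order; coords in [-1, 1]."""
    cols = []
    x, y, z = coords.T
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append(x ** i * y ** j * z ** k)
    return np.column_stack(cols)


def estimate_b1_dam(s_alpha: np.ndarray, s_2alpha: np.ndarray,
                    alpha_nominal_deg: float, mask: np.ndarray,
                    poly_order: int = 6) -> TransmitFieldMap:
    """Double-angle B1+ map with 3-D polynomial surface smoothing.

    Raw efficiency f = arccos(clamp(S_2a / (2 S_a), −1, 1)) / a_nominal; a
    polynomial surface of total degree ``poly_order`` is least-squares fit
    to the raw values within the mask and evaluated over the whole grid.
    """
    if not 0.0 < alpha_nominal_deg < 90.0:
        raise ValueError("nominal flip angle must lie in (0, 90) degrees")
    s_alpha = np.asarray(s_alpha, dtype=float)
    s_2alpha = np.asarray(s_2alpha, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    alpha = np.deg2rad(alpha_nominal_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.clip(s_2alpha / (2.0 * s_alpha), -1.0, 1.0)
    raw = np.arccos(ratio) / alpha
    fit_mask = mask & (s_alpha > 0) & np.isfinite(raw)
    if not np.any(fit_mask):
        raise ValueError("no valid voxels for B1 fit")
    shape = mask.shape
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    half = (np.array(shape) - 1) / 2.0
    norm = np.where(half > 0, half, 1.0)
    coords = (grid - half) / norm
    design_fit = _poly_design(coords[fit_mask], poly_order)
    coef, *_ = np.linalg.lstsq(design_fit, raw[fit_mask], rcond=None)
    f = (_poly_design(coords.reshape(-1, 3), poly_order) @ coef).reshape(shape)
    return TransmitFieldMap(f=f)


def raw_dam_efficiency(s_alpha, s_2alpha, alpha_nominal_deg: float):
    """Unsmoothed DAM efficiency (exposed for point-value checks)."""
    alpha = np.deg2rad(alpha_nominal_deg)
    ratio = np.clip(np.asarray(s_2alpha, float) / (2.0 * np.asarray(s_alpha, float)),
                    -1.0, 1.0)
    return np.arccos(ratio) / alpha


# --------------------------------------------------------------------------
# R1 / A / MTsat / PD
# --------------------------------------------------------------------------

def rational_flash_signal(a, r1, acq: AcqParams, f=1.0):
    """Small-angle rational approximation of the FLASH steady state."""
    alpha = np.asarray(f, float) * acq.flip_rad
    return a * alpha * (acq.tr * r1) / (alpha ** 2 / 2.0 + acq.tr * r1)


def exact_flash_signal(a, r1, acq: AcqParams, f=1.0):
    """Exact spoiled steady state S = A·sin(a)·(1−E1)/(1−cos(a)·E1)."""
    alpha = np.asarray(f, float) * acq.flip_rad
    e1 = np.exp(-acq.tr * np.asarray(r1, float))
    return a * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)


def compute_r1_a(s0_t1w: np.ndarray, s0_pdw: np.ndarray,
                 t1w_acq: AcqParams = T1W_ACQ, pdw_acq: AcqParams = PDW_ACQ,
                 f: TransmitFieldMap | float = 1.0):
    """R1 and amplitude maps from the dual-flip-angle intercept pair.

    Solves the 2×2 rational-approximation system
    S_c = A·a_c·(TR_c·R1)/(a_c²/2 + TR_c·R1) for c in {T1w, PDw} in closed
    form; A follows by back-substitution into the PDw equation.  Effective
    flip angles are f·a_nominal.  Non-physical signal pairs (denominator
    ≤ 0) become NaN.
    """
    fmap = f.f if isinstance(f, TransmitFieldMap) else np.asarray(f, float)
    s_t1 = np.asarray(s0_t1w, dtype=float)
    s_pd = np.asarray(s0_pdw, dtype=float)
    a_t1 = fmap * t1w_acq.flip_rad
    a_pd = fmap * pdw_acq.flip_rad
    with np.errstate(divide="ignore", invalid="ignore"):
        num = s_t1 * a_t1 / t1w_acq.tr - s_pd * a_pd / pdw_acq.tr
        den = s_pd / a_pd - s_t1 / a_t1
        r1 = 0.5 * num / den
        a = s_pd * (a_pd ** 2 / 2.0 + pdw_acq.tr * r1) / (a_pd * pdw_acq.tr * r1)
    bad = ~np.isfinite(r1) | (den <= 0) | (r1 <= 0)
    r1 = np.where(bad, np.nan, r1)
    a = np.where(bad, np.nan, a)
    return r1, a


def compute_mtsat(s0_mtw: np.ndarray, a: np.ndarray, r1: np.ndarray,
                  mtw_acq: AcqParams = MTW_ACQ,
                  f: TransmitFieldMap | float = 1.0,
                  corr_c: float = 0.4) -> np.ndarray:
    """MT saturation map in percent units with empirical B1 correction.

    delta = (A·a_MT/S_MT − 1)·R1·TR_MT − a_MT²/2 with a_MT = f·a_nominal,
    then delta_corr = delta·(1 − C)/(1 − C·f) with C = ``corr_c``; the map
    is reported ×100 (percent units).
    """
    fmap = f.f if isinstance(f, TransmitFieldMap) else np.asarray(f, float)
    s_mt = np.asarray(s0_mtw, dtype=float)
    alpha = fmap * mtw_acq.flip_rad
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a * alpha / s_mt - 1.0) * r1 * mtw_acq.tr - alpha ** 2 / 2.0
        delta = delta * (1.0 - corr_c) / (1.0 - corr_c * fmap)
    delta = np.where(s_mt <= 0, np.nan, delta)
    return delta * 100.0


def calibrate_pd(a: np.ndarray, wm_mask: np.ndarray,
                 target: float = 69.0) -> np.ndarray:
    """Scale the amplitude map so the white-matter mean equals ``target`` p.u."""
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not np.any(wm_mask):
        raise ValueError("white-matter mask is empty")
    ref = np.nanmean(np.asarray(a, float)[wm_mask])
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("non-positive white-matter mean amplitude")
    return np.asarray(a, float) * (target / ref)


def fit_mpm(trains: Sequence[EchoTrain], mask: np.ndarray,
            b1: TransmitFieldMap | float = 1.0,
            wm_mask: np.ndarray | None = None,
            pd_target: float = 69.0, mtsat_corr_c: float = 0.4) -> MpmMaps:
    """Full map computation: ESTATICS → R1/A → MTsat → PD calibration."""
    by_contrast = {t.contrast: t for t in trains}
    for needed in ("T1w", "PDw", "MTw"):
        if needed not in by_contrast:
            raise ValueError(f"missing {needed} echo train")
    intercepts, r2star = fit_estatics(trains, mask)
    r1, a = compute_r1_a(intercepts["T1w"], intercepts["PDw"],
                         by_contrast["T1w"].acq, by_contrast["PDw"].acq, f=b1)
    mtsat = compute_mtsat(intercepts["MTw"], a, r1, by_contrast["MTw"].acq,
                          f=b1, corr_c=mtsat_corr_c)
    pd = calibrate_pd(a, wm_mask if wm_mask is not None else mask, pd_target)
    mask_arr = np.asarray(mask, dtype=bool)
    for m in (r1, a, mtsat, r2star, pd):
        m[~mask_arr] = np.nan
    return MpmMaps(r1=r1, a=a, mtsat=mtsat, r2star=r2star, pd=pd)
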