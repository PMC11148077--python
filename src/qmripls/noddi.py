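"""Watson-dispersion NODDI forward model and a dictionary/NNLS fitter.

The tissue model is the standard three-compartment one: intra-neurite
"sticks" dispersed by a Watson distribution with concentration ``kappa``,
an extra-neurite axially symmetric tensor whose perpendicular diffusivity
follows the tortuosity constraint ``d_perp = d_par * (1 - f_ic)``, and an
isotropic free-water ball.  The per-voxel fit is a linearized dictionary
fit in the spirit of AMICO: a lattice of (f_ic, ODI) tissue atoms plus a
ball atom, oriented by a per-voxel DTI principal direction, solved by
non-negative least squares with a small Tikhonov penalty.

Diffusivities are fixed at the canonical NODDI values
``d_par = 1.7 µm²/ms`` and ``d_iso = 3.0 µm²/ms``.  b-values are carried
in s/mm² externally and converted to ms/µm² internally (b=1000 s/mm²
corresponds to 1.0 ms/µm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

D_PAR = 1.7  # parallel (stick) diffusivity, µm²/ms
D_ISO = 3.0  # free-water diffusivity, µm²/ms

_B0_THRESHOLD = 50.0  # s/mm²; below this a measurement counts as b=0
_N_QUAD = 1000  # spherical quadrature size for Watson averaging


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere (n, 3)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_QUAD_POINTS = fibonacci_sphere(_N_QUAD)


def odi_from_kappa(kappa):
    """Orientation dispersion index ODI = (2/pi)·arctan(1/kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be > 0")
    return (2.0 / np.pi) * np.arctan(1.0 / kappa)


def kappa_from_odi(odi):
    """Exact inverse of :func:`odi_from_kappa`."""
    odi = np.asarray(odi, dtype=float)
    if np.any((odi <= 0) | (odi > 1)):
        raise ValueError("odi must lie in (0, 1]")
    return 1.0 / np.tan(np.pi * odi / 2.0)


# --------------------------------------------------------------------------
# acquisition scheme
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionScheme:
    """Multi-shell diffusion acquisition: b-values (s/mm²) and unit b-vectors."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must be (n_meas, 3)")
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        dw = bvals > _B0_THRESHOLD
        if not np.any(~dw):
            raise ValueError("scheme must contain at least one b=0 measurement")
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("b>0 gradient directions must be unit vectors (tol 1e-6)")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= _B0_THRESHOLD

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b-values in ms/µm² (b=1000 s/mm² -> 1.0)."""
        return self.bvals / 1000.0

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique nonzero b-values (s/mm²)."""
        return np.unique(self.bvals[~self.is_b0])


def default_scheme() -> DiffusionScheme:
    """The study's 109-measurement scheme: 9×b0, 7×b300, 29×b1000, 64×b2000."""
    counts = {0.0: 9, 300.0: 7, 1000.0: 29, 2000.0: 64}
    bvals, bvecs = [], []
    offset = 0
    for b, n in counts.items():
        bvals.extend([b] * n)
        if b == 0.0:
            bvecs.extend([[0.0, 0.0, 0.0]] * n)
        else:
            # rotate each shell's lattice a little so shells interleave
            pts = fibonacci_sphere(2 * n)[offset::2][:n]
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            bvecs.extend(pts.tolist())
            offset = (offset + 1) % 2
    return DiffusionScheme(np.array(bvals), np.array(bvecs))


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoddiVoxelParams:
    """Per-voxel NODDI parameters.

    f_iso is the free-water (FW) fraction, f_ic the intra-neurite fraction
    of the tissue compartment (NDI), kappa the Watson concentration and mu
    the mean neurite orientation (unit 3-vector).
    """

    f_iso: float
    f_ic: float
    kappa: float
    mu: Sequence[float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if not (0.0 <= self.f_iso <= 1.0 and 0.0 <= self.f_ic <= 1.0):
            raise ValueError("f_iso and f_ic must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        mu = np.asarray(self.mu, dtype=float)
        n = np.linalg.norm(mu)
        if n == 0:
            raise ValueError("mu must be a nonzero vector")
        object.__setattr__(self, "mu", mu / n)

    @property
    def odi(self) -> float:
        return float(odi_from_kappa(self.kappa))


def _watson_weights(mu: np.ndarray, kappa: float, points: np.ndarray) -> np.ndarray:
    """Quadrature weights of Watson(mu, kappa), normalized to sum to 1."""
    t2 = (points @ mu) ** 2
    w = np.exp(kappa * (t2 - t2.max()))  # stable for large kappa
    return w / w.sum()


def _tissue_attenuation(b_ms, g_dot_n2, watson_w, f_ic):
    """Watson-averaged stick + tortuosity-tensor attenuation.

    ``g_dot_n2``: (n_meas, n_quad) squared dot products of gradient
    directions with the quadrature orientations.
    """
    b = np.asarray(b_ms, dtype=float)[:, None]
    a_ic = np.exp(-b * D_PAR * g_dot_n2) @ watson_w
    d_perp = D_PAR * (1.0 - f_ic)
    a_ec = np.exp(-b * (d_perp + (D_PAR - d_perp) * g_dot_n2)) @ watson_w
    return f_ic * a_ic + (1.0 - f_ic) * a_ec


def predict_signal(params: NoddiVoxelParams, scheme: DiffusionScheme) -> np.ndarray:
    """Normalized diffusion signal S/S0 for one voxel over the whole scheme.

    S/S0 = (1 - f_iso)·(f_ic·A_ic + (1 - f_ic)·A_ec) + f_iso·exp(-b·d_iso),
    with the intra- and extra-neurite attenuations averaged over the Watson
    orientation distribution by a fixed 1000-point spherical quadrature.
    """
    b = scheme.b_ms_um2
    w = _watson_weights(params.mu, params.kappa, _QUAD_POINTS)
    g_dot_n2 = (scheme.bvecs @ _QUAD_POINTS.T) ** 2
    tissue = _tissue_attenuation(b, g_dot_n2, w, params.f_ic)
    ball = np.exp(-b * D_ISO)
    s = (1.0 - params.f_iso) * tissue + params.f_iso * ball
    # b=0 rows carry zero bvecs; the attenuations there are exactly 1 anyway
    return s


# --------------------------------------------------------------------------
# direction estimation (orients the dictionary)
# --------------------------------------------------------------------------

def estimate_direction(signals: np.ndarray, scheme: DiffusionScheme,
                       b_max: float = 1000.0):
    """Principal diffusion direction from a log-linear tensor fit at b ≤ b_max.

    Returns ``(mu, degenerate)``; on a degenerate tensor (near-equal leading
    eigenvalues) mu falls back to the direction of the overall mean-signal
    gradient and the flag is set.

    Sign convention: mu_z > 0, ties broken toward positive y then x.
    """
    signals = np.asarray(signals, dtype=float)
    use = scheme.bvals <= b_max + 1e-9
    if (scheme.bvals[use] > _B0_THRESHOLD).sum() < 6:
        raise ValueError("need at least 6 diffusion-weighted directions at b <= b_max")
    b = scheme.b_ms_um2[use]
    g = scheme.bvecs[use]
    s0 = signals[scheme.is_b0].mean()
    y = np.log(np.maximum(signals[use], 1e-12) / max(s0, 1e-12))
    # design for the 6 unique tensor elements
    design = -b[:, None] * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])
    d, *_ = np.linalg.lstsq(design, y, rcond=None)
    tensor = np.array([[d[0], d[3], d[4]],
                       [d[3], d[1], d[5]],
                       [d[4], d[5], d[2]]])
    evals, evecs = np.linalg.eigh(tensor)
    spread = evals[-1] - evals[0]
    scale = max(abs(evals).max(), 1e-12)
    degenerate = spread / scale < 1e-3
    if degenerate:
        dw = ~scheme.is_b0
        mu = (signals[dw, None] * scheme.bvecs[dw]).mean(axis=0)
        if np.linalg.norm(mu) < 1e-12:
            mu = np.array([0.0, 0.0, 1.0])
    else:
        mu = evecs[:, -1]
    mu = mu / np.linalg.norm(mu)
    for axis in (2, 1, 0):
        if abs(mu[axis]) > 1e-12:
            if mu[axis] < 0:
                mu = -mu
            break
    return mu, bool(degenerate)


# --------------------------------------------------------------------------
# dictionary fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DictionaryGrid:
    """Lattice of tissue atoms: f_ic values × ODI-spaced kappa values."""

    f_ic: np.ndarray = field(default_factory=lambda: np.linspace(0.05, 0.95, 12))
    odi: np.ndarray = field(default_factory=lambda: np.linspace(0.04, 0.95, 12))
    lam: float = 1e-4  # Tikhonov penalty on atom weights

    def __post_init__(self):
        object.__setattr__(self, "f_ic", np.asarray(self.f_ic, dtype=float))
        object.__setattr__(self, "odi", np.asarray(self.odi, dtype=float))
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    @property
    def atoms(self):
        """(f_ic, odi) pairs, f_ic-major order."""
        ff, oo = np.meshgrid(self.f_ic, self.odi, indexing="ij")
        return ff.ravel(), oo.ravel()


class _ResponseTables:
    """Axially-symmetric tissue responses tabulated over t = |g·mu|.

    Because every compartment is axially symmetric about mu, an atom's
    signal depends on the gradient only through b and t = |g·mu|; each atom
    is tabulated per shell on a fine t-grid once and per-voxel dictionaries
    are then linear interpolations — this is what makes the volume fit fast.
    """

    def __init__(self, grid: DictionaryGrid, shells_s_mm2: np.ndarray,
                 n_t: int = 129):
        self.t_grid = np.linspace(0.0, 1.0, n_t)
        self.shells = np.asarray(shells_s_mm2, dtype=float)
        f_ic, odi = grid.atoms
        kappa = kappa_from_odi(odi)
        mu = np.array([0.0, 0.0, 1.0])
        nz2 = _QUAD_POINTS[:, 2] ** 2
        # gradient directions sweeping t = cos(theta) against mu = z
        sin_t = np.sqrt(np.maximum(0.0, 1.0 - self.t_grid ** 2))
        g = np.column_stack([sin_t, np.zeros_like(self.t_grid), self.t_grid])
        g_dot_n2 = (g @ _QUAD_POINTS.T) ** 2
        b_ms = self.shells / 1000.0
        # tables[s] : (n_atoms, n_t) for shell s
        self.tables = np.empty((self.shells.size, f_ic.size, n_t))
        for a in range(f_ic.size):
            w = _watson_weights(mu, kappa[a], _QUAD_POINTS)
            for s, b in enumerate(b_ms):
                self.tables[s, a] = _tissue_attenuation(
                    np.full(n_t, b), g_dot_n2, w, f_ic[a])
        del nz2

    def dictionary(self, scheme: DiffusionScheme, mu: np.ndarray) -> np.ndarray:
        """(n_meas, n_atoms) tissue dictionary for orientation mu."""
        t = np.abs(scheme.bvecs @ mu)
        out = np.ones((scheme.bvals.size, self.tables.shape[1]))
        for s, b in enumerate(self.shells):
            rows = np.isclose(scheme.bvals, b)
            frac = np.interp(t[rows], self.t_grid, np.arange(self.t_grid.size))
            lo = np.floor(frac).astype(int)
            hi = np.minimum(lo + 1, self.t_grid.size - 1)
            w_hi = frac - lo
            out[rows] = (self.tables[s][:, lo] * (1 - w_hi)
                         + self.tables[s][:, hi] * w_hi).T
        return out


@dataclass
class NoddiMaps:
    """Voxelwise NODDI parameter maps, NaN outside the mask."""

    ndi: np.ndarray
    odi: np.ndarray
    fw: np.ndarray
    degenerate: np.ndarray | None = None  # voxels where direction fit fell back


def _exact_dictionary(grid: DictionaryGrid, scheme: DiffusionScheme,
                      mu: np.ndarray) -> np.ndarray:
    """Tissue dictionary evaluated by direct quadrature (no t-interpolation)."""
    f_ic, odi = grid.atoms
    kappa = kappa_from_odi(odi)
    g_dot_n2 = (scheme.bvecs @ _QUAD_POINTS.T) ** 2
    b = scheme.b_ms_um2
    out = np.empty((scheme.bvals.size, f_ic.size))
    for a in range(f_ic.size):
        w = _watson_weights(mu, kappa[a], _QUAD_POINTS)
        out[:, a] = _tissue_attenuation(b, g_dot_n2, w, f_ic[a])
    return out


_TABLE_CACHE: dict = {}


def _cached_tables(grid: DictionaryGrid, shells: np.ndarray) -> _ResponseTables:
    key = (tuple(grid.f_ic), tuple(grid.odi), tuple(shells))
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _ResponseTables(grid, shells)
    return _TABLE_CACHE[key]


def fit_volume(dwi: np.ndarray, scheme: DiffusionScheme, mask: np.ndarray,
               grid: DictionaryGrid | None = None,
               exact_dictionary: bool = False,
               directions: np.ndarray | None = None) -> NoddiMaps:
    """Dictionary/NNLS NODDI fit of a 4-D DWI volume.

    Per voxel: estimate the neurite orientation from a DTI fit at b ≤ 1000
    (or take it from ``directions``, shape mask.shape + (3,), when the
    orientation field is known), assemble tissue atoms on the (f_ic, ODI)
    lattice plus one free-water ball atom, and solve non-negative least
    squares with Tikhonov penalty ``grid.lam`` on the atom weights.  NDI
    and ODI are the weight-weighted means over tissue atoms; FW is the
    ball atom's weight share.
    """
    if grid is None:
        grid = DictionaryGrid()
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dwi.shape[:-1] != mask.shape or dwi.shape[-1] != scheme.bvals.size:
        raise ValueError("dwi, mask and scheme shapes disagree")
    tables = None if exact_dictionary else _cached_tables(grid, scheme.shells)
    f_ic_atoms, odi_atoms = grid.atoms
    n_atoms = f_ic_atoms.size
    ball = np.exp(-scheme.b_ms_um2 * D_ISO)
    sqrt_lam = np.sqrt(grid.lam)
    reg = sqrt_lam * np.eye(n_atoms + 1)
    zeros = np.zeros(n_atoms + 1)

    shape = mask.shape
    ndi = np.full(shape, np.nan)
    odi = np.full(shape, np.nan)
    fw = np.full(shape, np.nan)
    degen = np.zeros(shape, dtype=bool)

    is_b0 = scheme.is_b0
    for idx in zip(*np.nonzero(mask)):
        sig = dwi[idx]
        s0 = sig[is_b0].mean()
        if not np.isfinite(s0) or s0 <= 0:
            continue
        y = sig / s0
        if directions is not None:
            mu = np.asarray(directions[idx], dtype=float)
            mu = mu / np.linalg.norm(mu)
            flag = False
        else:
            mu, flag = estimate_direction(sig, scheme)
        degen[idx] = flag
        if exact_dictionary:
            tissue = _exact_dictionary(grid, scheme, mu)
        else:
            tissue = tables.dictionary(scheme, mu)
        d = np.column_stack([tissue, ball])
        if grid.lam > 0:
            a_mat = np.vstack([d, reg])
            b_vec = np.concatenate([y, zeros])
        else:
            a_mat, b_vec = d, y
        w, _ = nnls(a_mat, b_vec)
        total = w.sum()
        if total <= 0:
            continue
        w_tissue = w[:n_atoms]
        tsum = w_tissue.sum()
        fw[idx] = w[-1] / total
        if tsum > 0:
            ndi[idx] = float(w_tissue @ f_ic_atoms / tsum)
            odi[idx] = float(w_tissue @ odi_atoms / tsum)
        else:
            ndi[idx] = 0.0
            odi[idx] = 0.0
    return NoddiMaps(ndi=ndi, odi=odi, fw=fw, degenerate=degen)
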