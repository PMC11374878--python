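"""Synthetic multi-shell acquisitions with known ground truth.

This module emulates, at desk scale, the acquisition geometry of a
high-angular-resolution multi-shell protocol (three shells at b = 1000,
2000, 3000 s/mm^2, 90 directions each, 6 b=0 volumes, 1.25 mm isotropic
voxels) and provides the two voxel-level signal laws used throughout:

* single Gaussian diffusion tensor:  S = S0 exp(-b g^T D g)
* three-compartment neurite model (Watson-dispersed sticks, tortuosity
  zeppelin, isotropic ball):

      S/S0 = nu_iso * exp(-b d_iso)
           + (1 - nu_iso) * [ nu_ic * E_stick(kappa, mu)
                              + (1 - nu_ic) * E_zeppelin ]

  with the zeppelin perpendicular diffusivity tied to the intracellular
  fraction by the tortuosity rule d_perp = d_par (1 - nu_ic).  The Watson
  orientation average is computed by sphere quadrature (3072 nodes), which
  is exact enough to test both the high- and low-concentration limits.

Phantoms are tubes (parametric centerlines with a radius) carrying an
anisotropic ground truth inside an isotropic background.  Noise is Rician
by default (magnitude MRI), Gaussian on request for analytic tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .gradients import GradientTable
from .shm import fibonacci_sphere

__all__ = [
    "D_PAR",
    "D_ISO",
    "BundleGeometry",
    "PhantomSpec",
    "MicrostructureField",
    "PhantomResult",
    "CohortSpec",
    "watson_weights",
    "simulate_signal_tensor",
    "simulate_signal_noddi",
    "axisymmetric_tensor_signal",
    "add_noise",
    "build_phantom",
    "simulate_cohort",
]

# Fixed compartment diffusivities (mm^2/s), the conventional in-vivo values.
D_PAR = 1.7e-3
D_ISO = 3.0e-3

_N_WATSON_NODES = 3072
_watson_nodes_cache: dict[int, np.ndarray] = {}


def _watson_nodes(n: int = _N_WATSON_NODES) -> np.ndarray:
    if n not in _watson_nodes_cache:
        _watson_nodes_cache[n] = fibonacci_sphere(n)
    return _watson_nodes_cache[n]


def watson_weights(kappa: float, mu: np.ndarray, nodes: np.ndarray | None = None) -> np.ndarray:
    """Normalized Watson density W(n; mu, kappa) ~ exp(kappa (mu.n)^2) on quadrature nodes."""
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    nodes = _watson_nodes() if nodes is None else nodes
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    c2 = (nodes @ mu) ** 2
    w = np.exp(kappa * (c2 - 1.0))  # shift by max for numerical safety
    return w / w.sum()


def simulate_signal_tensor(tensor: np.ndarray, gtab: GradientTable, s0: float = 1.0) -> np.ndarray:
    """Gaussian-tensor DWI signal, one value per gradient entry.

    ``tensor`` is a symmetric 3x3 diffusion tensor in mm^2/s; it must be
    positive semi-definite.  b=0 entries return exactly ``s0``.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T, atol=1e-12):
        raise ValueError("tensor must be symmetric 3x3")
    evals = np.linalg.eigvalsh(tensor)
    if evals.min() < -1e-12:
        raise ValueError(f"tensor has negative eigenvalue {evals.min():g}")
    quad = np.einsum("ni,ij,nj->n", gtab.bvecs, tensor, gtab.bvecs)
    return s0 * np.exp(-gtab.bvals * quad)


def axisymmetric_tensor_signal(
    bvals: np.ndarray,
    bvecs: np.ndarray,
    axes: np.ndarray,
    d_par: float,
    d_perp: float,
    s0: float = 1.0,
) -> np.ndarray:
    """Vectorized tensor signal for axially symmetric tensors.

    ``axes`` is (V, 3) unit principal directions; returns (V, G).
    """
    axes = np.atleast_2d(axes)
    c2 = (bvecs @ axes.T) ** 2  # (G, V)
    adc = d_perp + (d_par - d_perp) * c2
    return (s0 * np.exp(-bvals[:, None] * adc)).T


def simulate_signal_noddi(
    nu_ic: float,
    nu_iso: float,
    kappa: float,
    mu: np.ndarray,
    gtab: GradientTable,
    s0: float = 1.0,
    d_par: float = D_PAR,
    d_iso: float = D_ISO,
) -> np.ndarray:
    """Three-compartment neurite-model signal, one value per gradient entry."""
    for name, v in (("nu_ic", nu_ic), ("nu_iso", nu_iso)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    b, g = gtab.bvals, gtab.bvecs
    ball = np.exp(-b * d_iso)
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    c2 = (g @ mu) ** 2
    d_perp = d_par * (1.0 - nu_ic)
    zeppelin = np.exp(-b * (d_perp + (d_par - d_perp) * c2))
    nodes = _watson_nodes()
    w = watson_weights(kappa, mu, nodes)
    stick = np.exp(-b[:, None] * d_par * (g @ nodes.T) ** 2) @ w
    intra_extra = nu_ic * stick + (1.0 - nu_ic) * zeppelin
    return s0 * (nu_iso * ball + (1.0 - nu_iso) * intra_extra)


def add_noise(
    signal: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
    model: str = "rician",
) -> np.ndarray:
    """Add Gaussian or Rician (magnitude) noise of scale ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, size=np.shape(signal))
    if model == "rician":
        n1 = rng.normal(0.0, sigma, size=np.shape(signal))
        n2 = rng.normal(0.0, sigma, size=np.shape(signal))
        return np.sqrt((signal + n1) ** 2 + n2**2)
    raise ValueError(f"unknown noise model {model!r}")


# --------------------------------------------------------------------------
# Phantom construction


@dataclass
class BundleGeometry:
    """A tube: centerline polyline (world mm) plus radius and ground truth."""

    name: str
    centerline: np.ndarray  # (K, 3) world mm
    radius_mm: float
    d_par: float = D_PAR
    d_perp: float = 0.3e-3
    nu_ic: float = 0.6
    nu_iso: float = 0.05
    kappa: float = 16.0

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if self.radius_mm <= 0:
            raise ValueError("tube radius must be positive")
        if not (0 <= self.nu_ic <= 1 and 0 <= self.nu_iso <= 1):
            raise ValueError("volume fractions must be in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.d_par < 0 or self.d_perp < 0:
            raise ValueError("diffusivities must be non-negative")


@dataclass
class PhantomSpec:
    """Everything needed to build one synthetic acquisition."""

    grid_shape: tuple[int, int, int]
    gtab: GradientTable
    bundles: list[BundleGeometry] = field(default_factory=list)
    voxel_size: float = 1.25
    s0: float = 1.0
    background_adc: float = 0.9e-3
    noise_sigma: float = 0.0
    noise_model: str = "rician"
    signal_model: str = "tensor"  # or "noddi"
    allow_crossings: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.signal_model not in ("tensor", "noddi"):
            raise ValueError(f"unknown signal model {self.signal_model!r}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size
        return a


@dataclass
class MicrostructureField:
    """Voxelwise ground truth (or fit) of the local models on one grid.

    ``peak_dirs`` holds up to two unit orientations per voxel (NaN when
    absent); crossing voxels carry two.
    """

    evals: np.ndarray  # (X, Y, Z, 3) descending, mm^2/s
    peak_dirs: np.ndarray  # (X, Y, Z, 2, 3)
    nu_ic: np.ndarray
    nu_iso: np.ndarray
    kappa: np.ndarray
    crossing: np.ndarray  # bool
    bundle_label: np.ndarray  # int, -1 = background


@dataclass
class PhantomResult:
    dwi: np.ndarray  # (X, Y, Z, G)
    affine: np.ndarray
    gtab: GradientTable
    truth: MicrostructureField
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    bundles: dict[str, np.ndarray]  # name -> centerline streamline (mm)
    spec: PhantomSpec


def _tube_membership(spec: PhantomSpec, centers: np.ndarray):
    """For each voxel center return per-bundle (inside, tangent) info."""
    hits = []
    lo = -0.5 * spec.voxel_size
    hi = (np.asarray(spec.grid_shape) - 0.5) * spec.voxel_size
    for b in spec.bundles:
        if np.any(b.centerline < lo) or np.any(b.centerline > hi):
            raise ValueError(f"bundle {b.name!r} centerline leaves the grid")
        # densify centerline so nearest-point distance approximates tube distance
        seg = np.linalg.norm(np.diff(b.centerline, axis=0), axis=1)
        n_pts = max(int(np.ceil(seg.sum() / (0.25 * spec.voxel_size))) + 1, 2)
        dense = _resample_polyline(b.centerline, n_pts)
        tang = np.gradient(dense, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        tree = cKDTree(dense)
        dist, idx = tree.query(centers)
        inside = dist <= b.radius_mm
        hits.append((inside, tang[idx]))
    return hits


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, s, points[:, k])
    return out


def _noddi_signal_by_orientation(
    bundle: BundleGeometry, axes: np.ndarray, gtab: GradientTable, s0: float
) -> np.ndarray:
    """Per-voxel neurite-model signal grouped by (rounded) orientation."""
    key = np.round(axes, 5)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    out = np.empty((axes.shape[0], len(gtab)))
    for u_idx in range(uniq.shape[0]):
        mu = uniq[u_idx]
        sig = simulate_signal_noddi(
            bundle.nu_ic, bundle.nu_iso, bundle.kappa, mu, gtab, s0=s0, d_par=bundle.d_par
        )
        out[inv == u_idx] = sig
    return out


def build_phantom(spec: PhantomSpec) -> PhantomResult:
    """Rasterize tube bundles into a grid and simulate the DWI volume.

    Voxels inside a tube carry that bundle's anisotropic truth; voxels in
    two tubes are crossing voxels (mean of the two single-fiber signals,
    equal fractions) and are only allowed when ``spec.allow_crossings``.
    Reproducible for a fixed ``rng_seed``.
    """
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_size
    gtab = spec.gtab
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    centers = idx * vs
    n_vox = centers.shape[0]
    n_grad = len(gtab)

    hits = _tube_membership(spec, centers)
    count = np.zeros(n_vox, dtype=int)
    for inside, _ in hits:
        count += inside
    if np.any(count > 2):
        raise ValueError("more than two bundles overlap in one voxel")
    if np.any(count == 2) and not spec.allow_crossings:
        raise ValueError(
            "overlapping tubes carry contradictory single-compartment truth; "
            "set allow_crossings=True for two-orientation voxels"
        )

    signal = np.empty((n_vox, n_grad))
    signal[:] = spec.s0 * np.exp(-gtab.bvals * spec.background_adc)[None, :]

    label = np.full(n_vox, -1, dtype=int)
    peak_dirs = np.full((n_vox, 2, 3), np.nan)
    evals = np.zeros((n_vox, 3))
    evals[:] = spec.background_adc
    nu_ic = np.zeros(n_vox)
    nu_iso = np.ones(n_vox)  # background treated as isotropic water
    kappa = np.full(n_vox, np.nan)

    accum = np.zeros((n_vox, n_grad))
    for bi, (b, (inside, tangents)) in enumerate(zip(spec.bundles, hits)):
        if not np.any(inside):
            continue
        axes = tangents[inside]
        if spec.signal_model == "tensor":
            sig = axisymmetric_tensor_signal(
                gtab.bvals, gtab.bvecs, axes, b.d_par, b.d_perp, spec.s0
            )
        else:
            sig = _noddi_signal_by_orientation(b, axes, gtab, spec.s0)
        accum[inside] += sig
        first = np.isnan(peak_dirs[inside, 0, 0])
        rows = np.where(inside)[0]
        peak_dirs[rows[first], 0] = axes[first]
        peak_dirs[rows[~first], 1] = axes[~first]
        label[inside] = bi
        evals[inside] = np.array([b.d_par, b.d_perp, b.d_perp])
        nu_ic[inside] = b.nu_ic
        nu_iso[inside] = b.nu_iso
        kappa[inside] = b.kappa
    in_any = count > 0
    signal[in_any] = accum[in_any] / count[in_any, None]

    rng = np.random.default_rng(spec.rng_seed)
    signal = add_noise(signal, spec.noise_sigma, rng, spec.noise_model)

    def grid(a, extra=()):
        return a.reshape(shape + tuple(extra) if extra else shape + a.shape[1:])

    truth = MicrostructureField(
        evals=evals.reshape(shape + (3,)),
        peak_dirs=peak_dirs.reshape(shape + (2, 3)),
        nu_ic=nu_ic.reshape(shape),
        nu_iso=nu_iso.reshape(shape),
        kappa=kappa.reshape(shape),
        crossing=(count == 2).reshape(shape),
        bundle_label=label.reshape(shape),
    )
    return PhantomResult(
        dwi=signal.reshape(shape + (n_grad,)),
        affine=spec.affine,
        gtab=gtab,
        truth=truth,
        brain_mask=np.ones(shape, dtype=bool),
        wm_mask=(count > 0).reshape(shape),
        bundles={b.name: b.centerline.copy() for b in spec.bundles},
        spec=spec,
    )


# --------------------------------------------------------------------------
# Group cohorts


@dataclass
class CohortSpec:
    """Two-group cohort of per-subject scalar measures.

    ``measures`` maps a measure name to (mean_men, sd_men, mean_women,
    sd_women).  With ``stratified=True`` the per-group standard-normal
    deviates are quantile-stratified (seed-permuted normal quantiles at
    (i+1/2)/n), pinning each group's sample mean and SD near the generating
    values; this turns the cohort into a fixed study condition rather than
    a resampling experiment, and is what the end-to-end demo uses.
    """

    n_men: int
    n_women: int
    measures: dict[str, tuple[float, float, float, float]]
    rng_seed: int = 0
    stratified: bool = False

    def __post_init__(self):
        if self.n_men < 2 or self.n_women < 2:
            raise ValueError("need at least two subjects per group")
        for name, (m_m, s_m, m_f, s_f) in self.measures.items():
            if s_m <= 0 or s_f <= 0:
                raise ValueError(f"measure {name!r}: standard deviations must be positive")


def _group_deviates(rng: np.random.Generator, n: int, stratified: bool) -> np.ndarray:
    if not stratified:
        return rng.standard_normal(n)
    from scipy.stats import norm

    z = norm.ppf((np.arange(n) + 0.5) / n)
    return rng.permutation(z)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: one row per subject, one column per measure."""
    rng = np.random.default_rng(spec.rng_seed)
    rows = {
        "subject_id": [f"M{i:04d}" for i in range(spec.n_men)]
        + [f"F{i:04d}" for i in range(spec.n_women)],
        "sex": ["M"] * spec.n_men + ["F"] * spec.n_women,
    }
    for name, (m_m, s_m, m_f, s_f) in spec.measures.items():
        zm = _group_deviates(rng, spec.n_men, spec.stratified)
        zf = _group_deviates(rng, spec.n_women, spec.stratified)
        rows[name] = np.concatenate([m_m + s_m * zm, m_f + s_f * zf])
    return pd.DataFrame(rows)
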