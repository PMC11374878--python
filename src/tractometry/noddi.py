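"""Voxelwise fitting of the three-compartment neurite model.

The forward model is the one the phantom generator uses
(:func:`tractometry.phantom.simulate_signal_noddi`): Watson-dispersed
sticks + tortuosity zeppelin + isotropic ball, with fixed diffusivities
d_par = 1.7e-3 and d_iso = 3.0e-3 mm^2/s.  Fitting is a dense grid search
over (nu_ic, nu_iso, kappa, mu) followed, by default, by bounded
nonlinear least squares per voxel.  The Watson stick average inside the
refinement loop is evaluated from a precomputed (cos angle, log kappa)
interpolation table per shell, built once by sphere quadrature.

Outputs: NDI (= nu_ic), IWVF (= nu_iso) and ODI = (2/pi) atan(1/kappa),
all in [0, 1].  Voxels where refinement does not improve on the grid
point fall back to the grid solution and are flagged in a QC mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import least_squares

from .dti import ScalarMap
from .gradients import GradientTable
from .phantom import D_ISO, D_PAR, _watson_nodes, watson_weights
from .shm import fibonacci_sphere

__all__ = ["NoddiFit", "fit_noddi", "odi_from_kappa", "default_noddi_grid", "coarse_noddi_grid"]

_KAPPA_TABLE = np.exp(np.linspace(np.log(0.05), np.log(128.0), 25))
_COS_TABLE = np.linspace(0.0, 1.0, 51)


def odi_from_kappa(kappa: np.ndarray | float) -> np.ndarray | float:
    """Orientation dispersion index, (2/pi) * arctan(1/kappa); in (0, 1)."""
    return (2.0 / np.pi) * np.arctan(1.0 / np.asarray(kappa, dtype=float))


def default_noddi_grid() -> dict:
    return {
        "nu_ic": np.linspace(0.0, 1.0, 11),
        "nu_iso": np.linspace(0.0, 1.0, 11),
        "kappa": np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0]),
        "n_mu": 30,
    }


def coarse_noddi_grid() -> dict:
    """Reduced grid for throughput-bound runs (e.g. the pipeline demo)."""
    return {
        "nu_ic": np.linspace(0.0, 1.0, 6),
        "nu_iso": np.linspace(0.0, 1.0, 6),
        "kappa": np.array([0.5, 2.0, 8.0, 32.0]),
        "n_mu": 12,
    }


@dataclass
class NoddiFit:
    ndi: ScalarMap
    iwvf: ScalarMap
    odi: ScalarMap
    kappa: np.ndarray
    mu: np.ndarray  # (..., 3) fitted orientation
    qc_fallback: np.ndarray  # True where refinement fell back to the grid
    mask: np.ndarray

    @property
    def maps(self) -> dict[str, ScalarMap]:
        return {"ndi": self.ndi, "iwvf": self.iwvf, "odi": self.odi}


def _mu_set(n: int) -> np.ndarray:
    """~n orientations covering one hemisphere (orientation is axial)."""
    pts = fibonacci_sphere(2 * n)
    return pts[pts[:, 2] >= 0][:n]


def _stick_tables(gtab: GradientTable):
    """Per-shell Watson-stick interpolators over (|cos psi|, log kappa)."""
    nodes = _watson_nodes()
    weights = np.column_stack([watson_weights(k, [0.0, 0.0, 1.0], nodes) for k in _KAPPA_TABLE])
    shells = sorted(set(gtab.shell_ids[~gtab.b0_mask]))
    interps = {}
    sin_t = np.sqrt(1.0 - _COS_TABLE**2)
    g_psi = np.column_stack([sin_t, np.zeros_like(sin_t), _COS_TABLE])
    for s in shells:
        b = gtab.bvals[gtab.shell_ids == s].mean()
        m = np.exp(-b * D_PAR * (g_psi @ nodes.T) ** 2)
        table = m @ weights  # (n_cos, n_kappa)
        interps[s] = RegularGridInterpolator(
            (_COS_TABLE, np.log(_KAPPA_TABLE)), table, bounds_error=False, fill_value=None
        )
    return interps


def _candidate_signals(gtab: GradientTable, grid: dict):
    """Normalized model signals for every grid point; float32 (ncand, G)."""
    b, g = gtab.bvals, gtab.bvecs
    nu_ic = grid["nu_ic"]
    nu_iso = grid["nu_iso"]
    kappas = grid["kappa"]
    mus = _mu_set(grid["n_mu"])
    nodes = _watson_nodes()
    m_stick = np.exp(-b[:, None] * D_PAR * (g @ nodes.T) ** 2)  # (G, nodes)
    ball = np.exp(-b * D_ISO)

    n_ic, n_iso, n_k, n_mu = len(nu_ic), len(nu_iso), len(kappas), len(mus)
    stick = np.empty((n_mu, n_k, len(b)), dtype=np.float32)
    for j, mu in enumerate(mus):
        w = np.column_stack([watson_weights(k, mu, nodes) for k in kappas])
        stick[j] = (m_stick @ w).T
    c2 = (g @ mus.T) ** 2  # (G, n_mu)
    d_perp = D_PAR * (1.0 - nu_ic)  # (n_ic,)
    zepp = np.exp(
        -b[None, None, :]
        * (d_perp[:, None, None] + (D_PAR - d_perp[:, None, None]) * c2.T[None, :, :])
    ).astype(np.float32)  # (n_ic, n_mu, G)

    intra_extra = (
        nu_ic[:, None, None, None] * stick.transpose(0, 1, 2)[None, :, :, :]
        + (1.0 - nu_ic)[:, None, None, None] * zepp[:, :, None, :]
    )  # (n_ic, n_mu, n_k, G)
    cand = (
        nu_iso[None, :, None, None, None] * ball[None, None, None, None, :].astype(np.float32)
        + (1.0 - nu_iso)[None, :, None, None, None] * intra_extra[:, None]
    )  # (n_ic, n_iso, n_mu, n_k, G)
    params = np.stack(
        np.meshgrid(nu_ic, nu_iso, np.arange(len(mus)), kappas, indexing="ij"), axis=-1
    ).reshape(-1, 4)
    return cand.reshape(-1, len(b)), params, mus


def _model_signal_table(params, gtab, interps):
    """Forward model using the stick tables; params = (ic, iso, kappa, theta, phi)."""
    nu_ic, nu_iso, kappa, theta, phi = params
    mu = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    b, g = gtab.bvals, gtab.bvecs
    out = np.ones(len(b))
    dw = ~gtab.b0_mask
    cospsi = np.abs(g @ mu)
    d_perp = D_PAR * (1.0 - nu_ic)
    logk = np.log(np.clip(kappa, _KAPPA_TABLE[0], _KAPPA_TABLE[-1]))
    for s, it in interps.items():
        sel = gtab.shell_ids == s
        stick = it(np.column_stack([cospsi[sel], np.full(int(sel.sum()), logk)]))
        zepp = np.exp(-b[sel] * (d_perp + (D_PAR - d_perp) * cospsi[sel] ** 2))
        ball = np.exp(-b[sel] * D_ISO)
        out[sel] = nu_iso * ball + (1.0 - nu_iso) * (
            nu_ic * stick + (1.0 - nu_ic) * zepp
        )
    out[~dw] = 1.0
    return out


def fit_noddi(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    grid: dict | None = None,
    refine: bool = True,
    chunk: int = 512,
) -> NoddiFit:
    """Fit the neurite model voxelwise inside ``mask``."""
    dwi = np.asarray(dwi, dtype=float)
    shape = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    shells = set(gtab.shell_ids[~gtab.b0_mask])
    if len(shells) < 2:
        raise ValueError("neurite-model fitting needs at least two nonzero shells")
    grid = grid or default_noddi_grid()

    cand, params, mus = _candidate_signals(gtab, grid)
    c2_norm = np.einsum("cg,cg->c", cand, cand)

    b0 = np.maximum(dwi[..., gtab.b0_mask][mask].mean(axis=-1), 1e-12)
    e = (dwi[mask] / b0[:, None]).astype(np.float32)
    n_vox = e.shape[0]
    best = np.empty(n_vox, dtype=int)
    for lo in range(0, n_vox, chunk):
        hi = min(lo + chunk, n_vox)
        dots = e[lo:hi] @ cand.T
        best[lo:hi] = np.argmin(c2_norm[None, :] - 2.0 * dots, axis=1)

    p = params[best]  # columns: nu_ic, nu_iso, mu_index, kappa
    fit_ic, fit_iso, fit_kappa = p[:, 0].copy(), p[:, 1].copy(), p[:, 3].copy()
    fit_mu = mus[p[:, 2].astype(int)].copy()
    fallback = np.zeros(n_vox, dtype=bool)

    if refine:
        interps = _stick_tables(gtab)
        e64 = e.astype(float)
        for v in range(n_vox):
            mu0 = fit_mu[v]
            theta0 = float(np.arccos(np.clip(mu0[2], -1, 1)))
            phi0 = float(np.arctan2(mu0[1], mu0[0]))
            x0 = np.array(
                [
                    np.clip(fit_ic[v], 0.01, 0.99),
                    np.clip(fit_iso[v], 0.01, 0.99),
                    np.clip(fit_kappa[v], 0.1, 100.0),
                    theta0,
                    phi0,
                ]
            )
            target = e64[v]

            def resid(x):
                return _model_signal_table(x, gtab, interps) - target

            cost0 = 0.5 * np.sum(resid(x0) ** 2)
            try:
                sol = least_squares(
                    resid,
                    x0,
                    bounds=([0, 0, 0.05, -np.inf, -np.inf], [1, 1, 128.0, np.inf, np.inf]),
                    xtol=1e-10,
                    ftol=1e-10,
                    max_nfev=200,
                )
                if sol.cost <= cost0 + 1e-12:
                    fit_ic[v], fit_iso[v], fit_kappa[v] = sol.x[0], sol.x[1], sol.x[2]
                    th, ph = sol.x[3], sol.x[4]
                    fit_mu[v] = [
                        np.sin(th) * np.cos(ph),
                        np.sin(th) * np.sin(ph),
                        np.cos(th),
                    ]
                else:
                    fallback[v] = True
            except Exception:
                fallback[v] = True

    def to_grid(vals, fill=0.0):
        out = np.full(shape, fill)
        out[mask] = vals
        return out

    ndi = ScalarMap("ndi", np.clip(to_grid(fit_ic), 0, 1))
    iwvf = ScalarMap("iwvf", np.clip(to_grid(fit_iso), 0, 1))
    odi = ScalarMap("odi", np.clip(to_grid(odi_from_kappa(fit_kappa)), 0, 1))
    mu_out = np.zeros(shape + (3,))
    mu_out[mask] = fit_mu
    return NoddiFit(
        ndi, iwvf, odi, to_grid(fit_kappa, np.nan), mu_out, to_grid(fallback).astype(bool), mask
    )
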