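"""Analytical q-ball ODF reconstruction in constant solid angle (CSA).

Per shell, the normalized signal E = S/S0 is clamped into (0, 1), the
double-log transform log(-log E) is expanded in even-order real spherical
harmonics with Laplace-Beltrami regularization, and the ODF follows from
the Funk-Radon transform applied to the spherical Laplacian:

    ODF = 1/(4*pi) + (1/(16*pi^2)) * FRT{ Lap_b log(-log E) }

which in SH space multiplies each degree-l coefficient (l >= 2) by
-l(l+1) * 2*pi*P_l(0) / (16*pi^2); the l = 0 coefficient is fixed at
1/(2*sqrt(pi)).  Multi-shell acquisitions are combined by averaging the
per-shell ODF coefficients with equal weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import lpmv

from .dti import ScalarMap
from .gradients import GradientTable
from .shm import fibonacci_sphere, n_coeffs, real_sh_basis, sh_degrees

__all__ = ["ODFField", "fit_csa_odf", "gfa", "odf_peaks", "default_odf_sphere"]

_DEFAULT_SPHERE_N = 724


def default_odf_sphere(n: int = _DEFAULT_SPHERE_N) -> np.ndarray:
    return fibonacci_sphere(n)


@dataclass
class ODFField:
    """Per-voxel even-order real SH coefficients of the ODF."""

    sh_coeffs: np.ndarray  # (..., n_coeffs)
    sh_order: int
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        expect = n_coeffs(self.sh_order)
        if self.sh_coeffs.shape[-1] != expect:
            raise ValueError(
                f"sh_order {self.sh_order} implies {expect} coefficients, "
                f"got {self.sh_coeffs.shape[-1]}"
            )
        if self.mask is None:
            self.mask = np.ones(self.sh_coeffs.shape[:-1], dtype=bool)

    def sample(self, dirs: np.ndarray, normalize: bool = True) -> np.ndarray:
        """Sample the ODF on unit ``dirs``; clamp negatives, optionally
        normalize so each voxel's samples sum to 1."""
        basis = real_sh_basis(self.sh_order, dirs)
        vals = np.maximum(self.sh_coeffs @ basis.T, 0.0)
        if normalize:
            tot = vals.sum(axis=-1, keepdims=True)
            vals = np.where(tot > 0, vals / np.where(tot > 0, tot, 1.0), 0.0)
        return vals


def _csa_transform_weights(sh_order: int) -> np.ndarray:
    """Per-coefficient multiplier taking double-log SH to ODF SH (l >= 2)."""
    l = sh_degrees(sh_order)
    p_l_0 = lpmv(0, l, 0.0)
    w = (-l * (l + 1)) * 2.0 * np.pi * p_l_0 / (16.0 * np.pi**2)
    w[l == 0] = 0.0
    return w


def fit_csa_odf(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    sh_order: int = 8,
    smooth: float = 0.006,
    delta: float = 1e-3,
) -> ODFField:
    """Fit the CSA ODF per voxel from all shells.

    ``smooth`` is the Laplace-Beltrami regularization weight; ``delta`` the
    clamp bound keeping E inside [delta, 1-delta] so the double log is
    finite.  Requires at least n_coeffs(sh_order) directions per shell.
    """
    if sh_order % 2 != 0 or not 2 <= sh_order <= 12:
        raise ValueError(f"sh_order must be even and in [2, 12], got {sh_order}")
    dwi = np.asarray(dwi, dtype=float)
    shape = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    ncoef = n_coeffs(sh_order)
    l = sh_degrees(sh_order)
    csa_w = _csa_transform_weights(sh_order)

    b0 = dwi[..., gtab.b0_mask][mask].mean(axis=-1)  # (V,)
    b0 = np.maximum(b0, 1e-12)

    shells = sorted(set(gtab.shell_ids[~gtab.b0_mask]))
    coef_sum = np.zeros((int(mask.sum()), ncoef))
    for s in shells:
        sel = gtab.shell_ids == s
        if int(sel.sum()) < ncoef:
            raise ValueError(
                f"shell {s} has {int(sel.sum())} directions; sh_order {sh_order} "
                f"needs >= {ncoef}"
            )
        basis = real_sh_basis(sh_order, gtab.bvecs[sel])
        reg = np.diag((l * (l + 1.0)) ** 2)
        fit_mat = np.linalg.solve(basis.T @ basis + smooth * reg, basis.T)
        e = dwi[..., sel][mask] / b0[:, None]
        e = np.clip(e, delta, 1.0 - delta)
        loglog = np.log(-np.log(e))
        c = loglog @ fit_mat.T
        coef_sum += c * csa_w
    coefs = coef_sum / len(shells)
    coefs[:, 0] = 1.0 / (2.0 * np.sqrt(np.pi))

    out = np.zeros(shape + (ncoef,))
    out[mask] = coefs
    return ODFField(out, sh_order, mask)


def gfa(odf: ODFField, dirs: np.ndarray | None = None) -> ScalarMap:
    """Generalized fractional anisotropy: std/rms of the sampled ODF.

    Uses the population standard deviation, so a one-hot ODF on N
    directions gives sqrt((N-1)/N), a uniform ODF gives 0.  An all-zero
    ODF is defined to have GFA 0.
    """
    if dirs is None:
        dirs = default_odf_sphere()
    if dirs.shape[0] < 60:
        raise ValueError("GFA needs >= 60 sampling directions")
    vals = odf.sample(dirs, normalize=False)
    rms = np.sqrt(np.mean(vals**2, axis=-1))
    std = np.std(vals, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = std / rms
    g = np.where(rms > 0, g, 0.0)
    return ScalarMap("gfa", np.clip(g, 0.0, 1.0) * odf.mask)


def odf_peaks(
    values: np.ndarray,
    dirs: np.ndarray,
    n_peaks: int = 2,
    min_separation_deg: float = 25.0,
    relative_threshold: float = 0.25,
) -> np.ndarray:
    """Greedy peak extraction from ODF samples of a single voxel.

    Returns up to ``n_peaks`` unit directions, strongest first; antipodal
    duplicates are suppressed, as are peaks closer than the separation
    angle to an accepted one or weaker than ``relative_threshold`` times
    the (mean-subtracted) global maximum.
    """
    vals = np.asarray(values, dtype=float).copy()
    base = vals - vals.mean()
    peak_floor = relative_threshold * base.max()
    cos_sep = np.cos(np.deg2rad(min_separation_deg))
    peaks = []
    for _ in range(n_peaks):
        i = int(np.argmax(base))
        if base[i] <= 0 or (peaks and base[i] < peak_floor):
            break
        d = dirs[i]
        peaks.append(d)
        near = np.abs(dirs @ d) >= cos_sep
        base[near] = -np.inf
    return np.array(peaks).reshape(-1, 3)
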