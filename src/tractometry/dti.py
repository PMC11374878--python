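"""Diffusion tensor fitting and its scalar maps (FA, MD, AD, RD).

The tensor is fit by weighted linear least squares on the log signal
(one IRLS pass with predicted-signal weights), restricted to the b=0 and
b=1000 s/mm^2 entries: the quantitative DTI metrics are defined on the
b=1000 shell only, so a multi-shell input gives the same fit whether or
not the higher shells are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradients import GradientTable

__all__ = ["TensorFit", "ScalarMap", "fit_dti", "tensor_scalars"]

DTI_SHELL = 1000.0  # s/mm^2
_MIN_SIGNAL = 1e-10


@dataclass
class ScalarMap:
    """A named 3D quantitative map (diffusivities in mm^2/s, rest unitless)."""

    name: str
    data: np.ndarray
    units: str = ""


@dataclass
class TensorFit:
    """Voxelwise tensor eigendecomposition (eigenvalues descending)."""

    evals: np.ndarray  # (..., 3), lambda1 >= lambda2 >= lambda3, clamped >= 0
    evecs: np.ndarray  # (..., 3, 3), columns are eigenvectors
    s0: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0  # voxels whose negative eigenvalues were clamped to 0


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    return np.column_stack(
        [
            -bvals * g[:, 0] ** 2,
            -bvals * g[:, 1] ** 2,
            -bvals * g[:, 2] ** 2,
            -2 * bvals * g[:, 0] * g[:, 1],
            -2 * bvals * g[:, 0] * g[:, 2],
            -2 * bvals * g[:, 1] * g[:, 2],
            np.ones_like(bvals),
        ]
    )


def fit_dti(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    shell_bvalue: float = DTI_SHELL,
) -> TensorFit:
    """Fit the diffusion tensor on the b=0 + ``shell_bvalue`` subset.

    Non-positive signals are clamped to a small floor before the log.
    Voxels outside ``mask`` keep zero tensors.
    """
    dwi = np.asarray(dwi, dtype=float)
    shape = dwi.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    keep = gtab.b0_mask | gtab.shell_mask(shell_bvalue)
    if not np.any(gtab.shell_mask(shell_bvalue)):
        raise ValueError(f"gradient table has no b={shell_bvalue:g} shell")
    sub = gtab.subset(keep)
    n_dw = int((~sub.b0_mask).sum())
    if n_dw < 6:
        raise ValueError(f"need >= 6 diffusion-weighted directions, got {n_dw}")

    x = _design_matrix(sub.bvals, sub.bvecs)
    y = np.log(np.maximum(dwi[..., keep][mask], _MIN_SIGNAL))  # (V, G)

    # OLS pass
    beta = np.linalg.lstsq(x, y.T, rcond=None)[0].T  # (V, 7)
    # one weighted pass, weights = predicted squared signals
    pred = beta @ x.T
    w = np.exp(2.0 * np.clip(pred, -50.0, 50.0))
    xtwx = np.einsum("vg,gi,gj->vij", w, x, x)
    xtwy = np.einsum("vg,gi,vg->vi", w, x, y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]

    d6 = beta[:, :6]
    tensors = np.empty((d6.shape[0], 3, 3))
    tensors[:, 0, 0] = d6[:, 0]
    tensors[:, 1, 1] = d6[:, 1]
    tensors[:, 2, 2] = d6[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = d6[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = d6[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = d6[:, 5]
    evals, evecs = np.linalg.eigh(tensors)
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    n_clamped = int(np.any(evals < 0, axis=1).sum())
    evals = np.maximum(evals, 0.0)

    out_evals = np.zeros(shape + (3,))
    out_evecs = np.zeros(shape + (3, 3))
    out_s0 = np.zeros(shape)
    out_evals[mask] = evals
    out_evecs[mask] = evecs
    out_s0[mask] = np.exp(beta[:, 6])
    return TensorFit(out_evals, out_evecs, out_s0, mask, n_clamped)


def tensor_scalars(fit: TensorFit) -> dict[str, ScalarMap]:
    """FA, MD, AD, RD from the eigenvalues.

    MD = (l1+l2+l3)/3, AD = l1, RD = (l2+l3)/2,
    FA = sqrt(3/2 * sum((li-MD)^2) / sum(li^2)); FA of an all-zero tensor
    is defined as 0.
    """
    l1, l2, l3 = (fit.evals[..., k] for k in range(3))
    md = (l1 + l2 + l3) / 3.0
    ad = l1
    rd = (l2 + l3) / 2.0
    sumsq = l1**2 + l2**2 + l3**2
    num = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / sumsq)
    fa = np.where(sumsq > 0, fa, 0.0)
    return {
        "fa": ScalarMap("fa", fa),
        "md": ScalarMap("md", md, "mm^2/s"),
        "ad": ScalarMap("ad", ad, "mm^2/s"),
        "rd": ScalarMap("rd", rd, "mm^2/s"),
    }
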