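"""Real spherical harmonics and sphere sampling utilities.

The ODF machinery uses the real, antipodally symmetric (even-order) SH basis
common in diffusion MRI: for each even degree l and order m,

    Y_lm^real = sqrt(2) * Im(Y_l^|m|)   (m < 0)
              = Y_l^0                   (m = 0)
              = sqrt(2) * Re(Y_l^m)     (m > 0)

Sphere point sets are spherical Fibonacci lattices, which are deterministic
and close to uniform for any point count.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "fibonacci_sphere",
    "cart_to_sphere",
    "real_sh_basis",
    "sh_degrees",
    "n_coeffs",
    "random_rotation",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` approximately uniform unit vectors on the full sphere."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def cart_to_sphere(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian unit vectors -> (polar theta, azimuth phi)."""
    dirs = np.asarray(dirs, dtype=float)
    theta = np.arccos(np.clip(dirs[..., 2], -1.0, 1.0))
    phi = np.arctan2(dirs[..., 1], dirs[..., 0])
    return theta, phi


def n_coeffs(sh_order: int) -> int:
    """Number of even-order real SH coefficients up to ``sh_order``."""
    return (sh_order + 1) * (sh_order + 2) // 2


def sh_degrees(sh_order: int) -> np.ndarray:
    """Degree l of each coefficient in basis order (l ascending, m -l..l)."""
    return np.concatenate(
        [np.full(2 * l + 1, l, dtype=int) for l in range(0, sh_order + 1, 2)]
    )


def real_sh_basis(sh_order: int, dirs: np.ndarray) -> np.ndarray:
    """Evaluate the even-order real SH basis at unit ``dirs`` (N, 3).

    Returns an (N, n_coeffs) design matrix; column order is l ascending,
    m from -l to l within each degree.
    """
    if sh_order % 2 != 0 or sh_order < 0:
        raise ValueError(f"sh_order must be a non-negative even integer, got {sh_order}")
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    theta, phi = cart_to_sphere(dirs)
    cols = []
    for l in range(0, sh_order + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * y.real)
    return np.column_stack(cols)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
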