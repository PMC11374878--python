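"""Multi-shell q-space sampling schemes (FSL-style gradient tables).

A :class:`GradientTable` holds one b-value and one unit direction per DWI
volume, plus an integer shell id (shell 0 is the b=0 set).  The default
scheme mirrors a high-angular-resolution multi-shell protocol: shells at
b = 1000/2000/3000 s/mm^2, 90 directions per shell, 6 b=0 volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shm import fibonacci_sphere, random_rotation

__all__ = ["GradientTable", "make_gradient_table", "detect_shells"]

B0_THRESHOLD = 50.0  # s/mm^2; anything below counts as a b=0 volume


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-values (s/mm^2), unit directions and shell membership.

    b=0 entries carry the zero vector as direction.  Non-b0 directions are
    unit-norm to 1e-6.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) length mismatch"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        shell_ids = self.shell_ids
        if shell_ids is None:
            shell_ids = detect_shells(bvals)
        shell_ids = np.asarray(shell_ids, dtype=int).ravel()
        dw = bvals > B0_THRESHOLD
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-b0 directions must be unit vectors (1e-6)")
        if not np.any(~dw):
            raise ValueError("gradient table needs at least one b=0 entry")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "shell_ids", shell_ids)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def shell_bvalues(self) -> np.ndarray:
        """Mean b-value per shell id (index = shell id; shell 0 is b=0)."""
        n = int(self.shell_ids.max()) + 1
        return np.array(
            [self.bvals[self.shell_ids == s].mean() if np.any(self.shell_ids == s) else np.nan
             for s in range(n)]
        )

    def shell_mask(self, bvalue: float, tol: float = B0_THRESHOLD) -> np.ndarray:
        return np.abs(self.bvals - bvalue) <= tol

    def subset(self, mask: np.ndarray) -> "GradientTable":
        return GradientTable(self.bvals[mask], self.bvecs[mask], self.shell_ids[mask])


def detect_shells(bvals: np.ndarray, tol: float = B0_THRESHOLD) -> np.ndarray:
    """Cluster b-values into shells by 1-D tolerance grouping.

    Real-world bval files jitter by a few s/mm^2; values within ``tol`` of a
    running cluster mean share a shell.  Shell 0 is the b<=tol group; the
    remaining ids are assigned in ascending b order.
    """
    bvals = np.asarray(bvals, dtype=float).ravel()
    order = np.argsort(bvals)
    ids = np.zeros(bvals.shape[0], dtype=int)
    current = 0
    cluster_start = bvals[order[0]]
    for prev, idx in zip(order[:-1], order[1:]):
        if bvals[idx] - cluster_start > tol:
            current += 1
            cluster_start = bvals[idx]
        ids[idx] = current
    ids[order[0]] = 0
    return ids


def make_gradient_table(
    dirs_per_shell: int,
    shell_bvalues,
    n_b0: int,
    seed: int = 0,
) -> GradientTable:
    """Build a multi-shell scheme with near-uniform per-shell directions.

    Directions are a spherical Fibonacci lattice, given an independent
    seeded random rotation per shell so shells do not share exact
    directions.  Deterministic for a fixed seed.
    """
    shell_bvalues = [float(b) for b in np.atleast_1d(shell_bvalues)]
    if dirs_per_shell < 6:
        raise ValueError("dirs_per_shell must be >= 6")
    if any(b <= 0 for b in shell_bvalues):
        raise ValueError("shell b-values must be positive")
    if len(set(shell_bvalues)) != len(shell_bvalues):
        raise ValueError("shell b-values must be distinct")
    rng = np.random.default_rng(seed)
    base = fibonacci_sphere(dirs_per_shell)
    bvals = [np.zeros(n_b0)]
    bvecs = [np.zeros((n_b0, 3))]
    shell_ids = [np.zeros(n_b0, dtype=int)]
    for k, b in enumerate(sorted(shell_bvalues)):
        rot = random_rotation(rng)
        bvals.append(np.full(dirs_per_shell, b))
        bvecs.append(base @ rot.T)
        shell_ids.append(np.full(dirs_per_shell, k + 1, dtype=int))
    return GradientTable(
        np.concatenate(bvals), np.vstack(bvecs), np.concatenate(shell_ids)
    )
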