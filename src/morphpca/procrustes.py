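"""Generalized Procrustes superimposition of landmark configurations.

Each configuration is translated to a common origin, scaled to unit centroid
size, and rotated (rotations only, no reflections — faces have handedness) to
a consensus shape that is updated iteratively until the total Procrustes
distance stabilises. Scaling is part of the superimposition so that only
shape, not size, remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration, ShapeDataset


class DegenerateConfigurationError(ValueError):
    """A configuration collapses to a single point (zero centroid size)."""


@dataclass
class GPAResult:
    """Outcome of generalized Procrustes alignment."""

    aligned: ShapeDataset
    consensus: LandmarkConfiguration
    iterations: int
    converged: bool
    residual_change: float


def _center_scale(coords: np.ndarray) -> np.ndarray:
    """Center an (n, K, 3) stack and scale each config to unit centroid size."""
    centered = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.linalg.norm(centered, axis=(1, 2))
    if np.any(sizes <= 0):
        raise DegenerateConfigurationError(
            f"zero centroid size at subject index {int(np.argmin(sizes))}"
        )
    return centered / sizes[:, None, None]


def _rotations_to(stack: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Batched optimal rotations (no reflection) of each config onto target."""
    H = np.einsum("nki,kj->nij", stack, target)
    U, _, Vt = np.linalg.svd(H)
    # flip the smallest singular direction where det would be negative
    det = np.linalg.det(np.einsum("nij,njk->nik", U, Vt))
    signs = np.ones_like(H[:, :, 0])
    signs[:, -1] = np.sign(det)
    return np.einsum("nij,nj,njk->nik", U, signs, Vt)


def gpa_align(
    dataset: ShapeDataset, tol: float = 1e-8, max_iter: int = 100
) -> GPAResult:
    """Superimpose all configurations by generalized Procrustes analysis.

    Parameters
    ----------
    dataset : landmark dataset (n >= 2).
    tol : convergence tolerance on the change in total squared Procrustes
        distance to the consensus.
    max_iter : iteration cap; non-convergence is flagged, not fatal.
    """
    if dataset.n_subjects < 2:
        raise ValueError("GPA requires at least two configurations")
    stack = _center_scale(dataset.as_array())
    consensus = stack[0].copy()
    prev_total = np.inf
    change = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        R = _rotations_to(stack, consensus)
        stack = np.einsum("nki,nij->nkj", stack, R)
        consensus = stack.mean(axis=0)
        consensus -= consensus.mean(axis=0)
        size = np.linalg.norm(consensus)
        if size <= 0:
            raise DegenerateConfigurationError("consensus collapsed to a point")
        consensus /= size
        total = float(np.sum((stack - consensus) ** 2))
        change = abs(prev_total - total)
        prev_total = total
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last change {change:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    aligned = dataset.with_coordinates(
        stack.reshape(dataset.n_subjects, -1)
    )
    return GPAResult(
        aligned=aligned,
        consensus=LandmarkConfiguration(dataset.landmark_names, consensus),
        iterations=iterations,
        converged=converged,
        residual_change=float(change),
    )


def procrustes_distance(
    a: LandmarkConfiguration, b: LandmarkConfiguration
) -> float:
    """Full Procrustes distance between two configurations.

    Root summed squared coordinate differences after optimal translation,
    rotation (no reflection) and scaling of ``a`` onto ``b``. With both
    shapes at unit centroid size the optimum is ``sqrt(1 - s^2)`` where ``s``
    is the (reflection-corrected) sum of singular values of the cross-product
    matrix.
    """
    if a.n_landmarks != b.n_landmarks:
        raise ValueError(
            f"landmark count mismatch: {a.n_landmarks} vs {b.n_landmarks}"
        )
    xa = _center_scale(a.coordinates[None])[0]
    xb = _center_scale(b.coordinates[None])[0]
    U, sv, Vt = np.linalg.svd(xa.T @ xb)
    sign = np.sign(np.linalg.det(U @ Vt))
    signs = np.array([1.0, 1.0, sign])
    R = U @ np.diag(signs) @ Vt
    beta = float(sv @ signs)  # optimal scale of a onto b
    # direct residual, accurate when the shapes nearly coincide
    return float(np.linalg.norm(beta * (xa @ R) - xb))
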