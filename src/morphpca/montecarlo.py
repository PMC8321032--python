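"""Monte Carlo standard errors for multilevel eigenvalues.

A single multivariate normal (mu, sigma) is fitted to the pooled aligned
data. Each replicate redraws all n subjects from that normal, keeps the
original factor labels row-for-row (so every group retains its size), and
rebuilds the full multilevel model. The standard deviation of each retained
eigenvalue across replicates is a broad standard-error estimate. Pooling
(mu, sigma) over groups deliberately ignores group mean differences, so
some structure of the original data is lost; the estimates are calibration
checks, not exact sampling distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .model import MultilevelPCA, MultilevelPCAResults


@dataclass
class MCConfig:
    """Monte Carlo settings: replicate count, seed, replicate sample size."""

    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("need at least two replicates")


@dataclass
class MCErrorEstimate:
    """Per-level, per-PC eigenvalue standard errors across replicates."""

    table: pd.DataFrame  # level, pc, eigenvalue, se
    replicate_eigenvalues: np.ndarray  # (n_reps, total retained)
    n_reps: int
    seed: int


def fit_gaussian(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled multivariate normal fit: mean and sample covariance (n-1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two rows to fit a Gaussian")
    mu = X.mean(axis=0)
    dev = X - mu
    sigma = dev.T @ dev / (X.shape[0] - 1)
    return mu, sigma


def _covariance_factor(sigma: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = sigma, tolerant of singular sigma."""
    sigma = np.asarray(sigma, dtype=float)
    sym_err = np.max(np.abs(sigma - sigma.T)) if sigma.size else 0.0
    scale = max(np.max(np.abs(sigma)), 1.0)
    if sym_err > 1e-8 * scale:
        raise ValueError("sigma is not symmetric")
    w, V = scipy.linalg.eigh(0.5 * (sigma + sigma.T))
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("sigma is not positive semidefinite")
    return V * np.sqrt(np.clip(w, 0.0, None))


def mc_eigenvalue_errors(
    model: MultilevelPCA,
    retain,
    config: MCConfig,
    fitted: MultilevelPCAResults | None = None,
    allow_constant_factors: bool = False,
) -> MCErrorEstimate:
    """Eigenvalue standard errors by parametric Gaussian replication.

    Replicate r draws from its own generator spawned deterministically from
    ``config.seed`` (numpy ``SeedSequence.spawn``), so increasing ``n_reps``
    extends the existing replicate set instead of reshuffling it.
    """
    mu, sigma = fit_gaussian(model.X)
    L = _covariance_factor(sigma)
    n, p = model.X.shape
    if fitted is None:
        fitted = model.fit(retain=retain,
                           allow_constant_factors=allow_constant_factors)
    level_names = fitted.level_names
    retained = [c.retained for c in fitted.components]
    total = sum(retained)
    reps = np.empty((config.n_reps, total))
    children = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    labels = model.labels
    for r, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        Z = rng.standard_normal((n, p))
        Xr = mu + Z @ L.T
        rep_model = MultilevelPCA(
            Xr, labels, levels=model.levels,
            landmark_names=model.landmark_names,
        )
        rep_res = rep_model.fit(
            retain=retain, allow_constant_factors=allow_constant_factors
        )
        assert rep_model.labels.equals(labels)
        reps[r] = np.concatenate(
            [c.retained_eigenvalues for c in rep_res.components]
        )
    se = reps.std(axis=0, ddof=1)
    rows = []
    offset = 0
    for name, m, comp in zip(level_names, retained, fitted.components):
        for j in range(m):
            rows.append(
                {
                    "level": name,
                    "pc": j + 1,
                    "eigenvalue": comp.eigenvalues[j],
                    "se": se[offset + j],
                }
            )
        offset += m
    return MCErrorEstimate(
        table=pd.DataFrame(rows),
        replicate_eigenvalues=reps,
        n_reps=config.n_reps,
        seed=config.seed,
    )
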