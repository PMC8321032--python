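"""Four-level non-nested multilevel PCA of landmark shape.

The model decomposes aligned landmark variation into additive levels:

    shape = grand mean
          + weighted smoking modes
          + weighted alcohol modes
          + weighted sex modes
          + weighted subject modes

Each level owns its covariance matrix. A *between* level (smoking, alcohol,
sex) uses the unweighted covariance of that factor's marginal group means,
so its rank — and the number of retainable eigenvalues — is at most the
number of groups minus one. The *subject* (within) level captures whatever
group membership cannot explain: the element-wise median, across the full
smoking x alcohol x sex cells, of the within-cell covariance matrices. The
median makes the estimate robust to a single outlying cell.

Modes are orthonormal within a level but need not be orthogonal between
levels, so a new shape is fitted to all four levels simultaneously by exact
linear least squares on the concatenated retained modes (the global optimum
of the point-to-point cost, which is quadratic in the scores).

``MultilevelPCA`` is the model specification; ``fit()`` performs the
covariance construction and eigendecompositions and returns a
``MultilevelPCAResults`` carrying the eigenstructure, variance partition,
score fitting, and reporting tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .landmarks import ShapeDataset, unflatten

LEVEL_NAMES = ("smoking", "alcohol", "sex", "subject")

#: Eigenvalues retained per level by default (smoking, alcohol, sex, subject),
#: capped at each level's available rank.
DEFAULT_RETAIN = (2, 2, 1, 35)

_EIG_CLAMP_REL = 1e-12


@dataclass(frozen=True)
class LevelSpec:
    """Definition of one model level.

    kind ``between``: covariance of the marginal group means of ``columns[0]``.
    kind ``within``: median-averaged within-cell covariance over the cross of
    ``columns``.
    """

    name: str
    kind: str  # "between" | "within"
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("between", "within"):
            raise ValueError(f"unknown level kind {self.kind!r}")
        if self.kind == "between" and len(self.columns) != 1:
            raise ValueError("a between level uses exactly one factor column")


DEFAULT_LEVELS: tuple[LevelSpec, ...] = (
    LevelSpec("smoking", "between", ("smoking",)),
    LevelSpec("alcohol", "between", ("alcohol",)),
    LevelSpec("sex", "between", ("sex",)),
    LevelSpec("subject", "within", ("smoking", "alcohol", "sex")),
)


@dataclass
class LevelComponent:
    """Eigenstructure of one level's covariance matrix."""

    level_name: str
    eigenvectors: np.ndarray  # (p, m), orthonormal columns
    eigenvalues: np.ndarray  # (m,), descending, >= 0
    n_groups: int
    retained: int
    clamped_mass: float = 0.0  # negative eigenvalue mass removed by clamping

    @property
    def retained_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[: self.retained]

    @property
    def retained_eigenvectors(self) -> np.ndarray:
        return self.eigenvectors[:, : self.retained]

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.eigenvalues > 0))


@dataclass
class ScoreFit:
    """Per-level component scores fitted to one observation."""

    scores: dict[str, np.ndarray]
    standardized_scores: dict[str, np.ndarray]
    fitted: np.ndarray
    residual_norm: float


# ---------------------------------------------------------------------------
# covariance construction


def grand_mean(X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the flattened rows over all subjects."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a non-empty (n, p) matrix")
    return X.mean(axis=0)


def factor_level_covariance(
    X: np.ndarray,
    groups: Sequence,
    allow_single_group: bool = False,
) -> np.ndarray:
    """Unweighted between-group covariance of marginal group means.

    The G marginal group means are centred by their unweighted average and
    the divisor is G, so group-size imbalance does not re-weight the level.
    Rank is at most G - 1.
    """
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    G = codes.max() + 1
    if G < 2:
        if allow_single_group:
            return np.zeros((X.shape[1], X.shape[1]))
        raise ValueError(
            "between-group covariance needs at least two non-empty groups"
        )
    means = np.stack([X[codes == g].mean(axis=0) for g in range(G)])
    dev = means - means.mean(axis=0)
    return dev.T @ dev / G


def subject_level_covariance(
    X: np.ndarray, cells: Sequence
) -> tuple[np.ndarray, list]:
    """Element-wise median of within-cell covariance matrices.

    Each non-empty cell c with n_c >= 2 contributes
    ``C_c = (1/n_c) sum_i (z_i - m_c)(z_i - m_c)^T``; cells with fewer than
    two subjects are skipped and returned for reporting. The element-wise
    median is robust to one inflated cell but may lose positive
    semidefiniteness; downstream eigendecomposition clamps negative
    eigenvalues.
    """
    X = np.asarray(X, dtype=float)
    codes, uniques = pd.factorize(pd.Series(list(cells)))
    covs = []
    skipped = []
    for g in range(codes.max() + 1):
        idx = codes == g
        n_c = int(idx.sum())
        if n_c < 2:
            skipped.append(uniques[g])
            continue
        dev = X[idx] - X[idx].mean(axis=0)
        covs.append(dev.T @ dev / n_c)
    if not covs:
        raise ValueError("no cell with at least two subjects")
    median = np.median(np.stack(covs), axis=0)
    return 0.5 * (median + median.T), skipped


def eigendecompose_level(
    cov: np.ndarray,
    name: str,
    n_groups: int,
    retain: int,
    rank_bound: int | None = None,
) -> LevelComponent:
    """Descending eigendecomposition of a level covariance.

    Eigenvalues below ``1e-12 * trace`` (and any negatives, which can arise
    from median averaging) are clamped to zero; the removed negative mass is
    recorded. The sign of each eigenvector is fixed so its largest-magnitude
    coordinate is positive. ``rank_bound`` enforces the groups-minus-one rule
    for between levels.
    """
    cov = np.asarray(cov, dtype=float)
    p = cov.shape[0]
    if cov.shape != (p, p):
        raise ValueError("covariance must be square")
    asym = np.max(np.abs(cov - cov.T)) if p else 0.0
    scale = max(np.max(np.abs(cov)), 1.0)
    if asym > 1e-8 * scale:
        raise ValueError(f"covariance asymmetric beyond tolerance ({asym:.3g})")
    if rank_bound is not None and retain > min(p, rank_bound):
        raise ValueError(
            f"cannot retain {retain} eigenvalues at level {name!r}: the rank "
            f"is bounded by the number of groups minus 1 "
            f"(= {rank_bound}, p = {p})"
        )
    if retain > p:
        raise ValueError(f"retain={retain} exceeds dimension p={p}")
    w, V = scipy.linalg.eigh(0.5 * (cov + cov.T))
    order = np.argsort(w, kind="stable")[::-1]
    w, V = w[order], V[:, order]
    clamped = float(-w[w < 0].sum())
    threshold = _EIG_CLAMP_REL * max(np.trace(cov), 0.0)
    w = np.where(w < max(threshold, 0.0), 0.0, w)
    # sign convention: largest-magnitude coordinate positive
    flip = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])] < 0
    V = V * np.where(flip, -1.0, 1.0)
    return LevelComponent(
        level_name=name,
        eigenvectors=V,
        eigenvalues=w,
        n_groups=n_groups,
        retained=int(retain),
        clamped_mass=clamped,
    )


# ---------------------------------------------------------------------------
# conventional PCA baseline


def conventional_pca(
    X: np.ndarray, n_components: int | None = None
) -> tuple[LevelComponent, np.ndarray, np.ndarray]:
    """Ordinary PCA of the flattened rows about the grand mean.

    Uses the population covariance (divisor n), matching the divisor
    conventions of the multilevel levels so that the degenerate
    singleton-group multilevel model reproduces it exactly. Returns the
    eigenstructure block, raw scores (projections), and standardized scores
    (divided by sqrt(eigenvalue); zero where the eigenvalue is zero).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("conventional PCA needs n >= 2")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={max_comp}"
        )
    mu = grand_mean(X)
    dev = X - mu
    cov = dev.T @ dev / n
    comp = eigendecompose_level(cov, "conventional", n, n_components)
    scores = dev @ comp.eigenvectors
    lam = comp.eigenvalues
    with np.errstate(divide="ignore", invalid="ignore"):
        std = np.where(lam > 0, scores / np.sqrt(np.where(lam > 0, lam, 1.0)), 0.0)
    return comp, scores, std


# ---------------------------------------------------------------------------
# score fitting


def standardize_scores(
    scores: np.ndarray, eigenvalues: np.ndarray
) -> np.ndarray:
    """Element-wise score / sqrt(eigenvalue); zero eigenvalue maps to zero."""
    scores = np.asarray(scores, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)
    if scores.shape[-1] != lam.shape[0]:
        raise ValueError("scores and eigenvalues length mismatch")
    if np.any(lam < 0):
        raise ValueError("negative eigenvalue: clamp upstream")
    safe = np.where(lam > 0, lam, 1.0)
    return np.where(lam > 0, scores / np.sqrt(safe), 0.0)


# ---------------------------------------------------------------------------
# the model / results pair


class MultilevelPCA:
    """Multilevel PCA model specification for grouped landmark data.

    Parameters
    ----------
    endog : (n, p) flattened landmark matrix or a :class:`ShapeDataset`.
        Rows are expected to be Procrustes-superimposed already.
    labels : DataFrame of per-subject factor columns; taken from the dataset
        when ``endog`` is a :class:`ShapeDataset`.
    levels : level definitions; defaults to the four-level design
        smoking / alcohol / sex / subject.
    landmark_names : optional landmark labels for per-landmark reporting.

    Examples
    --------
    >>> model = MultilevelPCA(aligned)            # doctest: +SKIP
    >>> res = model.fit(retain=(2, 2, 1, 35))     # doctest: +SKIP
    >>> res.variance_partition()                  # doctest: +SKIP
    """

    def __init__(
        self,
        endog,
        labels: pd.DataFrame | None = None,
        levels: Sequence[LevelSpec] = DEFAULT_LEVELS,
        landmark_names: tuple[str, ...] | None = None,
    ) -> None:
        if isinstance(endog, ShapeDataset):
            self.X = endog.flattened
            self.labels = endog.labels if labels is None else labels.reset_index(drop=True)
            self.landmark_names = (
                endog.landmark_names if landmark_names is None else tuple(landmark_names)
            )
        else:
            self.X = np.asarray(endog, dtype=float)
            if labels is None:
                raise ValueError("labels are required with an array input")
            self.labels = labels.reset_index(drop=True)
            self.landmark_names = (
                tuple(landmark_names) if landmark_names is not None else None
            )
        if self.X.ndim != 2:
            raise ValueError("endog must be 2-D (n, p)")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length does not match endog rows")
        self.levels = tuple(levels)
        for spec in self.levels:
            for col in spec.columns:
                if col not in self.labels.columns:
                    raise ValueError(f"label column {col!r} missing")

    @classmethod
    def from_dataset(cls, dataset: ShapeDataset, **kwargs) -> "MultilevelPCA":
        return cls(dataset, **kwargs)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def _level_groups(self, spec: LevelSpec):
        if len(spec.columns) == 1:
            return self.labels[spec.columns[0]].to_numpy()
        return list(map(tuple, self.labels[list(spec.columns)].to_numpy()))

    def fit(
        self,
        retain: Sequence[int] = DEFAULT_RETAIN,
        allow_constant_factors: bool = False,
    ) -> "MultilevelPCAResults":
        """Build every level's covariance, eigendecompose, and retain.

        ``retain`` gives the requested retained eigenvalue count per level in
        level order; each entry is capped at the level's available rank
        (groups minus one for between levels, p for the subject level).
        """
        if len(retain) != len(self.levels):
            raise ValueError(
                f"retain must list {len(self.levels)} counts, one per level"
            )
        mu = grand_mean(self.X)
        components: list[LevelComponent] = []
        skipped_cells: dict[str, list] = {}
        for spec, r in zip(self.levels, retain):
            groups = self._level_groups(spec)
            if spec.kind == "between":
                n_groups = pd.unique(np.asarray(groups, dtype=object)).shape[0]
                cov = factor_level_covariance(
                    self.X, groups, allow_single_group=allow_constant_factors
                )
                bound = max(n_groups - 1, 0)
                r_eff = min(int(r), bound, self.p)
                comp = eigendecompose_level(
                    cov, spec.name, n_groups, r_eff, rank_bound=bound
                )
            else:
                cov, skipped = subject_level_covariance(self.X, groups)
                skipped_cells[spec.name] = skipped
                n_groups = len(pd.unique(pd.Series(groups)))
                r_eff = min(int(r), self.p)
                comp = eigendecompose_level(cov, spec.name, n_groups, r_eff)
            components.append(comp)
        return MultilevelPCAResults(
            model=self,
            grand_mean_=mu,
            components=components,
            skipped_cells=skipped_cells,
        )


class MultilevelPCAResults:
    """Fitted multilevel PCA: eigenstructure plus reporting and scoring."""

    def __init__(
        self,
        model: MultilevelPCA,
        grand_mean_: np.ndarray,
        components: list[LevelComponent],
        skipped_cells: dict[str, list] | None = None,
    ) -> None:
        self.model = model
        self.grand_mean_ = grand_mean_
        self.components = components
        self.skipped_cells = skipped_cells or {}

    # -- basic accessors ----------------------------------------------------

    @property
    def level_names(self) -> tuple[str, ...]:
        return tuple(c.level_name for c in self.components)

    def level(self, name: str) -> LevelComponent:
        for comp in self.components:
            if comp.level_name == name:
                return comp
        raise KeyError(f"no level named {name!r}")

    @property
    def all_eigenvalues_total(self) -> float:
        """Sum of every eigenvalue over all levels, retained or not."""
        return float(sum(c.eigenvalues.sum() for c in self.components))

    # -- variance partitioning ----------------------------------------------

    def variance_partition(self) -> pd.DataFrame:
        """Percent of total landmark variation explained per level and PC.

        The denominator is the total eigenvalue magnitude over ALL levels
        (retained and unretained), so the per-level retained percentages
        need not sum to 100.
        """
        total = self.all_eigenvalues_total
        if total <= 0:
            raise ValueError("zero total eigenvalue mass")
        rows = []
        for comp in self.components:
            lam = comp.retained_eigenvalues
            rows.append(
                {
                    "level": comp.level_name,
                    "pc1_pct": 100.0 * lam[0] / total if comp.retained >= 1 else np.nan,
                    "pc2_pct": 100.0 * lam[1] / total if comp.retained >= 2 else np.nan,
                    "all_retained_pct": 100.0 * lam.sum() / total,
                    "n_retained": comp.retained,
                }
            )
        return pd.DataFrame(rows)

    def eigenvalue_table(self) -> pd.DataFrame:
        """Long table of all eigenvalues per level (scree-plot data)."""
        rows = []
        for comp in self.components:
            for j, lam in enumerate(comp.eigenvalues, start=1):
                rows.append(
                    {
                        "level": comp.level_name,
                        "pc": j,
                        "eigenvalue": lam,
                        "retained": j <= comp.retained,
                    }
                )
        return pd.DataFrame(rows)

    # -- score fitting ------------------------------------------------------

    def _mode_matrix(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        blocks, index = [], []
        for comp in self.components:
            blocks.append(comp.retained_eigenvectors)
            index.append((comp.level_name, comp.retained))
        return np.hstack(blocks), index

    def fit_scores(self, observation: np.ndarray) -> ScoreFit:
        """Fit all levels' scores simultaneously to one configuration.

        Minimises the point-to-point cost
        ``|| observation - mu - B a ||^2`` where B concatenates the retained
        modes of every level; solved exactly by minimum-norm linear least
        squares, which attains the global optimum of the quadratic cost.
        """
        obs = np.asarray(observation, dtype=float)
        if obs.shape != (self.model.p,):
            raise ValueError(
                f"observation must have length p={self.model.p}"
            )
        fits = self.batch_fit(obs[None, :])
        return fits[0]

    def batch_fit(self, X: np.ndarray) -> list[ScoreFit]:
        """Vectorised :meth:`fit_scores` over the rows of ``X``."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.model.p:
            raise ValueError(f"X must be (n, {self.model.p})")
        B, index = self._mode_matrix()
        # minimum-norm least squares via the pseudoinverse, applied row by
        # row so scalar and batch paths are bitwise identical
        P = np.linalg.pinv(B)
        dev = X - self.grand_mean_
        A = np.stack([P @ d for d in dev], axis=1)
        fitted = self.grand_mean_ + np.stack([B @ a for a in A.T])
        residuals = np.linalg.norm(X - fitted, axis=1)
        out = []
        for i in range(X.shape[0]):
            scores: dict[str, np.ndarray] = {}
            std: dict[str, np.ndarray] = {}
            offset = 0
            for (name, m), comp in zip(index, self.components):
                a = A[offset : offset + m, i].copy()
                scores[name] = a
                std[name] = standardize_scores(a, comp.retained_eigenvalues)
                offset += m
            out.append(
                ScoreFit(
                    scores=scores,
                    standardized_scores=std,
                    fitted=fitted[i],
                    residual_norm=float(residuals[i]),
                )
            )
        return out

    def score_table(self, X: np.ndarray, subject_ids=None) -> pd.DataFrame:
        """Long-format scores: subject_id, level, pc, score, standardized."""
        fits = self.batch_fit(X)
        if subject_ids is None:
            subject_ids = list(range(len(fits)))
        rows = []
        for sid, f in zip(subject_ids, fits):
            for name in f.scores:
                for j, (s, z) in enumerate(
                    zip(f.scores[name], f.standardized_scores[name]), start=1
                ):
                    rows.append(
                        {
                            "subject_id": sid,
                            "level": name,
                            "pc": j,
                            "score": s,
                            "standardized_score": z,
                        }
                    )
        return pd.DataFrame(rows)

    # -- reporting tables ---------------------------------------------------

    def group_centroids(
        self,
        fits: Sequence[ScoreFit],
        labels: pd.DataFrame,
        level: str,
        pcs: Sequence[int] = (1, 2),
    ) -> pd.DataFrame:
        """Mean and SD of standardized scores per (smoking x alcohol, sex).

        SD is the sample standard deviation (divisor n-1); single-subject
        groups report SD 0 and are flagged.
        """
        comp = self.level(level)
        for pc in pcs:
            if pc > comp.retained:
                raise ValueError(
                    f"PC{pc} not retained at level {level!r} "
                    f"(retained={comp.retained})"
                )
        z = np.stack([f.standardized_scores[level] for f in fits])
        lab = labels.reset_index(drop=True)
        group_cols = [c for c in ("smoking", "alcohol") if c in lab.columns]
        sex_col = ["sex"] if "sex" in lab.columns else []
        rows = []
        for key, idx in lab.groupby(group_cols + sex_col, sort=True).groups.items():
            key = key if isinstance(key, tuple) else (key,)
            sub = z[np.asarray(idx)]
            row = dict(zip(group_cols + sex_col, key))
            row["n"] = len(idx)
            row["singleton"] = len(idx) == 1
            for pc in pcs:
                vals = sub[:, pc - 1]
                row[f"pc{pc}_mean"] = float(vals.mean())
                row[f"pc{pc}_sd"] = (
                    float(vals.std(ddof=1)) if len(idx) > 1 else 0.0
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def landmark_differences(self, level: str, pc: int) -> pd.DataFrame:
        """Per-landmark (x, y, z) differences for one level/PC, in mm.

        Differences between the reconstruction at +2 sqrt(eigenvalue) and at
        -2 sqrt(eigenvalue) along the mode, i.e. exactly
        ``4 sqrt(lambda) * mode`` reshaped to landmarks.
        """
        comp = self.level(level)
        if not (1 <= pc <= comp.retained):
            raise ValueError(
                f"PC{pc} not retained at level {level!r} "
                f"(retained={comp.retained})"
            )
        lam = comp.eigenvalues[pc - 1]
        u = comp.eigenvectors[:, pc - 1]
        plus = self.grand_mean_ + 2.0 * np.sqrt(lam) * u
        minus = self.grand_mean_ - 2.0 * np.sqrt(lam) * u
        diff = (plus - minus).reshape(-1, 3)
        names = self.model.landmark_names
        if names is None:
            names = tuple(f"landmark_{i+1}" for i in range(diff.shape[0]))
        return pd.DataFrame(
            diff, columns=["dx", "dy", "dz"], index=pd.Index(names, name="landmark")
        )

    # -- summary ------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Multilevel PCA results",
            "=" * 62,
            f"subjects: {self.model.n}    dimension p: {self.model.p}",
            f"total eigenvalue mass (all levels): "
            f"{self.all_eigenvalues_total:.6g}",
            "",
            f"{'level':<10}{'groups':>8}{'retained':>10}{'nonzero':>9}"
            f"{'% variation':>14}",
            "-" * 62,
        ]
        vp = self.variance_partition().set_index("level")
        for comp in self.components:
            pct = vp.loc[comp.level_name, "all_retained_pct"]
            lines.append(
                f"{comp.level_name:<10}{comp.n_groups:>8}"
                f"{comp.retained:>10}{comp.n_nonzero:>9}{pct:>13.2f}%"
            )
        lines.append("-" * 62)
        return "\n".join(lines)


def fit_iterative(
    results: MultilevelPCAResults,
    observation: np.ndarray,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Minimise the point-to-point cost with a generic iterative optimiser.

    Kept solely as an equivalence check against the exact least-squares
    solution of :meth:`MultilevelPCAResults.fit_scores`.
    """
    B, _ = results._mode_matrix()
    target = np.asarray(observation, dtype=float) - results.grand_mean_

    def cost(a: np.ndarray) -> float:
        r = target - B @ a
        return float(r @ r)

    def grad(a: np.ndarray) -> np.ndarray:
        return 2.0 * (B.T @ (B @ a - target))

    if x0 is None:
        x0 = np.zeros(B.shape[1])
    res = scipy.optimize.minimize(cost, x0, jac=grad, method="L-BFGS-B",
                                  options={"maxiter": 2000, "ftol": 1e-15,
                                           "gtol": 1e-12})
    return res.x
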