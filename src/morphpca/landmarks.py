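"""Landmark dataset containers and file I/O.

A subject is a configuration of K named 3D landmarks in millimetres, plus
three categorical covariates: maternal smoking and maternal alcohol exposure
(none / 1st trimester only / 1st+2nd trimesters) and biological sex.
Configurations are stored flattened landmark-major, ``(x1, y1, z1, x2, ...)``,
so each landmark occupies a consecutive coordinate triple.

Two on-disk formats are supported: a wide CSV dialect with one subject per
row, and TPS specimen records with a companion factor CSV keyed by ID.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The 21 Farkas soft-tissue landmarks, in the order used throughout.
FARKAS_LANDMARKS: tuple[str, ...] = (
    "glabella",
    "nasion",
    "endocanthion_left",
    "endocanthion_right",
    "exocanthion_left",
    "exocanthion_right",
    "palpebrale_superius_left",
    "palpebrale_superius_right",
    "palpebrale_inferius_left",
    "palpebrale_inferius_right",
    "pronasale",
    "subnasale",
    "alare_left",
    "alare_right",
    "labiale_superius",
    "labiale_inferius",
    "crista_philtri_left",
    "crista_philtri_right",
    "cheilion_left",
    "cheilion_right",
    "pogonion",
)

SMOKING_CATEGORIES: tuple[str, ...] = ("none", "t1_only", "t1_t2")
ALCOHOL_CATEGORIES: tuple[str, ...] = ("none", "t1_only", "t1_t2")
SEX_CATEGORIES: tuple[str, ...] = ("male", "female")

FACTOR_CATEGORIES: dict[str, tuple[str, ...]] = {
    "smoking": SMOKING_CATEGORIES,
    "alcohol": ALCOHOL_CATEGORIES,
    "sex": SEX_CATEGORIES,
}

_AXES = ("x", "y", "z")


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


class ValidationError(ValueError):
    """Data violate a dataset invariant (categories, finiteness, shape)."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One subject's named 3D landmarks (millimetres)."""

    landmark_names: tuple[str, ...]
    coordinates: np.ndarray  # (K, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "landmark_names", tuple(self.landmark_names))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError(
                f"coordinates must be (K, 3); got {coords.shape}"
            )
        if coords.shape[0] != len(self.landmark_names):
            raise ValidationError(
                f"{len(self.landmark_names)} names but {coords.shape[0]} rows"
            )
        if len(set(self.landmark_names)) != len(self.landmark_names):
            raise ValidationError("duplicate landmark names")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinate")

    @property
    def n_landmarks(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class FactorLabels:
    """Per-subject covariates: smoking, alcohol, sex."""

    smoking: str
    alcohol: str
    sex: str

    def __post_init__(self) -> None:
        for name in ("smoking", "alcohol", "sex"):
            value = getattr(self, name)
            allowed = FACTOR_CATEGORIES[name]
            if value not in allowed:
                raise ValidationError(
                    f"unknown {name} category {value!r}; allowed: {allowed}"
                )


def flatten(config: LandmarkConfiguration) -> np.ndarray:
    """Flatten to a length-3K vector, landmark-major (x1, y1, z1, x2, ...)."""
    return np.asarray(config.coordinates, dtype=float).ravel().copy()


def unflatten(
    vector: np.ndarray, landmark_names: tuple[str, ...]
) -> LandmarkConfiguration:
    """Inverse of :func:`flatten` for the given landmark name list."""
    vec = np.asarray(vector, dtype=float)
    k = len(landmark_names)
    if vec.shape != (3 * k,):
        raise ValidationError(f"expected length {3 * k}, got shape {vec.shape}")
    return LandmarkConfiguration(landmark_names, vec.reshape(k, 3))


class ShapeDataset:
    """n landmark configurations with aligned factor labels.

    Parameters
    ----------
    flattened : (n, 3K) array of landmark-major coordinates, mm.
    labels : DataFrame with columns ``smoking``, ``alcohol``, ``sex``.
    subject_ids : n unique identifiers.
    landmark_names : K landmark labels shared by all subjects.
    """

    def __init__(
        self,
        flattened: np.ndarray,
        labels: pd.DataFrame,
        subject_ids,
        landmark_names: tuple[str, ...] = FARKAS_LANDMARKS,
    ) -> None:
        X = np.asarray(flattened, dtype=float)
        if X.ndim != 2:
            raise ValidationError("flattened must be 2-D (n, 3K)")
        names = tuple(landmark_names)
        if X.shape[1] != 3 * len(names):
            raise ValidationError(
                f"p={X.shape[1]} does not equal 3K={3 * len(names)}"
            )
        if X.shape[0] < 1:
            raise ValidationError("dataset must contain at least one subject")
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValidationError(
                f"non-finite coordinate at subject {bad[0]}, column {bad[1]}"
            )
        ids = list(subject_ids)
        if len(ids) != X.shape[0]:
            raise ValidationError("subject_ids length mismatch")
        if len(set(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")
        lab = labels.reset_index(drop=True)
        missing = {"smoking", "alcohol", "sex"} - set(lab.columns)
        if missing:
            raise ValidationError(f"missing factor columns: {sorted(missing)}")
        if len(lab) != X.shape[0]:
            raise ValidationError("labels length mismatch")
        for col, allowed in FACTOR_CATEGORIES.items():
            bad = ~lab[col].isin(allowed)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"subject {ids[i]!r}: unknown {col} category "
                    f"{lab[col].iloc[i]!r}; allowed: {allowed}"
                )
        self.flattened = X
        self.labels = lab[["smoking", "alcohol", "sex"]].astype(str)
        self.subject_ids = ids
        self.landmark_names = names

    @property
    def n_subjects(self) -> int:
        return self.flattened.shape[0]

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_names)

    @property
    def p(self) -> int:
        return self.flattened.shape[1]

    def configuration(self, i: int) -> LandmarkConfiguration:
        return unflatten(self.flattened[i], self.landmark_names)

    def configurations(self) -> list[LandmarkConfiguration]:
        return [self.configuration(i) for i in range(self.n_subjects)]

    def factor_labels(self, i: int) -> FactorLabels:
        row = self.labels.iloc[i]
        return FactorLabels(row["smoking"], row["alcohol"], row["sex"])

    def with_coordinates(self, flattened: np.ndarray) -> "ShapeDataset":
        """Copy of the dataset with coordinates replaced (labels kept)."""
        return ShapeDataset(
            flattened, self.labels, self.subject_ids, self.landmark_names
        )

    def as_array(self) -> np.ndarray:
        """Coordinates as an (n, K, 3) array."""
        return self.flattened.reshape(self.n_subjects, self.n_landmarks, 3)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, ShapeDataset)
            and self.landmark_names == other.landmark_names
            and self.subject_ids == other.subject_ids
            and np.array_equal(self.flattened, other.flattened)
            and self.labels.equals(other.labels)
        )


def _csv_columns(names: tuple[str, ...]) -> list[str]:
    cols = ["subject_id", "smoking", "alcohol", "sex"]
    for name in names:
        cols.extend(f"{name}_{ax}" for ax in _AXES)
    return cols


def read_dataset(
    path, format: str = "csv", factor_path=None, landmark_names=None
) -> ShapeDataset:
    """Read a landmark dataset from ``csv`` or ``tps`` format.

    For TPS input, ``factor_path`` must point to a CSV with columns
    ``subject_id, smoking, alcohol, sex`` keyed by the TPS ``ID=`` records.
    ``landmark_names`` overrides the default Farkas list (required when the
    CSV header carries non-default names or the TPS file has K != 21).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "tps":
        if factor_path is None:
            raise FormatError("TPS input requires a companion factor table")
        return _read_tps(path, Path(factor_path), landmark_names)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> ShapeDataset:
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "smoking", "alcohol", "sex"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    coord_cols = [c for c in df.columns if re.search(r"_[xyz]$", c)]
    names: list[str] = []
    for col in coord_cols:
        base = col[:-2]
        if base not in names:
            names.append(base)
    for name in names:
        for ax in _AXES:
            if f"{name}_{ax}" not in df.columns:
                raise FormatError(f"missing landmark column {name}_{ax!r}")
    expected = _csv_columns(tuple(names))
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise FormatError(f"unexpected column {extra[0]!r}")
    cols = [f"{name}_{ax}" for name in names for ax in _AXES]
    block = df[cols]
    coerced = block.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise FormatError(
            f"non-numeric coordinate at row {r}, column {cols[c]!r}"
        )
    return ShapeDataset(
        coerced.to_numpy(dtype=float),
        df[["smoking", "alcohol", "sex"]],
        df["subject_id"].tolist(),
        tuple(names),
    )


def _read_tps(path: Path, factor_path: Path, landmark_names) -> ShapeDataset:
    text = path.read_text(encoding="utf-8")
    specimens: list[tuple[str, np.ndarray]] = []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        m = re.match(r"LM3?=(\d+)$", lines[i], flags=re.IGNORECASE)
        if not m:
            raise FormatError(f"expected LM= record, got {lines[i]!r}")
        k = int(m.group(1))
        rows = []
        for j in range(k):
            parts = lines[i + 1 + j].split()
            if len(parts) == 2:
                raise FormatError("2D TPS records are not supported")
            if len(parts) != 3:
                raise FormatError(
                    f"expected 3 coordinates, got {lines[i + 1 + j]!r}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric coordinate in {lines[i + 1 + j]!r}"
                ) from exc
        i += 1 + k
        if i >= len(lines) or not lines[i].upper().startswith("ID="):
            raise FormatError("specimen record missing ID= line")
        specimens.append((lines[i][3:], np.asarray(rows)))
        i += 1
    if not specimens:
        raise FormatError("empty TPS file")
    k = specimens[0][1].shape[0]
    if landmark_names is None:
        if k != len(FARKAS_LANDMARKS):
            raise FormatError(
                f"TPS has K={k}; supply landmark_names for non-default K"
            )
        landmark_names = FARKAS_LANDMARKS
    factors = pd.read_csv(factor_path, dtype={"subject_id": str})
    factors = factors.set_index("subject_id")
    X = np.stack([coords.ravel() for _, coords in specimens])
    ids = [sid for sid, _ in specimens]
    missing = [sid for sid in ids if sid not in factors.index]
    if missing:
        raise ValidationError(f"no factor row for subject {missing[0]!r}")
    lab = factors.loc[ids, ["smoking", "alcohol", "sex"]].reset_index(drop=True)
    return ShapeDataset(X, lab, ids, tuple(landmark_names))


def write_dataset(dataset: ShapeDataset, path, format: str = "csv") -> None:
    """Write a dataset in the CSV dialect or as TPS + factor table.

    TPS output writes ``<path>`` and a companion ``<path stem>.factors.csv``.
    """
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(
            dataset.flattened,
            columns=[
                f"{name}_{ax}"
                for name in dataset.landmark_names
                for ax in _AXES
            ],
        )
        df.insert(0, "sex", dataset.labels["sex"].to_numpy())
        df.insert(0, "alcohol", dataset.labels["alcohol"].to_numpy())
        df.insert(0, "smoking", dataset.labels["smoking"].to_numpy())
        df.insert(0, "subject_id", dataset.subject_ids)
        df.to_csv(path, index=False, float_format="%.12g")
    elif format == "tps":
        buf = io.StringIO()
        arr = dataset.as_array()
        for i, sid in enumerate(dataset.subject_ids):
            buf.write(f"LM={dataset.n_landmarks}\n")
            for row in arr[i]:
                buf.write(f"{row[0]:.12g} {row[1]:.12g} {row[2]:.12g}\n")
            buf.write(f"ID={sid}\n")
        path.write_text(buf.getvalue(), encoding="utf-8")
        fac = dataset.labels.copy()
        fac.insert(0, "subject_id", dataset.subject_ids)
        fac.to_csv(path.with_suffix(".factors.csv"), index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
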