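"""Trajectory ensemble containers and delimited-text I/O.

Single-cell trajectories live in a reduced feature space (e.g. morphology PC1,
vimentin-Haralick PC1/PC3/PC4).  On disk an ensemble is a long ("tidy") table,
one row per (cell, frame), with a ``#``-prefixed metadata header carrying the
frame interval, feature names and condition label so a round trip is lossless.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTrajectory",
    "TrajectoryEnsemble",
    "PCAModel",
    "TableDialect",
    "ValidationError",
    "FormatError",
    "read_trajectories",
    "write_trajectories",
    "read_pca",
    "write_pca",
]

_DT_RTOL = 1e-9


class ValidationError(ValueError):
    """A container violated one of its invariants."""


class FormatError(ValueError):
    """An on-disk table did not match the expected schema."""


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for trajectory tables with non-default headers."""

    cell_col: str = "cell_id"
    time_col: str = "time"
    feature_cols: tuple[str, ...] | None = None  # None: every other column
    sep: str = ","


@dataclass
class FeatureTrajectory:
    """One cell's time-ordered path through the reduced feature space.

    Parameters
    ----------
    cell_id : opaque identifier.
    times : (T,) strictly increasing, uniformly spaced, in hours.
    X : (T, d) feature-space coordinates, reduced units.
    """

    cell_id: str
    times: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.times.ndim != 1 or self.X.shape[0] != self.times.shape[0]:
            raise ValidationError(
                f"cell {self.cell_id}: times ({self.times.shape}) and X "
                f"({self.X.shape}) are inconsistent"
            )
        if len(self.times) < 2:
            raise ValidationError(f"cell {self.cell_id}: need at least 2 frames")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError(f"cell {self.cell_id}: missing/non-finite coordinates")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValidationError(f"cell {self.cell_id}: times not strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > _DT_RTOL * max(abs(dt), 1.0)):
            raise ValidationError(
                f"cell {self.cell_id}: non-uniform frame interval "
                f"(min {steps.min():g}, max {steps.max():g})"
            )

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories sharing dimension and frame interval."""

    trajectories: list[FeatureTrajectory]
    feature_names: list[str]
    dt: float
    condition_label: str = ""

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValidationError("ensemble must contain at least one trajectory")
        d = self.trajectories[0].d
        if len(self.feature_names) != d:
            raise ValidationError(
                f"{len(self.feature_names)} feature names for dimension {d}"
            )
        for tr in self.trajectories:
            if tr.d != d:
                raise ValidationError(f"cell {tr.cell_id}: dimension {tr.d} != {d}")
            if abs(tr.dt - self.dt) > _DT_RTOL * max(abs(self.dt), 1.0):
                raise ValidationError(
                    f"cell {tr.cell_id}: dt {tr.dt:g} != ensemble dt {self.dt:g}"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def d(self) -> int:
        return self.trajectories[0].d

    def stacked(self) -> np.ndarray:
        """All frames of all trajectories, (sum T_i, d)."""
        return np.vstack([tr.X for tr in self.trajectories])

    def subset(self, indices) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(
            [self.trajectories[i] for i in indices],
            list(self.feature_names),
            self.dt,
            self.condition_label,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.trajectories:
            df = pd.DataFrame(tr.X, columns=self.feature_names)
            df.insert(0, "time", tr.times)
            df.insert(0, "cell_id", tr.cell_id)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


@dataclass
class PCAModel:
    """Affine map between the original feature space and the reduced subspace.

    ``loadings`` has orthonormal columns (D x d); ``transform`` projects an
    original-space point onto the d principal coordinates, ``inverse_transform``
    lifts reduced coordinates back.
    """

    mean: np.ndarray
    loadings: np.ndarray
    original_feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        D, d = self.loadings.shape
        if d > D:
            raise ValidationError(f"d={d} exceeds D={D}")
        if self.mean.shape != (D,):
            raise ValidationError("mean length must match loadings rows")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(d), atol=1e-8):
            raise ValidationError("loadings columns are not orthonormal")
        if not self.original_feature_names:
            self.original_feature_names = [f"f{i}" for i in range(D)]

    @property
    def D(self) -> int:
        return self.loadings.shape[0]

    @property
    def d(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.loadings

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return self.mean + np.atleast_2d(Z) @ self.loadings.T


# ---------------------------------------------------------------------------
# readers / writers


def read_trajectories(path, dialect: TableDialect | None = None) -> TrajectoryEnsemble:
    """Read a long-format trajectory table into a :class:`TrajectoryEnsemble`.

    Rows are grouped by cell id and sorted by time; the frame interval is
    inferred and must be uniform per cell (and shared across cells).  Lines
    starting with ``#`` are metadata of the form ``# key: value`` and may carry
    ``condition``; they are otherwise ignored, so plain tables read fine.
    """
    dialect = dialect or TableDialect()
    meta: dict[str, str] = {}
    body: list[str] = []
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    k, v = stripped.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                body.append(line)
    df = pd.read_csv(
        _stdio.StringIO("".join(body)), sep=dialect.sep, float_precision="round_trip"
    )
    for col in (dialect.cell_col, dialect.time_col):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
    if dialect.feature_cols is not None:
        feature_cols = list(dialect.feature_cols)
        missing = [c for c in feature_cols if c not in df.columns]
        if missing:
            raise FormatError(f"feature columns missing from {path}: {missing}")
    else:
        feature_cols = [
            c for c in df.columns if c not in (dialect.cell_col, dialect.time_col)
        ]
    if not feature_cols:
        raise FormatError(f"no feature columns found in {path}")

    trajectories = []
    for cell_id, grp in df.groupby(dialect.cell_col, sort=True):
        grp = grp.sort_values(dialect.time_col, kind="mergesort")
        trajectories.append(
            FeatureTrajectory(
                cell_id=str(cell_id),
                times=grp[dialect.time_col].to_numpy(float),
                X=grp[feature_cols].to_numpy(float),
            )
        )
    dt = trajectories[0].dt
    return TrajectoryEnsemble(
        trajectories,
        feature_cols,
        dt,
        condition_label=meta.get("condition", ""),
    )


def write_trajectories(ensemble: TrajectoryEnsemble, path) -> None:
    """Write an ensemble as a long CSV with a metadata header.

    Coordinates are written with ``repr`` round-trip precision so
    ``read_trajectories(write_trajectories(e))`` reproduces ``e`` bit for bit.
    """
    df = ensemble.to_frame()
    with open(path, "wt") as fh:
        fh.write(f"# condition: {ensemble.condition_label}\n")
        fh.write(f"# dt: {ensemble.dt!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def write_pca(model: PCAModel, path) -> None:
    """Store a PCA model as structured text (names, mean, loadings rows)."""
    with open(path, "wt") as fh:
        fh.write(f"# D: {model.D}\n# d: {model.d}\n")
        fh.write("# names: " + ",".join(model.original_feature_names) + "\n")
        np.savetxt(fh, model.mean[None, :], fmt="%.17g")
        np.savetxt(fh, model.loadings, fmt="%.17g")


def read_pca(path) -> PCAModel:
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("names:"):
                    names = stripped.split(":", 1)[1].strip().split(",")
                continue
            if line.strip():
                rows.append([float(tok) for tok in line.split()])
    # first row is the mean (length D); the rest are loadings rows (length d)
    mean = np.asarray(rows[0], dtype=float)
    loadings = np.asarray(rows[1:], dtype=float)
    return PCAModel(mean=mean, loadings=loadings, original_feature_names=names)
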