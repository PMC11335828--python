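"""Sexual dimorphism scores by mean-difference projection.

Sexual shape dimorphism (SShD) and sexual color dimorphism (SCoD) are
scalar sex-typicality scores obtained the same way in two different
spaces: compute the female mean FM and male mean MM of the feature
matrix (Procrustes shape coordinates, or skin colors plus facial
contrasts), take the axis d = MM - FM joining them, and score each
individual by the dot product of its feature vector with d.  Higher
scores are more male-typical; by construction the male-minus-female
difference in mean scores equals ||d||^2, and ||d|| itself is the
between-sex mean distance tested by permutation in :mod:`facedim.stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .color import CHANNELS, FEATURE_REGIONS, ColorMeasurement, ContrastProfile
from .landmarks import AlignedShapeSet

__all__ = [
    "FeatureMatrix",
    "DimorphismAxis",
    "DegenerateAxisError",
    "build_axis",
    "project_scores",
    "mean_distance",
    "assemble_scod_matrix",
    "assemble_sshd_matrix",
]

logger = logging.getLogger(__name__)


class DegenerateAxisError(ValueError):
    """Raised when the two sex means coincide (zero-length axis)."""


@dataclass
class FeatureMatrix:
    """Specimens x variables matrix with sex labels.

    Rows with missing values are excluded at assembly time and recorded in
    ``excluded`` as (specimen_id, reason) pairs.
    """

    specimen_ids: list[str]
    sex_labels: list[str]
    variables: list[str]
    values: np.ndarray
    space: str = "generic"
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if not (len(self.specimen_ids) == len(self.sex_labels) == n):
            raise ValueError("row labels do not match value matrix")
        if len(self.variables) != p:
            raise ValueError("variable names do not match value matrix")
        if np.isnan(self.values).any():
            raise ValueError("FeatureMatrix must not contain missing values")

    @property
    def sex_array(self) -> np.ndarray:
        return np.asarray(self.sex_labels)

    def validate_for_axis(self) -> None:
        sexes = self.sex_array
        for s in ("F", "M"):
            if (sexes == s).sum() < 2:
                raise ValueError(f"need at least 2 specimens of sex {s}")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variables)
        df.insert(0, "specimen_id", self.specimen_ids)
        df.insert(1, "sex", self.sex_labels)
        return df


@dataclass
class DimorphismAxis:
    """The axis joining the sex-specific means in one feature space."""

    female_mean: np.ndarray
    male_mean: np.ndarray
    space: str
    variables: list[str]

    @property
    def direction(self) -> np.ndarray:
        return self.male_mean - self.female_mean

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.direction))

    def to_json_dict(self) -> dict:
        return {
            "space": self.space,
            "variables": list(self.variables),
            "female_mean": self.female_mean.tolist(),
            "male_mean": self.male_mean.tolist(),
            "direction": self.direction.tolist(),
            "length": self.length,
        }


def build_axis(X: FeatureMatrix) -> DimorphismAxis:
    """Axis from the female mean to the male mean of ``X``."""
    X.validate_for_axis()
    sexes = X.sex_array
    fm = X.values[sexes == "F"].mean(axis=0)
    mm = X.values[sexes == "M"].mean(axis=0)
    if np.allclose(fm, mm):
        raise DegenerateAxisError("sex means coincide; dimorphism axis undefined")
    return DimorphismAxis(
        female_mean=fm, male_mean=mm, space=X.space, variables=list(X.variables)
    )


def project_scores(
    X: FeatureMatrix,
    axis: DimorphismAxis,
    normalize_axis: bool = False,
    center: Literal["none", "mean"] = "none",
) -> pd.DataFrame:
    """Score each specimen by its dot product with the sex-difference axis.

    By default the direction vector is left unnormalized, so the
    male-minus-female mean score difference equals ||MM - FM||^2 exactly;
    ``normalize_axis=True`` divides by ||MM - FM|| to yield distance-unit
    scores.  ``center="mean"`` subtracts the grand mean score (rank order
    and all downstream statistics are unaffected).
    """
    if X.values.shape[1] != axis.direction.shape[0]:
        raise ValueError(
            f"matrix has {X.values.shape[1]} variables, axis has "
            f"{axis.direction.shape[0]}"
        )
    d = axis.direction
    if normalize_axis:
        d = d / np.linalg.norm(d)
    scores = X.values @ d
    if center == "mean":
        scores = scores - scores.mean()
    return pd.DataFrame(
        {
            "specimen_id": X.specimen_ids,
            "sex": X.sex_labels,
            "score": scores,
            "space": axis.space,
        }
    )


def mean_distance(X: FeatureMatrix) -> float:
    """Euclidean distance between the male and female mean vectors."""
    X.validate_for_axis()
    sexes = X.sex_array
    fm = X.values[sexes == "F"].mean(axis=0)
    mm = X.values[sexes == "M"].mean(axis=0)
    return float(np.linalg.norm(mm - fm))


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

_SKIN_PATCHES = ("cheek", "forehead")


def assemble_scod_matrix(
    measurements: Sequence[ColorMeasurement],
    profiles: Sequence[ContrastProfile],
    channels: Sequence[str] = CHANNELS,
    standardize: bool = False,
) -> FeatureMatrix:
    """Color-space feature matrix: cheek and forehead skin color plus the
    eye/brow/lips contrasts, in the selected channels.

    With all three channels the matrix has 15 columns (2 skin patches x 3
    channels + 3 features x 3 channels).  Specimens with any missing value
    are dropped and recorded in ``excluded``.  ``standardize=True``
    z-scores every column (off by default: the reported distances are in
    mixed raw units).
    """
    channels = tuple(channels)
    bad = [c for c in channels if c not in CHANNELS]
    if bad:
        raise ValueError(f"unknown channels {bad}; choose from {CHANNELS}")
    prof_by_id = {p.specimen_id: p for p in profiles}
    variables = [f"{patch}_{ch}" for patch in _SKIN_PATCHES for ch in channels]
    variables += [
        f"{feature}_contrast_{ch}" for feature in FEATURE_REGIONS for ch in channels
    ]

    ids: list[str] = []
    sexes: list[str] = []
    rows: list[list[float]] = []
    excluded: list[tuple[str, str]] = []
    common = [m for m in measurements if m.specimen_id in prof_by_id]
    if not common:
        raise ValueError("no specimens common to measurements and profiles")
    for m in common:
        prof = prof_by_id[m.specimen_id]
        row: list[float] = []
        missing: list[str] = []
        for patch in _SKIN_PATCHES:
            for ch in channels:
                ci = CHANNELS.index(ch)
                if patch in m.region_means:
                    row.append(m.region_means[patch][ci])
                else:
                    row.append(float("nan"))
                    missing.append(f"{patch}_{ch}")
        for feature in FEATURE_REGIONS:
            for ch in channels:
                v = prof.get(feature, ch)
                row.append(v)
                if np.isnan(v):
                    missing.append(f"{feature}_contrast_{ch}")
        if missing or m.sex not in ("F", "M"):
            reason = (
                "missing: " + ", ".join(missing) if missing else "sex label absent"
            )
            excluded.append((m.specimen_id, reason))
            logger.info("SCoD matrix: excluding %s (%s)", m.specimen_id, reason)
            continue
        ids.append(m.specimen_id)
        sexes.append(m.sex)
        rows.append(row)
    values = np.asarray(rows, dtype=float).reshape(len(rows), len(variables))
    if standardize and len(rows):
        sd = values.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd
    return FeatureMatrix(
        specimen_ids=ids,
        sex_labels=sexes,
        variables=variables,
        values=values,
        space="color",
        excluded=excluded,
    )


def assemble_sshd_matrix(aligned: AlignedShapeSet) -> FeatureMatrix:
    """Shape-space feature matrix: aligned coordinates flattened to columns
    x1, y1, ..., xk, yk (pure reshaping, coordinates unchanged).

    Specimens without an F/M sex label are dropped and recorded.
    """
    n, p, _ = aligned.coords.shape
    variables = [c for i in range(1, p + 1) for c in (f"x{i}", f"y{i}")]
    ids: list[str] = []
    sexes: list[str] = []
    rows: list[np.ndarray] = []
    excluded: list[tuple[str, str]] = []
    for i, sid in enumerate(aligned.specimens):
        sex = aligned.sexes[i] if aligned.sexes else None
        if sex not in ("F", "M"):
            excluded.append((sid, "sex label absent"))
            logger.info("SShD matrix: excluding %s (sex label absent)", sid)
            continue
        ids.append(sid)
        sexes.append(sex)
        rows.append(aligned.coords[i].reshape(-1))
    return FeatureMatrix(
        specimen_ids=ids,
        sex_labels=sexes,
        variables=variables,
        values=np.asarray(rows, dtype=float).reshape(len(rows), 2 * p),
        space="shape",
        excluded=excluded,
    )
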