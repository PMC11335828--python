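"""Landmark configurations, TPS file I/O, symmetrization, and generalized
Procrustes analysis (GPA).

A facial configuration is an ordered set of 2-D landmarks digitized on a
frontal photograph: true landmarks sit on anatomically homologous points,
semilandmarks sample curves (face outline, brow and lip arcs).  Both are
treated as fixed points here; no sliding is performed.

GPA removes position, scale and orientation from each configuration by
translating centroids to the origin, scaling to unit centroid size, and
iteratively rotating every configuration onto the evolving consensus
(mean) shape.  Reflections are never allowed.  The aligned coordinates
live in Procrustes shape space and are the raw material for sexual shape
dimorphism scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Pairing",
    "LandmarkConfiguration",
    "AlignedShapeSet",
    "TpsParseError",
    "ConfigurationError",
    "DegenerateShapeError",
    "read_tps",
    "write_tps",
    "read_pairing_csv",
    "write_pairing_csv",
    "centroid_size",
    "symmetrize",
    "gpa",
]

N_POINTS_STANDARD = 72


class TpsParseError(ValueError):
    """Raised when a TPS record cannot be parsed."""


class ConfigurationError(ValueError):
    """Raised when a landmark configuration violates its contract."""


class DegenerateShapeError(ValueError):
    """Raised for configurations with zero centroid size."""


@dataclass(frozen=True)
class Pairing:
    """Bilateral correspondence table: ``pairs`` of (left, right) point
    indices plus ``midline`` indices lying on the symmetry axis."""

    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]

    def __init__(self, pairs: Iterable[Sequence[int]], midline: Iterable[int]):
        object.__setattr__(self, "pairs", tuple((int(a), int(b)) for a, b in pairs))
        object.__setattr__(self, "midline", tuple(int(i) for i in midline))

    def validate(self, n_points: int) -> None:
        """Every index must appear in exactly one pair or in the midline."""
        seen: list[int] = [i for ab in self.pairs for i in ab] + list(self.midline)
        if sorted(seen) != list(range(n_points)):
            counts = {i: seen.count(i) for i in set(seen)}
            dupes = sorted(i for i, c in counts.items() if c > 1)
            missing = sorted(set(range(n_points)) - set(seen))
            raise ConfigurationError(
                f"pairing does not cover points exactly once: "
                f"missing={missing}, duplicated={dupes}"
            )

    def permutation(self, n_points: int) -> np.ndarray:
        """Index permutation that swaps left/right labels (midline fixed)."""
        perm = np.arange(n_points)
        for a, b in self.pairs:
            perm[a], perm[b] = b, a
        return perm


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark configuration.

    ``points`` is an (n, 2) float array in image units; ``kind_flags`` marks
    each point ``"landmark"`` or ``"semilandmark"``.  ``sex`` uses ``"F"`` /
    ``"M"`` when known.
    """

    specimen_id: str
    points: np.ndarray
    sex: str | None = None
    population: str | None = None
    kind_flags: tuple[str, ...] | None = None
    pairing: Pairing | None = None
    image: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ConfigurationError(
                f"{self.specimen_id}: points must be (n, 2), got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ConfigurationError(f"{self.specimen_id}: non-finite coordinates")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ConfigurationError(f"{self.specimen_id}: sex must be 'F' or 'M'")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def validate_standard(self) -> None:
        """Check the standard 72-point contract (and pairing coverage)."""
        if self.n_points != N_POINTS_STANDARD:
            raise ConfigurationError(
                f"{self.specimen_id}: expected {N_POINTS_STANDARD} points, "
                f"got {self.n_points}"
            )
        if self.pairing is not None:
            self.pairing.validate(self.n_points)


@dataclass
class AlignedShapeSet:
    """Jointly Procrustes-aligned configurations.

    ``coords`` has shape (n_specimens, n_points, 2) in Procrustes units:
    centroid at the origin, unit centroid size.  ``consensus`` is the mean
    shape; ``centroid_sizes`` are the pre-scaling sizes.
    """

    specimens: list[str]
    coords: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations_run: int
    converged: bool
    sexes: list[str | None] = field(default_factory=list)
    populations: list[str | None] = field(default_factory=list)

    def to_dataframe(self):
        """Flat table: specimen_id, sex, population, x1,y1,...,centroid_size."""
        import pandas as pd

        n, p, _ = self.coords.shape
        cols = [c for i in range(1, p + 1) for c in (f"x{i}", f"y{i}")]
        df = pd.DataFrame(self.coords.reshape(n, 2 * p), columns=cols)
        df.insert(0, "specimen_id", self.specimens)
        df.insert(1, "sex", self.sexes if self.sexes else None)
        df.insert(2, "population", self.populations if self.populations else None)
        df["centroid_size"] = self.centroid_sizes
        return df


# ---------------------------------------------------------------------------
# TPS I/O (tpsDig2 dialect: LM=, coordinate lines, optional IMAGE=, ID=, SCALE=)
# ---------------------------------------------------------------------------

def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file.

    Each record starts with ``LM=<n>`` followed by n ``x y`` lines and
    optional ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.  SCALE multiplies the
    stored coordinates.  Records whose point count differs from 72 are
    returned as-is (the caller validates); a record whose coordinate-line
    count does not match its LM= header is a parse error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(
                f"record {record_index}: expected 'LM=' header, got {line!r}"
            )
        try:
            n = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(f"record {record_index}: bad LM= count") from exc
        i += 1
        pts: list[tuple[float, float]] = []
        while i < len(lines) and len(pts) < n:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row and not _looks_like_coords(row):
                break
            parts = row.split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"record {record_index}: bad coordinate line {row!r}"
                )
            pts.append((float(parts[0]), float(parts[1])))
            i += 1
        if len(pts) != n:
            raise TpsParseError(
                f"record {record_index}: LM={n} but found {len(pts)} coordinate lines"
            )
        meta: dict[str, str] = {}
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            if "=" not in row:
                raise TpsParseError(
                    f"record {record_index}: unexpected line {row!r} after coordinates"
                )
            key, val = row.split("=", 1)
            meta[key.strip().upper()] = val.strip()
            i += 1
        points = np.asarray(pts, dtype=float)
        scale = float(meta["SCALE"]) if "SCALE" in meta else None
        if scale is not None:
            points = points * scale
        configs.append(
            LandmarkConfiguration(
                specimen_id=meta.get("ID", f"record_{record_index}"),
                points=points,
                image=meta.get("IMAGE"),
                scale=scale,
            )
        )
        record_index += 1
    return configs


def _looks_like_coords(row: str) -> bool:
    parts = row.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
        return True
    except ValueError:
        return False


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file (inverse of :func:`read_tps`).

    Coordinates are written with ``repr`` so a write/read round trip is
    bit-exact.  SCALE is not re-emitted (coordinates are already scaled).
    """
    path = Path(path)
    out: list[str] = []
    for cfg in configs:
        if cfg.n_points == 0:
            raise ConfigurationError(f"{cfg.specimen_id}: empty configuration")
        out.append(f"LM={cfg.n_points}")
        for x, y in cfg.points:
            out.append(f"{float(x)!r} {float(y)!r}")
        if cfg.image is not None:
            out.append(f"IMAGE={cfg.image}")
        out.append(f"ID={cfg.specimen_id}")
    path.write_text("\n".join(out) + ("\n" if out else ""))


def write_pairing_csv(pairing: Pairing, path: str | Path) -> None:
    """Write a bilateral-pairing table as CSV (kind,index_a,index_b)."""
    lines = ["kind,index_a,index_b"]
    for a, b in pairing.pairs:
        lines.append(f"pair,{a},{b}")
    for i in pairing.midline:
        lines.append(f"midline,{i},")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pairing_csv(path: str | Path) -> Pairing:
    """Read a pairing table written by :func:`write_pairing_csv`."""
    pairs: list[tuple[int, int]] = []
    midline: list[int] = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        kind, a, b = (line.split(",") + [""])[:3]
        if kind == "pair":
            pairs.append((int(a), int(b)))
        elif kind == "midline":
            midline.append(int(a))
        else:
            raise ConfigurationError(f"unknown pairing row kind {kind!r}")
    return Pairing(pairs=pairs, midline=midline)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def centroid_size(points: np.ndarray) -> float:
    """Square root of the summed squared distances of points from their
    centroid — the size measure removed by Procrustes scaling."""
    pts = np.asarray(points, dtype=float)
    return float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix R (det +1) minimizing ||source @ R - target||.

    Closed form in 2-D: the optimal angle is atan2 of the cross and dot
    sums.  Reflections are deliberately excluded.
    """
    a = float((source * target).sum())
    b = float((source[:, 0] * target[:, 1] - source[:, 1] * target[:, 0]).sum())
    theta = math.atan2(b, a)
    c, s = math.cos(theta), math.sin(theta)
    # rows are points: x' = x @ R rotates by +theta
    return np.array([[c, s], [-s, c]])


def _rotate_to(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    return source @ _optimal_rotation(source, target)


# ---------------------------------------------------------------------------
# Symmetrization (object symmetry)
# ---------------------------------------------------------------------------

def symmetrize(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Average a configuration with its relabeled reflection.

    Steps: center; reflect across the vertical midline (negate x); swap the
    labels within every bilateral pair; rotate the reflected copy onto the
    original (rotation only); average pointwise.  The output is perfectly
    bilaterally symmetric and the operation is idempotent to machine
    precision.
    """
    if config.pairing is None:
        raise ConfigurationError(
            f"{config.specimen_id}: symmetrize requires a pairing table"
        )
    config.pairing.validate(config.n_points)
    centered = config.points - config.points.mean(axis=0)
    reflected = centered * np.array([-1.0, 1.0])
    perm = config.pairing.permutation(config.n_points)
    relabeled = reflected[perm]
    aligned = _rotate_to(relabeled, centered)
    averaged = (centered + aligned) / 2.0
    return replace(config, points=averaged)


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def gpa(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Joint Procrustes superimposition of two or more configurations.

    Translates centroids to the origin, scales to unit centroid size
    (recording pre-scaling sizes), then iterates: rotate every configuration
    onto the current consensus, recompute the consensus, renormalize it, stop
    when its root-mean-square change drops below ``tol``.  After convergence
    the whole set is rotated so the consensus' principal axis is vertical,
    making the output independent of input order and of arbitrary rotations
    of the inputs.
    """
    if len(configs) < 2:
        raise ConfigurationError("GPA requires at least 2 configurations")
    n_pts = configs[0].n_points
    for cfg in configs:
        if cfg.n_points != n_pts:
            raise ConfigurationError(
                f"{cfg.specimen_id}: point count {cfg.n_points} != {n_pts}"
            )
    X = np.stack([cfg.points for cfg in configs]).astype(float)
    X -= X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((X**2).sum(axis=(1, 2)))
    for cfg, cs in zip(configs, sizes):
        if cs < 1e-12:
            raise DegenerateShapeError(
                f"{cfg.specimen_id}: zero centroid size (all points coincident)"
            )
    X /= sizes[:, None, None]

    # consensus is the plain arithmetic mean of the aligned configurations
    # (rotation targets are scale-insensitive, so no renormalization);
    # initialized with the raw mean so aligned input is a one-iteration
    # fixed point, falling back to the first configuration when arbitrary
    # input orientations make the raw mean nearly degenerate
    consensus = X.mean(axis=0)
    if float(np.sqrt((consensus**2).sum())) < 1e-3:
        consensus = X[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = _rotate_to(X[i], consensus)
        new_consensus = X.mean(axis=0)
        change = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
        consensus = new_consensus
        if change < tol:
            converged = True
            break

    # Orientation anchor: principal axis of the consensus vertical, with a
    # deterministic sign convention so the result is rotation-unique.  The
    # covariance is inversion-symmetric, so a third-moment convention breaks
    # the remaining 180-degree ambiguity.
    cov = consensus.T @ consensus
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    theta = math.atan2(v[0], v[1])  # rotate v onto (0, 1)
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, s], [-s, c]])
    rotated = consensus @ R
    skew_y = float((rotated[:, 1] ** 3).sum())
    skew_x = float((rotated[:, 0] ** 3).sum())
    if skew_y < -1e-12 or (abs(skew_y) <= 1e-12 and skew_x < -1e-12):
        R = -R
        rotated = -rotated
    consensus = rotated
    for i in range(len(X)):
        X[i] = _rotate_to(X[i] @ R, consensus)

    return AlignedShapeSet(
        specimens=[cfg.specimen_id for cfg in configs],
        coords=X,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations_run=iterations,
        converged=converged,
        sexes=[cfg.sex for cfg in configs],
        populations=[cfg.population for cfg in configs],
    )
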