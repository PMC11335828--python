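"""Synthetic two-sex face populations with known dimorphism parameters.

Stands in for a real photograph-derived dataset: generates (a) 72-point
landmark configurations (36 landmarks + 36 semilandmarks on a bilaterally
symmetric face template) with a male mean-shape displacement, isotropic
digitization/biological noise, and similarity-transform nuisance on the
raw coordinates; (b) per-region CIELAB color measurements with per-region
male offsets (e.g. lower male L*), a person-level color deviation shared
across regions, and smaller independent per-region noise; (c) rater x
stimulus attractiveness matrices on a 7-point scale with controlled
stimulus, rater and residual variance components, optionally coupled to a
per-stimulus covariate such as skin lightness.

All generators are deterministic given the spec's seed.  Three presets
emulate the dimorphism patterns of the three populations studied with
frontal-photograph datasets of this kind: a Central-African-like
population (strong skin-lightness dimorphism, moderate shape
dimorphism), a European-like one (no lightness dimorphism, yellower male
skin, strong shape dimorphism) and a Southeast-Asian-like one (lightness
dimorphism, none in yellowness).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .color import ALL_REGIONS, CHANNELS, SKIN_REGIONS, ColorMeasurement
from .landmarks import LandmarkConfiguration, Pairing, centroid_size

__all__ = [
    "RatingSpec",
    "PopulationSpec",
    "make_face_template",
    "default_shape_displacement",
    "generate_landmarks",
    "generate_colors",
    "generate_ratings",
    "population_presets",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# Face template: 72 points = 8 midline + 32 bilateral pairs
# ---------------------------------------------------------------------------

# (name, x, y, kind) for midline points (x = 0) and the right-side member of
# each bilateral pair.  The left member is the x-negated mirror.
_MIDLINE = [
    ("forehead_top", 0.0, 1.30, "semilandmark"),
    ("glabella", 0.0, 0.55, "landmark"),
    ("nasion", 0.0, 0.30, "landmark"),
    ("nose_tip", 0.0, -0.05, "landmark"),
    ("subnasale", 0.0, -0.22, "landmark"),
    ("upper_lip_mid", 0.0, -0.42, "landmark"),
    ("lower_lip_mid", 0.0, -0.62, "landmark"),
    ("chin", 0.0, -1.20, "semilandmark"),
]

_PAIRED_LANDMARKS = [
    ("brow_inner", 0.20, 0.62),
    ("brow_peak", 0.42, 0.68),
    ("brow_outer", 0.62, 0.58),
    ("eye_inner", 0.18, 0.38),
    ("eye_top", 0.35, 0.45),
    ("eye_outer", 0.52, 0.38),
    ("eye_bottom", 0.35, 0.31),
    ("nose_ala", 0.16, -0.10),
    ("nostril", 0.10, -0.18),
    ("mouth_corner", 0.30, -0.52),
    ("upper_lip", 0.15, -0.40),
    ("lower_lip", 0.15, -0.66),
    ("cheekbone", 0.55, 0.05),
    ("cheek_center", 0.45, -0.25),
    ("gonion", 0.62, -0.55),
]

_PAIRED_SEMI_EXTRA = [
    ("brow_arc_1", 0.30, 0.66),
    ("brow_arc_2", 0.52, 0.64),
    ("lip_arc_upper", 0.22, -0.45),
    ("lip_arc_lower", 0.22, -0.59),
]

_OUTLINE_A, _OUTLINE_B, _OUTLINE_CY = 0.95, 1.25, 0.05  # face oval half-axes


def _outline_pairs() -> list[tuple[str, float, float]]:
    # 13 right-side outline semilandmarks between forehead top and chin
    pts = []
    for j in range(1, 14):
        t = np.pi * j / 14.0  # angle from +y axis, exclusive of the poles
        pts.append(
            (
                f"outline_{j}",
                _OUTLINE_A * np.sin(t),
                _OUTLINE_CY + _OUTLINE_B * np.cos(t),
            )
        )
    return pts


def make_face_template(style: str = "oval") -> LandmarkConfiguration:
    """Bilaterally symmetric 72-point face template with a complete pairing
    table (36 landmarks, 36 semilandmarks).  ``style`` "oval" or "narrow"
    (the latter compressed horizontally)."""
    if style not in ("oval", "narrow"):
        raise ValueError(f"unknown template style {style!r}")
    names: list[str] = []
    pts: list[tuple[float, float]] = []
    kinds: list[str] = []
    midline_idx: list[int] = []
    pairs: list[tuple[int, int]] = []
    for name, x, y, kind in _MIDLINE:
        midline_idx.append(len(pts))
        names.append(name)
        pts.append((x, y))
        kinds.append(kind)
    paired = [(n, x, y, "landmark") for n, x, y in _PAIRED_LANDMARKS]
    paired += [(n, x, y, "semilandmark") for n, x, y in _PAIRED_SEMI_EXTRA]
    paired += [(n, x, y, "semilandmark") for n, x, y in _outline_pairs()]
    for name, x, y, kind in paired:
        i_left = len(pts)
        names.append(f"{name}_L")
        pts.append((-x, y))
        kinds.append(kind)
        i_right = len(pts)
        names.append(f"{name}_R")
        pts.append((x, y))
        kinds.append(kind)
        pairs.append((i_left, i_right))
    points = np.asarray(pts, dtype=float)
    if style == "narrow":
        points[:, 0] *= 0.85
    cfg = LandmarkConfiguration(
        specimen_id=f"template_{style}",
        points=points,
        kind_flags=tuple(kinds),
        pairing=Pairing(pairs=pairs, midline=midline_idx),
    )
    cfg.validate_standard()
    return cfg


def default_shape_displacement(template: LandmarkConfiguration) -> np.ndarray:
    """Unit-norm 144-vector of a plausible male shape pattern: wider jaw
    and lower face outline, lowered brows, thinner lips, slightly larger
    nose.  Mirror-symmetric; only its magnitude matters downstream."""
    delta = np.zeros_like(template.points)
    pts = template.points
    for i in range(len(pts)):
        x, y = pts[i]
        if y < -0.3 and abs(x) > 0.3:  # jaw / lower outline: widen
            delta[i, 0] += 0.6 * np.sign(x)
        if 0.55 <= y <= 0.75 and abs(x) > 0.1:  # brows: lower
            delta[i, 1] -= 0.5
        if -0.7 <= y <= -0.35 and abs(x) <= 0.35:  # lips: thinner
            delta[i, 1] -= 0.25 * np.sign(y + 0.52)
        if -0.25 <= y <= 0.0 and abs(x) <= 0.2:  # nose: slightly wider
            delta[i, 0] += 0.2 * np.sign(x) if x != 0 else 0.0
    flat = delta.reshape(-1)
    return flat / np.linalg.norm(flat)


# ---------------------------------------------------------------------------
# Population specification
# ---------------------------------------------------------------------------

#: Female mean CIELAB per region (plausible light-brown skin; features darker).
DEFAULT_FEMALE_COLOR_MEANS: dict[str, tuple[float, float, float]] = {
    "cheek": (62.0, 13.0, 16.0),
    "forehead": (60.0, 13.0, 17.0),
    "eye_skin": (58.0, 12.0, 16.0),
    "brow_skin": (59.0, 12.0, 16.0),
    "lips_skin": (57.0, 13.0, 16.0),
    "eye_feature": (28.0, 6.0, 8.0),
    "brow_feature": (22.0, 8.0, 10.0),
    "lips_feature": (45.0, 22.0, 14.0),
}


@dataclass
class RatingSpec:
    """Variance components of the 7-point attractiveness ratings.

    Expected ICC(3,k) ~= stimulus_sd^2 / (stimulus_sd^2 + noise_sd^2 / k)
    before the mild attenuation from rounding/clamping to the 1–7 scale.
    ``luminance_weight`` in [0, 1) mixes a standardized per-stimulus
    covariate (overall skin L*) into the stimulus effect, inducing an
    attractiveness–lightness correlation of roughly that size.
    """

    k_raters: int = 30
    stimulus_sd: float = 0.8
    rater_sd: float = 0.5
    noise_sd: float = 1.0
    luminance_weight: float = 0.0


@dataclass
class PopulationSpec:
    """All true parameters of one synthetic population.

    Shape: males are displaced from the template by ``m_shape`` times the
    unit displacement pattern (template coordinate units); every raw
    configuration receives isotropic Gaussian landmark noise and a random
    similarity transform (nuisance) before analysis.  Color: region means
    are the female means plus, for males, per-region offsets; each face
    gets a person-level per-channel deviation shared by all regions
    (``color_noise_sd``) plus smaller independent per-region noise
    (``region_noise_sd``).
    """

    name: str = "synthetic"
    n_female: int = 50
    n_male: int = 50
    template_style: str = "oval"
    m_shape: float = 0.2
    landmark_noise_sd: float = 0.03
    rotation_range: float = 0.3  # radians, +/-
    scale_range: tuple[float, float] = (0.7, 1.4)
    translation_range: float = 2.0
    color_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEMALE_COLOR_MEANS)
    )
    color_dimorphism: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    color_noise_sd: tuple[float, float, float] = (3.0, 1.2, 1.5)
    region_noise_sd: tuple[float, float, float] = (0.8, 0.4, 0.5)
    rating_spec: RatingSpec = field(default_factory=RatingSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ValueError("sample sizes must be non-negative")
        if self.landmark_noise_sd < 0 or any(
            s < 0 for s in (*self.color_noise_sd, *self.region_noise_sd)
        ):
            raise ValueError("noise SDs must be non-negative")

    def specimen_ids(self) -> tuple[list[str], list[str]]:
        f = [f"{self.name}_F{i + 1:03d}" for i in range(self.n_female)]
        m = [f"{self.name}_M{i + 1:03d}" for i in range(self.n_male)]
        return f, m

    def true_parameters(self) -> dict:
        d = asdict(self)
        d["shape_displacement"] = "default male pattern (unit norm) * m_shape"
        return d


def _subseed(spec: "PopulationSpec", stream: int) -> np.random.Generator:
    # per-population, per-purpose stream: distinct populations sharing a
    # seed must not share noise draws
    tag = zlib.crc32(spec.name.encode())
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream, tag]))


def generate_landmarks(spec: PopulationSpec) -> list[LandmarkConfiguration]:
    """Raw (un-aligned) landmark configurations for one population.

    Females are template + noise; males additionally receive the mean
    displacement.  Each configuration is then rotated, scaled and
    translated by random nuisance draws, so the analysis must undo them
    via Procrustes superimposition.
    """
    template = make_face_template(spec.template_style)
    delta = default_shape_displacement(template).reshape(-1, 2)
    rng = _subseed(spec, 1)
    f_ids, m_ids = spec.specimen_ids()
    configs: list[LandmarkConfiguration] = []
    for sex, ids in (("F", f_ids), ("M", m_ids)):
        base = template.points + (spec.m_shape * delta if sex == "M" else 0.0)
        for sid in ids:
            pts = base + rng.normal(0.0, spec.landmark_noise_sd, size=base.shape)
            theta = rng.uniform(-spec.rotation_range, spec.rotation_range)
            scale = rng.uniform(*spec.scale_range)
            shift = rng.uniform(
                -spec.translation_range, spec.translation_range, size=2
            )
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, s], [-s, c]])
            pts = scale * (pts @ R) + shift
            configs.append(
                LandmarkConfiguration(
                    specimen_id=sid,
                    points=pts,
                    sex=sex,
                    population=spec.name,
                    kind_flags=template.kind_flags,
                    pairing=template.pairing,
                )
            )
    return configs


def generate_colors(spec: PopulationSpec) -> list[ColorMeasurement]:
    """Per-region CIELAB measurements for one population.

    value = female mean (+ male offset) + person-level channel deviation
    (shared across regions) + independent per-region noise.
    """
    rng = _subseed(spec, 2)
    f_ids, m_ids = spec.specimen_ids()
    person_sd = np.asarray(spec.color_noise_sd, dtype=float)
    region_sd = np.asarray(spec.region_noise_sd, dtype=float)
    out: list[ColorMeasurement] = []
    for sex, ids in (("F", f_ids), ("M", m_ids)):
        for sid in ids:
            person = rng.normal(0.0, 1.0, size=3) * person_sd
            region_means: dict[str, tuple[float, float, float]] = {}
            for region in ALL_REGIONS:
                mean = np.asarray(spec.color_means[region], dtype=float)
                if sex == "M" and region in spec.color_dimorphism:
                    mean = mean + np.asarray(
                        spec.color_dimorphism[region], dtype=float
                    )
                val = mean + person + rng.normal(0.0, 1.0, size=3) * region_sd
                val[0] = float(np.clip(val[0], 0.0, 100.0))
                region_means[region] = tuple(float(v) for v in val)
            out.append(
                ColorMeasurement(
                    specimen_id=sid,
                    region_means=region_means,
                    sex=sex,
                    population=spec.name,
                )
            )
    return out


def generate_ratings(
    spec: PopulationSpec,
    stimuli: Sequence[str],
    stimulus_covariate: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Complete rater x stimulus matrix of 7-point ratings.

    rating = round(4 + stimulus effect + rater shift + noise) clamped to
    1–7.  With ``stimulus_covariate`` (e.g. each stimulus' overall skin
    L*) and a nonzero ``luminance_weight`` w, the stimulus effect is
    stimulus_sd * (w * z + sqrt(1 - w^2) * e) with z the standardized
    covariate, so mean ratings correlate with the covariate at ~w.
    Returned as a stimuli x raters DataFrame.
    """
    rs = spec.rating_spec
    if rs.k_raters < 2:
        raise ValueError("need at least 2 raters")
    # independent substream per stimulus set, deterministic given the seed
    tag = zlib.crc32("|".join([spec.name, *map(str, stimuli)]).encode())
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, tag]))
    n = len(stimuli)
    e = rng.normal(0.0, 1.0, size=n)
    if stimulus_covariate is not None and rs.luminance_weight != 0.0:
        z = np.asarray(stimulus_covariate, dtype=float)
        z = (z - z.mean()) / z.std(ddof=0)
        w = rs.luminance_weight
        stim_effect = rs.stimulus_sd * (w * z + np.sqrt(1 - w**2) * e)
    else:
        stim_effect = rs.stimulus_sd * e
    rater_shift = rng.normal(0.0, rs.rater_sd, size=rs.k_raters)
    noise = rng.normal(0.0, rs.noise_sd, size=(n, rs.k_raters))
    raw = 4.0 + stim_effect[:, None] + rater_shift[None, :] + noise
    ratings = np.clip(np.rint(raw), 1, 7).astype(int)
    return pd.DataFrame(
        ratings,
        index=pd.Index(list(stimuli), name="stimulus"),
        columns=[f"rater_{j + 1:03d}" for j in range(rs.k_raters)],
    )


# ---------------------------------------------------------------------------
# Presets emulating the three studied populations
# ---------------------------------------------------------------------------

def _skin_offsets(dL_patch, dL_other, da, db) -> dict:
    """Male offsets: cheek/forehead get dL_patch, other skin dL_other."""
    off = {}
    for region in SKIN_REGIONS:
        dl = dL_patch if region in ("cheek", "forehead") else dL_other
        off[region] = (dl, da, db)
    return off


def population_presets(seed: int = 0) -> dict[str, PopulationSpec]:
    """Three synthetic populations mirroring the study's qualitative
    dimorphism patterns and sample sizes.

    - ``central_african``: strong male skin darkening, no redness or
      yellowness dimorphism, moderate shape displacement.
    - ``european``: negligible lightness dimorphism, yellower male skin
      (b*), the largest shape displacement.
    - ``southeast_asian``: male skin darkening, no yellowness dimorphism,
      moderate shape displacement, strong brow/eye contrast dimorphism.
    """
    dark_features = {
        "brow_feature": (-4.0, 0.0, 0.0),
        "eye_feature": (-3.0, 0.0, 0.0),
        "lips_feature": (-1.0, -1.0, 0.0),
    }
    presets = {
        "central_african": PopulationSpec(
            name="central_african",
            n_female=63,
            n_male=50,
            m_shape=0.15,
            color_dimorphism={
                **_skin_offsets(-1.9, -2.1, -0.35, 0.1),
                **dark_features,
            },
            rating_spec=RatingSpec(k_raters=49, luminance_weight=0.33),
            seed=seed,
        ),
        "european": PopulationSpec(
            name="european",
            n_female=48,
            n_male=50,
            m_shape=0.30,
            color_means={
                **DEFAULT_FEMALE_COLOR_MEANS,
                "cheek": (68.0, 11.0, 14.0),
                "forehead": (66.0, 11.0, 15.0),
                "eye_skin": (65.0, 10.0, 14.0),
                "brow_skin": (66.0, 10.0, 14.0),
                "lips_skin": (64.0, 11.0, 14.0),
            },
            color_dimorphism={
                **_skin_offsets(-0.35, -0.35, 0.35, 1.2),
                "brow_feature": (-2.0, 0.0, 0.5),
                "eye_feature": (-1.5, 0.0, 0.5),
                "lips_feature": (-0.5, -0.5, 0.5),
            },
            rating_spec=RatingSpec(k_raters=32, luminance_weight=0.1),
            seed=seed,
        ),
        "southeast_asian": PopulationSpec(
            name="southeast_asian",
            n_female=31,
            n_male=60,
            m_shape=0.16,
            color_means={
                **DEFAULT_FEMALE_COLOR_MEANS,
                "cheek": (66.0, 12.0, 15.0),
                "forehead": (64.0, 12.0, 16.0),
            },
            color_dimorphism={
                **_skin_offsets(-2.2, -1.0, -0.3, 0.0),
                "brow_feature": (-5.0, 0.0, 0.0),
                "eye_feature": (-3.5, 0.0, 0.0),
                "lips_feature": (-0.5, -0.5, 0.0),
            },
            rating_spec=RatingSpec(k_raters=40, luminance_weight=0.05),
            seed=seed,
        ),
    }
    return presets


def write_manifest(spec: PopulationSpec, path: str | Path) -> None:
    """JSON manifest of the true generating parameters of a population."""
    Path(path).write_text(
        json.dumps(spec.true_parameters(), indent=2, sort_keys=True, default=str)
        + "\n"
    )
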