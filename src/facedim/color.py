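"""CIELAB color measurement and facial contrast.

Skin and feature colors are expressed in CIE L*a*b* (D65, 2° observer):
L* is lightness (0–100), a* the green–red axis, b* the blue–yellow axis.
Overall skin color is the unweighted mean of five skin areas (the skin
surrounding the eyes, brows and lips, plus the cheek and forehead).
Feature/skin contrast uses an adapted Michelson formula,

    C_f = (L_s - L_f) / (L_f + L_s),

positive when the feature is darker (for L*; greener/bluer for a*/b*)
than its surrounding skin, zero when they match.  The same formula is
applied unchanged to the a* and b* channels, where the |C| <= 1 bound is
not guaranteed and values are stored unclipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2lab

__all__ = [
    "SKIN_REGIONS",
    "FEATURE_REGIONS",
    "ALL_REGIONS",
    "CHANNELS",
    "ColorMeasurement",
    "ContrastProfile",
    "UndefinedContrastError",
    "MissingRegionError",
    "srgb_to_lab",
    "region_mean",
    "mean_skin_color",
    "michelson_contrast",
    "contrast_profile",
    "read_measurements_csv",
    "write_measurements_csv",
]

#: The five skin areas averaged into the overall skin color.
SKIN_REGIONS = ("eye_skin", "brow_skin", "lips_skin", "cheek", "forehead")

#: Feature region and its surrounding-skin region, per contrast.
FEATURE_REGIONS = {
    "eye": ("eye_feature", "eye_skin"),
    "brow": ("brow_feature", "brow_skin"),
    "lips": ("lips_feature", "lips_skin"),
}

ALL_REGIONS = (
    "eye_feature",
    "brow_feature",
    "lips_feature",
) + SKIN_REGIONS

CHANNELS = ("L", "a", "b")


class UndefinedContrastError(ValueError):
    """Raised when a Michelson contrast has a zero denominator."""


class MissingRegionError(KeyError):
    """Raised when a required region is absent from a measurement."""


@dataclass
class ColorMeasurement:
    """Per-region CIELAB means for one specimen.

    ``region_means`` maps region name -> (L*, a*, b*).  Regions may be
    missing (e.g. lips obscured by lipstick residue); downstream steps
    treat the derived quantities as missing rather than failing.
    """

    specimen_id: str
    region_means: dict[str, tuple[float, float, float]]
    sex: str | None = None
    population: str | None = None

    def __post_init__(self) -> None:
        for region, lab in self.region_means.items():
            L, a, b = (float(v) for v in lab)
            if not (0.0 <= L <= 100.0):
                raise ValueError(
                    f"{self.specimen_id}/{region}: L*={L} outside [0, 100]"
                )
            if not (math.isfinite(a) and math.isfinite(b)):
                raise ValueError(f"{self.specimen_id}/{region}: non-finite a*/b*")
            self.region_means[region] = (L, a, b)


@dataclass
class ContrastProfile:
    """Michelson contrasts per (feature, channel) plus the overall skin color.

    Undefined or unmeasurable contrasts are stored as NaN.
    """

    specimen_id: str
    contrasts: dict[tuple[str, str], float]
    mean_skin: tuple[float, float, float] | None = None

    def get(self, feature: str, channel: str) -> float:
        return self.contrasts.get((feature, channel), float("nan"))


def srgb_to_lab(rgb: Sequence[float]) -> tuple[float, float, float]:
    """Convert one 8-bit sRGB triple to CIELAB (D65, 2° observer)."""
    r, g, b = rgb
    for comp in (r, g, b):
        if not (0 <= comp <= 255):
            raise ValueError(f"sRGB component {comp} outside [0, 255]")
    arr = np.asarray([[[r, g, b]]], dtype=float) / 255.0
    L, a, bb = rgb2lab(arr)[0, 0]
    return float(L), float(a), float(bb)


def region_mean(image: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Mean CIELAB color of the masked pixels of an sRGB image.

    Pixels are converted to Lab first, then averaged (the measurement is
    taken on the Lab-transformed image, not on averaged RGB).  ``image`` is
    (H, W, 3) uint8 or float in [0, 1]; ``mask`` is (H, W), nonzero =
    selected.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} dimensions differ"
        )
    sel = mask.astype(bool)
    if not sel.any():
        raise ValueError("empty mask")
    if image.dtype == np.uint8:
        image = image.astype(float) / 255.0
    lab = rgb2lab(image)
    vals = lab[sel].mean(axis=0)
    return float(vals[0]), float(vals[1]), float(vals[2])


def mean_skin_color(m: ColorMeasurement) -> tuple[float, float, float]:
    """Unweighted per-channel mean over the five skin areas."""
    missing = [r for r in SKIN_REGIONS if r not in m.region_means]
    if missing:
        raise MissingRegionError(
            f"{m.specimen_id}: missing skin regions {missing}"
        )
    vals = np.array([m.region_means[r] for r in SKIN_REGIONS], dtype=float)
    L, a, b = vals.mean(axis=0)
    return float(L), float(a), float(b)


def michelson_contrast(feature_value: float, skin_value: float) -> float:
    """Adapted Michelson contrast (skin - feature) / (feature + skin).

    0 means no contrast; positive means the feature is darker (L*) than
    the surrounding skin, negative that it is lighter.
    """
    denom = feature_value + skin_value
    if denom == 0:
        raise UndefinedContrastError(
            f"zero denominator: feature={feature_value}, skin={skin_value}"
        )
    return (skin_value - feature_value) / denom


def contrast_profile(m: ColorMeasurement) -> ContrastProfile:
    """Per-feature, per-channel contrasts for one specimen.

    Missing regions and zero-denominator cases yield NaN contrasts rather
    than errors; the overall skin color is included when all five skin
    areas are present.
    """
    contrasts: dict[tuple[str, str], float] = {}
    for feature, (feat_region, skin_region) in FEATURE_REGIONS.items():
        for ci, channel in enumerate(CHANNELS):
            if feat_region in m.region_means and skin_region in m.region_means:
                fv = m.region_means[feat_region][ci]
                sv = m.region_means[skin_region][ci]
                try:
                    contrasts[(feature, channel)] = michelson_contrast(fv, sv)
                except UndefinedContrastError:
                    contrasts[(feature, channel)] = float("nan")
            else:
                contrasts[(feature, channel)] = float("nan")
    try:
        mean_skin = mean_skin_color(m)
    except MissingRegionError:
        mean_skin = None
    return ContrastProfile(
        specimen_id=m.specimen_id, contrasts=contrasts, mean_skin=mean_skin
    )


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

def write_measurements_csv(
    measurements: Sequence[ColorMeasurement], path: str | Path
) -> None:
    """Write a flat table: specimen_id, sex, population, <region>_<channel>."""
    rows = []
    for m in measurements:
        row: dict[str, object] = {
            "specimen_id": m.specimen_id,
            "sex": m.sex,
            "population": m.population,
        }
        for region in ALL_REGIONS:
            if region in m.region_means:
                for ci, ch in enumerate(CHANNELS):
                    row[f"{region}_{ch}"] = m.region_means[region][ci]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_measurements_csv(path: str | Path) -> list[ColorMeasurement]:
    """Read a measurements table written by :func:`write_measurements_csv`."""
    df = pd.read_csv(path)
    out: list[ColorMeasurement] = []
    for _, row in df.iterrows():
        region_means: dict[str, tuple[float, float, float]] = {}
        for region in ALL_REGIONS:
            cols = [f"{region}_{ch}" for ch in CHANNELS]
            if all(c in df.columns for c in cols):
                vals = [row[c] for c in cols]
                if all(pd.notna(v) for v in vals):
                    region_means[region] = tuple(float(v) for v in vals)
        sex = row.get("sex")
        pop = row.get("population")
        out.append(
            ColorMeasurement(
                specimen_id=str(row["specimen_id"]),
                region_means=region_means,
                sex=None if pd.isna(sex) else str(sex),
                population=None if pd.isna(pop) else str(pop),
            )
        )
    return out
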