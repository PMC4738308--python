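"""Objective sensory image features and the assembled stimulus feature table.

Sensory features are computed directly from the image pixels (CIELAB
statistics, JPEG compressibility) or from a traced focal-object mask
(area, lightness contrast against background, roundness, thickness,
horizontal spread).  Semantic and emotional features are subjective
ratings and are ingested as given.  Feature values are standardised to
z-scores across the whole stimulus set before any tuning statistic is
computed.

Conventions
-----------
* sRGB input, D65 white point, standard sRGB transfer function for the
  CIELAB conversion (via scikit-image).
* Image-level standard deviations (RMS contrast, luridness) use the
  population convention (divide by N); column z-scoring uses the sample
  convention (N-1).
* Mask perimeter counts exposed pixel edges under 4-connectivity.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as _skcolor

__all__ = [
    "LabImage",
    "FeatureTable",
    "JPEG_ENCODER_CFG",
    "SENSORY_FEATURES",
    "SEMANTIC_FEATURES",
    "EMOTIONAL_FEATURES",
    "rgb_to_lab",
    "image_complexity",
    "colour_statistics",
    "mask_perimeter",
    "object_shape_features",
    "zscore_columns",
    "build_feature_table",
    "compute_sensory_features",
]

# Pinned lossy-encoder configuration: absolute byte counts are encoder
# specific, so complexity is only meaningful comparatively (after
# z-scoring), and must be reproducible.
JPEG_ENCODER_CFG: dict = {"quality": 75, "subsampling": 2, "optimize": False}

#: Feature names by set; 11 sensory + 6 semantic + 2 emotional = 19.
SENSORY_FEATURES = (
    "image_complexity",
    "mean_lightness",
    "red_green_balance",
    "yellow_blue_balance",
    "rms_contrast",
    "luridness",
    "object_area",
    "object_lightness",
    "object_roundness",
    "object_thickness",
    "horizontal_spread",
)
SEMANTIC_FEATURES = (
    "real_world_size",
    "object_number",
    "animacy",
    "association_referent_1",
    "association_referent_2",
    "implied_motion",
)
EMOTIONAL_FEATURES = ("valence", "arousal")


@dataclass(frozen=True)
class LabImage:
    """CIELAB planes of an image (L* in [0, 100]; a*, b* signed)."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise ValueError("L*, a*, b* planes must share a shape")
        if self.L.size == 0:
            raise ValueError("empty image")
        if self.L.min() < -1e-6 or self.L.max() > 100 + 1e-6:
            raise ValueError("L* values must lie in [0, 100]")

    @property
    def shape(self) -> tuple:
        return self.L.shape


def rgb_to_lab(image: np.ndarray) -> LabImage:
    """Convert an sRGB raster (uint8 or float in [0, 1]) to CIELAB planes."""
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[-1] not in (3, 4):
        raise ValueError(f"expected an RGB raster, got shape {arr.shape}")
    arr = arr[..., :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    lab = _skcolor.rgb2lab(arr)
    return LabImage(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def _as_uint8_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.dtype != np.uint8:
        arr = np.clip(np.asarray(arr, dtype=np.float64), 0.0, 1.0)
        arr = np.round(arr * 255).astype(np.uint8)
    return arr[..., :3]


def image_complexity(image: np.ndarray, encoder_cfg: dict | None = None) -> int:
    """Size in bytes of the image encoded as JPEG under a pinned configuration.

    Compressed file size acts as a proxy for visual complexity: uniform
    images compress well, cluttered ones do not.
    """
    cfg = dict(JPEG_ENCODER_CFG if encoder_cfg is None else encoder_cfg)
    arr = _as_uint8_rgb(image)
    buf = io.BytesIO()
    Image.fromarray(arr, mode="RGB").save(buf, format="JPEG", **cfg)
    return buf.tell()


def colour_statistics(image: np.ndarray | LabImage) -> dict:
    """CIELAB colour summary statistics of a whole image.

    Returns ``mean_L``, ``mean_a``, ``mean_b`` (plane means), ``rms_contrast``
    (population SD of L*) and ``luridness`` (mean of the population SDs of the
    a* and b* planes).
    """
    lab = image if isinstance(image, LabImage) else rgb_to_lab(image)
    return {
        "mean_L": float(lab.L.mean()),
        "mean_a": float(lab.a.mean()),
        "mean_b": float(lab.b.mean()),
        "rms_contrast": float(lab.L.std()),
        "luridness": float((lab.a.std() + lab.b.std()) / 2.0),
    }


def mask_perimeter(mask: np.ndarray) -> int:
    """Number of exposed foreground pixel edges (4-connectivity)."""
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    area = int(m.sum())
    padded = np.pad(m, 1, mode="constant")
    horiz = int(np.logical_and(padded[:, :-1], padded[:, 1:]).sum())
    vert = int(np.logical_and(padded[:-1, :], padded[1:, :]).sum())
    return 4 * area - 2 * (horiz + vert)


def object_shape_features(image: np.ndarray | LabImage, mask: np.ndarray) -> dict:
    """Shape and contrast features of the focal object(s) given a traced mask.

    area
        foreground pixel count.
    object_lightness
        mean L*(foreground) - mean L*(background).
    roundness
        lambda_min / lambda_max of the covariance of foreground pixel
        coordinates, in (0, 1]; 1 for an isotropic blob.
    thickness
        area / perimeter^2 (1/(4*pi) for a disc in the continuous limit).
    horizontal_spread
        orientation x (1 - roundness), in [-pi/4, +pi/4]; -pi/4 = vertical
        elongation, +pi/4 = horizontal, 0 for round objects.
    """
    m = np.asarray(mask, dtype=bool)
    lab = image if isinstance(image, LabImage) else rgb_to_lab(image)
    if m.shape != lab.shape:
        raise ValueError("mask and image shapes differ")
    n_fg = int(m.sum())
    if n_fg == 0:
        raise ValueError("empty focal mask")
    if n_fg < 2:
        raise ValueError("focal mask must contain at least 2 pixels")
    if n_fg == m.size:
        raise ValueError("mask covers the full frame: no background")

    rows, cols = np.nonzero(m)
    # x grows rightwards (columns), y downwards (rows); only the axis
    # ratio and the fold of the angle matter, so the y sign is irrelevant.
    coords = np.stack([cols.astype(np.float64), rows.astype(np.float64)])
    cov = np.cov(coords)
    evals, evecs = np.linalg.eigh(cov)
    lam_min, lam_max = float(evals[0]), float(evals[1])
    if lam_max <= 0:
        raise ValueError("degenerate mask: zero coordinate variance")
    roundness = lam_min / lam_max

    principal = evecs[:, 1]
    # Angle from the horizontal axis, folded into [0, pi/2].
    phi = abs(np.arctan2(principal[1], principal[0]))
    if phi > np.pi / 2:
        phi = np.pi - phi
    orientation = np.pi / 4 - phi  # +pi/4 horizontal, -pi/4 vertical
    horizontal_spread = float(orientation * (1.0 - roundness))

    perim = mask_perimeter(m)
    if perim == 0:
        raise ValueError("zero-perimeter mask")

    return {
        "area": n_fg,
        "object_lightness": float(lab.L[m].mean() - lab.L[~m].mean()),
        "roundness": float(roundness),
        "thickness": float(n_fg / perim**2),
        "horizontal_spread": horizontal_spread,
    }


@dataclass
class FeatureTable:
    """Stimuli x features matrix with a set label per feature.

    ``values`` is indexed by stimulus id; ``sets`` maps each feature name to
    one of {"sensory", "semantic", "emotional"}.
    """

    values: pd.DataFrame
    sets: dict = field(default_factory=dict)
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing values in features: {bad}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated stimulus ids: {dups}")
        unknown = set(self.sets.values()) - {"sensory", "semantic", "emotional"}
        if unknown:
            raise ValueError(f"unknown feature sets: {sorted(unknown)}")
        missing = [c for c in self.values.columns if c not in self.sets]
        if missing:
            raise ValueError(f"features without a set label: {missing}")

    @property
    def stimulus_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    def features_in_set(self, set_name: str) -> list:
        return [f for f in self.values.columns if self.sets[f] == set_name]

    def set_counts(self) -> dict:
        counts: dict = {}
        for f in self.values.columns:
            counts[self.sets[f]] = counts.get(self.sets[f], 0) + 1
        return counts

    def to_csv(self, csv_path: str | Path, sets_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        self.values.rename_axis("stimulus_id").to_csv(csv_path)
        if sets_path is None:
            sets_path = csv_path.with_suffix(".sets.json")
        Path(sets_path).write_text(
            json.dumps({"sets": self.sets, "standardized": self.standardized}, indent=1)
        )

    @classmethod
    def from_csv(cls, csv_path: str | Path, sets_path: str | Path | None = None) -> "FeatureTable":
        csv_path = Path(csv_path)
        values = pd.read_csv(csv_path, index_col="stimulus_id")
        if sets_path is None:
            sets_path = csv_path.with_suffix(".sets.json")
        meta = json.loads(Path(sets_path).read_text())
        return cls(values=values, sets=meta["sets"], standardized=meta["standardized"])


def zscore_columns(table: FeatureTable) -> FeatureTable:
    """Standardise every feature column to mean 0, sample SD 1.

    Idempotent; raises on constant columns, naming the offending feature.
    """
    values = table.values.astype(np.float64)
    sd = values.std(ddof=1)
    constant = sd.index[(sd == 0) | ~np.isfinite(sd)].tolist()
    if constant:
        raise ValueError(f"constant feature columns cannot be z-scored: {constant}")
    z = (values - values.mean()) / sd
    return FeatureTable(values=z, sets=dict(table.sets), standardized=True)


def compute_sensory_features(
    images: dict,
    masks: dict,
    encoder_cfg: dict | None = None,
) -> pd.DataFrame:
    """Compute all Table-of-features sensory columns for a stimulus set.

    ``images`` maps stimulus id -> RGB raster, ``masks`` maps the same ids to
    focal-object masks.
    """
    if set(images) != set(masks):
        raise ValueError("image and mask stimulus ids differ")
    rows = {}
    for sid in images:
        lab = rgb_to_lab(images[sid])
        col = colour_statistics(lab)
        shp = object_shape_features(lab, masks[sid])
        rows[sid] = {
            "image_complexity": image_complexity(images[sid], encoder_cfg),
            "mean_lightness": col["mean_L"],
            "red_green_balance": col["mean_a"],
            "yellow_blue_balance": col["mean_b"],
            "rms_contrast": col["rms_contrast"],
            "luridness": col["luridness"],
            "object_area": shp["area"],
            "object_lightness": shp["object_lightness"],
            "object_roundness": shp["roundness"],
            "object_thickness": shp["thickness"],
            "horizontal_spread": shp["horizontal_spread"],
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[sorted(rows)]


def build_feature_table(
    sensory: pd.DataFrame,
    semantic: pd.DataFrame,
    emotional: pd.DataFrame,
) -> FeatureTable:
    """Assemble computed sensory and rated semantic/emotional columns.

    All three inputs must cover exactly the same stimulus ids.  Rated inputs
    use 5-point scales except animacy and object number, which are 3-level.
    """
    for name, df in (("sensory", sensory), ("semantic", semantic), ("emotional", emotional)):
        if df is None or len(df) == 0 or df.shape[1] == 0:
            raise ValueError(f"empty {name} feature input")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicated stimulus ids in {name} input: {dups}")
    ids = set(sensory.index)
    for name, df in (("semantic", semantic), ("emotional", emotional)):
        if set(df.index) != ids:
            missing = sorted(ids.symmetric_difference(df.index))
            raise ValueError(f"stimulus id mismatch in {name} input: {missing}")
    order = sorted(ids)
    values = pd.concat(
        [sensory.loc[order], semantic.loc[order], emotional.loc[order]], axis=1
    )
    sets = {c: "sensory" for c in sensory.columns}
    sets.update({c: "semantic" for c in semantic.columns})
    sets.update({c: "emotional" for c in emotional.columns})
    return FeatureTable(values=values, sets=sets, standardized=False)
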