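"""Blue color proportion (BCP) quantification for EBUS strain elastography.

Endobronchial-ultrasound strain elastography overlays a color map on the
B-mode image in which blue encodes hard tissue, green intermediate and
yellow/red soft tissue. Because metastatic lymph nodes tend to be stiffer
than benign ones, the fraction of blue pixels inside the node region — the
blue color proportion — is a semi-quantitative malignancy score.

This module implements the full pipeline in the order it runs:

1.  configuration and logging;
2.  domain types (elastogram raster, ROI mask, cohort container);
3.  image stage — seeded region growing for the node ROI, HSV blue-band
    pixel classification, and the BCP ratio;
4.  synthetic data — an elastogram renderer with exact ground-truth blue
    fraction, and a cohort simulator parameterized by published group
    distributions of BCP in malignant and benign nodes;
5.  diagnostics — empirical ROC curve, trapezoidal AUC with stratified
    bootstrap CI, Youden-optimal cutoff, confusion metrics, benchmarking of
    conventional B-mode/PET features, and the two-group location test;
6.  cohort CSV / PNG io, batch image processing and the analysis report.

All randomness flows through :class:`numpy.random.Generator` objects created
from explicit seeds; nothing touches global random state.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage, optimize, stats
from skimage.color import hsv2rgb, rgb2hsv
from skimage.measure import label as cc_label

__all__ = [
    "BENIGN_BCP_MEAN",
    "BENIGN_BCP_SD",
    "BENIGN_SUBTYPE_MEANS",
    "BINARY_FEATURES",
    "COHORT_COLUMNS",
    "DEFAULT_FEATURE_MODEL",
    "MALIGNANT_BCP_MEAN",
    "MALIGNANT_BCP_SD",
    "MALIGNANT_SUBTYPE_MEANS",
    "STATIONS",
    "BcpResult",
    "CohortDataset",
    "CohortSimParams",
    "CohortSchemaError",
    "ColorClassifierConfig",
    "ConfusionTable",
    "Elastogram",
    "ImageSimParams",
    "PipelineConfig",
    "RenderedElastogram",
    "RocResult",
    "RoiMask",
    "analyze_cohort",
    "batch_images",
    "binormal_auc",
    "classify_at",
    "classify_blue_pixels",
    "compare_groups",
    "compute_bcp",
    "configure_logging",
    "count_below",
    "diagnostic_metrics",
    "feature_performance",
    "node_bcp",
    "read_cohort",
    "read_elastogram",
    "read_mask",
    "render_elastogram",
    "roc_curve",
    "segment_roi",
    "simulate_cohort",
    "write_cohort",
    "write_elastogram",
    "write_mask",
    "youden_cutoff",
]

logger = logging.getLogger("elasto_bcp")


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())


# --------------------------------------------------------------------------
# Published cohort parameters used as simulator defaults
# --------------------------------------------------------------------------

#: Group BCP distributions (percent) reported for malignant vs benign nodes.
MALIGNANT_BCP_MEAN = 57.1
MALIGNANT_BCP_SD = 14.4
BENIGN_BCP_MEAN = 31.1
BENIGN_BCP_SD = 17.3

#: Mean BCP (percent) by pathology subtype; shipped as optional presets.
MALIGNANT_SUBTYPE_MEANS: dict[str, float] = {
    "adenocarcinoma": 61.9,
    "squamous_cell_carcinoma": 71.6,
    "small_cell_carcinoma": 45.8,
    "poorly_differentiated_carcinoma": 57.4,
    "metastatic_lung_cancer": 50.9,
}
BENIGN_SUBTYPE_MEANS: dict[str, float] = {
    "normal_lymphatic_tissue": 27.0,
    "inflammatory_exudation": 33.3,
    "bacterial_infection": 49.0,
    "sarcoidosis": 42.9,
}

#: Subtype sampling weights for the simulator (observed cohort composition).
MALIGNANT_SUBTYPE_WEIGHTS: dict[str, int] = {
    "adenocarcinoma": 17,
    "squamous_cell_carcinoma": 2,
    "small_cell_carcinoma": 9,
    "poorly_differentiated_carcinoma": 9,
    "metastatic_lung_cancer": 2,
}
BENIGN_SUBTYPE_WEIGHTS: dict[str, int] = {
    "normal_lymphatic_tissue": 22,
    "inflammatory_exudation": 14,
    "bacterial_infection": 2,
    "sarcoidosis": 2,
}

#: Conventional-feature model: sensitivity/specificity of each binary
#: malignancy flag, used to draw features conditionally on the true label.
DEFAULT_FEATURE_MODEL: dict[str, tuple[float, float]] = {
    "short_axis_gt_10mm": (1.0, 0.05),
    "round_shape": (0.282, 1.0),
    "distinct_margin": (0.308, 0.90),
    "heterogeneous_echo": (0.641, 0.325),
    "vascular_pattern": (0.487, 0.50),
    "suv_gt_2_5": (1.0, 0.154),
}

#: Thoracic lymph-node station codes and simulator sampling weights.
STATIONS: tuple[str, ...] = (
    "2R", "4R", "4L", "7", "10R", "10L", "11R", "11L", "12R", "12L",
)
STATION_WEIGHTS: dict[str, int] = {
    "2R": 7, "4R": 8, "4L": 8, "7": 39,
    "10R": 6, "10L": 6, "11R": 2, "11L": 1, "12R": 1, "12L": 1,
}

BINARY_FEATURES = (
    "round_shape", "distinct_margin", "heterogeneous_echo", "vascular_pattern",
)
COHORT_COLUMNS = (
    "node_id", "station", "pathology_subtype", "label", "bcp_percent",
    "short_axis_mm", "round_shape", "distinct_margin", "heterogeneous_echo",
    "vascular_pattern", "suv_gt_2_5",
)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ColorClassifierConfig:
    """Blue-band definition in HSV plus region-growing tolerance.

    The blue band defaults to hue 190°–270° with minimum saturation and
    value of 0.15, which covers the blue (hard-tissue) arm of clinical
    elastography palettes while rejecting desaturated B-mode show-through
    and near-black background. ``wand_tolerance`` is the Euclidean RGB
    distance to the seed color used by :func:`segment_roi`.
    """

    hue_min: float = 190.0
    hue_max: float = 270.0
    sat_min: float = 0.15
    val_min: float = 0.15
    wand_tolerance: float = 32.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_min < self.hue_max:
            raise ValueError("require 0 <= hue_min < hue_max")
        if not (0.0 <= self.sat_min <= 1.0 and 0.0 <= self.val_min <= 1.0):
            raise ValueError("sat_min and val_min must be in [0, 1]")
        if self.wand_tolerance < 0:
            raise ValueError("wand_tolerance must be non-negative")


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level knobs shared by the CLI and :func:`analyze_cohort`."""

    classifier: ColorClassifierConfig = field(default_factory=ColorClassifierConfig)
    bootstrap_replicates: int = 2000
    seed: int = 0
    cutoff_override: float | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if self.cutoff_override is not None and not 0 <= self.cutoff_override <= 100:
            raise ValueError("cutoff_override must be in [0, 100]")


# --------------------------------------------------------------------------
# Domain types — image stage
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Elastogram:
    """An RGB elastogram frame, optionally with a dual-panel layout.

    ``panel_box`` is the half-open rectangle ``(row_min, col_min, row_max,
    col_max)`` delimiting the elastography panel when the frame shows
    B-mode and elastography side by side; analysis is restricted to it.
    """

    pixels: np.ndarray
    panel_box: tuple[int, int, int, int] | None = None
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be an H x W x 3 raster")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if self.panel_box is not None:
            r0, c0, r1, c1 = self.panel_box
            h, w = px.shape[:2]
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError("panel_box must be a non-empty in-bounds rectangle")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def panel_mask(self) -> np.ndarray:
        """Boolean mask of the analyzable (elastography-panel) pixels."""
        m = np.zeros(self.shape, dtype=bool)
        if self.panel_box is None:
            m[:] = True
        else:
            r0, c0, r1, c1 = self.panel_box
            m[r0:r1, c0:c1] = True
        return m


@dataclass(frozen=True)
class RoiMask:
    """Binary mask delimiting one lymph node on one elastogram."""

    mask: np.ndarray
    source: str = "external_file"

    _SOURCES = ("external_file", "region_growing", "synthetic")

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be a 2-D boolean raster")
        object.__setattr__(self, "mask", m)
        if self.source not in self._SOURCES:
            raise ValueError(f"unknown mask source {self.source!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class BcpResult:
    """Blue-pixel count, ROI pixel count and their ratio for one image."""

    blue_pixels: int
    total_pixels: int
    bcp: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.blue_pixels <= self.total_pixels:
            raise ValueError("require 0 <= blue_pixels <= total_pixels")
        if self.total_pixels < 1:
            raise ValueError("total_pixels must be >= 1")
        if abs(self.bcp - self.blue_pixels / self.total_pixels) > 1e-12:
            raise ValueError("bcp must equal blue_pixels / total_pixels")

    @property
    def bcp_percent(self) -> float:
        """BCP as percent, rounded to one decimal (reporting convention)."""
        return round(100.0 * self.bcp, 1)


def _check_pair(image: Elastogram, roi: RoiMask) -> None:
    if roi.mask.shape != image.shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match image shape {image.shape}"
        )
    if roi.n_pixels == 0:
        raise ValueError("ROI is empty")
    if image.panel_box is not None and bool((roi.mask & ~image.panel_mask()).any()):
        raise ValueError("ROI extends outside the elastography panel")


# --------------------------------------------------------------------------
# Image stage
# --------------------------------------------------------------------------


def classify_blue_pixels(
    image: Elastogram, roi: RoiMask, config: ColorClassifierConfig | None = None
) -> np.ndarray:
    """Classify stiff ("blue") pixels inside the node ROI.

    A pixel is blue iff its HSV hue (standard hexcone conversion from RGB)
    lies in ``[hue_min, hue_max]`` degrees, saturation >= ``sat_min`` and
    value >= ``val_min``. Returns a boolean mask that is a subset of the ROI.
    """
    config = config or ColorClassifierConfig()
    _check_pair(image, roi)
    hsv = rgb2hsv(image.pixels)
    hue_deg = hsv[..., 0] * 360.0
    blue = (
        (hue_deg >= config.hue_min)
        & (hue_deg <= config.hue_max)
        & (hsv[..., 1] >= config.sat_min)
        & (hsv[..., 2] >= config.val_min)
    )
    return blue & roi.mask


def segment_roi(
    image: Elastogram,
    seed: tuple[int, int],
    config: ColorClassifierConfig | None = None,
) -> RoiMask:
    """Seeded region growing: the software analogue of a magic-wand click.

    Grows the 8-connected component containing ``seed`` of all pixels whose
    Euclidean RGB distance to the seed pixel's color is at most
    ``wand_tolerance``. Restricted to the elastography panel when the frame
    is dual-panel. Deterministic for fixed inputs.
    """
    config = config or ColorClassifierConfig()
    r, c = int(seed[0]), int(seed[1])
    h, w = image.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"seed {seed} out of bounds for image {image.shape}")
    panel = image.panel_mask()
    if not panel[r, c]:
        raise ValueError(f"seed {seed} lies outside the elastography panel")
    px = image.pixels.astype(np.float64)
    dist = np.sqrt(((px - px[r, c]) ** 2).sum(axis=-1))
    within = (dist <= config.wand_tolerance) & panel
    comp = cc_label(within, connectivity=2)
    return RoiMask(mask=comp == comp[r, c], source="region_growing")


def compute_bcp(
    image: Elastogram, roi: RoiMask, config: ColorClassifierConfig | None = None
) -> BcpResult:
    """Blue color proportion: blue pixels over all ROI pixels.

    An empty blue mask is a valid result (BCP = 0), covering nodes that are
    entirely soft on the color map.
    """
    blue = classify_blue_pixels(image, roi, config)
    blue_n = int(blue.sum())
    total = roi.n_pixels
    return BcpResult(
        blue_pixels=blue_n, total_pixels=total, bcp=blue_n / total, image_id=image.id
    )


def node_bcp(results: Sequence[BcpResult]) -> float:
    """Per-node BCP: unweighted mean over the node's per-image BCP values."""
    if len(results) == 0:
        raise ValueError("node_bcp requires at least one per-image result")
    return float(np.mean([r.bcp for r in results]))


# --------------------------------------------------------------------------
# Synthetic data — elastogram renderer
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSimParams:
    """Parameters of one rendered elastogram.

    An elliptical "node" is filled with a smooth synthetic relative-stiffness
    field; the stiffest ``target_blue_fraction`` of its pixels (to the
    nearest pixel) are drawn from the blue palette band, the rest from the
    red-to-green arm. The surround is gray B-mode-like speckle. ``noise_sd``
    adds per-channel Gaussian noise (0 disables). With ``dual_panel`` the
    frame doubles in width, speckle on the left, and carries a panel box.
    """

    height: int = 160
    width: int = 200
    center: tuple[float, float] = (80.0, 100.0)
    semi_axes: tuple[float, float] = (55.0, 75.0)
    rotation_deg: float = 0.0
    target_blue_fraction: float = 0.5
    noise_sd: float = 0.0
    dual_panel: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.target_blue_fraction <= 1.0:
            raise ValueError("target_blue_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        a, b = self.semi_axes
        cy, cx = self.center
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        r = math.hypot(a, b)  # conservative bound for any rotation
        if cy - r < -0.5 or cx - r < -0.5 or cy + r > self.height - 0.5 or cx + r > self.width - 0.5:
            if not self._ellipse_fits():
                raise ValueError("ellipse does not fit inside the image")

    def _ellipse_fits(self) -> bool:
        return bool(self.ellipse_mask().sum()) and not (
            self.ellipse_mask()[0, :].any()
            or self.ellipse_mask()[-1, :].any()
            or self.ellipse_mask()[:, 0].any()
            or self.ellipse_mask()[:, -1].any()
        )

    def ellipse_mask(self) -> np.ndarray:
        """Analytic boolean mask of the ellipse (single-panel coordinates)."""
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        cy, cx = self.center
        theta = math.radians(self.rotation_deg)
        dy, dx = yy - cy, xx - cx
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        a, b = self.semi_axes
        return (u / b) ** 2 + (v / a) ** 2 <= 1.0


class RenderedElastogram(NamedTuple):
    image: Elastogram
    roi: RoiMask
    true_blue_fraction: float
    true_blue_mask: np.ndarray


# Palette geometry: soft pixels get hues on the red->green arm (0°–175°),
# stiff pixels on the blue arm (205°–240°). The 30° gap keeps the default
# classifier band (190°–270°) unambiguous at the soft/stiff boundary.
_SOFT_HUE_MAX = 175.0
_STIFF_HUE_MIN = 205.0
_STIFF_HUE_MAX = 240.0
_PANEL_SAT = 0.9
_PANEL_VAL = 0.9


def render_elastogram(params: ImageSimParams) -> RenderedElastogram:
    """Render a synthetic elastogram with exact ground-truth blue fraction.

    A Gaussian-smoothed random field inside the ellipse plays the role of
    relative stiffness in [0, 1]; the per-image threshold is placed so that
    exactly ``round(target_blue_fraction * area)`` pixels fall in the stiff
    band, which is then mapped to blue hues. The recorded
    ``true_blue_mask`` is the pixel-exact oracle for the classifier.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    ellipse = params.ellipse_mask()
    area = int(ellipse.sum())
    if area == 0:
        raise ValueError("ellipse covers no pixels")

    # smooth continuous field -> negligible probability of ties
    f = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=min(h, w) / 8.0)
    vals = f[ellipse]
    u = (vals - vals.min()) / max(vals.max() - vals.min(), 1e-12)

    k = int(round(params.target_blue_fraction * area))
    order = np.argsort(-u, kind="stable")
    stiff_flat = np.zeros(area, dtype=bool)
    stiff_flat[order[:k]] = True
    u_t = u[order[k - 1]] if 0 < k else 1.0 + 1e-9  # lowest stiff value

    hue = np.empty(area)
    soft = ~stiff_flat
    hue[soft] = _SOFT_HUE_MAX * np.clip(u[soft] / max(u_t, 1e-12), 0.0, 1.0)
    if k:
        span = max(1.0 - u_t, 1e-12)
        hue[stiff_flat] = _STIFF_HUE_MIN + (_STIFF_HUE_MAX - _STIFF_HUE_MIN) * np.clip(
            (u[stiff_flat] - u_t) / span, 0.0, 1.0
        )

    hsv = np.zeros((h, w, 3))
    hsv[ellipse, 0] = hue / 360.0
    hsv[ellipse, 1] = _PANEL_SAT
    hsv[ellipse, 2] = _PANEL_VAL
    panel = (hsv2rgb(hsv) * 255.0).round()

    # gray B-mode-like speckle outside the node (saturation 0 -> never blue)
    speckle = np.clip(rng.normal(70.0, 25.0, size=(h, w)), 0, 255)
    panel[~ellipse] = speckle[~ellipse, None]

    blue_mask = np.zeros((h, w), dtype=bool)
    blue_mask[ellipse] = stiff_flat
    roi_mask = ellipse

    if params.dual_panel:
        bmode = np.clip(rng.normal(70.0, 25.0, size=(h, w)), 0, 255)
        frame = np.concatenate([np.repeat(bmode[..., None], 3, axis=-1), panel], axis=1)
        panel_box: tuple[int, int, int, int] | None = (0, w, h, 2 * w)
        blue_mask = np.concatenate([np.zeros((h, w), dtype=bool), blue_mask], axis=1)
        roi_mask = np.concatenate([np.zeros((h, w), dtype=bool), roi_mask], axis=1)
    else:
        frame = panel
        panel_box = None

    if params.noise_sd > 0:
        frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
    frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    image = Elastogram(pixels=frame, panel_box=panel_box, id=f"sim-{params.seed}")
    return RenderedElastogram(
        image=image,
        roi=RoiMask(mask=roi_mask, source="synthetic"),
        true_blue_fraction=k / area,
        true_blue_mask=blue_mask,
    )


# --------------------------------------------------------------------------
# Synthetic data — cohort simulator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort simulator parameters.

    BCP values are drawn from group-specific normal distributions truncated
    to ``truncation`` by resampling. The parent normal is moment-matched so
    that the truncated distribution has exactly the requested mean and SD:
    the defaults are the published group moments of the observed (hence
    in-range) data, and the simulated cohorts reproduce them. When
    ``subtype_means`` is given, each malignant node is first assigned a
    subtype (weights = observed cohort composition) and draws from the
    subtype-specific mean with the common group SD. Binary B-mode/PET
    features are drawn conditionally on the label from ``feature_model``
    (per-feature sensitivity/specificity pairs); SUV is only measured on a
    ``suv_measured_fraction`` subset, NA elsewhere.
    """

    n_malignant: int = 39
    n_benign: int = 40
    malignant_mean: float = MALIGNANT_BCP_MEAN
    malignant_sd: float = MALIGNANT_BCP_SD
    benign_mean: float = BENIGN_BCP_MEAN
    benign_sd: float = BENIGN_BCP_SD
    truncation: tuple[float, float] = (0.0, 100.0)
    subtype_means: Mapping[str, float] | None = None
    feature_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_MODEL)
    )
    suv_measured_fraction: float = 28 / 79
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant < 0 or self.n_benign < 0:
            raise ValueError("group sizes must be >= 0")
        if self.malignant_sd <= 0 or self.benign_sd <= 0:
            raise ValueError("group SDs must be > 0")
        lo, hi = self.truncation
        if not lo < hi:
            raise ValueError("truncation interval must have positive width")
        if not 0.0 <= self.suv_measured_fraction <= 1.0:
            raise ValueError("suv_measured_fraction must be in [0, 1]")
        for name, (sens, spec) in self.feature_model.items():
            if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
                raise ValueError(f"feature {name!r}: probabilities must be in [0, 1]")


@lru_cache(maxsize=64)
def _matched_parent_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent-normal (mu, sigma) whose [lo, hi]-truncation has the given moments."""
    if not lo < mean < hi:
        raise ValueError("target mean must lie strictly inside the truncation bounds")

    def resid(x: np.ndarray) -> list[float]:
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(resid, np.array([mean, math.log(sd)]))
    if not sol.success:
        raise ValueError(
            f"no truncated normal on [{lo}, {hi}] has mean {mean} and sd {sd}"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _draw_truncated(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Draw n values by resampling a moment-matched parent normal into [lo, hi]."""
    if n == 0:
        return np.empty(0)
    mu, sigma = _matched_parent_params(mean, sd, lo, hi)
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        x = rng.normal(mu, sigma, size=max(2 * (n - got), 16))
        x = x[(x >= lo) & (x <= hi)]
        out.append(x)
        got += x.size
    return np.concatenate(out)[:n]


@dataclass(frozen=True)
class CohortDataset:
    """A validated cohort of lymph-node records.

    Wraps a :class:`pandas.DataFrame` with the canonical column schema; see
    ``COHORT_COLUMNS``. ``suv_gt_2_5`` is tri-state (1/0/NaN for unmeasured).
    """

    records: pd.DataFrame
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns: {missing}")
        if df["node_id"].duplicated().any():
            dup = df.loc[df["node_id"].duplicated(), "node_id"].iloc[0]
            raise ValueError(f"duplicate node_id {dup!r}")
        bad_label = set(df["label"].unique()) - {"benign", "malignant"}
        if bad_label:
            raise ValueError(f"unknown labels: {sorted(bad_label)}")
        if len(df) and (df["bcp_percent"].min() < 0 or df["bcp_percent"].max() > 100):
            raise ValueError("bcp_percent must lie in [0, 100]")
        if len(df) and (df["short_axis_mm"] <= 0).any():
            raise ValueError("short_axis_mm must be positive")
        bad_station = set(df["station"].unique()) - set(STATIONS)
        if bad_station:
            raise ValueError(f"unknown station codes: {sorted(bad_station)}")
        for _, row in df.iterrows():
            sub = row["pathology_subtype"]
            if sub in MALIGNANT_SUBTYPE_MEANS and row["label"] != "malignant":
                raise ValueError(f"subtype {sub!r} inconsistent with label benign")
            if sub in BENIGN_SUBTYPE_MEANS and row["label"] != "benign":
                raise ValueError(f"subtype {sub!r} inconsistent with label malignant")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def scores(self) -> np.ndarray:
        return self.records["bcp_percent"].to_numpy(dtype=float)

    @property
    def is_malignant(self) -> np.ndarray:
        return (self.records["label"] == "malignant").to_numpy()

    @property
    def n_malignant(self) -> int:
        return int(self.is_malignant.sum())

    @property
    def n_benign(self) -> int:
        return len(self) - self.n_malignant


def simulate_cohort(params: CohortSimParams | None = None) -> CohortDataset:
    """Draw a synthetic lymph-node cohort; identical seeds give identical cohorts."""
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.truncation

    rows: dict[str, list] = {c: [] for c in COHORT_COLUMNS}

    def weighted_subtypes(weights: Mapping[str, int], n: int) -> np.ndarray:
        names = list(weights)
        p = np.array([weights[s] for s in names], dtype=float)
        return rng.choice(names, size=n, p=p / p.sum())

    groups = [
        ("malignant", params.n_malignant, params.malignant_mean, params.malignant_sd,
         MALIGNANT_SUBTYPE_WEIGHTS),
        ("benign", params.n_benign, params.benign_mean, params.benign_sd,
         BENIGN_SUBTYPE_WEIGHTS),
    ]
    station_names = list(STATION_WEIGHTS)
    station_p = np.array([STATION_WEIGHTS[s] for s in station_names], dtype=float)
    station_p /= station_p.sum()

    idx = 0
    for label, n, mean, sd, subtype_weights in groups:
        subtypes = weighted_subtypes(subtype_weights, n)
        if params.subtype_means is not None:
            bcp = np.empty(n)
            for sub in np.unique(subtypes):
                sel = subtypes == sub
                m = params.subtype_means.get(str(sub), mean)
                bcp[sel] = _draw_truncated(rng, int(sel.sum()), float(m), sd, lo, hi)
        else:
            bcp = _draw_truncated(rng, n, mean, sd, lo, hi)

        is_mal = label == "malignant"
        for i in range(n):
            idx += 1
            rows["node_id"].append(f"LN{idx:03d}")
            rows["station"].append(str(rng.choice(station_names, p=station_p)))
            rows["pathology_subtype"].append(str(subtypes[i]))
            rows["label"].append(label)
            rows["bcp_percent"].append(float(bcp[i]))

            def draw_flag(name: str) -> int:
                sens, spec = params.feature_model[name]
                p_pos = sens if is_mal else 1.0 - spec
                return int(rng.random() < p_pos)

            size_pos = draw_flag("short_axis_gt_10mm")
            if size_pos:
                rows["short_axis_mm"].append(float(10.0 + rng.gamma(2.0, 2.4)))
            else:
                rows["short_axis_mm"].append(float(rng.uniform(5.0, 10.0)))
            for feat in BINARY_FEATURES:
                rows[feat].append(draw_flag(feat))
            if rng.random() < params.suv_measured_fraction:
                rows["suv_gt_2_5"].append(float(draw_flag("suv_gt_2_5")))
            else:
                rows["suv_gt_2_5"].append(np.nan)

    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return CohortDataset(
        records=df,
        provenance={"kind": "simulated", "seed": params.seed},
    )


def binormal_auc(
    mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float
) -> float:
    """Closed-form AUC of two untruncated normal score distributions.

    ``Phi((mean_pos - mean_neg) / sqrt(sd_pos^2 + sd_neg^2))`` — the
    probability that a random positive scores above a random negative.
    """
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    return float(stats.norm.cdf((mean_pos - mean_neg) / math.hypot(sd_pos, sd_neg)))


# --------------------------------------------------------------------------
# Diagnostics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts with malignant as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one record")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class RocResult:
    """Threshold sweep, AUC with bootstrap CI and Youden-optimal cutoff.

    ``thresholds`` ascend; ``sens``/``spec`` are aligned with them under the
    decision rule *predicted malignant iff score > threshold*, so
    sensitivity is non-increasing and specificity non-decreasing.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    youden_cutoff: float
    youden_j: float


def _sweep(scores: np.ndarray, y: np.ndarray, thresholds: np.ndarray):
    npos = int(y.sum())
    nneg = int((~y).sum())
    sens = np.array([(scores[y] > t).sum() / npos for t in thresholds])
    spec = np.array([(scores[~y] <= t).sum() / nneg for t in thresholds])
    return sens, spec


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Pairwise concordance with ties counted 1/2 (rank formula)."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = pos.size, neg.size
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(
    cohort: CohortDataset, n_boot: int = 2000, seed: int = 0
) -> RocResult:
    """Empirical ROC of BCP for malignancy with bootstrap CI and Youden cutoff.

    Candidate thresholds are the midpoints between consecutive distinct BCP
    values plus sentinels below and above all observations. The AUC is the
    trapezoidal area under the empirical curve, which equals the
    Mann-Whitney concordance with ties counted 1/2. The CI is a stratified
    (label-preserving) bootstrap percentile interval. The Youden cutoff
    maximizes sensitivity + specificity - 1; ties break toward the lowest
    threshold, preserving sensitivity.
    """
    y = cohort.is_malignant
    if y.all() or not y.any():
        raise ValueError("ROC requires both benign and malignant records")
    scores = cohort.scores

    v = np.unique(scores)
    mids = (v[:-1] + v[1:]) / 2.0
    thresholds = np.concatenate([[v[0] - 1.0], mids, [v[-1] + 1.0]])
    sens, spec = _sweep(scores, y, thresholds)

    # order by (fpr, tpr): tied-fpr points must ascend in tpr so the
    # staircase (and the diagonal segments at tied scores) is traced fully
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    pos, neg = scores[y], scores[~y]
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    block = max(1, int(2_000_000 // max(pos.size * neg.size, 1)))
    done = 0
    while done < n_boot:
        b = min(block, n_boot - done)
        bp = rng.choice(pos, size=(b, pos.size))
        bn = rng.choice(neg, size=(b, neg.size))
        gt = (bp[:, :, None] > bn[:, None, :]).mean(axis=(1, 2))
        eq = (bp[:, :, None] == bn[:, None, :]).mean(axis=(1, 2))
        boot[done : done + b] = gt + 0.5 * eq
        done += b
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    j = sens + spec - 1.0
    best = _lowest_argmax(j)
    return RocResult(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        auc_ci_low=float(min(ci_low, auc)),
        auc_ci_high=float(max(ci_high, auc)),
        youden_cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
    )


def _lowest_argmax(j: np.ndarray, tol: float = 1e-9) -> int:
    """First index within tol of the maximum (ties break to the lowest threshold)."""
    return int(np.flatnonzero(j >= j.max() - tol)[0])


def youden_cutoff(roc: RocResult) -> tuple[float, float]:
    """(cutoff, J) maximizing sens + spec - 1; ties -> lowest threshold."""
    j = roc.sens + roc.spec - 1.0
    best = _lowest_argmax(j)
    return float(roc.thresholds[best]), float(j[best])


def classify_at(cohort: CohortDataset, cutoff: float) -> ConfusionTable:
    """Confusion table at a BCP cutoff: malignant iff BCP strictly above it."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = cohort.scores > cutoff
    y = cohort.is_malignant
    return ConfusionTable(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tn=int((~pred & ~y).sum()),
    )


def _pct(num: int, den: int) -> float | None:
    return round(100.0 * num / den, 1) if den > 0 else None


def diagnostic_metrics(t: ConfusionTable) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy, PPV and NPV as one-decimal percents.

    A metric whose denominator is zero is reported as None (undefined), not
    as 0.
    """
    return {
        "sensitivity": _pct(t.tp, t.tp + t.fn),
        "specificity": _pct(t.tn, t.tn + t.fp),
        "accuracy": _pct(t.tp + t.tn, t.total),
        "ppv": _pct(t.tp, t.tp + t.fp),
        "npv": _pct(t.tn, t.tn + t.fn),
    }


def feature_performance(
    cohort: CohortDataset, feature: str
) -> dict[str, float | None]:
    """Sensitivity/specificity of a conventional binary malignancy flag.

    ``short_axis_gt_10mm`` is derived from ``short_axis_mm``; ``suv_gt_2_5``
    is evaluated on the measured (non-NA) subset only; any other name must
    be a 0/1 column of the cohort table.
    """
    df = cohort.records
    if feature in ("short_axis_gt_10mm", "short_axis"):
        values = (df["short_axis_mm"] > 10.0).astype(float)
    elif feature == "suv_gt_2_5":
        values = df["suv_gt_2_5"].astype(float)
    elif feature in df.columns:
        values = df[feature].astype(float)
    else:
        raise ValueError(f"unknown feature {feature!r}")

    defined = values.notna().to_numpy()
    if not defined.any():
        raise ValueError(f"feature {feature!r} undefined for all records")
    y = cohort.is_malignant[defined]
    if y.all() or not y.any():
        raise ValueError(
            f"feature {feature!r} needs measured records of both labels"
        )
    pos = values.to_numpy()[defined] > 0.5
    t = ConfusionTable(
        tp=int((pos & y).sum()),
        fp=int((pos & ~y).sum()),
        fn=int((~pos & y).sum()),
        tn=int((~pos & ~y).sum()),
    )
    m = diagnostic_metrics(t)
    return {"sensitivity": m["sensitivity"], "specificity": m["specificity"]}


def compare_groups(cohort: CohortDataset) -> dict[str, object]:
    """Per-label BCP descriptives and a two-sided Welch test p-value.

    The unequal-variance form is used because the group spreads differ;
    sample SDs use the n-1 denominator.
    """
    df = cohort.records
    out: dict[str, object] = {}
    groups = {}
    for label in ("malignant", "benign"):
        x = df.loc[df["label"] == label, "bcp_percent"].to_numpy(dtype=float)
        if x.size < 2:
            raise ValueError(f"need >= 2 {label} records for the group comparison")
        groups[label] = x
        out[label] = {
            "n": int(x.size),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "min": float(x.min()),
            "max": float(x.max()),
        }
    res = stats.ttest_ind(groups["malignant"], groups["benign"], equal_var=False)
    out["p_value"] = float(res.pvalue)
    return out


def count_below(cohort: CohortDataset, floor_percent: float) -> dict[str, object]:
    """Reporting convenience: nodes with BCP below a floor, and whether all are benign."""
    below = cohort.scores < floor_percent
    return {
        "floor_percent": float(floor_percent),
        "n_below": int(below.sum()),
        "n_total": len(cohort),
        "all_benign": bool((~cohort.is_malignant[below]).all()),
    }


# --------------------------------------------------------------------------
# Cohort / image io and the end-to-end report
# --------------------------------------------------------------------------


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV violates the schema; collects per-row messages."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def write_cohort(dataset: CohortDataset, path: str | Path) -> None:
    df = dataset.records.copy()
    for col in BINARY_FEATURES:
        df[col] = df[col].astype(int)
    df["suv_gt_2_5"] = df["suv_gt_2_5"].map(
        lambda x: "NA" if pd.isna(x) else str(int(x))
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path: str | Path) -> CohortDataset:
    """Read and validate a cohort CSV; schema violations name the offending row."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortSchemaError([f"missing columns: {missing}"])

    problems: list[str] = []
    parsed: dict[str, list] = {c: [] for c in COHORT_COLUMNS}
    for i, row in raw.iterrows():
        line = i + 2  # 1-based file line, after the header
        try:
            bcp = float(row["bcp_percent"])
            if not 0.0 <= bcp <= 100.0:
                raise ValueError(f"bcp_percent {bcp} outside [0, 100]")
            sax = float(row["short_axis_mm"])
            if sax <= 0:
                raise ValueError(f"short_axis_mm {sax} not positive")
            if row["label"] not in ("benign", "malignant"):
                raise ValueError(f"unknown label {row['label']!r}")
            if row["station"] not in STATIONS:
                raise ValueError(f"unknown station {row['station']!r}")
            flags = {}
            for col in BINARY_FEATURES:
                if row[col] not in ("0", "1"):
                    raise ValueError(f"{col} must be 0 or 1, got {row[col]!r}")
                flags[col] = int(row[col])
            suv_raw = row["suv_gt_2_5"]
            if suv_raw in ("NA", ""):
                suv = np.nan
            elif suv_raw in ("0", "1", "0.0", "1.0"):
                suv = float(suv_raw)
            else:
                raise ValueError(f"suv_gt_2_5 must be 0, 1 or NA, got {suv_raw!r}")
        except ValueError as exc:
            problems.append(f"row {line}: {exc}")
            continue
        parsed["node_id"].append(row["node_id"])
        parsed["station"].append(row["station"])
        parsed["pathology_subtype"].append(row["pathology_subtype"])
        parsed["label"].append(row["label"])
        parsed["bcp_percent"].append(bcp)
        parsed["short_axis_mm"].append(sax)
        for col in BINARY_FEATURES:
            parsed[col].append(flags[col])
        parsed["suv_gt_2_5"].append(suv)

    if problems:
        raise CohortSchemaError(problems)
    df = pd.DataFrame(parsed, columns=list(COHORT_COLUMNS))
    return CohortDataset(records=df, provenance={"kind": "file", "path": str(path)})


def read_elastogram(
    path: str | Path,
    panel_box: tuple[int, int, int, int] | None = None,
    image_id: str | None = None,
) -> Elastogram:
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"))
    return Elastogram(
        pixels=px, panel_box=panel_box, id=image_id or Path(path).stem
    )


def write_elastogram(image: Elastogram, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def read_mask(path: str | Path, source: str = "external_file") -> RoiMask:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return RoiMask(mask=arr > 0, source=source)


def write_mask(mask: RoiMask, path: str | Path) -> None:
    Image.fromarray((mask.mask.astype(np.uint8)) * 255, mode="L").save(path)


def batch_images(
    manifest_path: str | Path, config: ColorClassifierConfig | None = None
) -> pd.DataFrame:
    """Process a manifest CSV of image/mask/node_id triples into per-node BCP.

    Runs :func:`compute_bcp` per image and :func:`node_bcp` per node and
    returns a cohort-ready table (node_id, n_images, bcp_percent). Missing
    files raise an error naming the manifest row.
    """
    config = config or ColorClassifierConfig()
    manifest = pd.read_csv(manifest_path, dtype=str)
    for col in ("image", "mask", "node_id"):
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing column {col!r}")

    per_image: dict[str, list[BcpResult]] = {}
    base = Path(manifest_path).parent
    for i, row in manifest.iterrows():
        line = i + 2
        img_path = (base / row["image"]) if not Path(row["image"]).is_absolute() else Path(row["image"])
        mask_path = (base / row["mask"]) if not Path(row["mask"]).is_absolute() else Path(row["mask"])
        for p in (img_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(f"manifest row {line}: file not found: {p}")
        image = read_elastogram(img_path)
        roi = read_mask(mask_path)
        result = compute_bcp(image, roi, config)
        logger.info(
            "image %s node %s: %d blue / %d ROI pixels (BCP %.1f%%)",
            image.id, row["node_id"], result.blue_pixels, result.total_pixels,
            result.bcp_percent,
        )
        per_image.setdefault(row["node_id"], []).append(result)

    rows = [
        {
            "node_id": node,
            "n_images": len(results),
            "bcp_percent": round(100.0 * node_bcp(results), 1),
        }
        for node, results in per_image.items()
    ]
    return pd.DataFrame(rows, columns=["node_id", "n_images", "bcp_percent"])


def analyze_cohort(
    cohort: CohortDataset, config: PipelineConfig | None = None
) -> dict[str, object]:
    """End-to-end diagnostic-accuracy report for one cohort.

    Computes the ROC/AUC with bootstrap CI, selects the Youden cutoff
    (unless overridden), tabulates the confusion matrix and its metrics at
    that cutoff, benchmarks the conventional features and compares the
    group BCP distributions. The result is JSON-serializable.
    """
    config = config or PipelineConfig()
    if len(cohort) == 0:
        raise ValueError("cohort is empty; nothing to analyze")
    roc = roc_curve(cohort, n_boot=config.bootstrap_replicates, seed=config.seed)
    cutoff = (
        config.cutoff_override if config.cutoff_override is not None
        else roc.youden_cutoff
    )
    confusion = classify_at(cohort, cutoff)
    features = {}
    for feat in ("short_axis_gt_10mm", *BINARY_FEATURES, "suv_gt_2_5"):
        try:
            features[feat] = feature_performance(cohort, feat)
        except ValueError as exc:
            features[feat] = {"error": str(exc)}
    report = {
        "n_records": len(cohort),
        "n_malignant": cohort.n_malignant,
        "n_benign": cohort.n_benign,
        "auc": roc.auc,
        "auc_ci": [roc.auc_ci_low, roc.auc_ci_high],
        "youden_cutoff": roc.youden_cutoff,
        "youden_j": roc.youden_j,
        "cutoff_used": float(cutoff),
        "confusion": {
            "tp": confusion.tp, "fp": confusion.fp,
            "fn": confusion.fn, "tn": confusion.tn,
        },
        "metrics": diagnostic_metrics(confusion),
        "feature_table": features,
        "group_stats": compare_groups(cohort),
        "config": {
            "bootstrap_replicates": config.bootstrap_replicates,
            "seed": config.seed,
            "cutoff_override": config.cutoff_override,
        },
    }
    return report


def roc_points_frame(roc: RocResult) -> pd.DataFrame:
    """ROC sweep as a tidy table (threshold, sensitivity, specificity)."""
    return pd.DataFrame(
        {"threshold": roc.thresholds, "sensitivity": roc.sens,
         "specificity": roc.spec}
    )


def write_report(report: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
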