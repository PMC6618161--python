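"""Gray-level calibration and mineralization-density histograms.

Images carry named calibration-standard regions of known material density.
The median gray level of each standard region anchors a least-squares
affine gray->density map; calibrated pixel values of the bone mask are then
binned into fixed-range relative-frequency histograms (16 intervals for
microradiography BMC, 8 intervals for qBSE micromineralization density)
whose CDFs are KS-comparable across genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from skelphen.synthetic import GrayField

__all__ = [
    "CalibrationMap",
    "DensityHistogram",
    "calibrate_gray",
    "bmc_summary",
    "qbse_histogram",
    "relative_bmc",
    "write_gray_field",
    "read_gray_field",
]


@dataclass(frozen=True)
class CalibrationMap:
    """Affine gray->density map fitted through standard-region anchors."""

    gain: float  # density units per gray level
    offset: float  # density at gray 0
    anchors: tuple[tuple[float, float], ...]  # (median gray, known density)
    fit_residual: float  # RMS of anchor residuals

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("calibration needs >= 2 anchors")
        if self.gain <= 0:
            raise ValueError("calibration map must be strictly increasing (gain > 0)")

    def density(self, gray) -> np.ndarray:
        return self.gain * np.asarray(gray, dtype=float) + self.offset


@dataclass(frozen=True)
class DensityHistogram:
    """Fixed-range relative-frequency histogram of calibrated densities."""

    edges: np.ndarray  # n_bins + 1 edges, equal intervals
    frequencies: np.ndarray  # sums to 1
    n_pixels: int
    median: float
    n_clipped_low: int = 0
    n_clipped_high: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "frequencies", freq)
        if edges.size != freq.size + 1:
            raise ValueError("edges must have one more entry than frequencies")
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be > 0")
        if (freq < 0).any() or abs(freq.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be >= 0 and sum to 1")

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.frequencies)


def _region_median(pixels: np.ndarray, rect: tuple[int, int, int, int]) -> float:
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= pixels.shape[0] and 0 <= c0 < c1 <= pixels.shape[1]):
        raise ValueError(f"standard region {rect} outside raster {pixels.shape}")
    patch = pixels[r0:r1, c0:c1]
    if patch.size < 25:
        raise ValueError(f"standard region {rect} has {patch.size} px (< 25)")
    return float(np.median(patch))


def calibrate_gray(
    field: GrayField,
    regions: Optional[Mapping[str, tuple[int, int, int, int]]] = None,
    densities: Optional[Mapping[str, float]] = None,
) -> CalibrationMap:
    """Fit the affine gray->density map from the standard regions.

    Each anchor pairs a standard region's median gray level with its known
    density; the map is the least-squares line through the anchors and must
    be strictly increasing (anchors ordered the same way in gray and in
    density).
    """
    regions = dict(regions if regions is not None else field.standard_regions)
    densities = dict(densities if densities is not None else field.standard_densities)
    if len(regions) < 2:
        raise ValueError("calibration needs >= 2 standard regions")
    anchors = []
    for name, rect in regions.items():
        anchors.append((_region_median(field.pixels, rect), float(densities[name])))
    anchors.sort(key=lambda a: a[1])
    grays = np.array([a[0] for a in anchors])
    dens = np.array([a[1] for a in anchors])
    if np.any(np.diff(grays) <= 0):
        raise ValueError("anchors are not monotone: gray order disagrees with density order")
    gain, offset = np.polyfit(grays, dens, 1)
    resid = dens - (gain * grays + offset)
    return CalibrationMap(
        gain=float(gain),
        offset=float(offset),
        anchors=tuple((float(g), float(d)) for g, d in anchors),
        fit_residual=float(np.sqrt(np.mean(resid**2))),
    )


def _masked_densities(
    pixels: np.ndarray, mask: np.ndarray, cmap: CalibrationMap
) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pixels.shape:
        raise ValueError("mask shape must match image")
    if not mask.any():
        raise ValueError("mask is empty")
    return cmap.density(pixels[mask])


def _histogram(
    values: np.ndarray, value_range: tuple[float, float], n_bins: int
) -> DensityHistogram:
    lo, hi = value_range
    if not hi > lo:
        raise ValueError("histogram range must have hi > lo")
    n_low = int(np.count_nonzero(values < lo))
    n_high = int(np.count_nonzero(values > hi))
    clipped = np.clip(values, lo, hi)  # out-of-range pixels land in end bins
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(clipped, bins=edges)
    return DensityHistogram(
        edges=edges,
        frequencies=counts / values.size,
        n_pixels=int(values.size),
        median=float(np.median(values)),
        n_clipped_low=n_low,
        n_clipped_high=n_high,
    )


def bmc_summary(
    field: GrayField,
    cmap: CalibrationMap,
    mask: Optional[np.ndarray] = None,
    value_range: Optional[tuple[float, float]] = None,
    n_bins: int = 16,
) -> DensityHistogram:
    """16-interval BMC histogram; the median is the specimen's relative BMC.

    ``value_range`` fixes the bin edges so histograms from different
    specimens are KS-comparable; it defaults to the span of the
    calibration anchors.
    """
    mask = field.bone_mask if mask is None else mask
    values = _masked_densities(field.pixels, mask, cmap)
    if value_range is None:
        value_range = (cmap.anchors[0][1], cmap.anchors[-1][1])
    return _histogram(values, value_range, n_bins)


def qbse_histogram(
    field: GrayField,
    cmap: CalibrationMap,
    mask: Optional[np.ndarray] = None,
    value_range: Optional[tuple[float, float]] = None,
    n_bins: int = 8,
) -> DensityHistogram:
    """8-interval micromineralization-density histogram.

    Bins span the two bracketing standard densities by default; pixels
    outside the range are clipped into the end bins and counted in the
    clip totals.
    """
    return bmc_summary(field, cmap, mask=mask, value_range=value_range, n_bins=n_bins)


def relative_bmc(median: float, reference_median: float) -> float:
    """Specimen median scaled by a pooled reference (e.g. WT batch) median."""
    if reference_median <= 0:
        raise ValueError("reference median must be > 0")
    return median / reference_median


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O
# ---------------------------------------------------------------------------


def write_gray_field(field: GrayField, stem: Path) -> dict[str, Path]:
    """Write pixels and bone mask as TIFF plus a JSON region sidecar.

    Coordinates in the sidecar are 0-based, row-major, half-open.
    """
    import tifffile

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    image_path = stem.with_suffix(".tif")
    mask_path = stem.parent / f"{stem.name}_mask.tif"
    sidecar_path = stem.with_suffix(".json")
    tifffile.imwrite(image_path, field.pixels)
    tifffile.imwrite(mask_path, field.bone_mask.astype(np.uint8))
    sidecar = {
        "standard_regions": {k: list(v) for k, v in field.standard_regions.items()},
        "standard_densities": dict(field.standard_densities),
        "bone_mask": mask_path.name,
        "truth": dict(field.truth),
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {"image": image_path, "mask": mask_path, "sidecar": sidecar_path}


def read_gray_field(stem: Path) -> GrayField:
    """Read a gray field written by :func:`write_gray_field`."""
    import tifffile

    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    pixels = tifffile.imread(stem.with_suffix(".tif"))
    mask = tifffile.imread(stem.parent / sidecar["bone_mask"]).astype(bool)
    return GrayField(
        pixels=pixels,
        standard_regions={k: tuple(v) for k, v in sidecar["standard_regions"].items()},
        standard_densities=sidecar["standard_densities"],
        bone_mask=mask,
        truth=sidecar.get("truth", {}),
    )
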