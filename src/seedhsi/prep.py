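"""Reflectance calibration, denoising, segmentation and spectral preprocessing.

The raw-to-model chain is: two-point reflectance calibration against
white/dark references, per-band 3x3 median filtering, thresholding of
the band-mean image into seed regions (with area opening), per-region
mean spectra, and one of the chemometric row transforms (normalisation,
MSC, SNV, Savitzky-Golay derivatives) applied before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .io import (CubeState, ReferenceFrames, SpectralCube, WavelengthGrid,
                 read_table, write_table)

__all__ = [
    "SeedRegion",
    "SpectraTable",
    "PreprocessMethod",
    "PreprocessSpec",
    "calibrate_reflectance",
    "median_filter3",
    "segment_seeds",
    "extract_mean_spectra",
    "apply_preprocess",
]

REFLECTANCE_CLIP = (0.0, 1.2)


@dataclass(frozen=True)
class SeedRegion:
    """A 4-connected seed footprint in (line, pixel) coordinates."""

    region_id: str
    pixels: tuple[np.ndarray, np.ndarray]   # (line indices, pixel indices)
    bbox: tuple[int, int, int, int]         # (l0, l1, p0, p1), half-open
    area: int
    centroid: tuple[float, float]


@dataclass
class SpectraTable:
    """Per-sample mean spectra plus seed metadata.

    ``spectra`` is (samples x bands) on ``grid``; ``meta`` carries one
    row per (seed, side) with columns sample_id, variety, side, label
    and split. Labels may be missing (pd.NA), never a 0/1 sentinel.
    """

    spectra: np.ndarray
    grid: WavelengthGrid
    meta: pd.DataFrame

    _META_COLS = ("sample_id", "variety", "side", "label", "split")

    def __post_init__(self) -> None:
        x = np.asarray(self.spectra, dtype=float)
        if x.ndim != 2 or x.shape[1] != len(self.grid):
            raise ValueError("spectra must be (samples x bands) on the grid")
        if not np.all(np.isfinite(x)):
            raise ValueError("spectra must be finite")
        meta = self.meta.reset_index(drop=True).copy()
        for col, default in (("variety", "V1"), ("side", "A"),
                             ("label", pd.NA), ("split", "unassigned")):
            if col not in meta.columns:
                meta[col] = default
        if "sample_id" not in meta.columns:
            raise ValueError("meta requires a sample_id column")
        if len(meta) != x.shape[0]:
            raise ValueError("meta rows must match spectra rows")
        if meta.duplicated(subset=["sample_id", "side"]).any():
            raise ValueError("duplicate (sample_id, side) rows")
        self.spectra, self.meta = x, meta

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def subset(self, mask: np.ndarray) -> "SpectraTable":
        return SpectraTable(self.spectra[mask], self.grid,
                            self.meta.loc[np.asarray(mask)])

    def labels(self) -> np.ndarray:
        """Integer labels; raises if any are missing."""
        if self.meta["label"].isna().any():
            raise ValueError("table contains unlabeled samples")
        return self.meta["label"].to_numpy(dtype=int)

    def to_csv(self, path: str | Path) -> None:
        band_cols = [f"wl_{w:.1f}" for w in self.grid.centers]
        frame = pd.concat(
            [self.meta[list(self._META_COLS)],
             pd.DataFrame(self.spectra, columns=band_cols)], axis=1)
        write_table(frame, path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        frame = read_table(path)
        band_cols = [c for c in frame.columns if c.startswith("wl_")]
        grid = WavelengthGrid(np.array([float(c[3:]) for c in band_cols]))
        meta = frame[list(cls._META_COLS)]
        return cls(frame[band_cols].to_numpy(dtype=float), grid, meta)


# ---------------------------------------------------------------------------
# Calibration and spatial cleaning


def calibrate_reflectance(raw: SpectralCube, refs: ReferenceFrames,
                          clip: tuple[float, float] = REFLECTANCE_CLIP
                          ) -> SpectralCube:
    """Two-point relative reflectance: (raw - dark) / (white - dark).

    The result is clipped to ``clip`` (default [0, 1.2], tolerating
    sample-vs-Teflon specular excursions) and the cube moves to the
    ``reflectance`` state.
    """
    if raw.state is not CubeState.RAW:
        raise ValueError(f"expected a raw cube, got state '{raw.state.value}'")
    if refs.white.shape != (raw.n_pixels, raw.n_bands):
        raise ValueError("reference frames do not cover the cube extent")
    span = refs.span()
    bad = span <= 0
    if np.any(bad):
        px, bd = np.argwhere(bad)[0]
        raise ValueError(
            f"white - dark is non-positive at pixel {px}, band {bd}"
        )
    cal = (raw.values.astype(float) - refs.dark[None]) / span[None]
    cal = np.clip(cal, *clip)
    return raw.advanced(cal, CubeState.REFLECTANCE,
                        f"reflectance calibration, clip {clip}")


def median_filter3(cube: SpectralCube) -> SpectralCube:
    """3x3 spatial median per band; reflect padding at the image edge."""
    if cube.state is CubeState.RAW:
        raise ValueError("median filter expects a calibrated cube")
    if cube.n_lines < 3 or cube.n_pixels < 3:
        raise ValueError("spatial extent must be at least 3x3")
    out = median_filter(cube.values, size=(3, 3, 1), mode="reflect")
    return cube.advanced(out, cube.state, "3x3 median filter")


def filter_lines_window(lines: np.ndarray) -> np.ndarray:
    """Median-filter the middle line of a 3-line window (streaming helper).

    ``lines`` is (3, pixels, bands); the caller supplies reflect-padded
    neighbours at stream boundaries so the result matches
    :func:`median_filter3` on the full cube exactly.
    """
    return median_filter(lines, size=(3, 3, 1), mode="reflect")[1]


# ---------------------------------------------------------------------------
# Segmentation and extraction


def segment_seeds(cube: SpectralCube, threshold: float, min_area: int,
                  band: int | None = None
                  ) -> tuple[list[SeedRegion], np.ndarray]:
    """Threshold the band-mean (or one band) into 4-connected seed regions.

    Components smaller than ``min_area`` are dropped (area opening).
    Regions come back in scan-line order: sorted by first line reached,
    then first pixel. An empty mask yields an empty list, not an error.
    """
    if cube.state is CubeState.RAW:
        raise ValueError("segmentation expects a calibrated cube")
    score = (cube.values[:, :, band] if band is not None
             else cube.values.mean(axis=2))
    mask = score > threshold
    labelled = cc_label(mask, connectivity=1)
    regions: list[SeedRegion] = []
    clean = np.zeros_like(mask)
    props = sorted(regionprops(labelled),
                   key=lambda r: (r.bbox[0], r.bbox[1]))
    for k, r in enumerate(props):
        if r.area < min_area:
            continue
        coords = (r.coords[:, 0], r.coords[:, 1])
        clean[coords] = True
        regions.append(SeedRegion(
            region_id=f"R{k:04d}",
            pixels=coords,
            bbox=tuple(int(v) for v in r.bbox),
            area=int(r.area),
            centroid=(float(r.centroid[0]), float(r.centroid[1])),
        ))
    return regions, clean


def extract_mean_spectra(cube: SpectralCube, regions: list[SeedRegion],
                         meta: pd.DataFrame | None = None) -> SpectraTable:
    """Arithmetic mean spectrum over each region's pixels."""
    if not all(r.area > 0 for r in regions):
        raise ValueError("cannot extract a mean spectrum from an empty region")
    rows = np.empty((len(regions), cube.n_bands))
    for i, r in enumerate(regions):
        lmax, pmax = r.pixels[0].max(initial=0), r.pixels[1].max(initial=0)
        if lmax >= cube.n_lines or pmax >= cube.n_pixels:
            raise ValueError(f"region {r.region_id} outside cube extent")
        rows[i] = cube.values[r.pixels[0], r.pixels[1], :].mean(axis=0)
    if meta is None:
        meta = pd.DataFrame({"sample_id": [r.region_id for r in regions]})
    return SpectraTable(rows, cube.grid, meta)


# ---------------------------------------------------------------------------
# Chemometric row transforms


class PreprocessMethod(str, Enum):
    NONE = "none"
    MEAN_NORM = "mean_norm"
    MAX_NORM = "max_norm"
    RANGE_NORM = "range_norm"
    MSC = "msc"
    SNV = "snv"
    SG1 = "sg1"
    SG2 = "sg2"


@dataclass(frozen=True)
class PreprocessSpec:
    """One row-wise transform plus its parameters.

    Savitzky-Golay derivatives differentiate with respect to the band
    index (delta = 1 sample); window must be odd and larger than the
    polynomial order. MSC needs a frozen reference spectrum — by
    convention the calibration-split mean.
    """

    method: PreprocessMethod = PreprocessMethod.NONE
    sg_window: int = 11
    sg_order: int = 2
    msc_reference: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", PreprocessMethod(self.method))
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("SG window must be odd and > polynomial order")
        if (self.method is PreprocessMethod.MSC) != (self.msc_reference is not None):
            raise ValueError("MSC reference present iff method is msc")

    def describe(self) -> str:
        if self.method in (PreprocessMethod.SG1, PreprocessMethod.SG2):
            return f"{self.method.value}(window={self.sg_window}, order={self.sg_order})"
        return self.method.value


def _valid_rows(spec: PreprocessSpec, X: np.ndarray) -> np.ndarray:
    """Rows on which the transform is well-defined (used per-pixel)."""
    m = spec.method
    if m is PreprocessMethod.SNV:
        return X.std(axis=1, ddof=1) > 0
    if m is PreprocessMethod.RANGE_NORM:
        return X.max(axis=1) > X.min(axis=1)
    if m is PreprocessMethod.MAX_NORM:
        return X.max(axis=1) > 0
    if m is PreprocessMethod.MEAN_NORM:
        return X.mean(axis=1) != 0
    return np.ones(X.shape[0], dtype=bool)


def apply_preprocess(spec: PreprocessSpec, X: np.ndarray) -> np.ndarray:
    """Apply the transform row-wise to a (samples x bands) matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = spec.method
    if m is PreprocessMethod.NONE:
        return X.copy()
    if m is PreprocessMethod.MEAN_NORM:
        mu = X.mean(axis=1, keepdims=True)
        if np.any(mu == 0):
            raise ValueError("mean normalisation undefined for zero-mean row")
        return X / mu
    if m is PreprocessMethod.MAX_NORM:
        mx = X.max(axis=1, keepdims=True)
        if np.any(mx <= 0):
            raise ValueError("max normalisation undefined for max <= 0")
        return X / mx
    if m is PreprocessMethod.RANGE_NORM:
        mn, mx = X.min(axis=1, keepdims=True), X.max(axis=1, keepdims=True)
        if np.any(mx == mn):
            raise ValueError("range normalisation undefined for constant row")
        return (X - mn) / (mx - mn)
    if m is PreprocessMethod.SNV:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)  # sample (n-1) convention
        if np.any(sd == 0):
            raise ValueError("SNV undefined for zero-variance row")
        return (X - mu) / sd
    if m is PreprocessMethod.MSC:
        ref = np.asarray(spec.msc_reference, dtype=float)
        if ref.shape != (X.shape[1],):
            raise ValueError("MSC reference length must equal band count")
        rc = ref - ref.mean()
        denom = float(rc @ rc)
        if denom == 0:
            raise ValueError("MSC reference is constant")
        a = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
        if np.any(a == 0):
            raise ValueError("MSC undefined for row orthogonal to reference")
        b = X.mean(axis=1) - a * ref.mean()
        return (X - b[:, None]) / a[:, None]
    if m in (PreprocessMethod.SG1, PreprocessMethod.SG2):
        deriv = 1 if m is PreprocessMethod.SG1 else 2
        if X.shape[1] < spec.sg_window:
            raise ValueError("row shorter than SG window")
        return savgol_filter(X, spec.sg_window, spec.sg_order, deriv=deriv,
                             axis=1, mode="interp")
    raise ValueError(f"unknown method {m}")  # pragma: no cover
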