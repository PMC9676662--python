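"""Pixel-wise chemical imaging and per-seed decisions.

A fitted PLS-DA model is projected through every masked pixel's
spectrum (after replaying the model's row preprocessing per pixel),
giving a continuous viability map. The map is binarised at the model's
decision threshold, speckle is removed by morphological area opening,
and each seed region is called viable when its viable-pixel fraction
reaches a configurable cut (default one half).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.measure import label as cc_label

from .io import SpectralCube
from .plsda import PLSDAModel, predict_scores
from .prep import SeedRegion, _valid_rows, apply_preprocess

__all__ = [
    "ChemicalImage",
    "predict_pixelwise",
    "binarize",
    "area_open",
    "seed_decision",
    "render_outputs",
]

# Score assigned to pixels whose spectrum breaks the row transform
# (e.g. zero variance under SNV); far below any decision threshold.
SCORE_FLOOR = 0.0


@dataclass
class ChemicalImage:
    """Per-pixel viability score map over a seed mask.

    ``prediction`` is finite exactly on ``mask`` (NaN elsewhere);
    ``binary`` is the thresholded viable map, always a subset of the
    mask. ``anomalies`` counts pixels whose preprocessing failed and
    were floored to nonviable.
    """

    prediction: np.ndarray
    mask: np.ndarray
    binary: np.ndarray | None = None
    threshold: float | None = None
    anomalies: int = 0

    def __post_init__(self) -> None:
        if self.prediction.shape != self.mask.shape:
            raise ValueError("prediction and mask shapes differ")
        on = np.isfinite(self.prediction[self.mask]) if self.mask.any() else True
        if not np.all(on):
            raise ValueError("prediction must be finite on the mask")
        if self.binary is not None and np.any(self.binary & ~self.mask):
            raise ValueError("binary map must be a subset of the mask")


def predict_pixelwise(model: PLSDAModel, cube: SpectralCube,
                      mask: np.ndarray) -> ChemicalImage:
    """Score every masked pixel through the model's preprocessing + b."""
    if mask.shape != cube.values.shape[:2]:
        raise ValueError("mask does not match cube spatial extent")
    prediction = np.full(mask.shape, np.nan)
    lines, pixels = np.nonzero(mask)
    anomalies = 0
    if lines.size:
        spectra = cube.values[lines, pixels, :].astype(float)
        if model.preprocess is not None:
            ok = _valid_rows(model.preprocess, spectra)
            anomalies = int(np.sum(~ok))
            scores = np.full(lines.size, SCORE_FLOOR)
            if ok.any():
                scores[ok] = predict_scores(
                    model, apply_preprocess(model.preprocess, spectra[ok]))
        else:
            scores = predict_scores(model, spectra)
        prediction[lines, pixels] = scores
    return ChemicalImage(prediction, mask.astype(bool), anomalies=anomalies)


def binarize(image: ChemicalImage, threshold: float) -> ChemicalImage:
    """Viable map: prediction strictly above t, within the mask."""
    with np.errstate(invalid="ignore"):
        binary = (image.prediction > threshold) & image.mask
    return replace(image, binary=binary, threshold=threshold)


def area_open(binary: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 4-connected components smaller than ``min_area`` pixels."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    binary = np.asarray(binary, dtype=bool)
    if min_area == 1:
        return binary.copy()
    labelled = cc_label(binary, connectivity=1)
    counts = np.bincount(labelled.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labelled]


def seed_decision(cleaned: np.ndarray, region: SeedRegion,
                  viable_fraction: float = 0.5) -> int:
    """1 iff the region's viable-pixel fraction reaches ``viable_fraction``."""
    if not (0.0 < viable_fraction <= 1.0):
        raise ValueError("viable_fraction must lie in (0, 1]")
    ll, pp = region.pixels
    if ll.max(initial=0) >= cleaned.shape[0] or pp.max(initial=0) >= cleaned.shape[1]:
        raise ValueError(f"region {region.region_id} outside map extent")
    frac = float(cleaned[ll, pp].sum()) / region.area
    return int(frac >= viable_fraction)


def render_outputs(image: ChemicalImage, regions: list[SeedRegion],
                   decisions: list[int], out_dir: str | Path) -> list[Path]:
    """Write heat map, binary map, and an annotated overlay as PNGs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(6, 6 * image.mask.shape[0] / max(image.mask.shape[1], 1)))
    im = ax.imshow(image.prediction, cmap="RdYlBu_r", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="PLS-DA score (1 = viable)")
    ax.set_title("Pixel-wise viability prediction")
    p = out / "prediction.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    binary = image.binary if image.binary is not None else np.zeros_like(image.mask)
    fig, ax = plt.subplots()
    ax.imshow(binary, cmap="gray", vmin=0, vmax=1)
    ax.set_title("Binary viability map")
    p = out / "binary.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots()
    ax.imshow(image.mask, cmap="gray", vmin=0, vmax=1)
    for region, dec in zip(regions, decisions):
        cy, cx = region.centroid
        ax.annotate(f"{region.region_id}:{'V' if dec else 'N'}", (cx, cy),
                    color="lime" if dec else "red", fontsize=7,
                    ha="center", va="center")
    ax.set_title("Per-seed decisions")
    p = out / "overlay.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
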