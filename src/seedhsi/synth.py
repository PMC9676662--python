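"""Synthetic line-scan scenes of watermelon seeds with known ground truth.

The generator emulates what a pushbroom NIR camera over a conveyor belt
records: elliptical seed footprints on a dark belt, a smooth lamp
profile, dark current with fixed-pattern noise, per-seed multiplicative
scatter and additive baseline shifts, and shot-like sensor noise.

Two seed classes (viable / nonviable) differ in a latent chemistry
triple — carbohydrate, protein, moisture on a 0-1 scale — that drives
three Gaussian absorption features near 1415, 1475 and 1605 nm
(C-H, N-H and O-H first-overtone bands) plus a broad intensity deficit
of the nonviable class between 1425 and 1670 nm. Linked assay tables
(germination outcome, wet/dry weight, chromatographic peak areas) are
drawn from the same latent chemistry, so classifier output can be
checked against germination and composition downstream.

All randomness flows through a single :class:`numpy.random.Generator`;
identical seeds give identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CubeState, ReferenceFrames, SpectralCube, WavelengthGrid

__all__ = [
    "AbsorptionFeature",
    "EndmemberSpec",
    "AssayParams",
    "SeedTruth",
    "SceneTruth",
    "default_grid",
    "make_endmembers",
    "seed_spectrum",
    "render_scene",
    "emit_assay_tables",
    "simulate_dataset",
    "sample_truth",
]

# Class-conditional means of the latent chemistry triple.
VIABLE_CHEM_MEAN = 0.70
NONVIABLE_CHEM_MEAN = 0.40
CHEM_SD = 0.10

_CHEM_NAMES = ("carbohydrate", "protein", "moisture")


def default_grid(n_bands: int = 128) -> WavelengthGrid:
    """Evenly spaced band centers spanning the 900-1700 nm camera range."""
    return WavelengthGrid(np.linspace(903.0, 1697.0, n_bands))


@dataclass(frozen=True)
class AbsorptionFeature:
    """One Gaussian absorption valley tied to a chemistry component."""

    center_nm: float
    width_nm: float
    depth_viable: float     # valley depth at the viable-class chemistry mean
    depth_nonviable: float  # shallower valley at the nonviable mean
    component: str          # which chemistry level modulates the depth


@dataclass(frozen=True)
class EndmemberSpec:
    """Parametric model of the two class reflectance spectra.

    ``contrast`` scales every viable-vs-nonviable difference (feature
    depth gaps and the broad intensity deficit); at 0 the classes are
    spectrally identical, at 1 they sit at the documented defaults.
    """

    features: tuple[AbsorptionFeature, ...] = (
        AbsorptionFeature(1415.0, 9.0, 0.15, 0.08, "carbohydrate"),
        AbsorptionFeature(1475.0, 9.0, 0.13, 0.06, "protein"),
        AbsorptionFeature(1605.0, 9.0, 0.17, 0.10, "moisture"),
    )
    base_level: float = 0.52
    base_slope: float = 0.06        # gentle reflectance rise across the range
    deficit_depth: float = 0.022    # nonviable broad intensity deficit
    deficit_lo_nm: float = 1425.0
    deficit_hi_nm: float = 1670.0
    deficit_edge_nm: float = 18.0   # softness of the deficit window edges
    contrast: float = 1.0

    def __post_init__(self) -> None:
        centers = {f.center_nm for f in self.features}
        for must in (1415.0, 1475.0, 1605.0):
            if must not in centers:
                raise ValueError(f"features must include a {must:.0f} nm band")
        for f in self.features:
            if f.depth_nonviable > f.depth_viable:
                raise ValueError(
                    f"nonviable depth must not exceed viable depth at {f.center_nm} nm"
                )
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


def _baseline(spec: EndmemberSpec, wl: np.ndarray) -> np.ndarray:
    x = (wl - 900.0) / 800.0
    return spec.base_level + spec.base_slope * x


def _deficit_window(spec: EndmemberSpec, wl: np.ndarray) -> np.ndarray:
    """Smooth plateau ~1 inside [deficit_lo, deficit_hi], ~0 outside."""
    from scipy.special import expit

    lo = expit((wl - spec.deficit_lo_nm) / spec.deficit_edge_nm)
    hi = expit((spec.deficit_hi_nm - wl) / spec.deficit_edge_nm)
    return lo * hi


def seed_spectrum(spec: EndmemberSpec, grid: WavelengthGrid,
                  chem: np.ndarray) -> np.ndarray:
    """Reflectance spectrum of a seed with chemistry triple ``chem``.

    Feature depths interpolate linearly in the matching chemistry level
    between the class means; the broad deficit scales with the distance
    of the mean chemistry below the viable mean. ``spec.contrast``
    multiplies both class-difference terms.
    """
    chem = np.asarray(chem, dtype=float)
    if chem.shape != (3,):
        raise ValueError("chemistry triple must have 3 components")
    wl = grid.centers
    r = _baseline(spec, wl).copy()
    span = VIABLE_CHEM_MEAN - NONVIABLE_CHEM_MEAN
    for f in spec.features:
        if not (wl[0] <= f.center_nm <= wl[-1]):
            raise ValueError(f"feature center {f.center_nm} nm outside grid")
        level = chem[_CHEM_NAMES.index(f.component)]
        gap = spec.contrast * (f.depth_viable - f.depth_nonviable)
        # depth at the nonviable mean stays depth_nonviable for any contrast
        depth = f.depth_viable - gap + gap * (level - NONVIABLE_CHEM_MEAN) / span
        r -= depth * np.exp(-0.5 * ((wl - f.center_nm) / f.width_nm) ** 2)
    mean_chem = float(chem.mean())
    deficit = (spec.contrast * spec.deficit_depth
               * np.clip((VIABLE_CHEM_MEAN - mean_chem) / span, 0.0, None))
    r -= deficit * _deficit_window(spec, wl)
    return np.clip(r, 1e-3, 1.0 - 1e-3)


def make_endmembers(spec: EndmemberSpec, grid: WavelengthGrid
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Class mean spectra (viable, nonviable) at the class chemistry means."""
    viable = seed_spectrum(spec, grid, np.full(3, VIABLE_CHEM_MEAN))
    nonviable = seed_spectrum(spec, grid, np.full(3, NONVIABLE_CHEM_MEAN))
    return viable, nonviable


# ---------------------------------------------------------------------------
# Scene truth


@dataclass
class SeedTruth:
    seed_id: str
    label: int                       # 1 viable, 0 nonviable
    chem: np.ndarray                 # (3,) latent chemistry
    germination: int                 # 0/1 outcome of the emulated assay
    center: tuple[float, float]      # (line, pixel)
    radii: tuple[float, float]       # (line halfaxis, pixel halfaxis)
    footprint: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    @property
    def viability_score(self) -> float:
        return float(self.chem.mean())


@dataclass
class SceneTruth:
    seeds: list[SeedTruth]
    shape: tuple[int, int]           # (lines, pixels)
    label_map: np.ndarray = field(repr=False, default=None)  # -1 = belt

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.seeds], dtype=int)


def _germination_probability(score: float) -> float:
    """Monotone link from latent viability score to germination odds."""
    return float(1.0 / (1.0 + np.exp(-10.0 * (score - 0.55))))


def sample_truth(n_seeds: int, rng: np.random.Generator | int = 0,
                 viable_fraction: float = 0.5) -> SceneTruth:
    """Draw per-seed truth (class, chemistry, germination) without a scene.

    Used when only the linked assay tables are needed; footprints and
    centers are left unset.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n_viable = int(round(viable_fraction * n_seeds))
    labels = np.array([1] * n_viable + [0] * (n_seeds - n_viable))
    rng.shuffle(labels)
    seeds = []
    for k in range(n_seeds):
        lab = int(labels[k])
        mean = VIABLE_CHEM_MEAN if lab == 1 else NONVIABLE_CHEM_MEAN
        chem = np.clip(rng.normal(mean, CHEM_SD, size=3), 0.02, 0.98)
        germ = int(rng.random() < _germination_probability(float(chem.mean())))
        seeds.append(SeedTruth(f"S{k:04d}", lab, chem, germ,
                               (float("nan"), float("nan")),
                               (float("nan"), float("nan"))))
    return SceneTruth(seeds, (0, 0))


def _layout(n_seeds: int, n_pixels: int, cell: tuple[int, int],
            margin: int, rng: np.random.Generator
            ) -> tuple[int, list[tuple[float, float]]]:
    """Jittered-grid seed centers; guarantees disjoint footprints."""
    ch, cw = cell
    n_cols = (n_pixels - 2 * margin) // cw
    if n_cols < 1:
        raise ValueError(
            f"cannot place seeds: frame width {n_pixels} px too small for "
            f"cell width {cw} px plus margins"
        )
    n_rows = -(-n_seeds // n_cols)
    n_lines = n_rows * ch + 2 * margin
    centers = []
    for k in range(n_seeds):
        r, c = divmod(k, n_cols)
        jl = rng.uniform(-1.5, 1.5)
        jp = rng.uniform(-1.5, 1.5)
        centers.append((margin + ch * (r + 0.5) + jl, margin + cw * (c + 0.5) + jp))
    return n_lines, centers


def render_scene(
    n_seeds: int,
    spec: EndmemberSpec,
    rng: np.random.Generator | int,
    grid: WavelengthGrid | None = None,
    n_pixels: int = 160,
    viable_fraction: float = 0.5,
    scatter_sigma: float = 0.05,
    baseline_sigma: float = 0.01,
    tilt_sigma: float = 0.005,
    noise_counts: float = 8.0,
    belt_reflectance: float = 0.06,
    dark_level: float = 100.0,
    lamp_peak_counts: float = 3000.0,
    side: str = "A",
    side_offset: float = 0.01,
    truth: SceneTruth | None = None,
) -> tuple[SpectralCube, ReferenceFrames, SceneTruth]:
    """Render one raw-count scene plus its reference frames and truth.

    When ``truth`` is given, the same seeds (chemistry, footprints,
    germination) are re-rendered with fresh scatter and noise draws —
    this is how the second camera side of a batch is produced. Side "B"
    additionally applies a small reflectance offset, emulating the seed
    face turned toward the camera.

    Raw counts follow ``dark + (white - dark) * (a * R_seed + b + tilt)``
    per pixel, quantised to uint16, so two-point calibration exactly
    inverts the gain model up to rounding.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    grid = grid or default_grid()
    wl = grid.centers
    n_bands = len(grid)

    # seed geometry: watermelon-seed-like ellipses, aspect ~1.5-2 along scan
    max_rl, max_rp = 9.0, 5.0
    cell = (int(2 * max_rl + 7), int(2 * max_rp + 7))

    if truth is None:
        n_lines, centers = _layout(n_seeds, n_pixels, cell, margin=4, rng=rng)
        seeds: list[SeedTruth] = []
        n_viable = int(round(viable_fraction * n_seeds))
        labels = np.array([1] * n_viable + [0] * (n_seeds - n_viable))
        rng.shuffle(labels)
        for k in range(n_seeds):
            lab = int(labels[k])
            mean = VIABLE_CHEM_MEAN if lab == 1 else NONVIABLE_CHEM_MEAN
            chem = np.clip(rng.normal(mean, CHEM_SD, size=3), 0.02, 0.98)
            rl = rng.uniform(7.0, max_rl)
            rp = rng.uniform(rl / 2.0, rl / 1.5)  # aspect 1.5-2.0
            germ = int(rng.random() < _germination_probability(float(chem.mean())))
            seeds.append(SeedTruth(f"S{k:04d}", lab, chem, germ,
                                   centers[k], (rl, min(rp, max_rp))))
        truth = SceneTruth(seeds, (n_lines, n_pixels))
    else:
        truth = SceneTruth([replace(s) for s in truth.seeds], truth.shape)
        n_lines = truth.shape[0]
        if truth.shape[1] != n_pixels:
            n_pixels = truth.shape[1]

    # rasterise footprints and the truth label map
    label_map = np.full((n_lines, n_pixels), -1, dtype=int)
    ll, pp = np.mgrid[0:n_lines, 0:n_pixels]
    for idx, s in enumerate(truth.seeds):
        cl, cp = s.center
        rl, rp = s.radii
        inside = ((ll - cl) / rl) ** 2 + ((pp - cp) / rp) ** 2 <= 1.0
        if np.any(label_map[inside] != -1):
            raise ValueError("seed footprints overlap; layout failed")
        label_map[inside] = idx
        s.footprint = np.nonzero(inside)
    truth.label_map = label_map

    # reflectance scene
    refl = np.empty((n_lines, n_pixels, n_bands))
    refl[:] = belt_reflectance
    tilt_axis = (wl - wl.mean()) / (wl[-1] - wl[0])
    for idx, s in enumerate(truth.seeds):
        spectrum = seed_spectrum(spec, grid, s.chem)
        a = float(np.exp(rng.normal(0.0, scatter_sigma)))
        b = float(rng.normal(0.0, baseline_sigma))
        tilt = float(rng.normal(0.0, tilt_sigma))
        off = float(rng.normal(0.0, side_offset)) if side == "B" else 0.0
        refl[s.footprint[0], s.footprint[1], :] = (
            a * spectrum + b + off + tilt * tilt_axis
        )

    # radiometry: lamp hump, dark current with fixed-pattern noise
    lamp = lamp_peak_counts * np.exp(-(((wl - 1300.0) / 350.0) ** 2))
    pixel_gain = 1.0 + 0.01 * rng.standard_normal(n_pixels)
    dark = np.clip(
        dark_level + 2.0 * rng.standard_normal((n_pixels, n_bands)), 0, None
    )
    white = dark + np.outer(pixel_gain, lamp)

    counts = dark[None, :, :] + (white - dark)[None, :, :] * refl
    if noise_counts > 0:
        counts = counts + rng.normal(0.0, noise_counts, size=counts.shape)
    counts = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)

    cube = SpectralCube(
        counts, grid, CubeState.RAW,
        [f"synthetic scene: {n_seeds} seeds, side {side}, "
         f"contrast {spec.contrast:g}"],
    )
    return cube, ReferenceFrames(white, dark), truth


# ---------------------------------------------------------------------------
# Linked assay tables


@dataclass(frozen=True)
class AssayParams:
    """Emulated wet-lab measurement model.

    Moisture fraction and chromatographic peak areas are affine in the
    matching chemistry level; ``noise_scale`` multiplies both the
    seed-to-seed chemistry spread and the measurement noise, so 0 gives
    deterministic class-conditional values.
    """

    wet_weight_g: float = 0.060        # typical triploid watermelon seed
    weight_cv: float = 0.08
    moisture_base: float = 0.04        # water mass fraction at chemistry 0
    moisture_gain: float = 0.08
    moisture_noise: float = 0.004
    area_base: float = 12.0            # HPLC peak area % at chemistry 0
    area_gain: float = 30.0
    area_noise: float = 1.5
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise scale must be >= 0")


def emit_assay_tables(truth: SceneTruth, params: AssayParams = AssayParams(),
                      rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Per-seed assay table: weights, moisture, peak areas, germination."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    rows = []
    for s in truth.seeds:
        class_mean = VIABLE_CHEM_MEAN if s.label == 1 else NONVIABLE_CHEM_MEAN
        # chemistry as seen by the assay: class mean plus scaled seed deviation
        eff = class_mean + params.noise_scale * (s.chem - class_mean)
        frac = (params.moisture_base + params.moisture_gain * eff[2]
                + params.noise_scale * rng.normal(0.0, params.moisture_noise))
        frac = float(np.clip(frac, 0.0, 0.9))
        wet = params.wet_weight_g * (
            1.0 + params.noise_scale * rng.normal(0.0, params.weight_cv))
        wet = max(wet, 1e-4)
        dry = wet * (1.0 - frac)
        carb = (params.area_base + params.area_gain * eff[0]
                + params.noise_scale * rng.normal(0.0, params.area_noise))
        prot = (params.area_base + params.area_gain * eff[1]
                + params.noise_scale * rng.normal(0.0, params.area_noise))
        rows.append({
            "sample_id": s.seed_id,
            "label": s.label,
            "germination": s.germination,
            "wet_weight_g": wet,
            "dry_weight_g": dry,
            "carbohydrate_area_pct": max(carb, 0.0),
            "protein_area_pct": max(prot, 0.0),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Batch helper


def simulate_dataset(
    n_per_class: int,
    spec: EndmemberSpec,
    rng: np.random.Generator | int,
    seeds_per_scene: int = 50,
    sides: tuple[str, ...] = ("A", "B"),
    **render_kwargs,
):
    """Yield ``(side, cube, refs, truth)`` scenes covering both camera sides.

    Seeds are split across scenes of ``seeds_per_scene`` so individual
    cubes stay small; each scene is rendered once per requested side
    with shared truth (same seeds, fresh scatter and noise).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    total = 2 * n_per_class
    offset = 0
    while total > 0:
        n = min(seeds_per_scene, total)
        cube, refs, truth = render_scene(n, spec, rng, side=sides[0],
                                         **render_kwargs)
        for s in truth.seeds:  # globally unique ids across scenes
            s.seed_id = f"S{offset + int(s.seed_id[1:]):04d}"
        yield sides[0], cube, refs, truth
        for side in sides[1:]:
            cube_b, refs_b, truth_b = render_scene(
                n, spec, rng, side=side, truth=truth, **render_kwargs)
            yield side, cube_b, refs_b, truth_b
        offset += n
        total -= n
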