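"""Cube and table I/O for the line-scan NIR imaging pipeline.

Hyperspectral cubes travel on disk as an ENVI-style pair: a small text
header (``.hdr``) describing shape, interleave, dtype and the wavelength
grid, next to a raw band-interleaved-by-line (BIL) binary (``.bil``).
Tables (per-seed spectra, assays, reports) are plain UTF-8 CSV with a
header row. A :class:`RunConfig` bundles the rig parameters (belt speed,
exposure, frame height) and the pipeline thresholds, serialised as YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HSIIOError",
    "WavelengthGrid",
    "CubeState",
    "SpectralCube",
    "ReferenceFrames",
    "RunConfig",
    "read_cube",
    "write_cube",
    "read_table",
    "write_table",
]


class HSIIOError(IOError):
    """Raised when an on-disk cube or table violates its contract.

    The message always names the offending field (header key, column,
    pixel/band index) so the failure is actionable.
    """


# ENVI numeric codes for the dtypes the pipeline produces.
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WavelengthGrid:
    """Band-center wavelengths in nm, strictly increasing within 900-1700."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.ndim != 1 or c.size < 8:
            raise ValueError("wavelength grid needs >= 8 band centers")
        if not np.all(np.diff(c) > 0):
            raise ValueError("wavelength centers must be strictly increasing")
        if c[0] < 900.0 or c[-1] > 1700.0:
            raise ValueError("wavelength centers must lie within [900, 1700] nm")

    def __len__(self) -> int:
        return int(self.centers.size)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band center nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))

    def window(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean band mask for centers in the closed interval [lo, hi]."""
        return (self.centers >= lo_nm) & (self.centers <= hi_nm)


class CubeState(str, Enum):
    RAW = "raw"
    REFLECTANCE = "reflectance"
    PREPROCESSED = "preprocessed"


_STATE_ORDER = [CubeState.RAW, CubeState.REFLECTANCE, CubeState.PREPROCESSED]


@dataclass
class SpectralCube:
    """A (lines x pixels x bands) radiometric array with provenance.

    ``state`` records where the cube sits in the raw -> reflectance ->
    preprocessed chain; transitions may only move forward. ``provenance``
    is an append-only audit trail of the transforms applied.
    """

    values: np.ndarray
    grid: WavelengthGrid
    state: CubeState = CubeState.RAW
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("cube values must be 3-D (lines, pixels, bands)")
        if v.shape[2] != len(self.grid):
            raise ValueError(
                f"band axis length {v.shape[2]} != wavelength count {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("cube values must all be finite")
        self.values = v
        self.state = CubeState(self.state)

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def advanced(self, values: np.ndarray, state: CubeState, note: str) -> "SpectralCube":
        """Return a new cube one step further along the state chain."""
        new, old = CubeState(state), self.state
        if _STATE_ORDER.index(new) < _STATE_ORDER.index(old):
            raise ValueError(f"illegal state transition {old.value} -> {new.value}")
        return SpectralCube(values, self.grid, new, [*self.provenance, note])

    def with_note(self, note: str) -> "SpectralCube":
        """Same state, appended provenance (state-preserving transforms)."""
        return SpectralCube(self.values, self.grid, self.state,
                            [*self.provenance, note])


@dataclass
class ReferenceFrames:
    """White (Teflon) and dark (shuttered) reference frames, pixels x bands."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.white, dtype=float)
        d = np.asarray(self.dark, dtype=float)
        if w.shape != d.shape or w.ndim != 2:
            raise ValueError("white and dark frames must be 2-D with equal shape")
        self.white, self.dark = w, d

    def span(self) -> np.ndarray:
        """white - dark; must be strictly positive wherever calibration uses it."""
        return self.white - self.dark


@dataclass
class RunConfig:
    """Rig and pipeline configuration.

    Belt speed and exposure reproduce the line-scan geometry: the belt
    advances ``belt_speed * exposure / 1000`` mm per acquired line, which
    fixes the simulated line rate used by throughput reporting.
    """

    belt_speed: float = 49.0      # mm/s along the scan direction
    exposure: float = 17.0        # ms per line
    frame_height: int = 64        # lines per processing frame
    seg_threshold: float = 0.2    # band-mean reflectance cut for the seed mask
    min_area: int = 20            # px; segmentation and area-opening floor
    decision_threshold: float = 0.5
    viable_fraction: float = 0.5  # per-seed viable-pixel fraction rule
    nozzle_distance: float = 150.0  # mm from FOV exit to the suction nozzle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.belt_speed <= 0:
            raise ValueError("belt_speed must be > 0")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")
        if self.frame_height < 1:
            raise ValueError("frame_height must be >= 1")

    @property
    def line_pitch_mm(self) -> float:
        """Belt advance per scan line."""
        return self.belt_speed * self.exposure / 1000.0

    @property
    def lines_per_second(self) -> float:
        return 1000.0 / self.exposure

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# ENVI header + BIL binary container


def _paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix in {".hdr", ".bil"} else p
    return stem.with_suffix(".hdr"), stem.with_suffix(".bil")


def write_cube(cube: SpectralCube, path: str | Path) -> None:
    """Write ``<path>.hdr`` + ``<path>.bil``; round-trips bit-exactly."""
    hdr_path, bil_path = _paths(path)
    dtype = np.dtype(cube.values.dtype)
    if dtype not in _DTYPE_CODES:
        raise HSIIOError(f"unsupported cube dtype {dtype}")
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.centers)
    prov = "; ".join(cube.provenance) if cube.provenance else "none"
    hdr = (
        "ENVI\n"
        f"description = {{{prov}}}\n"
        f"samples = {cube.n_pixels}\n"
        f"lines = {cube.n_lines}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        "interleave = bil\n"
        "byte order = 0\n"
        f"seedhsi state = {cube.state.value}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    hdr_path.write_text(hdr)
    # BIL layout: line-major, band-middle, pixel-minor
    np.ascontiguousarray(
        cube.values.transpose(0, 2, 1).astype(dtype, copy=False)
    ).tofile(bil_path)


def _parse_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    key, buf, in_block = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if in_block:
            buf.append(line)
            if line.endswith("}"):
                fields[key] = " ".join(buf).rstrip("}").strip()
                in_block = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and not val.endswith("}"):
            buf, in_block = [val.lstrip("{").strip()], True
        else:
            fields[key] = val.strip("{} ")
    return fields


def read_cube(path: str | Path) -> SpectralCube:
    """Read an ENVI-style ``.hdr``/``.bil`` pair written by :func:`write_cube`."""
    hdr_path, bil_path = _paths(path)
    if not hdr_path.exists():
        raise HSIIOError(f"missing header file {hdr_path}")
    if not bil_path.exists():
        raise HSIIOError(f"missing binary file {bil_path}")
    fields = _parse_header(hdr_path.read_text())
    for req in ("samples", "lines", "bands", "data type", "interleave", "wavelength"):
        if req not in fields:
            raise HSIIOError(f"header missing required field '{req}'")
    if fields["interleave"].lower() != "bil":
        raise HSIIOError(f"unsupported interleave '{fields['interleave']}'")
    n_pixels = int(fields["samples"])
    n_lines = int(fields["lines"])
    n_bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise HSIIOError(f"unsupported data type code {code}")
    wavelengths = np.array(
        [float(w) for w in fields["wavelength"].split(",") if w.strip()]
    )
    if wavelengths.size != n_bands:
        raise HSIIOError(
            f"wavelength count mismatch: header declares {n_bands} bands "
            f"but lists {wavelengths.size} wavelengths"
        )
    raw = np.fromfile(bil_path, dtype=_ENVI_DTYPES[code])
    expected = n_lines * n_bands * n_pixels
    if raw.size != expected:
        raise HSIIOError(
            f"binary payload has {raw.size} values, expected {expected}"
        )
    values = raw.reshape(n_lines, n_bands, n_pixels).transpose(0, 2, 1)
    if not np.all(np.isfinite(values)):
        raise HSIIOError("binary payload contains non-finite values")
    state = CubeState(fields.get("seedhsi state", "raw"))
    prov = fields.get("description", "")
    provenance = [] if prov in ("", "none") else [s.strip() for s in prov.split(";")]
    return SpectralCube(values, WavelengthGrid(wavelengths), state, provenance)


# ---------------------------------------------------------------------------
# CSV tables


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV with a header row.

    Duplicate sample identities are rejected: rows must be unique on
    ``(sample_id, side)`` when a ``side`` column is present, else on
    ``sample_id`` alone. Missing labels stay empty fields, never 0/1.
    """
    if "sample_id" in table.columns:
        keys = ["sample_id"] + (["side"] if "side" in table.columns else [])
        dup = table.duplicated(subset=keys)
        if dup.any():
            offender = table.loc[dup, keys].iloc[0].tolist()
            raise HSIIOError(f"duplicate sample id {offender}")
    table.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
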