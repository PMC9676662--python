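"""Streaming emulation of the online sorting loop.

A pushbroom camera over a conveyor delivers the cube frame by frame.
The runtime calibrates each incoming line, median-filters it with a
one-line lookahead (so results are bit-identical to whole-cube
filtering), grows seed blobs across frame boundaries, and the moment a
blob closes — a line arrives with no pixels of it — classifies the seed
pixel-wise and emits a sort event with a simulated actuation time for
the suction nozzle. Decisions are exactly those of batch processing of
the full cube; frame height is a buffering knob, never a result knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import area_open, seed_decision
from .io import ReferenceFrames, RunConfig, SpectralCube
from .plsda import ConfusionMatrix, PLSDAModel, evaluate, predict_scores
from .prep import (REFLECTANCE_CLIP, SeedRegion, _valid_rows, apply_preprocess,
                   filter_lines_window)
from .synth import SceneTruth

__all__ = [
    "FrameStream",
    "SortEvent",
    "OnlineReport",
    "stream_frames",
    "run_online",
    "batch_report",
]


def stream_frames(cube: SpectralCube, frame_height: int) -> list[np.ndarray]:
    """Partition the cube into scan-ordered frames of <= frame_height lines."""
    if frame_height < 1:
        raise ValueError("frame_height must be >= 1")
    v = cube.values
    return [v[i:i + frame_height] for i in range(0, v.shape[0], frame_height)]


@dataclass
class FrameStream:
    """Frame-wise view of a raw cube with the rig timing model attached."""

    cube: SpectralCube
    config: RunConfig

    def __iter__(self):
        return iter(stream_frames(self.cube, self.config.frame_height))

    @property
    def total_lines(self) -> int:
        return self.cube.n_lines

    @property
    def duration_s(self) -> float:
        return self.total_lines / self.config.lines_per_second


@dataclass
class SortEvent:
    """One per-seed decision from the online loop."""

    event_id: str
    decision: int                    # 1 viable, 0 nonviable
    closure_line: int                # first line past the seed
    decision_time_s: float
    actuation_time_s: float
    area: int
    viable_pixel_fraction: float
    centroid: tuple[float, float]
    pixels: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    open_at_end: bool = False        # blob forced closed at stream end


class _Blob:
    __slots__ = ("lines", "cols", "spectra", "prev_cols", "touched")

    def __init__(self):
        self.lines: list[int] = []
        self.cols: list[int] = []
        self.spectra: list[np.ndarray] = []
        self.prev_cols: set[int] = set()
        self.touched = False


def _runs(mask_line: np.ndarray):
    """Maximal runs of True as (start, stop) half-open column spans."""
    idx = np.flatnonzero(mask_line)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, stops)]


def run_online(stream: FrameStream, refs: ReferenceFrames, model: PLSDAModel,
               config: RunConfig | None = None) -> list[SortEvent]:
    """Run the full online loop over a frame stream.

    Per line: two-point calibration, 3x3 median (one-line lookahead,
    reflect padding at stream start/end), band-mean threshold mask,
    4-connected blob stitching across lines and frames. A closed blob
    of at least ``min_area`` pixels is preprocessed per pixel, projected
    through the model, binarised at the model threshold, area-opened,
    and called by the viable-pixel-fraction rule. Events are ordered by
    closure line.
    """
    config = config or stream.config
    cube = stream.cube
    if refs.white.shape != (cube.n_pixels, cube.n_bands):
        raise ValueError("reference frames do not match the frame extent")
    span = refs.span()
    if np.any(span <= 0):
        px, bd = np.argwhere(span <= 0)[0]
        raise ValueError(f"white - dark is non-positive at pixel {px}, band {bd}")

    t = model.threshold
    events: list[SortEvent] = []
    open_blobs: list[_Blob] = []
    counter = 0

    def close(blob: _Blob, line_idx: int, at_end: bool) -> None:
        nonlocal counter
        area = len(blob.lines)
        if area < config.min_area:
            return
        spectra = np.vstack(blob.spectra)
        if model.preprocess is not None:
            ok = _valid_rows(model.preprocess, spectra)
            scores = np.zeros(area)
            if ok.any():
                scores[ok] = predict_scores(
                    model, apply_preprocess(model.preprocess, spectra[ok]))
        else:
            scores = predict_scores(model, spectra)
        ll = np.asarray(blob.lines)
        cc = np.asarray(blob.cols)
        l0, c0 = ll.min(), cc.min()
        patch = np.zeros((ll.max() - l0 + 1, cc.max() - c0 + 1), dtype=bool)
        patch[ll - l0, cc - c0] = scores > t
        cleaned = area_open(patch, config.min_area)
        frac = float(cleaned[ll - l0, cc - c0].sum()) / area
        decision = int(frac >= config.viable_fraction)
        decision_time = line_idx / config.lines_per_second
        actuation = decision_time + config.nozzle_distance / config.belt_speed
        events.append(SortEvent(
            event_id=f"E{counter:04d}", decision=decision,
            closure_line=int(line_idx), decision_time_s=decision_time,
            actuation_time_s=actuation, area=area,
            viable_pixel_fraction=frac,
            centroid=(float(ll.mean()), float(cc.mean())),
            pixels=(ll, cc), open_at_end=at_end,
        ))
        counter += 1

    def process_line(line_idx: int, filtered: np.ndarray) -> None:
        mask_line = filtered.mean(axis=1) > config.seg_threshold
        for blob in open_blobs:
            blob.touched = False
        new_cols: dict[int, set[int]] = {}
        for start, stop in _runs(mask_line):
            hits = [b for b in open_blobs
                    if any(c in b.prev_cols for c in range(start, stop))]
            if hits:
                target = hits[0]
                for other in hits[1:]:       # run bridges blobs: merge
                    target.lines += other.lines
                    target.cols += other.cols
                    target.spectra += other.spectra
                    target.prev_cols |= other.prev_cols
                    new_cols.setdefault(id(target), set()).update(
                        new_cols.pop(id(other), set()))
                    open_blobs.remove(other)
            else:
                target = _Blob()
                open_blobs.append(target)
            for c in range(start, stop):
                target.lines.append(line_idx)
                target.cols.append(c)
                target.spectra.append(filtered[c])
            target.touched = True
            new_cols.setdefault(id(target), set()).update(range(start, stop))
        for blob in list(open_blobs):
            if blob.touched:
                blob.prev_cols = new_cols[id(blob)]
            else:
                open_blobs.remove(blob)
                close(blob, line_idx, at_end=False)

    # line pump: calibrate incoming lines, filter with one-line lookahead
    dark, lo, hi = refs.dark, *REFLECTANCE_CLIP
    buffer: list[np.ndarray] = []      # calibrated lines awaiting filtering
    emitted = 0
    for frame in stream:
        for raw_line in frame:
            cal = np.clip((raw_line.astype(float) - dark) / span, lo, hi)
            buffer.append(cal)
            if len(buffer) == 2 and emitted == 0:
                # first line: reflect-pad with itself
                process_line(0, filter_lines_window(
                    np.stack([buffer[0], buffer[0], buffer[1]])))
                emitted = 1
            elif len(buffer) >= 3:
                window = np.stack(buffer[-3:])
                process_line(emitted, filter_lines_window(window))
                emitted += 1
                buffer.pop(0)
    # stream end: last line reflect-pads with itself
    if emitted == 0 and len(buffer) == 1:
        process_line(0, filter_lines_window(
            np.stack([buffer[0], buffer[0], buffer[0]])))
        emitted = 1
    elif buffer:
        process_line(emitted, filter_lines_window(
            np.stack([buffer[-2], buffer[-1], buffer[-1]])))
        emitted += 1
    for blob in open_blobs:            # flagged: still open at stream end
        close(blob, emitted, at_end=True)
    events.sort(key=lambda e: (e.closure_line, e.centroid[1]))
    return events


@dataclass(frozen=True)
class OnlineReport:
    confusion: ConfusionMatrix
    n_events: int
    duration_s: float                  # simulated scan time, never wall-clock
    seeds_per_second: float


def batch_report(events: list[SortEvent], truth: SceneTruth,
                 config: RunConfig) -> OnlineReport:
    """Score sort events against scene truth and summarise throughput."""
    assigned: dict[int, int] = {}
    for e in events:
        overlap = truth.label_map[e.pixels[0], e.pixels[1]]
        overlap = overlap[overlap >= 0]
        if overlap.size == 0:
            raise ValueError(f"event {e.event_id} matches no truth seed")
        idx = int(np.bincount(overlap).argmax())
        if idx in assigned:
            raise ValueError(f"two events match truth seed {idx}")
        assigned[idx] = e.decision
    if len(assigned) != len(truth.seeds):
        raise ValueError(
            f"{len(events)} events for {len(truth.seeds)} truth seeds")
    pred = np.array([assigned[i] for i in range(len(truth.seeds))])
    cm = evaluate(pred, truth.labels())
    duration = truth.shape[0] / config.lines_per_second
    return OnlineReport(cm, len(events), duration,
                        len(events) / duration if duration else float("nan"))
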