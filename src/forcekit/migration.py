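"""Cell tracking and migration metrics from label-mask time-lapses.

Cells are linked across frames by nearest centroid; per-cell series of
speed, straightness, projected area and indented volume are derived, the
free-movement inclusion rule (no contact with another cell for a minimum
contiguous window) is applied, and the coupling between speed and
mechanical activity is quantified as the Pearson correlation of the first
time derivatives of the two series.

Speed follows the path-length convention (sum of frame-to-frame steps
divided by elapsed time); straightness is net displacement over path
length, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .mechanics import DisplacementMap, indented_volume


@dataclass
class CellTrack:
    """Time-indexed centroid/mask series for one cell."""

    cell_id: int
    frames: np.ndarray  # frame indices, contiguous
    centroids_um: np.ndarray  # (n, 2), (x, y)
    areas_um2: np.ndarray
    labels: np.ndarray  # per-frame label in the mask stack
    contact: np.ndarray  # per-frame flag: touching another cell
    frame_interval_s: float
    indented_volumes_um3: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.centroids_um = np.asarray(self.centroids_um, dtype=float)
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.contact = np.asarray(self.contact, dtype=bool)

    def __len__(self) -> int:
        return len(self.frames)

    def window(self, start: int, stop: int) -> "CellTrack":
        """Sub-track over positions [start, stop)."""
        sl = slice(start, stop)
        return CellTrack(
            cell_id=self.cell_id,
            frames=self.frames[sl],
            centroids_um=self.centroids_um[sl],
            areas_um2=self.areas_um2[sl],
            labels=self.labels[sl],
            contact=self.contact[sl],
            frame_interval_s=self.frame_interval_s,
            indented_volumes_um3=(
                None
                if self.indented_volumes_um3 is None
                else self.indented_volumes_um3[sl]
            ),
        )


@dataclass
class MigrationSummary:
    cell_id: int
    mean_speed_um_min: float
    straightness: float
    mean_area_um2: float
    mean_indented_volume_um3: float
    included: bool
    free_window_h: float


def _contact_flags(mask: np.ndarray) -> dict[int, bool]:
    """True for labels whose mask is 8-connected-adjacent to another label."""
    out: dict[int, bool] = {}
    labels = [int(l) for l in np.unique(mask) if l != 0]
    for label in labels:
        own = mask == label
        halo = morphology.dilation(own, morphology.footprint_rectangle((3, 3))) & ~own
        out[label] = bool((mask[halo] > 0).any())
    return out


def track_cells(
    mask_stack: np.ndarray,
    pixel_size_um: float,
    frame_interval_s: float,
    max_step_um: float = 10.0,
) -> list[CellTrack]:
    """Link per-frame label images into cell tracks.

    Greedy nearest-centroid linking under ``max_step_um``; unmatched
    regions start new tracks.  Contact flags record 8-connected adjacency
    with any other labelled region in the same frame.  Deterministic.
    """
    mask_stack = np.asarray(mask_stack)
    if mask_stack.ndim != 3:
        raise ValueError("mask_stack must be (frames, H, W)")
    raw: list[list[dict]] = []
    for t in range(mask_stack.shape[0]):
        frame_mask = mask_stack[t]
        contact = _contact_flags(frame_mask)
        regs = []
        for r in measure.regionprops(frame_mask.astype(int)):
            cy, cx = r.centroid
            regs.append(
                {
                    "centroid": np.array(
                        [(cx + 0.5) * pixel_size_um, (cy + 0.5) * pixel_size_um]
                    ),
                    "area": r.area * pixel_size_um ** 2,
                    "label": r.label,
                    "contact": contact[r.label],
                }
            )
        regs.sort(key=lambda d: d["label"])
        raw.append(regs)

    tracks: list[dict] = []
    active: list[dict] = []
    for t, regs in enumerate(raw):
        pairs = []
        for ti, tr in enumerate(active):
            if tr["frames"][-1] != t - 1:
                continue
            for ri, reg in enumerate(regs):
                d = float(np.linalg.norm(reg["centroid"] - tr["centroids"][-1]))
                if d <= max_step_um:
                    pairs.append((d, ti, ri))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_t: set[int] = set()
        used_r: set[int] = set()
        for d, ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            used_t.add(ti)
            used_r.add(ri)
            tr = active[ti]
            reg = regs[ri]
            tr["frames"].append(t)
            tr["centroids"].append(reg["centroid"])
            tr["areas"].append(reg["area"])
            tr["labels"].append(reg["label"])
            tr["contact"].append(reg["contact"])
        for ri, reg in enumerate(regs):
            if ri in used_r:
                continue
            tr = {
                "frames": [t],
                "centroids": [reg["centroid"]],
                "areas": [reg["area"]],
                "labels": [reg["label"]],
                "contact": [reg["contact"]],
            }
            tracks.append(tr)
            active.append(tr)

    return [
        CellTrack(
            cell_id=i + 1,
            frames=np.array(tr["frames"]),
            centroids_um=np.array(tr["centroids"]),
            areas_um2=np.array(tr["areas"]),
            labels=np.array(tr["labels"]),
            contact=np.array(tr["contact"]),
            frame_interval_s=frame_interval_s,
        )
        for i, tr in enumerate(tracks)
    ]


def mean_speed(track: CellTrack) -> float:
    """Mean migration speed in um/min: path length / elapsed time."""
    if len(track) < 2:
        raise ValueError("speed requires at least 2 frames")
    steps = np.linalg.norm(np.diff(track.centroids_um, axis=0), axis=1)
    total_min = (len(track) - 1) * track.frame_interval_s / 60.0
    return float(steps.sum() / total_min)


def straightness(track: CellTrack) -> float:
    """Net displacement over path length; NaN when the path length is 0."""
    if len(track) < 2:
        raise ValueError("straightness requires at least 2 frames")
    steps = np.linalg.norm(np.diff(track.centroids_um, axis=0), axis=1)
    path = steps.sum()
    if path == 0:
        return float("nan")
    net = float(np.linalg.norm(track.centroids_um[-1] - track.centroids_um[0]))
    return net / path


def free_movement_filter(
    tracks: list[CellTrack],
    min_free_hours: float = 2.0,
) -> list[CellTrack]:
    """Retain tracks with a contiguous contact-free window of at least
    ``min_free_hours``, cropped to their longest such window.

    A run of k contact-free frames spans (k - 1) frame intervals.  Ties
    between equally long windows go to the earliest.
    """
    out = []
    for track in tracks:
        best_len = 0
        best_start = 0
        run_start = None
        for i, c in enumerate(list(track.contact) + [True]):
            if not c and run_start is None:
                run_start = i
            elif c and run_start is not None:
                if i - run_start > best_len:
                    best_len = i - run_start
                    best_start = run_start
                run_start = None
        if best_len < 2:
            continue
        span_h = (best_len - 1) * track.frame_interval_s / 3600.0
        if span_h >= min_free_hours:
            out.append(track.window(best_start, best_start + best_len))
    return out


def volume_series(
    track: CellTrack,
    displacement_maps: list[DisplacementMap],
    mask_stack: np.ndarray,
    threshold_nm: float = 20.0,
) -> np.ndarray:
    """Per-frame indented volume (um^3) under the track's cell mask.

    Applies the 20 nm indentation threshold inside the mask frame by
    frame; stores the series on the track and returns it.
    """
    if track.frames.max() >= len(displacement_maps) or track.frames.max() >= len(
        mask_stack
    ):
        raise ValueError("track frames exceed the supplied stacks")
    vols = np.empty(len(track))
    for i, (frame, label) in enumerate(zip(track.frames, track.labels)):
        mask = mask_stack[frame] == label
        vols[i] = indented_volume(displacement_maps[frame], mask, threshold_nm)
    track.indented_volumes_um3 = vols
    return vols


def derivative_correlation(
    speed_series: np.ndarray, volume_series: np.ndarray
) -> float:
    """Pearson correlation of the first differences of two series.

    Quantifies the coupling between changes in migration speed and
    changes in mechanical activity; in [-1, 1], NaN when either
    differenced series is constant.
    """
    s = np.asarray(speed_series, dtype=float)
    v = np.asarray(volume_series, dtype=float)
    if s.shape != v.shape:
        raise ValueError("series must have equal length")
    if len(s) < 3:
        raise ValueError("need at least 3 samples")
    ds, dv = np.diff(s), np.diff(v)
    if ds.std() == 0 or dv.std() == 0:
        return float("nan")
    return float(np.corrcoef(ds, dv)[0, 1])


def normalise_to_mean(series: np.ndarray) -> np.ndarray:
    """Divide a series by its mean (output mean is exactly 1)."""
    s = np.asarray(series, dtype=float)
    m = s.mean()
    if m == 0:
        raise ValueError("cannot normalise a zero-mean series")
    return s / m


def speed_series(track: CellTrack) -> np.ndarray:
    """Per-step instantaneous speed (um/min), length len(track) - 1."""
    steps = np.linalg.norm(np.diff(track.centroids_um, axis=0), axis=1)
    return steps / (track.frame_interval_s / 60.0)


def summarise_track(
    track: CellTrack,
    included: bool = True,
) -> MigrationSummary:
    """Collapse a (windowed) track into the per-cell summary row."""
    vols = track.indented_volumes_um3
    free = ~track.contact
    free_h = (
        (int(free.sum()) - 1) * track.frame_interval_s / 3600.0 if free.any() else 0.0
    )
    return MigrationSummary(
        cell_id=track.cell_id,
        mean_speed_um_min=mean_speed(track),
        straightness=straightness(track),
        mean_area_um2=float(track.areas_um2.mean()),
        mean_indented_volume_um3=(
            float(np.mean(vols)) if vols is not None else float("nan")
        ),
        included=included,
        free_window_h=free_h,
    )
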