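"""High-level analysis workflows chaining the per-module operations.

These wrap the common end-to-end paths — render or load a time-lapse,
filter, invert to stress, detect and link features, track cells and
summarise migration — so scripts, tests and the CLI share one code path.
"""

from __future__ import annotations

import numpy as np

from .features import (
    classify_cell_protrusion_status,
    detect_protrusion_dots,
    indentation_force,
    link_features,
)
from .mechanics import (
    BandpassSpec,
    SubstrateModel,
    displacement_to_stress,
    fourier_bandpass,
)
from .migration import (
    free_movement_filter,
    summarise_track,
    track_cells,
    volume_series,
)
from .synthetic import SyntheticScene, render_displacement_map, render_mask

FINE_BANDPASS = BandpassSpec(low_cut=0.1, high_cut=0.6, rolloff_width=0.03)


def dot_force_series(
    scene: SyntheticScene,
    substrate: SubstrateModel,
    spec: BandpassSpec = FINE_BANDPASS,
    stress_threshold_pa: float = 4.0,
    tikhonov: float | None = None,
) -> np.ndarray:
    """Per-frame indentation force (pN) of the strongest protrusion dot.

    Renders each frame, bandpass-filters, inverts to stress and applies
    the thresholded area x mean-stress estimator; frames where no dot is
    detected yield 0.
    """
    out = np.zeros(scene.n_frames)
    for frame in range(scene.n_frames):
        m = render_displacement_map(scene, substrate, frame)
        filt = fourier_bandpass(m, spec)
        kwargs = {} if tikhonov is None else {"tikhonov": tikhonov}
        stress = displacement_to_stress(filt, substrate, **kwargs)
        dots = detect_protrusion_dots(filt)
        if dots:
            out[frame] = indentation_force(dots[0], stress, stress_threshold_pa)
    return out


def cell_bears_persistent_dot(
    scene: SyntheticScene,
    substrate: SubstrateModel,
    spec: BandpassSpec = FINE_BANDPASS,
    min_dot_frames: int = 3,
    max_link_distance_um: float = 2.0,
) -> bool:
    """Whether the scene's cell shows a protrusion-dot track persisting
    for at least ``min_dot_frames`` frames."""
    per_frame = []
    for frame in range(scene.n_frames):
        m = render_displacement_map(scene, substrate, frame)
        per_frame.append(detect_protrusion_dots(fourier_bandpass(m, spec)))
    tracks = link_features(per_frame, max_link_distance_um)
    return classify_cell_protrusion_status({1: tracks}, min_dot_frames)[1]


def migration_summaries(
    scene: SyntheticScene,
    substrate: SubstrateModel,
    min_free_hours: float = 2.0,
    threshold_nm: float = 20.0,
):
    """Track all cells of a scene and summarise the included ones.

    Renders masks and displacement maps, links tracks, applies the
    free-movement inclusion window and computes per-cell mean speed,
    straightness, area and indented volume on that window.
    """
    maps = [
        render_displacement_map(scene, substrate, f) for f in range(scene.n_frames)
    ]
    masks = np.stack(
        [render_mask(scene, substrate, f) for f in range(scene.n_frames)]
    )
    tracks = track_cells(masks, substrate.pixel_size_um, scene.frame_interval_s)
    included = free_movement_filter(tracks, min_free_hours)
    summaries = []
    for tr in included:
        volume_series(tr, maps, masks, threshold_nm)
        summaries.append(summarise_track(tr, included=True))
    return summaries
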