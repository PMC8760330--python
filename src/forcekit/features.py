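"""Detection and quantification of sub-cellular force-transmission features.

Two signatures are detected in Fourier-filtered displacement maps:

* **twist dipoles** — paired push (indentation, positive) and pull
  (upward, negative) lobes where a focal adhesion transmits horizontal
  contractile force; the twist amplitude (half the peak-to-trough
  difference) converts linearly to force at 6.6 nm per nN;
* **protrusion dots** — micron-scale confined indentation cores ringed by
  upward pulling, quantified as indentation area x mean stress above a
  threshold (default 4 Pa) on the matching stress map; forces are pN.

Features can be linked over time into tracks and aggregated per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

from .mechanics import DisplacementMap, StressMap

TWIST_NM_PER_NN = 6.6
"""Calibration: nm of substrate twist per nN of horizontal force."""


@dataclass
class ForceFeature:
    """One detected force-transmission site in a single frame."""

    kind: str  # "twist_dipole" | "protrusion_dot"
    centroid_um: tuple[float, float]  # (x, y)
    frame: int = 0
    frame_time_s: float | None = None
    axis_angle: float | None = None  # twists only
    twist_amplitude_nm: float | None = None  # twists only
    core_area_um2: float | None = None  # dots only
    force: float | None = None  # nN (twist) / pN (dot)
    core_mask: np.ndarray | None = field(default=None, repr=False)


@dataclass
class FeatureTrack:
    """A time-linked sequence of the same feature across frames."""

    track_id: int
    features: list[ForceFeature] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([f.frame for f in self.features])

    @property
    def forces(self) -> np.ndarray:
        return np.array(
            [f.force if f.force is not None else np.nan for f in self.features]
        )

    @property
    def max_force(self) -> float:
        forces = self.forces
        return float(np.nanmax(forces)) if len(forces) else float("nan")

    def __len__(self) -> int:
        return len(self.features)

    def oscillation_period_s(self, frame_interval_s: float) -> float:
        """Dominant oscillation period of the force series (s) via the
        discrete Fourier spectrum of the mean-subtracted series; NaN when
        fewer than four samples or no oscillatory power."""
        f = self.forces
        f = f[~np.isnan(f)]
        if len(f) < 4:
            return float("nan")
        spec = np.abs(np.fft.rfft(f - f.mean()))
        if not spec[1:].any():
            return float("nan")
        k = int(np.argmax(spec[1:])) + 1
        return float(len(f) * frame_interval_s / k)


def _require_filtered(dmap: DisplacementMap, dc_tolerance_nm: float) -> None:
    mean = float(np.nanmean(dmap.values))
    if abs(mean) > dc_tolerance_nm:
        raise ValueError(
            f"map mean {mean:.2f} nm exceeds {dc_tolerance_nm} nm: input does "
            "not look Fourier-filtered; apply fourier_bandpass first"
        )


def _local_extrema(
    v: np.ndarray, min_distance_px: int, threshold: float, sign: int
) -> list[tuple[int, int]]:
    from skimage.feature import peak_local_max

    coords = peak_local_max(
        sign * v,
        min_distance=min_distance_px,
        threshold_abs=threshold,
        exclude_border=False,
    )
    return [tuple(c) for c in coords]


def _refine_peak(v: np.ndarray, ij: tuple[int, int], sign: int) -> tuple[float, float, float]:
    """Sub-pixel peak refinement at a local extremum.

    Fits a separable parabola to the log of the (sign-corrected) values in
    a 3-point stencil per axis — exact for a Gaussian lobe — and falls
    back to the raw pixel value at borders or sign changes.  Returns
    (refined value with original sign, dy, dx) with offsets in pixels.
    """
    i, j = ij
    val = sign * v[i, j]
    offsets = [0.0, 0.0]
    log_corr = 0.0
    for axis, n in enumerate(v.shape):
        idx = ij[axis]
        if idx == 0 or idx == n - 1:
            continue
        lo = sign * (v[i - 1, j] if axis == 0 else v[i, j - 1])
        hi = sign * (v[i + 1, j] if axis == 0 else v[i, j + 1])
        if lo <= 0 or hi <= 0 or val <= max(lo, hi):
            continue
        a, b, c = math.log(lo), math.log(val), math.log(hi)
        den = a - 2 * b + c
        if den >= 0:
            continue
        d = 0.5 * (a - c) / den
        if abs(d) <= 1.0:
            offsets[axis] = d
            log_corr += -0.125 * (a - c) * d * 2  # = -(a-c)^2 / (8 den) at vertex
    return sign * val * math.exp(log_corr), offsets[0], offsets[1]


def detect_twists(
    filtered: DisplacementMap,
    min_amplitude_nm: float = 5.0,
    min_separation_um: float = 3.0,
    pairing_radius_um: float = 4.0,
    max_lobe_asymmetry: float = 3.0,
    dc_tolerance_nm: float = 0.5,
) -> list[ForceFeature]:
    """Detect focal-adhesion push-pull twist dipoles.

    Each feature pairs one local maximum (indentation lobe) with one local
    minimum (pulling lobe) within ``pairing_radius_um``; both lobes must
    exceed ``min_amplitude_nm`` in magnitude and their depths may differ
    by at most ``max_lobe_asymmetry`` (a genuine dipole is balanced; a
    protrusion core flanked by its much shallower pulling ring is not).
    The twist amplitude is half the peak-to-trough difference and
    converts to horizontal contraction force at 6.6 nm/nN.  Features are
    returned in descending amplitude, ties broken row-major by centroid;
    pairing is greedy by amplitude, so the result is deterministic.
    """
    _require_filtered(filtered, dc_tolerance_nm)
    v = filtered.values
    px = filtered.pixel_size_um
    mind = max(1, int(round(min_separation_um / px)))
    maxima = _local_extrema(v, mind, min_amplitude_nm, +1)
    minima = _local_extrema(v, mind, min_amplitude_nm, -1)
    if not maxima or not minima:
        return []
    # sub-pixel refined (value, y, x) per extremum
    ref_max = [_refine_peak(v, m, +1) for m in maxima]
    ref_min = [_refine_peak(v, n, -1) for n in minima]

    candidates = []
    for mi, m in enumerate(maxima):
        for ni, n in enumerate(minima):
            d = math.hypot(m[0] - n[0], m[1] - n[1]) * px
            if d > pairing_radius_um:
                continue
            hi_lobe = ref_max[mi][0]
            lo_lobe = -ref_min[ni][0]
            if max(hi_lobe, lo_lobe) > max_lobe_asymmetry * min(hi_lobe, lo_lobe):
                continue
            amp = 0.5 * (hi_lobe + lo_lobe)
            candidates.append((amp, m, n, mi, ni))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    used_max: set[int] = set()
    used_min: set[int] = set()
    feats: list[ForceFeature] = []
    frame = 0
    t = filtered.frame_time_s
    for amp, m, n, mi, ni in candidates:
        if mi in used_max or ni in used_min:
            continue
        used_max.add(mi)
        used_min.add(ni)
        my = m[0] + ref_max[mi][1]
        mx = m[1] + ref_max[mi][2]
        ny_ = n[0] + ref_min[ni][1]
        nx_ = n[1] + ref_min[ni][2]
        cy = (my + ny_) / 2.0
        cx = (mx + nx_) / 2.0
        # axis from pulling (negative) lobe to pushing (positive) lobe
        angle = math.atan2(my - ny_, mx - nx_) % math.pi
        feats.append(
            ForceFeature(
                kind="twist_dipole",
                centroid_um=((cx + 0.5) * px, (cy + 0.5) * px),
                frame=frame,
                frame_time_s=t,
                axis_angle=angle,
                twist_amplitude_nm=float(amp),
                force=contraction_force(float(amp)),
            )
        )
    feats.sort(
        key=lambda f: (-f.twist_amplitude_nm, f.centroid_um[1], f.centroid_um[0])
    )
    return feats


def contraction_force(
    twist_amplitude_nm: float, nm_per_nn: float = TWIST_NM_PER_NN
) -> float:
    """Horizontal contraction force (nN) from twist amplitude (nm).

    Linear calibration: force = amplitude / 6.6 nm/nN by default.
    """
    if twist_amplitude_nm < 0:
        raise ValueError("twist amplitude must be >= 0")
    return twist_amplitude_nm / nm_per_nn


def detect_protrusion_dots(
    filtered: DisplacementMap,
    core_diameter_range_um: tuple[float, float] = (1.0, 4.0),
    ring_check: bool = True,
    min_depth_nm: float = 5.0,
    ring_inner_factor: float = 2.0,
    ring_search_um: float = 3.5,
    n_sectors: int = 8,
    twin_lobe_frac: float = 0.5,
    twin_lobe_radius_um: float = 3.5,
    dc_tolerance_nm: float = 0.5,
) -> list[ForceFeature]:
    """Detect confined indentation cores ringed by upward pulling.

    Connected components of indentation above ``min_depth_nm`` are
    candidate cores; their diameter is measured on the half-depth (FWHM)
    contour, which reflects the core geometry independent of the
    instantaneous force, and must lie in ``core_diameter_range_um``.
    With ``ring_check``, the surrounding annulus (from
    ``ring_inner_factor`` footprint radii out to ``ring_search_um``
    further, judged against the local background median) must show net
    upward displacement in at least half of ``n_sectors`` angular
    sectors, and no opposite extremum of comparable depth may sit within
    ``twin_lobe_radius_um`` — an isotropically counterbalanced
    protrusion passes, the lobe of a twist dipole does not.  Ordered by
    descending core depth, then row-major centroid.
    """
    lo, hi = core_diameter_range_um
    if not 0 < lo < hi:
        raise ValueError(f"degenerate core diameter range {core_diameter_range_um}")
    _require_filtered(filtered, dc_tolerance_nm)
    v = filtered.values
    px = filtered.pixel_size_um
    labels = measure.label(v > min_depth_nm, connectivity=2)
    feats: list[ForceFeature] = []
    t = filtered.frame_time_s
    yy, xx = np.indices(v.shape)
    for region in measure.regionprops(labels):
        full_mask = labels == region.label
        peak = float(v[full_mask].max())
        # size the core on its half-depth (FWHM) contour so the measured
        # diameter reflects geometry, not the instantaneous force
        half = measure.label(full_mask & (v >= 0.5 * peak), connectivity=2)
        peak_ij = np.unravel_index(np.argmax(np.where(full_mask, v, -np.inf)), v.shape)
        half_mask = half == half[peak_ij]
        eqd = 2.0 * math.sqrt(half_mask.sum() / math.pi) * px
        if not lo <= eqd <= hi:
            continue
        cy, cx = np.argwhere(half_mask).mean(axis=0)
        # twin-lobe rejection: a protrusion's pulling ring is shallow
        # relative to its core, whereas the positive lobe of a twist
        # dipole has an opposite lobe of comparable depth nearby
        r = np.hypot(yy - cy, xx - cx)
        near = r <= twin_lobe_radius_um / px
        if near.any() and v[near].min() <= -twin_lobe_frac * peak:
            continue
        if ring_check:
            # anchor the ring annulus on the full supra-threshold
            # footprint (not the FWHM core) so the core's positive skirt
            # stays out of the ring zone
            r_full = math.sqrt(full_mask.sum() / math.pi)  # pixels
            inner = ring_inner_factor * r_full
            outer = inner + ring_search_um / px
            annulus = (r >= inner) & (r <= outer)
            if not annulus.any():
                continue
            # local background: residual broad deformation can offset the
            # whole neighbourhood, so the ring is judged against the
            # median of a wider annulus beyond the ring search zone
            bg_zone = (r > outer) & (r <= outer + 3.0 / px)
            bg = float(np.median(v[bg_zone])) if bg_zone.any() else 0.0
            # the counterbalancing ring surrounds the core on all sides,
            # unlike the single opposite lobe of a twist dipole: require
            # net upward displacement (relative to background) in at
            # least half the angular sectors
            theta = np.arctan2(yy - cy, xx - cx)
            sectors = np.floor((theta + np.pi) / (2 * np.pi / n_sectors)).astype(int)
            sectors = np.clip(sectors, 0, n_sectors - 1)
            neg = 0
            for s_i in range(n_sectors):
                sel = annulus & (sectors == s_i)
                if sel.any() and v[sel].mean() < bg:
                    neg += 1
            if neg < n_sectors / 2:
                continue
        feats.append(
            ForceFeature(
                kind="protrusion_dot",
                centroid_um=((cx + 0.5) * px, (cy + 0.5) * px),
                frame=0,
                frame_time_s=t,
                core_area_um2=float(half_mask.sum() * px ** 2),
                core_mask=half_mask,
            )
        )
    depth = {id(f): float(v[f.core_mask].max()) for f in feats}
    feats.sort(key=lambda f: (-depth[id(f)], f.centroid_um[1], f.centroid_um[0]))
    return feats


def indentation_force(
    feature: ForceFeature,
    stress: StressMap,
    stress_threshold_pa: float | None = 4.0,
    core_dilation_um: float = 0.75,
) -> float:
    """Vertical indentation force (pN) of a protrusion dot.

    The feature's core mask is dilated by ``core_dilation_um`` so the
    deconvolved stress footprint is covered; within it, the indentation
    area is the connected patch of stress at or above
    ``stress_threshold_pa`` that contains the stress peak (scattered
    supra-threshold noise pixels elsewhere do not count), and the force
    is that area times its mean stress (Pa x um^2 = pN).  Returns 0 when
    nothing survives.  ``stress_threshold_pa=None`` integrates every
    pixel of the dilated core without exclusion, which is the unbiased
    choice when validating force recovery on noiseless data (a threshold
    at 0 would rectify deconvolution ringing).
    """
    if feature.kind != "protrusion_dot":
        raise ValueError(f"expected a protrusion_dot feature, got {feature.kind}")
    if feature.core_mask is None:
        raise ValueError("feature carries no core mask")
    if feature.core_mask.shape != stress.values.shape:
        raise ValueError("stress map is not aligned with the feature's source map")
    mask = feature.core_mask
    if core_dilation_um > 0:
        radius = int(round(core_dilation_um / stress.pixel_size_um))
        if radius > 0:
            mask = morphology.dilation(mask, morphology.disk(radius))
    s = stress.values
    if stress_threshold_pa is None:
        return float(s[mask].sum() * stress.pixel_area_um2)
    above = mask & (s >= stress_threshold_pa)
    if not above.any():
        return 0.0
    comp = measure.label(above, connectivity=2)
    peak_ij = np.unravel_index(np.argmax(np.where(mask, s, -np.inf)), s.shape)
    patch = comp == comp[peak_ij]
    if not patch.any():
        return 0.0
    return float(s[patch].sum() * stress.pixel_area_um2)


def link_features(
    per_frame_features: list[list[ForceFeature]],
    max_link_distance_um: float = 2.0,
    max_gap_frames: int = 0,
) -> list[FeatureTrack]:
    """Greedy nearest-neighbour linking of per-frame features into tracks.

    Frames must be supplied in temporal order (strictly increasing frame
    times where set).  In each frame, candidate (track end, feature) pairs
    within ``max_link_distance_um`` are assigned closest-first; leftover
    features start new tracks.  Deterministic given the input order.
    """
    times = [
        fs[0].frame_time_s
        for fs in per_frame_features
        if fs and fs[0].frame_time_s is not None
    ]
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("frame times are not strictly increasing")

    tracks: list[FeatureTrack] = []
    active: list[FeatureTrack] = []
    next_id = 0
    for frame_idx, feats in enumerate(per_frame_features):
        for f in feats:
            f.frame = frame_idx
        active = [
            tr for tr in active
            if frame_idx - tr.features[-1].frame <= max_gap_frames + 1
        ]
        pairs = []
        for ti, tr in enumerate(active):
            ex, ey = tr.features[-1].centroid_um
            for fi, f in enumerate(feats):
                d = math.hypot(f.centroid_um[0] - ex, f.centroid_um[1] - ey)
                if d <= max_link_distance_um:
                    pairs.append((d, ti, fi))
        pairs.sort()
        used_t: set[int] = set()
        used_f: set[int] = set()
        for d, ti, fi in pairs:
            if ti in used_t or fi in used_f:
                continue
            used_t.add(ti)
            used_f.add(fi)
            active[ti].features.append(feats[fi])
        for fi, f in enumerate(feats):
            if fi not in used_f:
                tr = FeatureTrack(track_id=next_id, features=[f])
                next_id += 1
                tracks.append(tr)
                active.append(tr)
    return tracks


def assign_features_to_cells(
    features: list[ForceFeature],
    label_image: np.ndarray,
    pixel_size_um: float,
) -> dict[int, list[ForceFeature]]:
    """Group features by the cell label their centroid falls on.

    Features over background (label 0) are dropped.
    """
    out: dict[int, list[ForceFeature]] = {}
    for f in features:
        j = int(f.centroid_um[0] / pixel_size_um)
        i = int(f.centroid_um[1] / pixel_size_um)
        if not (0 <= i < label_image.shape[0] and 0 <= j < label_image.shape[1]):
            continue
        label = int(label_image[i, j])
        if label > 0:
            out.setdefault(label, []).append(f)
    return out


def classify_cell_protrusion_status(
    dot_tracks_by_cell: dict[int, list[FeatureTrack]],
    min_dot_frames: int = 3,
) -> dict[int, bool]:
    """Flag each cell positive when it carries at least one dot track that
    persists for ``min_dot_frames`` frames or more."""
    return {
        cell: any(len(tr) >= min_dot_frames for tr in tracks)
        for cell, tracks in dot_tracks_by_cell.items()
    }


def features_to_frame(features: list[ForceFeature]):
    """Flatten features into a tidy table (one row per feature)."""
    import pandas as pd

    rows = []
    for f in features:
        rows.append(
            {
                "frame": f.frame,
                "kind": f.kind,
                "x_um": f.centroid_um[0],
                "y_um": f.centroid_um[1],
                "amplitude_nm": f.twist_amplitude_nm,
                "area_um2": f.core_area_um2,
                "force": f.force,
                "units": "nN" if f.kind == "twist_dipole" else "pN",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "kind", "x_um", "y_um", "amplitude_nm",
            "area_um2", "force", "units",
        ],
    )
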