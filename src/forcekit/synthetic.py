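"""Forward simulator: synthetic displacement scenes with known ground truth.

Generates displacement-map time-lapses, cell label masks, cilium polylines
and qPCR Ct tables whose ground truth is known exactly, emulating the
statistical structure the downstream analyses assume:

* migrating contractile cells indent the soft layer broadly under their
  body (Gaussian indentation, nm scale over tens of um);
* focal adhesions appear as push-pull displacement dipoles whose twist
  amplitude is 6.6 nm per nN of horizontal contractile force (the
  calibration embedded identically in the analyser);
* podosome-like protrusions push down through a tightly confined core
  (~2 um observed diameter) with oscillating pN-scale vertical force,
  surrounded by an annular ring of upward pulling that conserves the
  displaced volume;
* sensor noise is i.i.d. Gaussian per pixel (default 2 nm).

All randomness flows through explicit seeds; identical seeds give
bit-identical output.  Rendering is linear in the sources (noise off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanics import DisplacementMap, SubstrateModel, gaussian_otf

TWIST_NM_PER_NN = 6.6
"""Twist amplitude (nm) rendered per nN of horizontal contractile force."""


@dataclass
class AdhesionDipole:
    """A focal-adhesion push-pull twist source.

    Rendered as two opposite-sign Gaussian displacement lobes along
    ``axis_angle`` separated by ``lobe_separation_um``; the twist
    amplitude (half the peak-to-trough difference) equals
    ``TWIST_NM_PER_NN x force_nn``.
    """

    position_um: tuple[float, float] = (0.0, 0.0)  # offset from cell centroid
    axis_angle: float = 0.0
    force_nn: float | np.ndarray = 4.0  # scalar or per-frame series
    lobe_separation_um: float = 3.0
    lobe_sigma_um: float = 0.8

    def __post_init__(self) -> None:
        if self.lobe_separation_um <= 0:
            raise ValueError("lobe_separation_um must be > 0")
        if np.any(np.asarray(self.force_nn) < 0):
            raise ValueError("force_nn must be >= 0")

    def force_at(self, frame: int) -> float:
        f = np.asarray(self.force_nn, dtype=float)
        return float(f if f.ndim == 0 else f[frame])


@dataclass
class ProtrusionSource:
    """A confined vertical protrusion (actin-dot / podosome-like source).

    The core is a uniform stress disk of radius ``core_radius_um``
    carrying the frame's total force (pN); an annular Gaussian-profile
    ring of opposite sign at ``ring_radius_um`` balances the core so the
    total signed displaced volume is zero (volume-conserving elastomer
    approximation).  The observed displacement core, after lateral
    coupling, has a diameter of roughly 2 um at the defaults.
    """

    position_um: tuple[float, float] = (0.0, 0.0)
    force_series_pn: np.ndarray = field(default_factory=lambda: np.array([50.0]))
    core_radius_um: float = 0.6
    edge_taper_um: float = 0.6
    ring_radius_um: float = 3.5
    ring_width_um: float = 0.4
    oscillation_period_s: float | None = None

    def __post_init__(self) -> None:
        self.force_series_pn = np.atleast_1d(
            np.asarray(self.force_series_pn, dtype=float)
        )
        if self.core_radius_um <= 0 or self.ring_width_um <= 0:
            raise ValueError("core_radius_um and ring_width_um must be > 0")
        if self.ring_radius_um <= self.core_radius_um:
            raise ValueError("ring_radius_um must exceed core_radius_um")
        if np.any(self.force_series_pn < 0):
            raise ValueError("forces must be >= 0")

    def force_at(self, frame: int) -> float:
        if self.force_series_pn.size == 1:
            return float(self.force_series_pn[0])
        return float(self.force_series_pn[frame])

    @classmethod
    def sinusoidal(
        cls,
        n_frames: int,
        frame_interval_s: float,
        peak_pn: float = 80.0,
        trough_pn: float = 40.0,
        period_s: float = 120.0,
        phase: float = 0.0,
        position_um: tuple[float, float] = (0.0, 0.0),
        **kwargs,
    ) -> "ProtrusionSource":
        """Sinusoidally oscillating vertical force between trough and peak."""
        t = np.arange(n_frames) * frame_interval_s
        mid = 0.5 * (peak_pn + trough_pn)
        amp = 0.5 * (peak_pn - trough_pn)
        series = mid + amp * np.sin(2 * np.pi * t / period_s + phase)
        return cls(
            position_um=position_um,
            force_series_pn=series,
            oscillation_period_s=period_s,
            **kwargs,
        )


@dataclass
class SyntheticCell:
    """One simulated cell: trajectory, body footprint and force sources."""

    trajectory_um: np.ndarray  # (n_frames, 2), (x, y) in um
    body_radius_um: float = 25.0
    adhesions: list[AdhesionDipole] = field(default_factory=list)
    protrusions: list[ProtrusionSource] = field(default_factory=list)
    central_indentation_amplitude_nm: float = 160.0
    indentation_sigma_factor: float = 0.55

    def __post_init__(self) -> None:
        self.trajectory_um = np.atleast_2d(np.asarray(self.trajectory_um, dtype=float))
        if self.trajectory_um.shape[1] != 2:
            raise ValueError("trajectory must be (n_frames, 2)")
        if self.body_radius_um <= 0:
            raise ValueError("body_radius_um must be > 0")

    @property
    def indentation_sigma_um(self) -> float:
        return self.indentation_sigma_factor * self.body_radius_um


@dataclass
class SyntheticScene:
    """Ground-truth description of a rendered time-lapse."""

    field_size_um: tuple[float, float]  # (width, height)
    frame_interval_s: float
    n_frames: int
    cells: list[SyntheticCell] = field(default_factory=list)
    noise_sd_nm: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.field_size_um, (int, float)):
            self.field_size_um = (float(self.field_size_um), float(self.field_size_um))
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd_nm < 0:
            raise ValueError("noise_sd_nm must be >= 0")
        w, h = self.field_size_um
        for i, cell in enumerate(self.cells):
            if cell.trajectory_um.shape[0] != self.n_frames:
                raise ValueError(
                    f"cell {i}: trajectory length {cell.trajectory_um.shape[0]} "
                    f"!= n_frames {self.n_frames}"
                )
            r = cell.body_radius_um
            xy = cell.trajectory_um
            if (
                (xy[:, 0] - r < 0).any()
                or (xy[:, 0] + r > w).any()
                or (xy[:, 1] - r < 0).any()
                or (xy[:, 1] + r > h).any()
            ):
                raise ValueError(f"cell {i}: footprint leaves the field")

    def grid_shape(self, substrate: SubstrateModel) -> tuple[int, int]:
        w, h = self.field_size_um
        px = substrate.pixel_size_um
        return int(round(h / px)), int(round(w / px))


def _pixel_centers(scene: SyntheticScene, substrate: SubstrateModel):
    ny, nx = scene.grid_shape(substrate)
    px = substrate.pixel_size_um
    x = (np.arange(nx) + 0.5) * px
    y = (np.arange(ny) + 0.5) * px
    return x[None, :], y[:, None]


def _check_frame(scene: SyntheticScene, frame: int) -> None:
    if not 0 <= frame < scene.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {scene.n_frames})")


def render_displacement_map(
    scene: SyntheticScene,
    substrate: SubstrateModel,
    frame: int,
) -> DisplacementMap:
    """Render one frame as the linear superposition of all sources.

    Protrusion sources are composed in stress space and pushed through the
    forward Winkler + Gaussian-coupling response; dipole twists and the
    broad cell-body indentation are rendered directly in displacement
    space.  White Gaussian noise of ``scene.noise_sd_nm`` is added last,
    seeded by ``(scene.rng_seed, frame)``.
    """
    _check_frame(scene, frame)
    ny, nx = scene.grid_shape(substrate)
    if ny < 2 or nx < 2:
        raise ValueError("scene/substrate geometry mismatch: grid too small")
    x, y = _pixel_centers(scene, substrate)
    px = substrate.pixel_size_um
    a = px ** 2
    k = substrate.winkler_pa_per_nm

    stress = np.zeros((ny, nx))
    u = np.zeros((ny, nx))

    for cell in scene.cells:
        cx, cy = cell.trajectory_um[frame]

        if cell.central_indentation_amplitude_nm != 0:
            sig = cell.indentation_sigma_um
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            u += cell.central_indentation_amplitude_nm * np.exp(-r2 / (2 * sig ** 2))

        for dip in cell.adhesions:
            f_nn = dip.force_at(frame)
            if f_nn == 0:
                continue
            half = 0.5 * dip.lobe_separation_um
            dx, dy = math.cos(dip.axis_angle), math.sin(dip.axis_angle)
            px0 = cx + dip.position_um[0]
            py0 = cy + dip.position_um[1]
            amp = TWIST_NM_PER_NN * f_nn
            for sign in (+1.0, -1.0):
                lx = px0 + sign * half * dx
                ly = py0 + sign * half * dy
                r2 = (x - lx) ** 2 + (y - ly) ** 2
                u += sign * amp * np.exp(-r2 / (2 * dip.lobe_sigma_um ** 2))

        for prot in cell.protrusions:
            f_pn = prot.force_at(frame)
            if f_pn == 0:
                continue
            px0 = cx + prot.position_um[0]
            py0 = cy + prot.position_um[1]
            r = np.hypot(x - px0, y - py0)
            # uniform disk with a cosine-tapered rim carrying the full force;
            # the taper keeps the stress spectrum inside the band the
            # deconvolution can restore, avoiding ringing artefacts
            w = prot.edge_taper_um
            t = np.clip((r - (prot.core_radius_um - w)) / (2 * w), 0.0, 1.0)
            cover = 0.5 * (1 + np.cos(np.pi * t))
            core_total = cover.sum() * a
            if core_total == 0:
                continue
            core = cover * (f_pn / core_total)
            ring = np.exp(-((r - prot.ring_radius_um) ** 2) / (2 * prot.ring_width_um ** 2))
            ring_total = ring.sum() * a
            # scale the ring so core + ring conserve displaced volume exactly
            stress += core - ring * (f_pn / ring_total)

    if stress.any():
        if substrate.coupling_sigma_um > 0:
            g = gaussian_otf(stress.shape, px, substrate.coupling_sigma_um)
            smoothed = np.fft.ifft2(np.fft.fft2(stress) * g).real
        else:
            smoothed = stress
        u += smoothed / k

    if scene.noise_sd_nm > 0:
        rng = np.random.default_rng([scene.rng_seed, frame])
        u = u + rng.normal(0.0, scene.noise_sd_nm, size=u.shape)

    return DisplacementMap(u, px, frame_time_s=frame * scene.frame_interval_s)


def render_mask(
    scene: SyntheticScene,
    substrate: SubstrateModel,
    frame: int,
) -> np.ndarray:
    """Render the frame's cell label image (uint16; background 0).

    Cell ``i`` receives label ``i + 1``, stable across frames.  Where two
    bodies overlap, the pixel goes to the nearer centroid; exact ties go
    to the lower label.
    """
    _check_frame(scene, frame)
    ny, nx = scene.grid_shape(substrate)
    x, y = _pixel_centers(scene, substrate)
    labels = np.zeros((ny, nx), dtype=np.uint16)
    best = np.full((ny, nx), np.inf)
    for i, cell in enumerate(scene.cells):
        cx, cy = cell.trajectory_um[frame]
        d = np.hypot(x - cx, y - cy)
        inside = d <= cell.body_radius_um
        take = inside & (d < best)
        labels[take] = i + 1
        best[take] = d[take]
    return labels


def scene_ground_truth(scene: SyntheticScene) -> pd.DataFrame:
    """Per-frame, per-source ground truth table.

    Columns: frame, cell_id, type, x_um, y_um, force (nN for adhesions,
    pN for protrusions, NaN for the cell body row).
    """
    rows = []
    for frame in range(scene.n_frames):
        for i, cell in enumerate(scene.cells):
            cx, cy = cell.trajectory_um[frame]
            rows.append((frame, i + 1, "cell", cx, cy, np.nan))
            for dip in cell.adhesions:
                rows.append(
                    (frame, i + 1, "adhesion",
                     cx + dip.position_um[0], cy + dip.position_um[1],
                     dip.force_at(frame))
                )
            for prot in cell.protrusions:
                rows.append(
                    (frame, i + 1, "protrusion",
                     cx + prot.position_um[0], cy + prot.position_um[1],
                     prot.force_at(frame))
                )
    return pd.DataFrame(
        rows, columns=["frame", "cell_id", "type", "x_um", "y_um", "force"]
    )


def persistent_trajectory(
    n_frames: int,
    frame_interval_s: float,
    speed_um_min: float,
    start_um: tuple[float, float],
    bounds_um: tuple[float, float],
    margin_um: float,
    rng: np.random.Generator,
    turn_sd: float = 0.5,
) -> np.ndarray:
    """Persistent random walk with reflecting boundaries.

    The step length is fixed at speed x interval; the heading diffuses
    with per-step Gaussian turns of ``turn_sd`` radians, which yields
    straightness values in the range migrating epithelial cells show.
    """
    step = speed_um_min * frame_interval_s / 60.0
    pos = np.array(start_um, dtype=float)
    heading = rng.uniform(0, 2 * np.pi)
    out = np.empty((n_frames, 2))
    out[0] = pos
    lo = margin_um
    hi_x = bounds_um[0] - margin_um
    hi_y = bounds_um[1] - margin_um
    for i in range(1, n_frames):
        heading += rng.normal(0, turn_sd)
        pos = pos + step * np.array([math.cos(heading), math.sin(heading)])
        # reflect off the margins
        if pos[0] < lo:
            pos[0] = 2 * lo - pos[0]
            heading = math.pi - heading
        elif pos[0] > hi_x:
            pos[0] = 2 * hi_x - pos[0]
            heading = math.pi - heading
        if pos[1] < lo:
            pos[1] = 2 * lo - pos[1]
            heading = -heading
        elif pos[1] > hi_y:
            pos[1] = 2 * hi_y - pos[1]
            heading = -heading
        out[i] = pos
    return out


def make_migration_scene(
    n_cells: int = 1,
    field_um: float = 150.0,
    n_frames: int = 25,
    frame_interval_s: float = 300.0,
    speed_um_min: float = 0.32,
    body_radius_um: float = 25.0,
    indentation_nm: float = 160.0,
    noise_sd_nm: float = 2.0,
    seed: int = 0,
    turn_sd: float = 0.5,
) -> SyntheticScene:
    """A migration-assay scene: contractile cells on a random walk.

    Defaults mirror the study conditions for the migration stage: 5-min
    frame interval, wild-type-scale speed (0.32 um/min), ~2000 um^2 cell
    bodies and a central indentation producing indented volumes of order
    1.5e2 um^3 at the 20 nm threshold.
    """
    rng = np.random.default_rng(seed)
    margin = body_radius_um + 2.0
    cells = []
    starts: list[np.ndarray] = []
    for i in range(n_cells):
        # rejection-sample starting positions so bodies begin separated;
        # trajectories may still bring cells into contact later
        for _ in range(1000):
            start = rng.uniform(margin, field_um - margin, size=2)
            if all(np.linalg.norm(start - s) > 2.2 * body_radius_um for s in starts):
                break
        else:
            raise ValueError("could not place cells without overlap; enlarge field")
        starts.append(start)
        traj = persistent_trajectory(
            n_frames, frame_interval_s, speed_um_min, tuple(start),
            (field_um, field_um), margin, rng, turn_sd=turn_sd,
        )
        cells.append(
            SyntheticCell(
                trajectory_um=traj,
                body_radius_um=body_radius_um,
                central_indentation_amplitude_nm=indentation_nm,
            )
        )
    return SyntheticScene(
        field_size_um=(field_um, field_um),
        frame_interval_s=frame_interval_s,
        n_frames=n_frames,
        cells=cells,
        noise_sd_nm=noise_sd_nm,
        rng_seed=seed,
    )


def make_fine_structure_scene(
    n_dots: int = 1,
    n_dipoles: int = 2,
    field_um: float = 48.0,
    n_frames: int = 12,
    frame_interval_s: float = 5.0,
    peak_pn: float = 80.0,
    trough_pn: float = 40.0,
    period_s: float = 120.0,
    body_radius_um: float = 12.0,
    indentation_nm: float = 120.0,
    noise_sd_nm: float = 2.0,
    seed: int = 0,
) -> SyntheticScene:
    """A fine-structure scene: one slow cell bearing dots and/or dipoles.

    Emulates the high-frame-rate stage (5 s interval) used to resolve
    sub-cellular force transmission: protrusion dots oscillate between
    ``trough_pn`` and ``peak_pn``; adhesion dipoles sit towards the cell
    periphery with nN-scale contraction.
    """
    rng = np.random.default_rng(seed)
    center = (field_um / 2.0, field_um / 2.0)
    traj = np.tile(np.asarray(center), (n_frames, 1))
    protrusions = []
    for i in range(n_dots):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.3 * body_radius_um)
        protrusions.append(
            ProtrusionSource.sinusoidal(
                n_frames, frame_interval_s,
                peak_pn=peak_pn, trough_pn=trough_pn, period_s=period_s,
                phase=rng.uniform(0, 2 * np.pi),
                position_um=(rad * math.cos(ang), rad * math.sin(ang)),
            )
        )
    adhesions = []
    for i in range(n_dipoles):
        ang = 2 * np.pi * i / max(n_dipoles, 1) + rng.uniform(0, 0.5)
        rad = 0.75 * body_radius_um
        adhesions.append(
            AdhesionDipole(
                position_um=(rad * math.cos(ang), rad * math.sin(ang)),
                axis_angle=ang,
                force_nn=rng.uniform(2.0, 6.0),
            )
        )
    cell = SyntheticCell(
        trajectory_um=traj,
        body_radius_um=body_radius_um,
        adhesions=adhesions,
        protrusions=protrusions,
        central_indentation_amplitude_nm=indentation_nm,
    )
    return SyntheticScene(
        field_size_um=(field_um, field_um),
        frame_interval_s=frame_interval_s,
        n_frames=n_frames,
        cells=[cell],
        noise_sd_nm=noise_sd_nm,
        rng_seed=seed,
    )


def generate_cilium_set(
    n: int,
    length_mean_um: float = 4.5,
    length_sd_um: float = 1.0,
    curvature_per_um: float = 0.2,
    seed: int = 0,
    points_per_um: float = 20.0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Constant-curvature cilium polylines with known arc lengths.

    Returns ``(polylines, lengths)``: each polyline is an (m, 2) array of
    planar points (um) traced along a circular arc of the sampled length,
    randomly rotated and translated; ``lengths`` are the ground-truth arc
    lengths.  Each polyline's chordal arc length matches its ground truth
    to well within 0.1%.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length_mean_um <= 0:
        raise ValueError("length_mean_um must be > 0")
    if length_sd_um < 0:
        raise ValueError("length_sd_um must be >= 0")
    rng = np.random.default_rng(seed)
    polylines = []
    lengths = np.empty(n)
    for i in range(n):
        length = length_mean_um
        if length_sd_um > 0:
            length = float(rng.normal(length_mean_um, length_sd_um))
            length = max(length, 0.05 * length_mean_um)
        m = max(32, int(math.ceil(length * points_per_um)))
        t = np.linspace(0.0, length, m)
        if curvature_per_um == 0:
            pts = np.column_stack([t, np.zeros_like(t)])
        else:
            r = 1.0 / curvature_per_um
            pts = np.column_stack([r * np.sin(t / r), r * (1 - np.cos(t / r))])
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        pts = pts @ rot.T + rng.uniform(0, 100, size=2)
        polylines.append(pts)
        lengths[i] = length
    return polylines, lengths


def generate_ct_table(
    fold_change: float,
    sd_ct: float = 0.15,
    n_reps: int = 3,
    seed: int = 0,
    conditions: tuple[str, str] = ("WT", "KO"),
    base_target_ct: float = 23.0,
    base_reference_ct: float = 17.0,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table (target and reference gene x condition).

    The first condition is the calibrator.  The second condition's target
    gene is offset by ddCt = -log2(fold_change), so the downstream
    relative-expression estimate recovers ``fold_change`` exactly at
    ``sd_ct = 0``.  Columns: condition, gene, replicate, ct.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if sd_ct < 0:
        raise ValueError("sd_ct must be >= 0")
    rng = np.random.default_rng(seed)
    ddct = -math.log2(fold_change)
    rows = []
    for cond_i, cond in enumerate(conditions):
        shift = ddct if cond_i > 0 else 0.0
        for rep in range(1, n_reps + 1):
            for gene, base in (
                ("target", base_target_ct + shift),
                ("reference", base_reference_ct),
            ):
                ct = base + (rng.normal(0, sd_ct) if sd_ct > 0 else 0.0)
                rows.append((cond, gene, rep, ct))
    return pd.DataFrame(rows, columns=["condition", "gene", "replicate", "ct"])
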