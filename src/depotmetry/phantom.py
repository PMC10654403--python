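"""Fully synthetic assay sessions with analytic ground truth.

The phantom emulates the features of an explant micro-CT session that the
pipeline exploits, at a scaled-down field of view:

* a layered background: air above the skin surface, a dense dermis band,
  and below it subcutaneous fat divided into lobules by brighter
  interlobular septa (modeled as the boundary walls of a 3D Voronoi
  tessellation of random lobule centers);
* a cylindrical cannula whose lumen can transiently contain an air-bubble
  segment on scheduled frames;
* a depot that appears at the first post-pump-start frame and grows
  monotonically, one pump impulse per frame interval.  The
  ``septal_growth`` shape adds new voxels preferentially on septal walls
  adjacent to the current depot, reproducing the spread of insulin along
  the interlobular septa (and hence an index of dispersion that rises with
  time); ``sphere``, ``cube`` and ``cylinder`` shapes provide closed-form
  volume and surface oracles;
* an optional sub-voxel translation of even frames (default 0.3 voxel),
  standing in for the slight tilt between the two rotation directions of
  the scanner, which is what makes the per-parity reference logic
  necessary;
* additive Gaussian noise, deterministic per (seed, frame);
* a matched pressure trace: baseline plus one triangular impulse spike per
  frame interval from the pump start, optional step elevations (plateaus)
  and optional impulse suppression during an occlusion.

Everything is deterministic for a fixed spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .classify import LayerMap
from .errors import ConfigError
from .pressure import PressureTrace
from .segment import STRUCTURE_18, build_cannula_mask
from .session_io import (AssaySession, CannulaModel, SessionConfig,
                         VolumeFrame)

UM_PER_MM = 1000.0


# --------------------------------------------------------------------------
# Spec dataclasses
# --------------------------------------------------------------------------

@dataclass
class SeptaSpec:
    """Lobular background parameters.

    Septal walls are 3 voxels thick by default: explants from
    post-bariatric surgery show thickened, collagen-dense interlobular
    septa, and the wall thickness also sets the sheet thickness of a
    septal-growth depot.
    """

    n_lobules: int = 24
    wall_thickness_vox: float = 3.0
    wall_intensity: float = 140.0
    lobule_intensity: float = 100.0
    dermis_intensity: float = 150.0
    air_intensity: float = 5.0


@dataclass
class DepotSpec:
    """Depot shape and per-frame growth parameters.

    ``septal_growth`` (default) grows ``voxels_per_impulse`` voxels per
    frame from the cannula tip, choosing septal-wall voxels with
    probability ``wall_preference`` whenever available.  The analytic
    shapes interpolate their size parameter linearly over the post-start
    frames.
    """

    shape: str = "septal_growth"
    intensity: float = 190.0
    # septal growth
    voxels_per_impulse: int = 1500
    wall_preference: float = 0.9
    # sphere
    radius_start_vox: float = 8.0
    radius_end_vox: float = 20.0
    # cube
    edge_start_vox: float = 8.0
    edge_end_vox: float = 30.0
    # cylinder (axis along y, fixed radius, growing length)
    cyl_radius_vox: float = 3.0
    cyl_length_start_vox: float = 45.0
    cyl_length_end_vox: float = 225.0

    SHAPES = ("sphere", "cube", "cylinder", "septal_growth")

    def __post_init__(self):
        if self.shape not in self.SHAPES:
            raise ConfigError(f"unknown depot shape {self.shape!r}")


@dataclass
class PressureSpec:
    """Pressure-trace generation parameters.

    The protocol never states a sensor sampling rate; 10 Hz is the phantom
    default.  Impulses are triangular spikes (the true stroke waveform is
    unspecified, only that impulses are easy to identify).  ``step_events``
    are (start_min, duration_min, peak_mbar) plateaus;
    ``suppress_impulses_min`` are (start_min, end_min) windows without
    impulses (no delivery during an occlusion).  ``clip_mbar`` emulates
    sensor saturation when set.
    """

    baseline_mbar: float = 20.0
    impulse_amplitude_mbar: float = 30.0
    impulse_width_s: float = 2.0
    sampling_hz: float = 10.0
    noise_sd_mbar: float = 1.0
    step_events: tuple = ()
    suppress_impulses_min: tuple = ()
    clip_mbar: Optional[float] = None


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic assay session.

    The acquisition schedule matches the reference protocol (36 frames at
    one per 5 min over 3 h, pump started at 10 min, so frames 1-2 are
    insulin-free references).  The grid is a scaled-down field of view
    centered on the infusion site; at the default 17 um voxels it covers
    roughly 1.6 x 2.2 x 2.2 mm.
    """

    grid_shape: tuple[int, int, int] = (96, 128, 128)
    voxel_size_um: float = 17.0
    n_frames: int = 36
    frame_interval_min: float = 5.0
    pump_start_offset_min: float = 10.0
    septa: SeptaSpec = field(default_factory=SeptaSpec)
    depot: DepotSpec = field(default_factory=DepotSpec)
    cannula: Optional[CannulaModel] = None
    cannula_intensity: float = 220.0
    cannula_radius_vox: float = 2.5
    bubble_frames: tuple = ()            # inclusive (first, last) frame ranges
    occlusion_until_frame: int = 0       # no delivery up to this frame
    noise_gaussian_sd: float = 10.0
    epidermis_z: int = 10
    dermis_hypodermis_z: int = 28
    even_frame_shift_vox: float = 0.3
    pressure: PressureSpec = field(default_factory=PressureSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 3:
            raise ConfigError("n_frames must be >= 3 (2 references + depot)")
        if not (0 < self.epidermis_z < self.dermis_hypodermis_z
                < self.grid_shape[0]):
            raise ConfigError(
                "need 0 < epidermis_z < dermis_hypodermis_z < grid depth")
        s = self.septa
        if not (self.depot.intensity > s.wall_intensity > s.lobule_intensity):
            raise ConfigError(
                "intensity ordering must be depot > wall > lobule")
        if self.cannula is None:
            cz, cy, cx = self.grid_shape
            tip_z = self.dermis_hypodermis_z + 4
            self.cannula = CannulaModel(
                entry_point_vox=(0.0, cy / 2.0, cx / 2.0),
                tip_point_vox=(float(tip_z), cy / 2.0, cx / 2.0),
                radius_um=self.cannula_radius_vox * self.voxel_size_um,
            )

    @property
    def tip_vox(self) -> tuple[int, int, int]:
        return tuple(int(round(v)) for v in self.cannula.tip_point_vox)

    def frame_time_min(self, frame_index: int) -> float:
        return self.frame_interval_min * (frame_index - 1)

    def first_depot_frame(self) -> int:
        """First frame whose acquisition starts at/after the pump start."""
        k = int(math.ceil(self.pump_start_offset_min
                          / self.frame_interval_min - 1e-9)) + 1
        return max(k, 3, self.occlusion_until_frame + 1)

    def layer_map(self) -> LayerMap:
        return LayerMap(epidermis_z=float(self.epidermis_z),
                        dermis_hypodermis_z=float(self.dermis_hypodermis_z))

    def session_config(self) -> SessionConfig:
        return SessionConfig(
            frame_interval_min=self.frame_interval_min,
            session_duration_min=self.frame_interval_min * self.n_frames,
            pump_start_offset_min=self.pump_start_offset_min,
            cannula=self.cannula,
            layer_boundaries=self.layer_map(),
        )


@dataclass
class GroundTruth:
    """Analytic truth accompanying a synthetic session (the test oracle)."""

    masks: list[np.ndarray]
    analytic_volume_mm3: list[Optional[float]]
    analytic_surface_mm2: list[Optional[float]]
    size_parameter_vox: list[Optional[float]]   # r, edge or length per frame
    bubble_flags: list[bool]
    wall_fraction: list[Optional[float]]
    impulse_times_s: list[float] = field(default_factory=list)
    step_events: list[dict] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _rng(seed: Optional[int], *stream) -> np.random.Generator:
    return np.random.default_rng([seed if seed is not None else 0, *stream])


# --------------------------------------------------------------------------
# Pure digitized shapes (calibration oracles)
# --------------------------------------------------------------------------

def digitize_sphere(radius_vox: float, pad: int = 3) -> np.ndarray:
    """Binary ball: voxel centers within ``radius_vox`` of the grid center."""
    n = int(2 * math.ceil(radius_vox) + 2 * pad + 1)
    c = n // 2
    z, y, x = np.ogrid[:n, :n, :n]
    return ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= radius_vox ** 2


def digitize_cube(edge_vox: int) -> np.ndarray:
    return np.ones((edge_vox,) * 3, dtype=bool)


def digitize_cylinder(radius_vox: float, length_vox: int,
                      pad: int = 3) -> np.ndarray:
    """Binary capped cylinder with axis along the last grid axis."""
    d = int(2 * math.ceil(radius_vox) + 2 * pad + 1)
    c = d // 2
    z, y = np.ogrid[:d, :d]
    disk = ((z - c) ** 2 + (y - c) ** 2) <= radius_vox ** 2
    return np.broadcast_to(disk[:, :, None],
                           (d, d, int(length_vox))).copy()


def sphere_analytic(radius_vox: float, voxel_size_um: float) -> tuple[float, float]:
    e = voxel_size_um / UM_PER_MM
    r = radius_vox * e
    return 4.0 / 3.0 * math.pi * r ** 3, 4.0 * math.pi * r ** 2


def cube_analytic(edge_vox: float, voxel_size_um: float) -> tuple[float, float]:
    a = edge_vox * voxel_size_um / UM_PER_MM
    return a ** 3, 6.0 * a ** 2


def cylinder_analytic(radius_vox: float, length_vox: float,
                      voxel_size_um: float) -> tuple[float, float]:
    e = voxel_size_um / UM_PER_MM
    r, length = radius_vox * e, length_vox * e
    return math.pi * r ** 2 * length, 2.0 * math.pi * r * (length + r)


# --------------------------------------------------------------------------
# Background, cannula, noise
# --------------------------------------------------------------------------

def _lobule_centers(spec: PhantomSpec,
                    rng: np.random.Generator) -> np.ndarray:
    gz, gy, gx = spec.grid_shape
    lo = np.array([spec.dermis_hypodermis_z, 0, 0], dtype=float)
    hi = np.array([gz, gy, gx], dtype=float)
    return rng.uniform(lo, hi, size=(spec.septa.n_lobules, 3))


def septal_wall_mask(spec: PhantomSpec,
                     seed: Optional[int] = None) -> np.ndarray:
    """Boolean mask of interlobular septal walls (hypodermis only).

    Walls are the boundaries of the Voronoi tessellation of the lobule
    centers: voxels whose distances to the two nearest centers differ by
    less than the wall thickness.  A single lobule has no interior walls.
    """
    if spec.septa.n_lobules < 1:
        raise ConfigError("n_lobules must be >= 1")
    rng = _rng(seed if seed is not None else spec.seed, 1)
    wall = np.zeros(spec.grid_shape, dtype=bool)
    if spec.septa.n_lobules == 1:
        return wall
    centers = _lobule_centers(spec, rng)
    gz, gy, gx = spec.grid_shape
    dz = spec.dermis_hypodermis_z
    pts = np.stack(np.meshgrid(
        np.arange(dz, gz), np.arange(gy), np.arange(gx),
        indexing="ij"), axis=-1).reshape(-1, 3).astype(float)
    d, _ = cKDTree(centers).query(pts, k=2, workers=-1)
    sub = (d[:, 1] - d[:, 0]) < spec.septa.wall_thickness_vox
    wall[dz:] = sub.reshape(gz - dz, gy, gx)
    return wall


def generate_septa_background(spec: PhantomSpec,
                              seed: Optional[int] = None) -> VolumeFrame:
    """Noise-free layered background volume (air / dermis / lobules+walls)."""
    s = spec.septa
    bg = np.full(spec.grid_shape, s.lobule_intensity, dtype=np.float32)
    bg[:spec.epidermis_z] = s.air_intensity
    bg[spec.epidermis_z:spec.dermis_hypodermis_z] = s.dermis_intensity
    bg[septal_wall_mask(spec, seed)] = s.wall_intensity
    return VolumeFrame(data=bg, voxel_size_um=spec.voxel_size_um,
                       frame_index=1, time_min=0.0)


def bubble_in_frame(spec: PhantomSpec, frame_index: int) -> bool:
    return any(lo <= frame_index <= hi for lo, hi in spec.bubble_frames)


def generate_cannula(
    spec: PhantomSpec,
    frame_index: int,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Cannula voxel mask, air-bubble sub-segment mask and bubble flag."""
    mask = build_cannula_mask(spec.cannula, spec.grid_shape,
                              spec.voxel_size_um, dilation_vox=0.0)
    flag = bubble_in_frame(spec, frame_index)
    bubble = np.zeros(spec.grid_shape, dtype=bool)
    if flag:
        entry = np.asarray(spec.cannula.entry_point_vox)
        tip = np.asarray(spec.cannula.tip_point_vox)
        seg = CannulaModel(
            entry_point_vox=tuple(entry + 0.55 * (tip - entry)),
            tip_point_vox=tuple(entry + 0.85 * (tip - entry)),
            radius_um=spec.cannula.radius_um,
        )
        bubble = build_cannula_mask(seg, spec.grid_shape,
                                    spec.voxel_size_um, dilation_vox=0.0)
        bubble &= mask
    return mask, bubble, flag


def add_noise(frame: VolumeFrame, gaussian_sd: float,
              seed: Optional[int] = None) -> VolumeFrame:
    """Additive zero-mean Gaussian noise, deterministic per (seed, frame)."""
    if gaussian_sd < 0:
        raise ConfigError("gaussian_sd must be >= 0")
    if gaussian_sd == 0:
        return frame
    rng = _rng(seed, 977, frame.frame_index)
    noisy = frame.data.astype(np.float32) + \
        rng.normal(0.0, gaussian_sd, frame.data.shape).astype(np.float32)
    return VolumeFrame(data=noisy, voxel_size_um=frame.voxel_size_um,
                       frame_index=frame.frame_index, time_min=frame.time_min)


# --------------------------------------------------------------------------
# Depot growth
# --------------------------------------------------------------------------

def _growth_fraction(spec: PhantomSpec, frame_index: int) -> float:
    """Linear 0..1 interpolation over the post-start frames."""
    first = spec.first_depot_frame()
    last = spec.n_frames
    if last == first:
        return 1.0
    return (frame_index - first) / (last - first)


def _analytic_masks(spec: PhantomSpec):
    """Nested masks + closed forms for sphere / cube / cylinder shapes."""
    d = spec.depot
    tz, ty, tx = spec.tip_vox
    gz, gy, gx = spec.grid_shape
    zz, yy, xx = np.ogrid[:gz, :gy, :gx]
    first = spec.first_depot_frame()
    masks, vols, surfs, sizes = [], [], [], []
    flags = []
    for i in range(1, spec.n_frames + 1):
        if i < first:
            masks.append(np.zeros(spec.grid_shape, dtype=bool))
            vols.append(None); surfs.append(None); sizes.append(None)
            continue
        f = _growth_fraction(spec, i)
        if d.shape == "sphere":
            r = d.radius_start_vox + f * (d.radius_end_vox - d.radius_start_vox)
            cz = tz + 4
            m = ((zz - cz) ** 2 + (yy - ty) ** 2 + (xx - tx) ** 2) <= r * r
            v, s = sphere_analytic(r, spec.voxel_size_um)
            size = r
        elif d.shape == "cube":
            a = d.edge_start_vox + f * (d.edge_end_vox - d.edge_start_vox)
            half = a / 2.0
            m = ((zz >= tz + 1) & (zz < tz + 1 + a)
                 & (np.abs(yy - ty) <= half) & (np.abs(xx - tx) <= half))
            v, s = cube_analytic(a, spec.voxel_size_um)
            size = a
        else:  # cylinder
            length = d.cyl_length_start_vox + f * (
                d.cyl_length_end_vox - d.cyl_length_start_vox)
            r = d.cyl_radius_vox
            cz2 = tz + 2
            m = (((zz - cz2) ** 2 + (xx - tx) ** 2) <= r * r) & \
                (yy >= ty) & (yy < ty + length)
            v, s = cylinder_analytic(r, length, spec.voxel_size_um)
            size = length
        m = np.ascontiguousarray(np.broadcast_to(m, spec.grid_shape))
        masks.append(m)
        vols.append(v); surfs.append(s); sizes.append(size)
    # growth truncation check: final mask touching a grid face
    final = masks[-1]
    if (final[0].any() or final[-1].any() or final[:, 0].any()
            or final[:, -1].any() or final[:, :, 0].any()
            or final[:, :, -1].any()):
        flags.append("growth_truncated")
    return masks, vols, surfs, sizes, flags


def _septal_masks(spec: PhantomSpec, rng: np.random.Generator,
                  wall: np.ndarray, cannula_mask: np.ndarray):
    """Stochastic septa-following growth; returns nested masks."""
    d = spec.depot
    gz, gy, gx = spec.grid_shape
    tz, ty, tx = spec.tip_vox
    first = spec.first_depot_frame()
    offsets = np.argwhere(STRUCTURE_18) - 1
    offsets = offsets[np.any(offsets != 0, axis=1)]

    allowed = np.ones(spec.grid_shape, dtype=bool)
    allowed[:spec.epidermis_z] = False       # depot stays inside the tissue
    # keep clear of the cannula plus its one-voxel partial-volume halo: a
    # depot voxel there is indistinguishable from the Teflon wall and is
    # removed by any cannula-masking analysis, so it is not part of the
    # measurable depot the phantom models
    halo = build_cannula_mask(spec.cannula, spec.grid_shape,
                              spec.voxel_size_um, dilation_vox=1.0)
    allowed &= ~halo

    # seed cap: allowed voxels within ~2 voxels of the removed halo at the
    # tip (the first insulin emerges around the cannula tip)
    r_seed = spec.cannula_radius_vox + 3.0
    lo = [max(int(t - r_seed - 1), 0) for t in (tz, ty, tx)]
    hi = [min(int(t + r_seed + 2), s)
          for t, s in zip((tz, ty, tx), spec.grid_shape)]
    cur = np.zeros(spec.grid_shape, dtype=bool)
    box = np.stack(np.meshgrid(*(np.arange(lo[k], hi[k]) for k in range(3)),
                               indexing="ij"), axis=-1)
    dist = np.linalg.norm(box - np.array([tz, ty, tx]), axis=-1)
    seedcap = (dist <= r_seed)
    cur[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = seedcap
    cur &= allowed

    masks = [np.zeros(spec.grid_shape, dtype=bool)
             for _ in range(min(first - 1, spec.n_frames))]
    flags: list[str] = []

    def grow(n_new: int) -> int:
        ext = ndimage.binary_dilation(cur, STRUCTURE_18) & ~cur & allowed
        fw = [tuple(v) for v in np.argwhere(ext & wall)]
        fo = [tuple(v) for v in np.argwhere(ext & ~wall)]
        added = 0
        while added < n_new and (fw or fo):
            use_wall = bool(fw) and (not fo or rng.random() < d.wall_preference)
            lst = fw if use_wall else fo
            v = lst.pop(int(rng.integers(len(lst))))
            if cur[v]:
                continue
            cur[v] = True
            added += 1
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if (0 <= w[0] < gz and 0 <= w[1] < gy and 0 <= w[2] < gx
                        and allowed[w] and not cur[w]):
                    (fw if wall[w] else fo).append(w)
        return added

    for i in range(first, spec.n_frames + 1):
        added = grow(d.voxels_per_impulse)
        if added < d.voxels_per_impulse and "growth_truncated" not in flags:
            flags.append("growth_truncated")
        masks.append(cur.copy())
    return masks, flags


def generate_depot_sequence(
    spec: PhantomSpec,
    seed: Optional[int] = None,
) -> tuple[list[VolumeFrame], GroundTruth]:
    """Generate the full noisy frame sequence and its ground truth.

    Frames 1 to (first post-start frame - 1) contain no depot; afterwards
    the true mask grows monotonically (each frame's mask contains the
    previous one).  Clean volumes are composed as background + cannula
    (+ bubble segment) + depot, even frames are shifted by the sub-voxel
    tilt, and Gaussian noise is added last.
    """
    seed = spec.seed if seed is None else seed
    background = generate_septa_background(spec, seed).data
    wall = septal_wall_mask(spec, seed)
    cannula_mask, _, _ = generate_cannula(spec, 1)

    if spec.depot.shape == "septal_growth":
        masks, gflags = _septal_masks(spec, _rng(seed, 2), wall, cannula_mask)
        vols = [None] * spec.n_frames
        surfs = [None] * spec.n_frames
        sizes = [None] * spec.n_frames
    else:
        masks, vols, surfs, sizes, gflags = _analytic_masks(spec)
        masks = [m & ~cannula_mask for m in masks]

    wall_frac = []
    for m in masks:
        n = int(m.sum())
        wall_frac.append(float((m & wall).sum()) / n if n else None)

    frames: list[VolumeFrame] = []
    bubble_flags: list[bool] = []
    for i in range(1, spec.n_frames + 1):
        _, bubble_mask, bflag = generate_cannula(spec, i)
        bubble_flags.append(bflag)
        clean = background.copy()
        clean[cannula_mask] = spec.cannula_intensity
        if bflag:
            clean[bubble_mask] = spec.septa.air_intensity
        clean[masks[i - 1]] = spec.depot.intensity
        if i % 2 == 0 and spec.even_frame_shift_vox:
            clean = ndimage.shift(clean, (0.0, spec.even_frame_shift_vox, 0.0),
                                  order=1, mode="nearest")
        frame = VolumeFrame(data=clean.astype(np.float32),
                            voxel_size_um=spec.voxel_size_um,
                            frame_index=i,
                            time_min=spec.frame_time_min(i))
        frames.append(add_noise(frame, spec.noise_gaussian_sd, seed))

    gt = GroundTruth(
        masks=masks,
        analytic_volume_mm3=vols,
        analytic_surface_mm2=surfs,
        size_parameter_vox=sizes,
        bubble_flags=bubble_flags,
        wall_fraction=wall_frac,
        flags=gflags,
    )
    return frames, gt


# --------------------------------------------------------------------------
# Pressure trace
# --------------------------------------------------------------------------

def impulse_schedule(spec: PhantomSpec) -> list[float]:
    """Impulse times (s): pump start, then one per frame interval, strictly
    before the session end (a 3 h session with a 10 min start offset and
    5 min intervals gives 34 impulses at minutes 10, 15, ..., 175)."""
    duration_s = spec.n_frames * spec.frame_interval_min * 60.0
    t = spec.pump_start_offset_min * 60.0
    step = spec.frame_interval_min * 60.0
    out = []
    while t < duration_s - 1e-9:
        out.append(t)
        t += step
    return out


def generate_pressure_trace(
    spec: PhantomSpec,
    seed: Optional[int] = None,
) -> tuple[PressureTrace, dict]:
    """Synthesize the pressure trace and return it with its true events."""
    p = spec.pressure
    if p.sampling_hz <= 0:
        raise ConfigError("sampling_hz must be positive")
    seed = spec.seed if seed is None else seed
    duration_s = spec.n_frames * spec.frame_interval_min * 60.0
    n = int(round(duration_s * p.sampling_hz))
    t = np.arange(n) / p.sampling_hz
    sig = np.full(n, p.baseline_mbar, dtype=np.float64)

    # step plateaus (5 s linear ramps), checked for overlap
    steps = sorted(p.step_events, key=lambda e: e[0])
    for a, b in zip(steps, steps[1:]):
        if a[0] + a[1] > b[0]:
            raise ConfigError(f"step events overlap: {a} and {b}")
    ramp_s = 5.0
    for start_min, dur_min, peak in steps:
        s0, s1 = start_min * 60.0, start_min * 60.0 + dur_min * 60.0
        amp = peak - p.baseline_mbar
        rise = np.clip((t - s0) / ramp_s, 0.0, 1.0)
        fall = np.clip((s1 - t) / ramp_s, 0.0, 1.0)
        sig += amp * np.minimum(rise, fall) * ((t >= s0) & (t <= s1))

    suppress = [(a * 60.0, b * 60.0) for a, b in p.suppress_impulses_min]
    if spec.occlusion_until_frame > 0:
        # no delivery while the set is occluded
        suppress.append(
            (0.0, spec.frame_time_min(spec.occlusion_until_frame + 1) * 60.0))
    impulses = []
    half = p.impulse_width_s / 2.0
    for tau in impulse_schedule(spec):
        if any(a <= tau <= b for a, b in suppress):
            continue
        impulses.append(tau)
        i0 = max(0, int((tau - half) * p.sampling_hz))
        i1 = min(n, int((tau + half) * p.sampling_hz) + 1)
        local = t[i0:i1]
        sig[i0:i1] += p.impulse_amplitude_mbar * \
            np.maximum(0.0, 1.0 - np.abs(local - tau) / half)

    if p.noise_sd_mbar > 0:
        sig += _rng(seed, 3).normal(0.0, p.noise_sd_mbar, n)
    if p.clip_mbar is not None:
        np.clip(sig, -p.clip_mbar, p.clip_mbar, out=sig)

    trace = PressureTrace(time_s=t, pressure_mbar=sig,
                          sampling_hz=p.sampling_hz)
    events = {
        "impulse_times_s": impulses,
        "step_events": [
            {"start_s": s * 60.0, "duration_s": d * 60.0, "peak_mbar": pk}
            for s, d, pk in steps],
        "suppressed_windows_s": suppress,
    }
    return trace, events


# --------------------------------------------------------------------------
# Spec (de)serialization
# --------------------------------------------------------------------------

def phantom_spec_to_dict(spec: PhantomSpec) -> dict:
    from dataclasses import asdict
    d = asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    d["bubble_frames"] = [list(r) for r in spec.bubble_frames]
    d["pressure"]["step_events"] = [list(e) for e in spec.pressure.step_events]
    d["pressure"]["suppress_impulses_min"] = [
        list(w) for w in spec.pressure.suppress_impulses_min]
    return d


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    if "grid_shape" in d:
        d["grid_shape"] = tuple(d["grid_shape"])
    if "bubble_frames" in d:
        d["bubble_frames"] = tuple(tuple(r) for r in d["bubble_frames"])
    if "septa" in d and isinstance(d["septa"], dict):
        d["septa"] = SeptaSpec(**d["septa"])
    if "depot" in d and isinstance(d["depot"], dict):
        d["depot"] = DepotSpec(**d["depot"])
    if "pressure" in d and isinstance(d["pressure"], dict):
        p = dict(d["pressure"])
        p["step_events"] = tuple(tuple(e) for e in p.get("step_events", ()))
        p["suppress_impulses_min"] = tuple(
            tuple(w) for w in p.get("suppress_impulses_min", ()))
        d["pressure"] = PressureSpec(**p)
    if d.get("cannula") is not None and isinstance(d["cannula"], dict):
        d["cannula"] = CannulaModel.from_dict(d["cannula"])
    return PhantomSpec(**d)


# --------------------------------------------------------------------------
# Full session
# --------------------------------------------------------------------------

def generate_session(
    spec: PhantomSpec,
    seed: Optional[int] = None,
) -> tuple[AssaySession, GroundTruth]:
    """Generate frames + pressure trace + config as one assay session."""
    seed = spec.seed if seed is None else seed
    frames, gt = generate_depot_sequence(spec, seed)
    trace, events = generate_pressure_trace(spec, seed)
    gt.impulse_times_s = list(events["impulse_times_s"])
    gt.step_events = list(events["step_events"])
    session = AssaySession(frames=frames, config=spec.session_config(),
                           pressure=trace)
    return session, gt
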