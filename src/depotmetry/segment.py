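"""Per-frame depot segmentation.

The depot is isolated by dual-reference subtraction followed by quantile
thresholding and seeded connected-component selection:

1. The two pre-infusion volumes serve as references: frame 1 for all
   odd-indexed frames, frame 2 for all even-indexed ones (odd and even
   frames are acquired with opposite rotation directions and carry a slight
   relative tilt, so each parity gets its own reference).
2. The cylindrical cannula volume (dilated by one voxel to cover the
   partial-volume halo around the Teflon wall) is zeroed everywhere.
3. The reference is subtracted slice by slice; negative values are clamped
   to zero.  No registration is applied: at these infused volumes the
   tissue displacement is negligible.
4. The clamped difference is min-max rescaled to [0, 1] (an order-preserving
   linear transformation kept for numerical hygiene and display) and
   binarized at its 0.95 quantile, computed over the entire masked volume
   including the clamped zeros.
5. Connected-component labeling with 18-connectivity (face + edge
   neighbors, no vertex diagonals) keeps only the component that contains
   the cannula tip; if the tip voxel itself was carved out by the cannula
   mask the search widens to its 18-neighborhood and then, optionally, to
   the nearest foreground voxel within a small radius around the tip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import ConfigError, FormatError, InsufficientReferencesError
from .session_io import AssaySession, CannulaModel, VolumeFrame

#: 18-connectivity structuring element: faces and edges, not vertices.
STRUCTURE_18 = ndimage.generate_binary_structure(3, 2)


@dataclass
class DepotMask:
    """Binary 3D mask of the segmented depot for one frame."""

    mask: np.ndarray
    voxel_size_um: float
    frame_index: int
    seed_voxel: tuple[int, int, int]
    flags: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def select_references(session: AssaySession) -> tuple[VolumeFrame, VolumeFrame]:
    """Return the (odd-frame, even-frame) pre-infusion reference volumes.

    Frame 1 is the reference for all odd-indexed frames and frame 2 for all
    even-indexed ones.  With the default schedule (pump start 10 min after
    the acquisition cascade, one volume per 5 min) exactly these two frames
    are free of insulin.
    """
    if len(session.frames) < 2:
        raise InsufficientReferencesError(
            "a session needs at least 2 frames to provide the per-parity "
            "pre-infusion references"
        )
    ref_odd = session.frame(1)
    ref_even = session.frame(2)
    return ref_odd, ref_even


def build_cannula_mask(
    cannula: CannulaModel,
    grid_shape: tuple[int, int, int],
    voxel_size_um: float,
    dilation_vox: float = 1.0,
) -> np.ndarray:
    """Rasterize the cannula cylinder, dilated by ``dilation_vox`` voxels.

    A voxel belongs to the mask when its center lies within
    ``radius_um / voxel_size_um + dilation_vox`` of the entry-tip segment.
    """
    entry = np.asarray(cannula.entry_point_vox, dtype=float)
    tip = np.asarray(cannula.tip_point_vox, dtype=float)
    for p, name in ((entry, "entry"), (tip, "tip")):
        if np.any(p < 0) or np.any(p >= np.asarray(grid_shape)):
            raise ConfigError(f"cannula {name} point {tuple(p)} outside grid "
                              f"{grid_shape}")
    r_vox = cannula.radius_um / voxel_size_um + dilation_vox
    axis = tip - entry
    norm2 = float(axis @ axis)
    if norm2 == 0:
        raise ConfigError("degenerate cannula segment")

    # Work on a bounding box around the segment to keep memory local.
    lo = np.maximum(np.floor(np.minimum(entry, tip) - r_vox - 1), 0).astype(int)
    hi = np.minimum(np.ceil(np.maximum(entry, tip) + r_vox + 1),
                    np.asarray(grid_shape)).astype(int)
    zz, yy, xx = np.meshgrid(*(np.arange(lo[d], hi[d]) for d in range(3)),
                             indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    rel = pts - entry
    t = np.clip((rel @ axis) / norm2, 0.0, 1.0)
    closest = entry + t[..., None] * axis
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    sub = dist2 <= r_vox * r_vox

    mask = np.zeros(grid_shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask


def subtract_reference(
    frame: VolumeFrame | np.ndarray,
    reference: VolumeFrame | np.ndarray,
    cannula_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Clamped difference ``max(frame - reference, 0)`` with cannula zeroed."""
    f = frame.data if isinstance(frame, VolumeFrame) else np.asarray(frame)
    r = reference.data if isinstance(reference, VolumeFrame) \
        else np.asarray(reference)
    if f.shape != r.shape:
        raise FormatError(
            f"frame shape {f.shape} != reference shape {r.shape}")
    diff = f.astype(np.float64) - r.astype(np.float64)
    np.clip(diff, 0.0, None, out=diff)
    if cannula_mask is not None:
        diff[cannula_mask] = 0.0
    return diff


def threshold_quantile(
    difference: np.ndarray,
    q: float = 0.95,
) -> tuple[np.ndarray, list[str]]:
    """Binarize a difference volume at its q-quantile.

    The volume is first linearly rescaled to [0, 1]; since the rescale is
    order-preserving it cannot change which voxels pass.  Foreground voxels
    are those *strictly greater* than the linear-interpolation q-quantile of
    all voxels (ties sit in the background), so the foreground fraction is
    at most ``1 - q`` plus any tie mass.  A constant volume has no
    foreground and is flagged.
    """
    if not (0 < q < 1):
        raise ConfigError("quantile q must lie in (0, 1)")
    difference = np.asarray(difference, dtype=np.float64)
    lo = float(difference.min())
    hi = float(difference.max())
    if hi == lo:
        return np.zeros(difference.shape, dtype=bool), ["constant_volume"]
    scaled = (difference - lo) / (hi - lo)
    thr = float(np.quantile(scaled, q))
    return scaled > thr, []


def select_depot_component(
    binary: np.ndarray,
    seed_voxel: tuple[int, int, int],
    voxel_size_um: float = 1.0,
    frame_index: int = 1,
    search_radius_vox: float = 0.0,
) -> DepotMask:
    """Keep only the 18-connected component seeded at the cannula tip.

    If the seed voxel is background the 18-neighborhood of the seed is
    examined (the cannula-mask removal may carve out the exact tip
    coordinate); with ``search_radius_vox > 0`` the search further extends
    to the nearest foreground voxel within that radius of the seed, which
    is needed when the dilated cannula mask clears the whole tip
    neighborhood.  Among several candidate components the one with the
    closest foreground voxel wins.  Without any candidate the result is an
    empty mask flagged ``empty_depot``.
    """
    binary = np.asarray(binary, dtype=bool)
    seed = tuple(int(round(v)) for v in seed_voxel)
    if not all(0 <= seed[d] < binary.shape[d] for d in range(3)):
        raise ConfigError(f"seed voxel {seed} outside grid {binary.shape}")

    labels, _ = ndimage.label(binary, structure=STRUCTURE_18)
    target = labels[seed]
    if target == 0:
        # 18-neighborhood of the seed, then (optionally) a widening search.
        candidates: set[int] = set()
        offsets = np.argwhere(STRUCTURE_18) - 1
        offsets = offsets[np.any(offsets != 0, axis=1)]
        for off in offsets:
            w = tuple(seed + off)
            if all(0 <= w[d] < binary.shape[d] for d in range(3)) and labels[w]:
                candidates.add(int(labels[w]))
        if not candidates and search_radius_vox > 0:
            r = int(math.ceil(search_radius_vox))
            lo = [max(seed[d] - r, 0) for d in range(3)]
            hi = [min(seed[d] + r + 1, binary.shape[d]) for d in range(3)]
            box = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            zz, yy, xx = np.nonzero(box)
            d2 = ((zz + lo[0] - seed[0]) ** 2 + (yy + lo[1] - seed[1]) ** 2
                  + (xx + lo[2] - seed[2]) ** 2)
            near = d2 <= search_radius_vox ** 2
            candidates = set(np.unique(box[zz[near], yy[near],
                                           xx[near]]).tolist())
        if candidates:
            # several components can touch the carved tip region; the depot
            # is the one that dominates it, so keep the largest
            sizes = np.bincount(labels.ravel())
            target = max(candidates, key=lambda lab: (sizes[lab], -lab))

    if target == 0:
        return DepotMask(
            mask=np.zeros(binary.shape, dtype=bool),
            voxel_size_um=voxel_size_um,
            frame_index=frame_index,
            seed_voxel=seed,
            flags=["empty_depot"],
        )
    return DepotMask(
        mask=labels == target,
        voxel_size_um=voxel_size_um,
        frame_index=frame_index,
        seed_voxel=seed,
    )


def segment_frame(
    frame: VolumeFrame,
    reference: VolumeFrame,
    cannula_mask: Optional[np.ndarray],
    seed_voxel: tuple[int, int, int],
    q: float = 0.95,
    search_radius_vox: float = 0.0,
) -> DepotMask:
    """Run the full subtraction -> threshold -> seeded-component chain."""
    diff = subtract_reference(frame, reference, cannula_mask)
    binary, flags = threshold_quantile(diff, q)
    depot = select_depot_component(
        binary, seed_voxel,
        voxel_size_um=frame.voxel_size_um,
        frame_index=frame.frame_index,
        search_radius_vox=search_radius_vox,
    )
    depot.flags = flags + depot.flags
    return depot


def segment_session(
    session: AssaySession,
    dilation_vox: float = 1.0,
) -> list[DepotMask]:
    """Segment every frame of a session.

    The two reference frames are emitted as empty masks flagged
    ``reference_frame``; frames acquired before the pump start are
    additionally flagged ``pre_infusion``.  The seeded-component search
    radius is derived from the cannula geometry (nominal radius + dilation
    + 2 voxels) so that a depot hugging the removed cannula tip is still
    found.
    """
    cfg = session.config
    if cfg.cannula is None:
        raise ConfigError("session config has no cannula model")
    ref_odd, ref_even = select_references(session)
    cannula_mask = build_cannula_mask(
        cfg.cannula, session.grid_shape, session.voxel_size_um, dilation_vox)
    seed = tuple(int(round(v)) for v in cfg.cannula.tip_point_vox)
    r_vox = cfg.cannula.radius_um / session.voxel_size_um
    search_radius = r_vox + dilation_vox + 2.0

    out = []
    for frame in session.frames:
        if frame.frame_index <= 2:
            out.append(DepotMask(
                mask=np.zeros(session.grid_shape, dtype=bool),
                voxel_size_um=session.voxel_size_um,
                frame_index=frame.frame_index,
                seed_voxel=seed,
                flags=["reference_frame", "pre_infusion"],
            ))
            continue
        ref = ref_odd if frame.parity == "odd" else ref_even
        depot = segment_frame(
            frame, ref, cannula_mask, seed,
            q=cfg.quantile_q, search_radius_vox=search_radius)
        if frame.time_min < cfg.pump_start_offset_min:
            depot.flags.append("pre_infusion")
        out.append(depot)
    return out
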