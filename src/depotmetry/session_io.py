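"""Reading, writing and assembly of assay sessions.

An assay session is a time-ordered series of reconstructed 3D grayscale
volumes (one per acquisition interval, here one volume every 5 minutes over
3 hours), an optional in-line pressure trace, and the session configuration
(pump schedule, cannula geometry, skin-layer depths).

Conventions
-----------
* Voxel indices are 0-based, axis order ``(z, y, x)`` with ``z`` the depth
  axis increasing from the skin surface into the tissue.
* All lengths are reported in mm, volumes in mm^3 (1 mm^3 == 1 uL) and
  surfaces in mm^2; voxel size is given in micrometres and is isotropic.
* Frame indices are 1-based.  Frames with an odd index are acquired with a
  clockwise source rotation, even frames counterclockwise, which is why the
  segmentation stage keeps one reference volume per parity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, FormatError, InsufficientReferencesError

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .classify import LayerMap
    from .pressure import PressureTrace


FRAME_PATTERN = re.compile(r"frame_(\d+)\.tiff?$")


@dataclass
class CannulaModel:
    """Parametric model of the inserted cannula.

    The cannula is a cylinder between ``entry_point_vox`` (where it crosses
    the top of the imaged volume) and ``tip_point_vox`` (the tip seeding the
    depot segmentation), with physical radius ``radius_um``.
    """

    entry_point_vox: tuple[float, float, float]
    tip_point_vox: tuple[float, float, float]
    radius_um: float
    length_um: Optional[float] = None

    def __post_init__(self):
        self.entry_point_vox = tuple(float(v) for v in self.entry_point_vox)
        self.tip_point_vox = tuple(float(v) for v in self.tip_point_vox)
        if self.entry_point_vox == self.tip_point_vox:
            raise ConfigError("cannula entry and tip points coincide")
        if self.radius_um <= 0:
            raise ConfigError("cannula radius must be positive")

    def axis_length_vox(self) -> float:
        e = np.asarray(self.entry_point_vox, dtype=float)
        t = np.asarray(self.tip_point_vox, dtype=float)
        return float(np.linalg.norm(t - e))

    def validate_length(self, voxel_size_um: float) -> None:
        """Check declared physical length against the entry-tip segment.

        The declared ``length_um`` must agree with ``|entry - tip|`` to
        within one voxel; inconsistent geometry raises :class:`ConfigError`.
        """
        if self.length_um is None:
            return
        seg_um = self.axis_length_vox() * voxel_size_um
        if abs(seg_um - self.length_um) > voxel_size_um:
            raise ConfigError(
                f"cannula length {self.length_um} um inconsistent with "
                f"entry-tip segment {seg_um:.1f} um (> 1 voxel apart)"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CannulaModel":
        return cls(
            entry_point_vox=tuple(d["entry_point_vox"]),
            tip_point_vox=tuple(d["tip_point_vox"]),
            radius_um=float(d["radius_um"]),
            length_um=d.get("length_um"),
        )


@dataclass
class VolumeFrame:
    """One reconstructed 3D grayscale volume with acquisition metadata."""

    data: np.ndarray
    voxel_size_um: float
    frame_index: int
    time_min: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise FormatError(
                f"volume must be 3D with every dimension >= 2, got shape "
                f"{self.data.shape}"
            )
        if self.voxel_size_um <= 0:
            raise ConfigError("voxel_size_um must be positive")
        if self.frame_index < 1:
            raise ConfigError("frame_index is 1-based and must be >= 1")

    @property
    def parity(self) -> str:
        """``"odd"`` or ``"even"``, from the 1-based frame index."""
        return "odd" if self.frame_index % 2 == 1 else "even"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SessionConfig:
    """Acquisition and infusion schedule plus geometry for one assay.

    Defaults describe the reference protocol: a 3 h acquisition at one
    volume per 5 min (36 frames), pump started 10 min after the first
    acquisition, basal rate 1 UI/h.
    """

    frame_interval_min: float = 5.0
    session_duration_min: float = 180.0
    pump_start_offset_min: float = 10.0
    basal_rate_UI_per_h: float = 1.0
    cannula: Optional[CannulaModel] = None
    layer_boundaries: Optional["LayerMap"] = None
    quantile_q: float = 0.95

    def __post_init__(self):
        if self.frame_interval_min <= 0:
            raise ConfigError("frame_interval_min must be positive")
        if not (0 <= self.pump_start_offset_min < self.session_duration_min):
            raise ConfigError(
                "pump_start_offset_min must lie in [0, session_duration_min)"
            )
        if not (0 < self.quantile_q < 1):
            raise ConfigError("quantile_q must lie in (0, 1)")

    @property
    def n_frames(self) -> int:
        """Number of frames the schedule yields.

        Frame k is acquired over ``[(k-1)*interval, k*interval)``, so a
        180 min session at 5 min per volume yields 36 frames (the last one
        starting at 175 min).
        """
        return int(math.floor(
            (self.session_duration_min - 1e-9) / self.frame_interval_min)) + 1

    def frame_time_min(self, frame_index: int) -> float:
        return self.frame_interval_min * (frame_index - 1)

    def to_dict(self) -> dict:
        d = {
            "frame_interval_min": self.frame_interval_min,
            "session_duration_min": self.session_duration_min,
            "pump_start_offset_min": self.pump_start_offset_min,
            "basal_rate_UI_per_h": self.basal_rate_UI_per_h,
            "quantile_q": self.quantile_q,
        }
        if self.cannula is not None:
            d["cannula"] = self.cannula.to_dict()
        if self.layer_boundaries is not None:
            d["layer_boundaries"] = self.layer_boundaries.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        from .classify import LayerMap

        kwargs = {k: d[k] for k in (
            "frame_interval_min", "session_duration_min",
            "pump_start_offset_min", "basal_rate_UI_per_h", "quantile_q",
        ) if k in d}
        if d.get("cannula") is not None:
            kwargs["cannula"] = CannulaModel.from_dict(d["cannula"])
        if d.get("layer_boundaries") is not None:
            kwargs["layer_boundaries"] = LayerMap.from_dict(
                d["layer_boundaries"])
        return cls(**kwargs)


@dataclass
class AssaySession:
    """A complete assay: ordered frames, optional pressure trace, config."""

    frames: list[VolumeFrame]
    config: SessionConfig
    pressure: Optional["PressureTrace"] = None
    missing_frames: list[int] = field(default_factory=list)

    def __post_init__(self):
        idx = [f.frame_index for f in self.frames]
        if sorted(idx) != idx or len(set(idx)) != len(idx):
            raise FormatError("frame indices must be strictly increasing")
        expected = set(range(idx[0], idx[-1] + 1)) if idx else set()
        gaps = expected - set(idx) - set(self.missing_frames)
        if gaps:
            raise FormatError(
                f"frame indices have unflagged gaps: {sorted(gaps)}")
        shapes = {f.shape for f in self.frames}
        vox = {f.voxel_size_um for f in self.frames}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent frame shapes: {shapes}")
        if len(vox) > 1:
            raise FormatError(f"inconsistent voxel sizes: {vox}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames[0].shape

    @property
    def voxel_size_um(self) -> float:
        return self.frames[0].voxel_size_um

    def frame(self, frame_index: int) -> VolumeFrame:
        for f in self.frames:
            if f.frame_index == frame_index:
                return f
        raise KeyError(f"no frame with index {frame_index}")


def discover_frame_paths(directory: str | Path) -> list[Path]:
    """Find ``frame_###.tif`` files in *directory*, ordered by frame number."""
    directory = Path(directory)
    found = []
    for p in directory.iterdir():
        m = FRAME_PATTERN.search(p.name)
        if m:
            found.append((int(m.group(1)), p))
    if not found:
        raise FormatError(f"no frame_###.tif files found in {directory}")
    found.sort(key=lambda t: t[0])
    return [p for _, p in found]


def read_volume_series(
    paths: Sequence[str | Path],
    voxel_size_um: float,
    frame_interval_min: float = 5.0,
    config: Optional[SessionConfig] = None,
) -> AssaySession:
    """Load a time-ordered series of TIFF stacks into an :class:`AssaySession`.

    Each path holds one multi-page TIFF (z-slices as pages) for one time
    step; the position in *paths* assigns the 1-based frame index, from
    which acquisition time and rotation parity follow.

    Raises
    ------
    InsufficientReferencesError
        If fewer than two volumes are given -- the segmentation stage needs
        the two pre-infusion volumes as references.
    FormatError
        If the volumes do not all share the same grid shape.
    """
    paths = list(paths)
    if len(paths) < 2:
        raise InsufficientReferencesError(
            f"need at least 2 volumes (pre-infusion references), "
            f"got {len(paths)}"
        )
    if config is None:
        duration = frame_interval_min * len(paths)
        offset = 2.0 * frame_interval_min  # frames 1-2 are the references
        config = SessionConfig(
            frame_interval_min=frame_interval_min,
            session_duration_min=duration,
            pump_start_offset_min=offset if offset < duration else 0.0,
        )
    frames = []
    shape = None
    for i, p in enumerate(paths, start=1):
        data = tifffile.imread(str(p))
        if data.ndim == 2:
            data = data[np.newaxis]
        if shape is None:
            shape = data.shape
        elif data.shape != shape:
            raise FormatError(
                f"volume {p} has shape {data.shape}, expected {shape}")
        frames.append(VolumeFrame(
            data=data,
            voxel_size_um=voxel_size_um,
            frame_index=i,
            time_min=config.frame_time_min(i),
        ))
    return AssaySession(frames=frames, config=config)


def write_volume_series(session: AssaySession, directory: str | Path) -> list[Path]:
    """Write each frame as ``frame_###.tif`` (z-pages) under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for f in session.frames:
        p = directory / f"frame_{f.frame_index:03d}.tif"
        tifffile.imwrite(str(p), f.data, photometric="minisblack")
        out.append(p)
    return out


def load_session_config(path: str | Path) -> SessionConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"config file {path} does not hold a mapping")
    return SessionConfig.from_dict(d)


def save_session_config(config: SessionConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


MORPHO_COLUMNS = [
    "frame_index", "time_min", "volume_mm3", "surface_mm2",
    "r_compact_mm", "s_compact_mm2", "iod", "flags",
]


def write_morphometry_table(records: Iterable, path: str | Path) -> pd.DataFrame:
    """Write per-frame morphometry records to CSV.

    Records are :class:`depotmetry.morpho.DepotMorphometry` instances (or
    anything exposing the same attributes).  Frames without a measurable
    depot (pre-infusion, empty or missing) are emitted with empty numeric
    fields and their flags, not dropped: the output always has one row per
    frame so downstream aggregation can see which frames were uncomputable.
    """
    rows = []
    for r in records:
        rows.append({
            "frame_index": r.frame_index,
            "time_min": r.time_min,
            "volume_mm3": r.volume_mm3,
            "surface_mm2": r.surface_mm2,
            "r_compact_mm": r.r_compact_mm,
            "s_compact_mm2": r.s_compact_mm2,
            "iod": r.iod,
            "flags": ";".join(r.flags) if r.flags else "",
        })
    df = pd.DataFrame(rows, columns=MORPHO_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")
    return df


def read_morphometry_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MORPHO_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"morphometry table missing columns: {missing}")
    df["flags"] = df["flags"].fillna("")
    return df
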