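"""Automated infusion-layer classification.

Skin explants present three layers along the depth axis: epidermis (top),
dermis, hypodermis.  The infusion site taxonomy follows what the cannula
tip reached:

* ``extradermal``             -- tip above the skin surface;
* ``intradermal``             -- tip inside the dermis;
* ``dermis_hypodermis_limit`` -- tip within a tolerance band around the
  dermis-hypodermis boundary (the band width is a free parameter, default
  3 voxels ~ 51 um at 17 um voxels, because the visual "limit" class has no
  quantified tolerance);
* ``hypodermal``              -- tip below the boundary (the intended CSII
  target).

The primary label depends only on the tip depth; per-layer depot volume
fractions are reported separately and depend only on the mask and the layer
map, with spread notes (e.g. an intradermal infusion partly spreading into
the hypodermis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError
from .segment import DepotMask
from .session_io import CannulaModel

LABELS = {
    "extradermal": "extradermal",
    "dermis": "intradermal",
    "limit": "dermis_hypodermis_limit",
    "hypodermis": "hypodermal",
}

#: Depot volume fraction in a non-tip layer above which a spread note is added.
SPREAD_NOTE_MIN_FRACTION = 0.05


@dataclass
class LayerMap:
    """Depths (voxel indices along z) of the skin-layer boundaries.

    ``epidermis_z`` is the skin surface: voxels with z below it are outside
    the tissue.  ``dermis_hypodermis_z`` separates dermis from hypodermis.
    Optional per-(x, y) boundary surfaces (2D arrays) replace the flat
    depths where supplied.
    """

    epidermis_z: float
    dermis_hypodermis_z: float
    epidermis_surface: Optional[np.ndarray] = None
    dermis_hypodermis_surface: Optional[np.ndarray] = None

    def __post_init__(self):
        if not (0 <= self.epidermis_z < self.dermis_hypodermis_z):
            raise ConfigError(
                "layer depths must satisfy 0 <= epidermis_z < "
                "dermis_hypodermis_z")

    def boundaries_at(self, y: int, x: int) -> tuple[float, float]:
        ez = (self.epidermis_surface[y, x]
              if self.epidermis_surface is not None else self.epidermis_z)
        dz = (self.dermis_hypodermis_surface[y, x]
              if self.dermis_hypodermis_surface is not None
              else self.dermis_hypodermis_z)
        return float(ez), float(dz)

    def to_dict(self) -> dict:
        return {"epidermis_z": self.epidermis_z,
                "dermis_hypodermis_z": self.dermis_hypodermis_z}

    @classmethod
    def from_dict(cls, d: dict) -> "LayerMap":
        return cls(epidermis_z=float(d["epidermis_z"]),
                   dermis_hypodermis_z=float(d["dermis_hypodermis_z"]))


@dataclass
class InfusionClassification:
    """Tip layer, mapped label, per-layer depot fractions, spread notes."""

    tip_layer: str                      # extradermal / dermis / limit / hypodermis
    label: str                          # the four-category taxonomy
    fractions: dict[str, float]         # extradermal / dermis / hypodermis
    notes: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _tip_layer(tip_z: float, ez: float, dz: float, limit_band_vox: float) -> str:
    if tip_z < ez:
        return "extradermal"
    if abs(tip_z - dz) <= limit_band_vox:
        return "limit"
    if tip_z < dz:
        return "dermis"
    return "hypodermis"


def classify_infusion(
    mask: Optional[DepotMask],
    layers: LayerMap,
    cannula: CannulaModel,
    limit_band_vox: float = 3.0,
) -> InfusionClassification:
    """Classify one infusion from its depot mask and cannula tip depth.

    The label derives from the tip depth alone; depot volume fractions per
    layer are computed from the mask voxel depths.  An empty (or missing)
    mask still yields a tip-based label, flagged ``empty_depot``.
    """
    tip = cannula.tip_point_vox
    tip_z = float(tip[0])
    ez, dz = layers.boundaries_at(int(round(tip[1])), int(round(tip[2])))
    layer = _tip_layer(tip_z, ez, dz, limit_band_vox)
    label = LABELS[layer]

    fractions = {"extradermal": 0.0, "dermis": 0.0, "hypodermis": 0.0}
    flags: list[str] = []
    notes: list[str] = []
    if mask is None or mask.empty:
        flags.append("empty_depot")
    else:
        if layers.epidermis_surface is None and \
                layers.dermis_hypodermis_surface is None:
            z = np.nonzero(mask.mask)[0].astype(float)
            n = z.size
            fractions["extradermal"] = float(np.sum(z < ez)) / n
            fractions["dermis"] = float(np.sum((z >= ez) & (z < dz))) / n
            fractions["hypodermis"] = float(np.sum(z >= dz)) / n
        else:
            zz, yy, xx = np.nonzero(mask.mask)
            n = zz.size
            ezs = (layers.epidermis_surface[yy, xx]
                   if layers.epidermis_surface is not None else ez)
            dzs = (layers.dermis_hypodermis_surface[yy, xx]
                   if layers.dermis_hypodermis_surface is not None else dz)
            fractions["extradermal"] = float(np.sum(zz < ezs)) / n
            fractions["dermis"] = float(np.sum((zz >= ezs) & (zz < dzs))) / n
            fractions["hypodermis"] = float(np.sum(zz >= dzs)) / n

        for other, text in (
            ("hypodermis", "partly spread in the hypodermis"),
            ("dermis", "partly spread in the dermis"),
            ("extradermal", "partly spread above the skin surface"),
        ):
            tip_region = {"extradermal": "extradermal", "dermis": "dermis",
                          "limit": "dermis", "hypodermis": "hypodermis"}[layer]
            if other != tip_region and \
                    fractions[other] >= SPREAD_NOTE_MIN_FRACTION:
                notes.append(text)

    return InfusionClassification(
        tip_layer=layer,
        label=label,
        fractions=fractions,
        notes=notes,
        flags=flags,
    )
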