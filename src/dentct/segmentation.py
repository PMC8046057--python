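"""Density-window tissue segmentation.

Windows (mg/cm³ HA) follow the dental μCT convention for deciduous teeth:
enamel strictly above 1600; dentin in the closed interval [650, 1600];
acellular cementum candidates in [450, 1050] on a median-filtered volume,
kept only where the original volume exceeds 650 (filter-and-mask-back);
interglobular dentin below 650 inside the crown-dentin territory.  The
bounds are recorded verbatim in every mask's provenance, and boundary
semantics are chosen so the enamel/dentin/interglobular windows partition
the density axis disjointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibratedVolume
from .anatomy import RegionOfInterest

__all__ = [
    "TissueMask",
    "SegmentationError",
    "THRESHOLDS",
    "segment_enamel",
    "segment_dentin",
    "segment_pulp",
    "segment_cementum",
    "segment_interglobular",
    "remove_small_components",
]

# default density windows; `igd_fig` is the alternative interglobular
# threshold used for display-style renderings
THRESHOLDS = {
    "enamel_lo": 1600.0,
    "dentin_lo": 650.0,
    "dentin_hi": 1600.0,
    "cementum_lo": 450.0,
    "cementum_hi": 1050.0,
    "cementum_maskback": 650.0,
    "igd_hi": 650.0,
    "igd_fig": 450.0,
    "pulp_hi": 450.0,
}


class SegmentationError(RuntimeError):
    pass


@dataclass
class TissueMask:
    """Boolean voxel mask with its tissue label and threshold provenance."""

    mask: np.ndarray
    tissue: str
    lo: float | None
    hi: float | None
    lo_strict: bool = False
    hi_strict: bool = False
    filter: str = "none"
    extra: dict = field(default_factory=dict)

    @property
    def voxels(self) -> int:
        return int(self.mask.sum())

    def provenance(self) -> dict:
        return {
            "tissue": self.tissue,
            "lo": self.lo,
            "hi": self.hi,
            "lo_strict": self.lo_strict,
            "hi_strict": self.hi_strict,
            "filter": self.filter,
            **self.extra,
        }


def _data(vol) -> np.ndarray:
    return vol.data if isinstance(vol, CalibratedVolume) else np.asarray(vol)


def remove_small_components(mask, min_voxels: int = 27) -> np.ndarray:
    """Drop 3D connected components smaller than ``min_voxels``.

    Grey-value noise flips isolated voxels across a threshold; real
    anatomy forms large connected structures.  Landmark detection on
    noisy volumes runs on masks cleaned this way so that a single stray
    supra-threshold voxel deep in the root cannot masquerade as the
    apical extension of enamel.
    """
    m = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(m)
    if n == 0:
        return m
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[labels]


def segment_enamel(vol, threshold: float = THRESHOLDS["enamel_lo"]) -> TissueMask:
    """Enamel: density strictly above the enamel floor (1600 mg/cm³ HA)."""
    d = _data(vol)
    return TissueMask(d > threshold, "enamel", lo=threshold, hi=None, lo_strict=True)


def segment_dentin(vol, lo: float = THRESHOLDS["dentin_lo"],
                   hi: float = THRESHOLDS["dentin_hi"]) -> TissueMask:
    """Dentin: closed density window [650, 1600] mg/cm³ HA."""
    d = _data(vol)
    return TissueMask((d >= lo) & (d <= hi), "dentin", lo=lo, hi=hi)


def segment_pulp(vol, threshold: float = THRESHOLDS["pulp_hi"]) -> TissueMask:
    """Pulp cavity: sub-450 voxels enclosed by the mineralized cross-section.

    The tooth cross-section is hole-filled per axial slice, so the pulp
    chamber/canal (enclosed in-plane, open along the axis) is captured
    while exterior background is not.
    """
    d = _data(vol)
    hard = d >= threshold
    enclosed = np.empty_like(hard)
    for z in range(hard.shape[0]):
        enclosed[z] = ndimage.binary_fill_holes(hard[z])
    return TissueMask(enclosed & (d < threshold), "pulp", lo=None, hi=threshold,
                      hi_strict=True)


def segment_cementum(
    vol,
    pulp_mask,
    lo: float = THRESHOLDS["cementum_lo"],
    hi: float = THRESHOLDS["cementum_hi"],
    maskback: float = THRESHOLDS["cementum_maskback"],
    kernel: int = 11,
    filter_mode: str = "3d",
    zrange: tuple[int, int] | None = None,
) -> TissueMask:
    """Acellular cementum by filter-and-mask-back.

    1. median filter (kernel 11, volumetric by default; ``filter_mode='2d'``
       filters each axial slice with an 11×11 kernel instead);
    2. threshold the filtered volume at [450, 1050];
    3. drop candidate components adjacent to the pulp cavity — the
       automated surrogate for manually excluding softer dentin highlighted
       next to the pulp;
    4. keep only voxels whose ORIGINAL density exceeds 650; all
       quantification downstream uses original densities.

    ``zrange`` restricts the computation to an axial slab (e.g. the root);
    the median filter support is padded inside the full volume so results
    within the slab are unchanged.
    """
    d = _data(vol)
    pulp = np.asarray(pulp_mask.mask if isinstance(pulp_mask, TissueMask) else pulp_mask,
                      dtype=bool)
    full_shape = d.shape
    pad = kernel // 2
    if zrange is not None:
        z0, z1 = max(0, zrange[0]), min(full_shape[0], zrange[1])
        z0p, z1p = max(0, z0 - pad), min(full_shape[0], z1 + pad)
        dcrop = d[z0p:z1p]
    else:
        z0 = z0p = 0
        z1 = z1p = full_shape[0]
        dcrop = d

    if filter_mode == "3d":
        filt = ndimage.median_filter(dcrop, size=kernel)
    elif filter_mode == "2d":
        filt = np.stack([ndimage.median_filter(sl, size=kernel) for sl in dcrop])
    else:
        raise ValueError(f"unknown filter_mode {filter_mode!r}")

    cand_crop = (filt >= lo) & (filt <= hi)
    cand = np.zeros(full_shape, dtype=bool)
    cand[z0p:z1p] = cand_crop
    if zrange is not None:
        cand[:z0] = False
        cand[z1:] = False

    labels, n = ndimage.label(cand)
    if n:
        near_pulp = ndimage.binary_dilation(pulp)
        bad = np.unique(labels[near_pulp & (labels > 0)])
        if bad.size:
            cand &= ~np.isin(labels, bad)

    mask = cand & (d > maskback)
    if not mask.any():
        warnings.warn("cementum segmentation is empty (aplastic cementum?)")
    return TissueMask(
        mask, "cementum", lo=lo, hi=hi,
        filter=f"median-{kernel}-{filter_mode}",
        extra={"maskback_gt": maskback, "zrange": zrange},
    )


def segment_interglobular(
    vol,
    crown_roi: RegionOfInterest,
    dentin: TissueMask | None = None,
    threshold: float = THRESHOLDS["igd_hi"],
    closing_um: float = 35.0,
    voxel_size_um: float | None = None,
) -> tuple[TissueMask, np.ndarray]:
    """Interglobular dentin: sub-650 voxels inside the crown dentin territory.

    The dentin territory is the crown-ROI dentin mask with its internal
    cavities closed: 3D hole filling captures enclosed hypomineralized
    voids, and a morphological closing (ball radius ``closing_um``)
    additionally recovers voids cut by the ROI faces, which hole filling
    alone would treat as open.  The pulp chamber — open at the crop faces
    and far wider than the closing ball — stays excluded.  Returns the
    interglobular mask and the territory mask (both full-volume shaped).
    """
    d = _data(vol)
    if voxel_size_um is None:
        voxel_size_um = getattr(vol, "voxel_size_um", 10.0)
    if dentin is None:
        dentin = segment_dentin(vol)
    crop = dentin.mask[crown_roi.zslice]
    if not crop.any():
        raise SegmentationError("crown ROI contains no dentin")
    filled = ndimage.binary_fill_holes(crop)
    rc = max(1, int(np.ceil(closing_um / voxel_size_um)))
    off = np.ogrid[-rc:rc + 1, -rc:rc + 1, -rc:rc + 1]
    ball = (off[0] ** 2 + off[1] ** 2 + off[2] ** 2) <= rc ** 2
    # replicate the end slices so the closing sees continuing anatomy at
    # the crop faces instead of an artificial boundary
    padded = np.pad(crop, ((rc, rc), (0, 0), (0, 0)), mode="edge")
    closed = ndimage.binary_closing(padded, structure=ball)[rc:-rc]
    filled |= closed
    # exclude the pulp cavity itself: sub-threshold components spanning the
    # whole ROI axially are the open pulp chamber/canal (voids never do)
    dcrop = d[crown_roi.zslice]
    low = filled & (dcrop < threshold)
    lbl, n = ndimage.label(low)
    if n:
        spanning = np.intersect1d(np.unique(lbl[0]), np.unique(lbl[-1]))
        spanning = spanning[spanning > 0]
        if spanning.size:
            filled &= ~np.isin(lbl, spanning)
    territory = np.zeros(d.shape, dtype=bool)
    territory[crown_roi.zslice] = filled
    igd = territory & (d < threshold)
    tm = TissueMask(
        igd, "interglobular_dentin", lo=None, hi=threshold, hi_strict=True,
        extra={"roi": [crown_roi.z_start, crown_roi.z_stop]},
    )
    return tm, territory
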