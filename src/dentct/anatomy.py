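"""Tooth orientation, landmark detection, and region-of-interest rules.

Axial convention: slices are indexed along array axis 0 with the index
increasing coronally — slice 0 lies at the root-apex side.  All slice
ranges are half-open and 0-based; μm extents are converted to slice counts
with ceiling division so results are bit-reproducible.

Landmarks: the cementum–enamel junction (CEJ) is found by scanning axial
slices from the root toward the crown and taking the first slice on which
the enamel cross-section forms a topologically complete ring (the
non-enamel pixels split into an inside and an outside component under
4-connectivity).  The apical extension of enamel is the most apical slice
containing any enamel voxel.

ROIs: crown measurements use the 0.5 mm (50 slices at 10 μm) coronal to
the CEJ; root dentin uses a 0.5 mm span beginning 150 μm apical of the
apical enamel extension; acellular cementum uses the most apical 25–50
consecutive slices on which cementum forms a complete ring.  Root dentin
is subdivided into mantle (outermost 150 μm, cementum excluded),
proximal pulpal (innermost 150 μm), and circumpulpal (remainder) shells
by Euclidean distance from the respective surfaces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibratedVolume

__all__ = [
    "LandmarkError",
    "RoiError",
    "ToothLandmarks",
    "RegionOfInterest",
    "DentinZones",
    "ring_complete",
    "detect_cej",
    "detect_apical_enamel",
    "build_crown_roi",
    "build_root_roi",
    "build_cementum_roi",
    "subdivide_dentin",
    "estimate_root_axis",
    "orient_volume",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class LandmarkError(RuntimeError):
    """A required anatomical landmark could not be detected."""


class RoiError(ValueError):
    """The volume cannot accommodate the requested ROI."""


@dataclass(frozen=True)
class ToothLandmarks:
    cej_slice: int
    apical_enamel_slice: int
    mesial_cej_point: tuple | None = None
    distal_cej_point: tuple | None = None
    root_axis: tuple = (1.0, 0.0, 0.0)  # unit vector in (z, y, x) index order

    def __post_init__(self):
        if self.apical_enamel_slice > self.cej_slice:
            raise ValueError(
                "apical_enamel_slice must lie on the rootward side of cej_slice"
            )


@dataclass
class RegionOfInterest:
    """A half-open axial slab [z_start, z_stop), optionally with a mask."""

    label: str
    z_start: int
    z_stop: int
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.z_stop <= self.z_start:
            raise ValueError("empty slice range")
        if self.mask is not None:
            outside = self.mask.copy()
            outside[self.zslice] = False
            if outside.any():
                raise ValueError("ROI mask has voxels outside its slice range")

    @property
    def zslice(self) -> slice:
        return slice(self.z_start, self.z_stop)

    @property
    def n_slices(self) -> int:
        return self.z_stop - self.z_start


@dataclass
class DentinZones:
    """Mantle / circumpulpal / proximal-pulpal partition of root dentin."""

    mantle: np.ndarray
    circumpulpal: np.ndarray
    proximal_pulpal: np.ndarray
    shell_um: float = 150.0
    overlap_resolved: bool = False  # True when thin dentin made the shells meet

    def partition_ok(self, dentin_mask) -> bool:
        union = self.mantle | self.circumpulpal | self.proximal_pulpal
        disjoint = not (
            (self.mantle & self.circumpulpal).any()
            or (self.mantle & self.proximal_pulpal).any()
            or (self.circumpulpal & self.proximal_pulpal).any()
        )
        return disjoint and bool((union == np.asarray(dentin_mask, bool)).all())


def _slices_for_um(extent_um: float, voxel_size_um: float) -> int:
    return math.ceil(extent_um / voxel_size_um)


def ring_complete(slice2d) -> bool:
    """True when the foreground forms a topologically closed ring.

    Operationalized as: the background of the 2D slice (4-connectivity)
    splits into inside and outside — specifically, the background
    component at the ring's own centroid has no border contact.  Anchoring
    the inside at the centroid keeps incidental pinholes in a partial arc
    (single noise pixels enclosed by foreground) from passing as a ring.
    """
    m = np.asarray(slice2d, dtype=bool)
    if not m.any():
        return False
    bg, n = ndimage.label(~m, structure=_STRUCT4)
    if n < 2:
        return False
    cy, cx = (int(round(c)) for c in ndimage.center_of_mass(m))
    cy = min(max(cy, 0), m.shape[0] - 1)
    cx = min(max(cx, 0), m.shape[1] - 1)
    inside = bg[cy, cx]
    if inside == 0:  # centroid falls on the foreground itself (filled disc)
        return False
    border = np.unique(
        np.concatenate([bg[0], bg[-1], bg[:, 0], bg[:, -1]])
    )
    return inside not in border


def detect_cej(enamel_mask) -> int:
    """First slice, scanning from root toward crown, with a complete enamel ring."""
    m = np.asarray(enamel_mask, dtype=bool)
    if not m.any():
        raise LandmarkError("enamel mask is empty")
    has = m.any(axis=(1, 2))
    for z in np.flatnonzero(has.cumsum() > 0):
        if has[z] and ring_complete(m[z]):
            return int(z)
    raise LandmarkError("no axial slice forms a complete enamel ring")


def detect_apical_enamel(enamel_mask) -> int:
    """Most apical slice (lowest index) containing any enamel voxel."""
    m = np.asarray(enamel_mask, dtype=bool)
    zs = np.flatnonzero(m.any(axis=(1, 2)))
    if zs.size == 0:
        raise LandmarkError("enamel mask is empty")
    return int(zs[0])


def _slab(label, lo, hi, n_slices, what) -> RegionOfInterest:
    if lo < 0 or hi > n_slices:
        short = max(0 - lo, hi - n_slices)
        raise RoiError(
            f"{what}: requested slices [{lo}, {hi}) exceed the volume "
            f"({n_slices} slices) by {short} slice(s)"
        )
    return RegionOfInterest(label=label, z_start=lo, z_stop=hi)


def build_crown_roi(cej_slice: int, voxel_size_um: float, n_slices: int,
                    extent_um: float = 500.0, direction: int = 1) -> RegionOfInterest:
    """0.5 mm slab starting at the CEJ and extending coronally.

    ``direction`` is the sign of the coronal direction in slice indices
    (+1 when the index increases coronally).
    """
    n = _slices_for_um(extent_um, voxel_size_um)
    if direction >= 0:
        lo, hi = cej_slice, cej_slice + n
    else:
        lo, hi = cej_slice - n + 1, cej_slice + 1
    return _slab("crown", lo, hi, n_slices, "crown ROI")


def build_root_roi(apical_enamel_slice: int, voxel_size_um: float, n_slices: int,
                   skip_um: float = 150.0, extent_um: float = 500.0,
                   direction: int = 1) -> RegionOfInterest:
    """0.5 mm slab beginning 150 μm apical of the apical enamel extension.

    ``direction`` is the sign of the apical direction in slice indices
    (-1 under the package convention of apex at low index).
    """
    skip = _slices_for_um(skip_um, voxel_size_um)
    span = _slices_for_um(extent_um, voxel_size_um)
    if direction >= 0:
        lo, hi = apical_enamel_slice + skip, apical_enamel_slice + skip + span
    else:
        hi = apical_enamel_slice - skip
        lo = hi - span
    return _slab("root_dentin", lo, hi, n_slices, "root ROI")


def build_cementum_roi(cementum_mask, min_slices: int = 25,
                       max_slices: int = 50) -> RegionOfInterest:
    """Most apical 25–50 consecutive slices of complete cementum rings."""
    m = np.asarray(cementum_mask, dtype=bool)
    if not m.any():
        raise RoiError("cementum mask is empty")
    qualifying = np.array([ring_complete(m[z]) for z in range(m.shape[0])])
    z = 0
    nz = m.shape[0]
    while z < nz:
        if qualifying[z]:
            z1 = z
            while z1 < nz and qualifying[z1]:
                z1 += 1
            if z1 - z >= min_slices:
                stop = z + min(z1 - z, max_slices)
                mask = np.zeros_like(m)
                mask[z:stop] = m[z:stop]
                return RegionOfInterest("cementum_apical", z, stop, mask=mask)
            z = z1
        else:
            z += 1
    raise RoiError(
        f"fewer than {min_slices} consecutive complete cementum rings: "
        "insufficient root structure"
    )


def subdivide_dentin(dentin_mask, cementum_mask, pulp_mask, voxel_size_um: float,
                     shell_um: float = 150.0) -> DentinZones:
    """Partition a root-ROI dentin mask into 150-μm surface shells.

    Mantle dentin is every dentin voxel within ``shell_um`` (Euclidean
    distance, isotropic) of the outer dentin surface, with cementum
    excluded from dentin but counted as exterior; proximal pulpal dentin is
    within ``shell_um`` of the pulp-facing surface; circumpulpal dentin is
    the remainder.  Where the two shells would overlap (thin dentin) the
    mantle assignment wins.  Operates on the ROI crop: masks should span
    the crop axially so no artificial end surfaces are introduced.
    """
    dentin = np.asarray(dentin_mask, bool)
    cementum = np.asarray(cementum_mask, bool)
    pulp = np.asarray(pulp_mask, bool)
    if not dentin.any():
        raise ValueError("dentin mask is empty")
    dentin = dentin & ~cementum
    s = float(voxel_size_um)

    # distance to the outer surface: exterior is anything neither dentin nor pulp
    d_out = ndimage.distance_transform_edt(dentin | pulp, sampling=s)
    d_pulp = ndimage.distance_transform_edt(~pulp, sampling=s)

    mantle = dentin & (d_out <= shell_um)
    pulpal_shell = dentin & (d_pulp <= shell_um)
    overlap = mantle & pulpal_shell
    proximal = pulpal_shell & ~mantle
    circum = dentin & ~mantle & ~proximal
    if not circum.any():
        warnings.warn(
            "dentin wall thinner than the two surface shells: "
            "circumpulpal zone is empty"
        )
    return DentinZones(
        mantle=mantle,
        circumpulpal=circum,
        proximal_pulpal=proximal,
        shell_um=shell_um,
        overlap_resolved=bool(overlap.any()),
    )


def estimate_root_axis(data, fg_threshold: float = 300.0,
                       enamel_threshold: float = 1600.0):
    """Principal axis of the tooth foreground, signed apex→crown.

    Returns a unit vector in (z, y, x) index order; the sign is chosen so
    the enamel (densest tissue) lies on the positive side.
    """
    vol = np.asarray(data)
    coords = np.argwhere(vol > fg_threshold)
    if len(coords) < 10:
        raise LandmarkError("too few foreground voxels to estimate an axis")
    if len(coords) > 500_000:
        coords = coords[:: len(coords) // 500_000 + 1]
    c = coords.mean(axis=0)
    x = coords - c
    cov = x.T @ x / len(x)
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    en = np.argwhere(vol > enamel_threshold)
    if len(en) > 0 and float((en.mean(axis=0) - c) @ axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _rotation_to_z(axis):
    a = np.asarray(axis, dtype=np.float64)
    a = a / np.linalg.norm(a)
    b = np.array([1.0, 0.0, 0.0])  # +z in (z, y, x) order
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(a @ b)
    if s < 1e-12:
        # parallel: identity; antiparallel: π turn about the y index axis
        return np.eye(3) if c > 0 else np.diag([-1.0, 1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def orient_volume(vol: CalibratedVolume,
                  landmarks: ToothLandmarks | None = None,
                  fg_threshold: float = 300.0) -> CalibratedVolume:
    """Rigidly rotate the tooth so the root axis aligns with +z (coronal up).

    With landmarks, the supplied root axis is used and, when both CEJ
    points are given, a secondary in-plane rotation puts the mesial–distal
    CEJ chord along the x axis (so the chord lies in an axial plane).
    Without landmarks the axis is estimated from the foreground principal
    axis.  Resampling is trilinear; the voxel size is unchanged.
    """
    if landmarks is not None:
        axis = np.asarray(landmarks.root_axis, dtype=np.float64)
        if np.linalg.norm(axis) < 1e-12:
            raise LandmarkError("degenerate root axis")
        if float(axis[0]) < 0:  # stored apex→crown; normalize sign to +z
            axis = -axis
    else:
        axis = estimate_root_axis(vol.data, fg_threshold=fg_threshold)
    rot = _rotation_to_z(axis)

    if (
        landmarks is not None
        and landmarks.mesial_cej_point is not None
        and landmarks.distal_cej_point is not None
    ):
        p = rot @ np.asarray(landmarks.mesial_cej_point, dtype=np.float64)
        q = rot @ np.asarray(landmarks.distal_cej_point, dtype=np.float64)
        chord = q - p
        if np.linalg.norm(chord[1:]) < 1e-12:
            raise LandmarkError("CEJ chord is parallel to the root axis")
        ang = math.atan2(chord[1], chord[2])  # (y, x) components
        ca, sa = math.cos(-ang), math.sin(-ang)
        rz = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        rot = rz @ rot

    center = (np.array(vol.data.shape, dtype=np.float64) - 1) / 2
    inv = rot.T
    offset = center - inv @ center
    data = ndimage.affine_transform(
        vol.data.astype(np.float32), inv, offset=offset, order=1,
        mode="constant", cval=0.0,
    )
    prov = dict(vol.provenance)
    prov["orientation"] = {"rotation": rot.tolist(), "mode":
                           "landmarks" if landmarks is not None else "auto"}
    return CalibratedVolume(data=data, voxel_size_um=vol.voxel_size_um,
                            provenance=prov)
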