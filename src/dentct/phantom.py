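"""Synthetic tooth, calibration-standard, and histology-section phantoms.

Every generator returns a grey-value image together with a ground-truth
record, so that each downstream operator (calibration, segmentation,
landmark detection, morphometry) can be validated by parameter recovery.

The tooth phantom is a single-rooted primary tooth modeled as a solid of
revolution around the axial (z) axis: an enamel-capped crown over a dentin
body, a pulp chamber/canal open at the apex, and an acellular cementum
sheath on the root surface.  The axial index increases coronally: slice 0
is at the root apex side, the last slice at the crown tip side.

Hypomineralized interglobular dentin is emulated by carving non-overlapping
spheres out of the crown dentin and filling them at pulp density, the CT
appearance of unmerged calcospherite regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "HistoTruth",
    "generate_tooth_phantom",
    "generate_calibration_phantom",
    "generate_histology_section",
]

# label codes for the truth label volume
BACKGROUND, ENAMEL, DENTIN, CEMENTUM, PULP, VOID = 0, 1, 2, 3, 4, 5
LABEL_NAMES = {
    "background": BACKGROUND,
    "enamel": ENAMEL,
    "dentin": DENTIN,
    "cementum": CEMENTUM,
    "pulp": PULP,
    "void": VOID,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic single-rooted tooth volume.

    Lengths are physical; the voxel grid is isotropic at ``voxel_size_um``
    (10 μm by default, matching high-resolution dental μCT).  Densities are
    hydroxyapatite-equivalent mineral densities in mg/cm³ HA.  Defaults sit
    centrally inside the segmentation windows used downstream (enamel
    >1600, dentin 650–1600, cementum 450–1050, pulp < 450); they are
    generator choices, not claims about real teeth.
    """

    voxel_size_um: float = 10.0
    crown_height_mm: float = 0.8
    root_length_mm: float = 1.2
    enamel_thickness_mm: float = 0.2
    dentin_wall_mm: float = 0.4
    cementum_thickness_um: float = 200.0
    predentin_width_um: float = 40.0
    pulp_radius_mm: float = 0.10
    cej_slope_um: float = 150.0
    root_taper: float = 0.8
    density_enamel: float = 2000.0
    density_dentin: float = 1200.0
    density_cementum: float = 900.0
    density_pulp: float = 200.0
    density_background: float = 0.0
    void_fraction: float = 0.0
    void_radius_um: float = 20.0
    void_zone_um: float | None = 500.0
    noise_sd: float = 0.0
    margin_um: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        lengths = dict(
            voxel_size_um=self.voxel_size_um,
            crown_height_mm=self.crown_height_mm,
            root_length_mm=self.root_length_mm,
            enamel_thickness_mm=self.enamel_thickness_mm,
            dentin_wall_mm=self.dentin_wall_mm,
            cementum_thickness_um=self.cementum_thickness_um,
            predentin_width_um=self.predentin_width_um,
            pulp_radius_mm=self.pulp_radius_mm,
            void_radius_um=self.void_radius_um,
        )
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if not (0.0 <= self.void_fraction < 1.0):
            raise ValueError("void_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.root_taper <= 1.0):
            raise ValueError("root_taper must lie in (0, 1]")


@dataclass
class PhantomTruth:
    """Ground truth for a generated tooth phantom.

    ``labels`` is a uint8 volume with one code per tissue (pairwise
    disjoint by construction, and together a partition of the volume).
    """

    labels: np.ndarray
    voxel_size_um: float
    nominal_density: dict
    cej_slice: int
    apical_enamel_slice: int
    crown_top_slice: int
    apex_slice: int
    requested_void_fraction: float
    realized_void_fraction: float
    void_voxels: int
    void_volume_mm3: float
    crown_dentin_voxels: int
    zone_dentin_voxels: int = 0
    nominal_thickness_um: dict = field(default_factory=dict)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABEL_NAMES[name]

    def window_mask(self, lo: float | None = None, hi: float | None = None,
                    lo_strict: bool = False, hi_strict: bool = False) -> np.ndarray:
        """Exact expected mask of a density window, from nominal densities.

        Mirrors the downstream threshold semantics, so that on a noiseless
        phantom a window segmentation can be compared voxel-for-voxel.
        """
        out = np.zeros(self.labels.shape, dtype=bool)
        for name, code in LABEL_NAMES.items():
            d = self.nominal_density[name]
            ok = True
            if lo is not None:
                ok &= (d > lo) if lo_strict else (d >= lo)
            if hi is not None:
                ok &= (d < hi) if hi_strict else (d <= hi)
            if ok:
                out |= self.labels == code
        return out

    def summary(self) -> dict:
        d = asdict(self)
        d.pop("labels")
        return d


def _disk_r2(shape_yx, cy, cx):
    yy, xx = np.ogrid[: shape_yx[0], : shape_yx[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2


def generate_tooth_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Generate a grey-value tooth volume (identity grey map) plus truth.

    Identical spec + seed produce a bit-identical volume.  Grey values are
    on the mg/cm³ HA scale directly; an identity calibration downstream
    reproduces them, and an affine grey map can be composed externally.
    """
    spec.validate()
    v = spec.voxel_size_um
    rng = np.random.default_rng(spec.seed)

    m = max(2, int(round(spec.margin_um / v)))
    nz_root = int(round(spec.root_length_mm * 1000 / v))
    nz_crown = int(round(spec.crown_height_mm * 1000 / v))
    t_en = max(1, int(round(spec.enamel_thickness_mm * 1000 / v)))
    t_wall = max(1, int(round(spec.dentin_wall_mm * 1000 / v)))
    t_cem = max(1, int(round(spec.cementum_thickness_um / v)))
    r_pulp = max(1, int(round(spec.pulp_radius_mm * 1000 / v)))
    n_slope = min(nz_root - 1, max(1, int(round(spec.cej_slope_um / v))))

    r_dentin_crown = r_pulp + t_wall          # outer dentin radius (cervical)
    r_crown = r_dentin_crown + t_en           # crown outer radius
    r_root = r_dentin_crown + t_cem           # root outer radius at CEJ

    z_apex = m
    z_cej = m + nz_root
    z_top = z_cej + nz_crown - 1
    nz = z_top + 1 + m
    nr = max(r_crown, r_root) + m
    ny = nx = 2 * nr + 1
    cy = cx = nr

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    r2 = _disk_r2((ny, nx), cy, cx)
    r = np.sqrt(r2)

    # --- root: tapering dentin around a constant pulp canal, cementum sheath
    for z in range(z_apex, z_cej):
        frac = (z_cej - z) / nz_root  # 0 at CEJ, 1 at apex
        rd = spec.root_taper * r_dentin_crown + (1 - frac) * (1 - spec.root_taper) * r_dentin_crown
        rd = max(rd, r_pulp + 1.5)
        sl = labels[z]
        sl[r <= rd + t_cem] = CEMENTUM
        sl[r <= rd] = DENTIN
        sl[r < r_pulp] = PULP

    # --- sloping enamel margin below the CEJ: an angular sector replaces
    #     cementum, so the enamel ring is incomplete on these slices
    theta = np.arctan2(
        np.arange(ny)[:, None] - cy, np.arange(nx)[None, :] - cx
    )
    for k, z in enumerate(range(z_cej - n_slope, z_cej)):
        span = np.pi * (0.25 + 1.5 * (k + 1) / n_slope) / 2  # grows toward CEJ
        sector = np.abs(theta) < span
        band = (r > r_dentin_crown) & (r <= r_dentin_crown + t_en) & sector
        labels[z][band] = ENAMEL

    # --- crown: enamel shell over dentin, pulp chamber, solid enamel cap
    for z in range(z_cej, z_top + 1):
        sl = labels[z]
        if z > z_top - t_en:
            sl[r <= r_crown] = ENAMEL
        else:
            sl[r <= r_crown] = ENAMEL
            sl[r <= r_dentin_crown] = DENTIN
            sl[r < r_pulp] = PULP

    dentin = labels == DENTIN
    crown_zs = slice(z_cej, z_top - t_en + 1)
    crown_dentin = np.zeros_like(dentin)
    crown_dentin[crown_zs] = dentin[crown_zs]
    n_crown_dentin = int(crown_dentin.sum())

    # void-bearing zone: the cervical crown dentin (the axial window where
    # interglobular dentin is quantified); the requested fraction is
    # defined relative to the dentin content of this zone
    if spec.void_zone_um is None:
        zone_zs = crown_zs
    else:
        n_zone = int(np.ceil(spec.void_zone_um / v))
        zone_zs = slice(z_cej, min(z_cej + n_zone, crown_zs.stop))
    zone_dentin = np.zeros_like(dentin)
    zone_dentin[zone_zs] = dentin[zone_zs]
    n_zone_dentin = int(zone_dentin.sum())

    # --- interglobular voids: non-overlapping spheres fully inside dentin
    void = np.zeros_like(dentin)
    n_void = 0
    if spec.void_fraction > 0:
        rv = max(1, int(round(spec.void_radius_um / v)))
        off = np.ogrid[-rv:rv + 1, -rv:rv + 1, -rv:rv + 1]
        ball = (off[0] ** 2 + off[1] ** 2 + off[2] ** 2) <= rv ** 2
        ball_idx = np.argwhere(ball) - rv
        target = int(round(spec.void_fraction * n_zone_dentin))
        # centers must keep the sphere (plus a 1-voxel guard) inside dentin
        edt = ndimage.distance_transform_edt(dentin)
        allowed = np.zeros_like(dentin)
        allowed[zone_zs] = edt[zone_zs] >= rv + 1.5
        centers = np.argwhere(allowed)
        if len(centers) == 0:
            warnings.warn("no admissible void centers; realized fraction is 0")
        else:
            max_attempts = 200 * max(1, target // max(1, int(ball.sum())))
            attempts = 0
            while n_void < target and attempts < max_attempts:
                attempts += 1
                c = centers[rng.integers(len(centers))]
                pts = ball_idx + c
                zz, yy, xx = pts[:, 0], pts[:, 1], pts[:, 2]
                if void[zz, yy, xx].any():
                    continue
                void[zz, yy, xx] = True
                n_void += len(pts)
            if n_void < target:
                warnings.warn(
                    f"void placement saturated: realized {n_void} of {target} "
                    "requested void voxels"
                )
        labels[void] = VOID

    density_of = {
        "background": spec.density_background,
        "enamel": spec.density_enamel,
        "dentin": spec.density_dentin,
        "cementum": spec.density_cementum,
        "pulp": spec.density_pulp,
        "void": spec.density_pulp,
    }
    lut = np.zeros(6, dtype=np.float32)
    for name, code in LABEL_NAMES.items():
        lut[code] = density_of[name]
    vol = lut[labels]
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape).astype(np.float32)
    vol = vol.astype(np.float32, copy=False)

    mm3 = (v / 1000.0) ** 3
    truth = PhantomTruth(
        labels=labels,
        voxel_size_um=v,
        nominal_density=density_of,
        cej_slice=z_cej,
        apical_enamel_slice=z_cej - n_slope,
        crown_top_slice=z_top,
        apex_slice=z_apex,
        requested_void_fraction=spec.void_fraction,
        realized_void_fraction=(n_void / n_zone_dentin) if n_zone_dentin else 0.0,
        void_voxels=n_void,
        void_volume_mm3=n_void * mm3,
        crown_dentin_voxels=n_crown_dentin,
        zone_dentin_voxels=n_zone_dentin,
        nominal_thickness_um={
            "enamel": t_en * v,
            "dentin_wall": t_wall * v,
            "cementum": t_cem * v,
        },
    )
    return vol, truth


def generate_calibration_phantom(
    rod_densities,
    grey_map=(1.0, 0.0),
    noise_sd: float = 0.0,
    rod_radius_px: int = 12,
    rod_height_px: int = 40,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """A multi-rod hydroxyapatite calibration standard.

    One homogeneous cylinder per density, side by side along x.
    ``grey_map = (gain, offset)`` maps density to grey value as
    ``grey = gain * density + offset``.  Returns the grey volume and one
    boolean mask per rod.
    """
    rod_densities = [float(d) for d in rod_densities]
    if len(rod_densities) < 2:
        raise ValueError("need at least two rod densities")
    if len(set(rod_densities)) != len(rod_densities):
        raise ValueError("duplicate rod densities produce a degenerate fit")
    gain, offset = float(grey_map[0]), float(grey_map[1])

    n = len(rod_densities)
    pitch = 2 * rod_radius_px + 6
    ny = 2 * rod_radius_px + 8
    nx = pitch * n + 6
    vol = np.zeros((rod_height_px, ny, nx), dtype=np.float32)
    masks = []
    rng = np.random.default_rng(seed)
    for i, d in enumerate(rod_densities):
        cx = 3 + pitch * i + rod_radius_px
        cy = ny // 2
        disk = _disk_r2((ny, nx), cy, cx) <= rod_radius_px ** 2
        mask = np.zeros(vol.shape, dtype=bool)
        mask[:, disk] = True
        vol[mask] = gain * d + offset
        masks.append(mask)
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, vol.shape).astype(np.float32)
    return vol, masks


@dataclass
class HistoTruth:
    """Ground truth for a generated 2D histology section."""

    um_per_px: float
    requested_fraction: float
    realized_fraction: float
    predentin_width_px: int
    cementum_width_px: int
    masks: dict

    def summary(self) -> dict:
        return {
            "um_per_px": self.um_per_px,
            "requested_fraction": self.requested_fraction,
            "realized_fraction": self.realized_fraction,
            "predentin_width_px": self.predentin_width_px,
            "cementum_width_px": self.cementum_width_px,
        }


# grey levels of the synthetic toluidine-blue-like section (16-bit semantics,
# stored as float32): mineralized dentin is dark, unmineralized matrix bright
_GREY = dict(mineralized=60.0, unmineralized=200.0, pulp=210.0,
             cementum=90.0, background=230.0)


def generate_histology_section(
    area_fraction_mineralized: float,
    predentin_width_um: float = 40.0,
    cementum_width_um: float = 25.0,
    um_per_px: float = 1.0,
    seed: int = 0,
    shape=(400, 600),
    mode: str = "blobs",
    blob_radius_um: float = 8.0,
    noise_sd: float = 2.0,
) -> tuple[np.ndarray, HistoTruth]:
    """Generate a 2D grayscale dentin section with band-shaped layers.

    Column layout (left to right): pulp | predentin | dentin field |
    cementum | background.  Unmineralized blobs are placed in the dentin
    field until the mineralized area fraction falls to the requested value;
    ``mode='checkerboard'`` instead produces an exactly half-mineralized
    field (requested fraction must be 0.5).
    """
    if not (0.0 <= area_fraction_mineralized <= 1.0):
        raise ValueError("area_fraction_mineralized must lie in [0, 1]")
    w_pre = int(round(predentin_width_um / um_per_px))
    w_cem = int(round(cementum_width_um / um_per_px))
    if w_pre < 1 or w_cem < 1:
        raise ValueError("layer widths must be at least 1 pixel")
    ny, nx = shape
    w_pulp, w_bg = 50, 40
    x0_pre = w_pulp
    x0_field = x0_pre + w_pre
    x0_cem = nx - w_bg - w_cem
    if x0_cem <= x0_field + 20:
        raise ValueError("image too narrow for the requested layer widths")

    rng = np.random.default_rng(seed)
    img = np.empty(shape, dtype=np.float32)
    img[:, :x0_pre] = _GREY["pulp"]
    img[:, x0_pre:x0_field] = _GREY["unmineralized"]  # predentin is unmineralized
    img[:, x0_field:x0_cem] = _GREY["mineralized"]
    img[:, x0_cem:x0_cem + w_cem] = _GREY["cementum"]
    img[:, x0_cem + w_cem:] = _GREY["background"]

    field = np.zeros(shape, dtype=bool)
    field[:, x0_field:x0_cem] = True
    field_area = int(field.sum())

    unmin = np.zeros(shape, dtype=bool)
    if mode == "checkerboard":
        if abs(area_fraction_mineralized - 0.5) > 1e-12:
            raise ValueError("checkerboard mode realizes exactly fraction 0.5")
        yy, xx = np.indices(shape)
        unmin = field & (((yy + xx) % 2) == 1)
    elif mode == "blobs":
        target = int(round((1.0 - area_fraction_mineralized) * field_area))
        if target > 0:
            rb = max(1, int(round(blob_radius_um / um_per_px)))
            yy, xx = np.ogrid[-rb:rb + 1, -rb:rb + 1]
            disk = (yy ** 2 + xx ** 2) <= rb ** 2
            attempts, max_attempts = 0, 400 * max(1, target // int(disk.sum()))
            while int(unmin.sum()) < target and attempts < max_attempts:
                attempts += 1
                cyx = (rng.integers(rb, ny - rb), rng.integers(x0_field + rb, x0_cem - rb))
                sl = (slice(cyx[0] - rb, cyx[0] + rb + 1),
                      slice(cyx[1] - rb, cyx[1] + rb + 1))
                unmin[sl] |= disk
            if int(unmin.sum()) < target:
                warnings.warn("blob placement saturated below requested fraction")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    img[unmin] = _GREY["unmineralized"]

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape).astype(np.float32)

    masks = {
        "pulp": np.zeros(shape, dtype=bool),
        "predentin": np.zeros(shape, dtype=bool),
        "dentin_field": field,
        "cementum": np.zeros(shape, dtype=bool),
        "unmineralized": unmin,
    }
    masks["pulp"][:, :x0_pre] = True
    masks["predentin"][:, x0_pre:x0_field] = True
    masks["cementum"][:, x0_cem:x0_cem + w_cem] = True

    realized = 1.0 - unmin.sum() / field_area if field_area else float("nan")
    truth = HistoTruth(
        um_per_px=um_per_px,
        requested_fraction=area_fraction_mineralized,
        realized_fraction=float(realized),
        predentin_width_px=w_pre,
        cementum_width_px=w_cem,
        masks=masks,
    )
    return img, truth
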