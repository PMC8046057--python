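"""Grey-value to mineral-density calibration.

μCT densitometry references grey values against a multi-rod standard of
known hydroxyapatite densities.  The calibration model is affine,
``density = slope * grey + intercept`` — the linear HA calibration
conventional for Scanco-style densitometry — fitted by ordinary least
squares over the rod mean grey values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "CalibratedVolume",
    "DegenerateCalibrationError",
    "fit_calibration",
    "apply_calibration",
    "rod_mean_greys",
]


class DegenerateCalibrationError(ValueError):
    """The rod data cannot support an affine fit."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine grey→density map with its fit diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    rod_densities: tuple = ()
    rod_mean_greys: tuple = ()

    def __post_init__(self):
        if self.slope == 0:
            raise DegenerateCalibrationError("calibration slope must be nonzero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def __call__(self, grey):
        return self.slope * np.asarray(grey, dtype=np.float64) + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "rod_densities": list(self.rod_densities),
                    "rod_mean_greys": list(self.rod_mean_greys),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            rod_densities=tuple(d.get("rod_densities", ())),
            rod_mean_greys=tuple(d.get("rod_mean_greys", ())),
        )


@dataclass
class CalibratedVolume:
    """A 3D mineral-density map (mg/cm³ HA) on an isotropic voxel grid.

    Axis convention after orientation: axis 0 (z) is the tooth axis with
    the index increasing coronally (apex at low z).
    """

    data: np.ndarray
    voxel_size_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if not np.isfinite(self.data).all():
            raise ValueError("density values must be finite")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um / 1000.0) ** 3


def rod_mean_greys(volume, rod_masks):
    """Mean grey value inside each rod mask."""
    vol = np.asarray(volume)
    return [float(vol[m].mean()) for m in rod_masks]


def fit_calibration(rod_mean_greys, rod_densities) -> CalibrationCurve:
    """Ordinary least-squares fit of density = slope·grey + intercept."""
    greys = np.asarray(rod_mean_greys, dtype=np.float64)
    dens = np.asarray(rod_densities, dtype=np.float64)
    if greys.shape != dens.shape or greys.ndim != 1:
        raise ValueError("rod greys and densities must be matched 1-D sequences")
    if len(greys) < 2:
        raise DegenerateCalibrationError("need at least two rods")
    if np.ptp(greys) == 0:
        raise DegenerateCalibrationError("identical rod grey values")
    if np.ptp(dens) == 0:
        raise DegenerateCalibrationError("identical rod densities")
    fit = stats.linregress(greys, dens)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rod_densities=tuple(map(float, dens)),
        rod_mean_greys=tuple(map(float, greys)),
    )


def apply_calibration(raw_volume, curve: CalibrationCurve,
                      voxel_size_um: float, source: str | None = None) -> CalibratedVolume:
    """Voxelwise affine transform of a grey-value volume into mg/cm³ HA."""
    raw = np.asarray(raw_volume)
    out_dtype = np.float64 if raw.dtype == np.float64 else np.float32
    data = (curve.slope * raw.astype(np.float64) + curve.intercept).astype(out_dtype)
    return CalibratedVolume(
        data=data,
        voxel_size_um=float(voxel_size_um),
        provenance={
            "source": source,
            "curve": {"slope": curve.slope, "intercept": curve.intercept,
                      "r_squared": curve.r_squared},
        },
    )
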