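"""Voxelwise photon-equivalent conversion, DVHs and dose-statistics reporting.

Works on four co-registered 3-D dose(-rate) component grids — the boron
per-ppm grid, two neutron grids (thermal-capture and fast-recoil) and the
photon grid — plus boolean ROI masks. The two neutron grids are summed into
a single neutron term before the three-term survival model is applied.

Grid convention: voxel-center coordinates, axis order (x, y, z), explicit
spacing (mm per axis) and origin (mm). NIfTI is the on-disk format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import IrradiationProtocol
from .dosimetry import (
    RadiobiologicalParameterSet,
    RBEWeights,
    isoeffective_dose_components,
    rbe_weighted_components,
)
from .errors import (
    ConfigError,
    InvalidInputError,
    InvalidMaskError,
    RegistrationError,
    UnboundedTimeError,
)

__all__ = [
    "DoseComponentField",
    "ROIMask",
    "DVHCurve",
    "DoseSummary",
    "convert_field",
    "compute_dvh",
    "dose_statistics",
    "scale_time_to_prescription",
    "percent_difference",
    "write_field",
    "read_field",
    "write_mask",
    "read_mask",
    "write_grid",
    "read_grid",
]

_COMPONENT_NAMES = ("boron_per_ppm", "neutron_thermal", "neutron_fast", "photon")


@dataclass(frozen=True)
class DoseComponentField:
    """Four co-registered component grids (Gy/min in rate mode, Gy otherwise).

    The boron grid is stored per ppm of boron-10 and scaled by each ROI's
    concentration when doses are assembled.
    """

    boron_per_ppm: np.ndarray
    neutron_thermal: np.ndarray
    neutron_fast: np.ndarray
    photon: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units_mode: str = "rate"

    def __post_init__(self) -> None:
        shape = np.shape(self.boron_per_ppm)
        for name in _COMPONENT_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 3 or arr.shape != shape:
                raise RegistrationError(f"component {name} is not co-registered")
            if np.any(arr < 0):
                raise InvalidInputError(f"component {name} has negative values")
        if self.units_mode not in ("rate", "absolute"):
            raise InvalidInputError(f"unknown units_mode {self.units_mode!r}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidInputError("spacing must be three positive lengths (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.boron_per_ppm.shape


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask with its boron concentration (ppm)."""

    mask: np.ndarray
    name: str
    boron_concentration: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 3:
            raise InvalidMaskError("mask must be a 3-D boolean array")
        if not m.any():
            raise InvalidMaskError(f"ROI {self.name!r} selects no voxels")
        if self.boron_concentration is not None and self.boron_concentration < 0:
            raise InvalidInputError("boron concentration must be >= 0")


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram: fraction of volume receiving >= dose."""

    dose_edges: np.ndarray
    volume_fraction: np.ndarray

    def volume_at_dose(self, dose: float) -> float:
        """Right-continuous step lookup of the cumulative volume fraction."""
        idx = np.searchsorted(self.dose_edges, dose, side="right") - 1
        idx = int(np.clip(idx, 0, self.volume_fraction.size - 1))
        return float(self.volume_fraction[idx])

    def dose_at_volume(self, volume_fraction: float) -> float:
        """Largest dose edge still covering at least the given volume fraction."""
        ok = np.nonzero(self.volume_fraction >= volume_fraction)[0]
        if ok.size == 0:
            return 0.0
        return float(self.dose_edges[ok[-1]])


@dataclass(frozen=True)
class DoseSummary:
    """Maximum, mean and minimum photon-equivalent dose over one ROI."""

    d_max: float
    d_mean: float
    d_min: float
    model: str
    parameter_label: str = ""

    def __post_init__(self) -> None:
        if not (self.d_min <= self.d_mean <= self.d_max):
            raise InvalidInputError("dose summary must satisfy min <= mean <= max")

    def to_dict(self) -> dict:
        return {
            "d_max": self.d_max,
            "d_mean": self.d_mean,
            "d_min": self.d_min,
            "model": self.model,
            "parameter_label": self.parameter_label,
        }


# --------------------------------------------------------------------------
# Dose assembly and conversion
# --------------------------------------------------------------------------

def assemble_components(
    field: DoseComponentField,
    roi: ROIMask,
    irradiation_time: float | None = None,
):
    """Per-voxel (boron, neutron, photon) doses in Gy over the ROI voxels.

    Boron: per-ppm grid times the ROI concentration; neutron: thermal plus
    fast grids; rate-mode grids are multiplied by the irradiation time.
    """
    if roi.mask.shape != field.shape:
        raise RegistrationError("ROI mask is not co-registered with the field")
    scale = 1.0
    if field.units_mode == "rate":
        if irradiation_time is None or irradiation_time <= 0:
            raise ConfigError("rate-mode fields need a positive irradiation time")
        scale = irradiation_time
    if roi.boron_concentration is None:
        raise ConfigError(f"ROI {roi.name!r} has no boron concentration configured")
    m = roi.mask
    db = field.boron_per_ppm[m] * roi.boron_concentration * scale
    dn = (field.neutron_thermal[m] + field.neutron_fast[m]) * scale
    dg = field.photon[m] * scale
    return db, dn, dg


def convert_field(
    field: DoseComponentField,
    roi: ROIMask,
    model: str,
    params_or_weights,
    irradiation_time: float | None = None,
    reference_mode: str = "acute",
    reference_dose_rate: float = 1.0,
) -> np.ndarray:
    """Photon-equivalent grid over one ROI (NaN outside the ROI).

    ``model`` selects ``"isoeffective"`` (with a ``RadiobiologicalParameterSet``)
    or ``"rbe_weighted"`` (with ``RBEWeights``). The BNCT delivery protocol for
    the protraction factors is the constant-rate irradiation over
    ``irradiation_time`` minutes (acute if not given in absolute mode).
    """
    db, dn, dg = assemble_components(field, roi, irradiation_time)
    if model == "isoeffective":
        if not isinstance(params_or_weights, RadiobiologicalParameterSet):
            raise ConfigError("isoeffective model needs a RadiobiologicalParameterSet")
        protocol = IrradiationProtocol(duration=irradiation_time or 0.0)
        values = isoeffective_dose_components(
            db,
            dn,
            dg,
            params_or_weights,
            protocol,
            reference_mode=reference_mode,
            reference_dose_rate=reference_dose_rate,
        )
    elif model == "rbe_weighted":
        if not isinstance(params_or_weights, RBEWeights):
            raise ConfigError("rbe_weighted model needs RBEWeights")
        values = rbe_weighted_components(db, dn, dg, params_or_weights)
    else:
        raise ConfigError(f"unknown model {model!r}")
    out = np.full(field.shape, np.nan)
    out[roi.mask] = values
    return out


# --------------------------------------------------------------------------
# DVH and statistics
# --------------------------------------------------------------------------

def _roi_values(equivalent_grid: np.ndarray, roi: ROIMask) -> np.ndarray:
    if equivalent_grid.shape != roi.mask.shape:
        raise RegistrationError("grid and mask shapes differ")
    vals = np.asarray(equivalent_grid)[roi.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InvalidMaskError(f"ROI {roi.name!r} contains no converted voxels")
    return vals


def compute_dvh(equivalent_grid: np.ndarray, roi: ROIMask, n_bins: int = 256) -> DVHCurve:
    """Cumulative DVH over the ROI voxels: V(d) = fraction with dose >= d.

    Edges run uniformly from 0 to just above the ROI maximum, so the curve
    starts at 1 and ends at 0.
    """
    vals = _roi_values(equivalent_grid, roi)
    top = float(vals.max())
    top = top * (1.0 + 1e-9) + 1e-12  # strictly above the maximum
    edges = np.linspace(0.0, top, n_bins + 1)
    # fraction with dose >= edge, via one sort instead of a scan per edge
    frac = (vals.size - np.searchsorted(np.sort(vals), edges, side="left")) / vals.size
    return DVHCurve(dose_edges=edges, volume_fraction=frac)


def dose_statistics(
    equivalent_grid: np.ndarray,
    roi: ROIMask,
    model: str = "isoeffective",
    parameter_label: str = "",
) -> DoseSummary:
    """Max / mean / min photon-equivalent dose over the ROI voxels."""
    vals = _roi_values(equivalent_grid, roi)
    return DoseSummary(
        d_max=float(vals.max()),
        d_mean=float(vals.mean()),
        d_min=float(vals.min()),
        model=model,
        parameter_label=parameter_label,
    )


def scale_time_to_prescription(
    field: DoseComponentField,
    brain_roi: ROIMask,
    weights: RBEWeights,
    limit: float = 2.5,
    volume_fraction: float = 0.5,
) -> float:
    """Irradiation time (min) meeting a normal-tissue RBE-weighted prescription.

    Finds the largest time such that no more than ``volume_fraction`` of the
    ROI receives an RBE-weighted dose above ``limit``. The weighted dose is
    linear in time, so the answer is the limit divided by the per-minute
    weighted dose rate at the prescribed volume fraction (the median rate for
    the usual 50% prescription).
    """
    if field.units_mode != "rate":
        raise ConfigError("prescription scaling needs a rate-mode field")
    if limit < 0:
        raise InvalidInputError("prescription limit must be >= 0")
    if not (0.0 < volume_fraction < 1.0):
        raise InvalidInputError("volume fraction must lie in (0, 1)")
    db, dn, dg = assemble_components(field, brain_roi, irradiation_time=1.0)
    rate = rbe_weighted_components(db, dn, dg, weights)
    q = float(np.quantile(rate, 1.0 - volume_fraction))
    if q <= 0.0:
        raise UnboundedTimeError("weighted dose rate is zero at the prescription level")
    return limit / q


def percent_difference(reference_value: float, other_value: float) -> float:
    """Percentage difference 100 (reference - other) / reference.

    The reference value is the denominator; reporting rounds to the nearest
    integer percent.
    """
    if reference_value <= 0:
        raise InvalidInputError("reference value must be > 0")
    return 100.0 * (reference_value - other_value) / reference_value


# --------------------------------------------------------------------------
# NIfTI IO
# --------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_grid(path, grid: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a single 3-D grid as NIfTI with a diagonal affine."""
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float64), _affine(spacing, origin))
    nib.save(img, str(path))


def read_grid(path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return np.asarray(img.get_fdata()), spacing, origin


def write_field(directory, field: DoseComponentField) -> None:
    """One NIfTI file per component, sharing the affine, in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _COMPONENT_NAMES:
        write_grid(directory / f"{name}.nii", getattr(field, name), field.spacing, field.origin)
    (directory / "units_mode.txt").write_text(field.units_mode)


def read_field(directory) -> DoseComponentField:
    directory = Path(directory)
    grids = {}
    spacing = origin = None
    for name in _COMPONENT_NAMES:
        g, sp, org = read_grid(directory / f"{name}.nii")
        grids[name] = g
        if spacing is None:
            spacing, origin = sp, org
        elif sp != spacing or org != origin:
            raise RegistrationError(f"component {name} has a different affine")
    units_path = directory / "units_mode.txt"
    units_mode = units_path.read_text().strip() if units_path.exists() else "rate"
    return DoseComponentField(spacing=spacing, origin=origin, units_mode=units_mode, **grids)


def write_mask(path, roi: ROIMask, spacing, origin=(0.0, 0.0, 0.0)) -> None:
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), _affine(spacing, origin))
    nib.save(img, str(path))


def read_mask(path, name: str, boron_concentration: float | None = None) -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(
        mask=np.asarray(img.get_fdata()) > 0.5,
        name=name,
        boron_concentration=boron_concentration,
    )
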