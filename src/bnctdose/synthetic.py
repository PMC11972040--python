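"""Seeded generators emulating the statistical structure of the pipeline inputs.

Three generators cover the three kinds of experimental input:

* clonogenic assays — Poisson colony counts under MLQ mixed-field survival,
  with the boron dose perturbed by the (dominant) boron-concentration
  measurement error;
* foci-decay time series — bi-exponential repair intensity plus Gaussian
  noise;
* phantom dose-component fields — a water-equivalent block traversed by a
  forward-peaked beam with per-component exponential depth attenuation and a
  Gaussian lateral profile, a spherical tumor, and per-ppm boron dose rates.

All generators are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    IrradiationProtocol,
    MixedFieldDose,
    RepairKinetics,
    foci_intensity,
    g_factors,
    survival_mixed_field,
)
from .dosimetry import RadiobiologicalParameterSet
from .errors import InvalidInputError
from .fitting import Condition, FociTimeSeries, SurvivalDataPoint
from .grids import DoseComponentField, ROIMask

__all__ = [
    "AssayDesign",
    "PhantomSpec",
    "generate_clonogenic_assay",
    "generate_foci_series",
    "generate_phantom_field",
    "noiseless_survival_points",
    "reference_photon_design",
    "beam_only_design",
    "bnct_design",
]


@dataclass(frozen=True)
class AssayDesign:
    """Design of one clonogenic assay: dose points, seeding and noise levels.

    ``cells_seeded`` may be a single count or one count per dose point
    (escalating seeding at high doses is standard practice so that expected
    colony numbers stay countable).
    """

    condition: Condition
    dose_points: tuple[MixedFieldDose, ...]
    protocol: IrradiationProtocol
    cells_seeded: int | tuple[int, ...] = 500
    plating_efficiency: float = 0.8
    replicates: int = 3
    boron_sigma_rel: float = 0.0
    control_cells_seeded: int = 500

    def __post_init__(self) -> None:
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise InvalidInputError("plating efficiency must lie in (0, 1]")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")
        seeded = self.cells_seeded
        if isinstance(seeded, (int, np.integer)):
            seeded = tuple([int(seeded)] * len(self.dose_points))
        else:
            seeded = tuple(int(s) for s in seeded)
            if len(seeded) != len(self.dose_points):
                raise InvalidInputError("cells_seeded must match the dose points")
        if any(s <= 0 for s in seeded) or self.control_cells_seeded <= 0:
            raise InvalidInputError("seeded cell counts must be positive")
        object.__setattr__(self, "cells_seeded", seeded)
        object.__setattr__(self, "dose_points", tuple(self.dose_points))


def _expected_survival(
    dose: MixedFieldDose,
    truth: RadiobiologicalParameterSet,
    protocol: IrradiationProtocol,
) -> float:
    g = g_factors(protocol, truth.kinetics)
    return survival_mixed_field(dose, truth.photon, truth.neutron, truth.boron, g)


def generate_clonogenic_assay(
    truth: RadiobiologicalParameterSet,
    design: AssayDesign,
    seed: int = 0,
) -> list[SurvivalDataPoint]:
    """Simulate one clonogenic assay and return its survival data points.

    Per dose point, each replicate flask seeds the design's cell count and
    colonies are Poisson with mean ``seeded * PE * S(dose)``. Surviving
    fractions are normalized to the plating efficiency estimated from a
    zero-dose control; uncertainties propagate the Poisson counting errors of
    both the point and the control. The boron dose is perturbed by a relative
    Gaussian error representing the boron-concentration measurement.
    """
    rng = np.random.default_rng(seed)
    pe = design.plating_efficiency
    n_ctrl = design.control_cells_seeded * design.replicates
    ctrl_colonies = rng.poisson(n_ctrl * pe)
    if ctrl_colonies == 0:
        raise InvalidInputError("degenerate design: control produced no colonies")
    pe_hat = ctrl_colonies / n_ctrl

    points: list[SurvivalDataPoint] = []
    # zero-dose anchor: S = 1 by construction with the control's counting error
    anchor_sigma = 1.0 / np.sqrt(ctrl_colonies)
    points.append(
        SurvivalDataPoint(
            dose=MixedFieldDose(),
            surviving_fraction=1.0,
            sf_sigma=float(anchor_sigma * np.sqrt(2.0)),
            protocol=design.protocol,
            condition=design.condition,
        )
    )
    for dose, seeded in zip(design.dose_points, design.cells_seeded):
        realized = dose
        dose_sigma = None
        if design.boron_sigma_rel > 0 and dose.d_boron > 0:
            db = dose.d_boron * max(1.0 + rng.normal(0.0, design.boron_sigma_rel), 0.0)
            realized = replace(dose, d_boron=db)
            dose_sigma = MixedFieldDose(d_boron=design.boron_sigma_rel * db)
        s_true = _expected_survival(realized, truth, design.protocol)
        n_seeded = seeded * design.replicates
        colonies = rng.poisson(n_seeded * pe * s_true)
        if colonies == 0:
            # keep the point usable: one colony is the detection floor
            colonies = 1
        sf = colonies / (n_seeded * pe_hat)
        # Poisson counting errors of the point and of the control, in quadrature
        rel = np.sqrt(1.0 / colonies + 1.0 / ctrl_colonies)
        points.append(
            SurvivalDataPoint(
                dose=realized,
                surviving_fraction=float(min(sf, 1.0)),
                sf_sigma=float(sf * rel),
                protocol=design.protocol,
                condition=design.condition,
                dose_sigma=dose_sigma,
            )
        )
    return points


def noiseless_survival_points(
    truth: RadiobiologicalParameterSet,
    doses: Sequence[MixedFieldDose],
    protocol: IrradiationProtocol,
    condition: Condition,
    sigma_rel: float = 0.05,
) -> list[SurvivalDataPoint]:
    """Exact model survival at the given doses (for oracle round trips).

    ``sigma_rel`` sets nominal uncertainties so the points can be used in the
    error-weighted fits; it adds no noise.
    """
    pts = []
    for dose in doses:
        s = _expected_survival(dose, truth, protocol)
        pts.append(
            SurvivalDataPoint(
                dose=dose,
                surviving_fraction=s,
                sf_sigma=sigma_rel * s,
                protocol=protocol,
                condition=condition,
            )
        )
    return pts


# --------------------------------------------------------------------------
# Default assay designs
# --------------------------------------------------------------------------

#: photon doses (Gy) of the reference curves, delivered at ~1 Gy/min
_REFERENCE_DOSES = (1.0, 2.0, 4.0, 6.0, 8.0)

#: relative thermal-column dose scale across the four reactor powers
#: (7.5, 30, 100, 250 kW) at the fixed 10-min irradiation
_POWER_SCALE = (7.5 / 250.0, 30.0 / 250.0, 100.0 / 250.0, 1.0)


def reference_photon_design(
    doses: Sequence[float] = _REFERENCE_DOSES,
    dose_rate: float = 1.0,
    acute: bool = True,
) -> AssayDesign:
    """Reference photon assay: five escalating doses at a ~1 Gy/min source."""
    protocol = IrradiationProtocol(duration=0.0 if acute else max(doses) / dose_rate,
                                   dose_rate=dose_rate)
    return AssayDesign(
        condition=Condition.REFERENCE_PHOTON,
        dose_points=tuple(MixedFieldDose(d_photon=d) for d in doses),
        protocol=protocol,
        cells_seeded=(300, 300, 500, 1000, 2000),
        replicates=3,
    )


def beam_only_design(
    max_total_dose: float = 3.0,
    photon_fraction: float = 0.1,
) -> AssayDesign:
    """Beam-only assay: 10-min irradiations at four reactor powers.

    The total point dose scales with power; a configurable fraction is the
    photon contamination of the thermal column, the rest the neutron term.
    """
    doses = tuple(
        MixedFieldDose(
            d_neutron=(1.0 - photon_fraction) * max_total_dose * s,
            d_photon=photon_fraction * max_total_dose * s,
        )
        for s in _POWER_SCALE
    )
    return AssayDesign(
        condition=Condition.BEAM_ONLY,
        dose_points=doses,
        protocol=IrradiationProtocol(duration=10.0),
        cells_seeded=(300, 400, 1000, 4000),
        replicates=3,
    )


def bnct_design(
    max_boron_dose: float = 2.0,
    max_beam_dose: float = 1.5,
    photon_fraction: float = 0.1,
    boron_sigma_rel: float = 0.05,
) -> AssayDesign:
    """BPA-BNCT assay: the beam-only field plus the boron-capture dose.

    Boron and beam doses share the reactor-power scaling (both are driven by
    the thermal fluence at the fixed 10-min irradiation).
    """
    doses = tuple(
        MixedFieldDose(
            d_boron=max_boron_dose * s,
            d_neutron=(1.0 - photon_fraction) * max_beam_dose * s,
            d_photon=photon_fraction * max_beam_dose * s,
        )
        for s in _POWER_SCALE
    )
    return AssayDesign(
        condition=Condition.BPA_BNCT,
        dose_points=doses,
        protocol=IrradiationProtocol(duration=10.0),
        cells_seeded=(500, 1000, 5000, 100000),
        replicates=3,
        boron_sigma_rel=boron_sigma_rel,
    )


# --------------------------------------------------------------------------
# Foci series
# --------------------------------------------------------------------------

def generate_foci_series(
    kinetics: RepairKinetics,
    times: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> FociTimeSeries:
    """Bi-exponential foci intensity at ``times`` with Gaussian noise.

    Values are clipped to stay positive and renormalized to the first sample,
    mimicking the foci/nuclei normalization of the measured series. The
    low-LET fast fraction of ``kinetics`` is the bi-exponential weight c.
    """
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise InvalidInputError("times must be non-empty")
    rng = np.random.default_rng(seed)
    y = foci_intensity(t, kinetics.frac_fast_low_let, kinetics.t0_fast, kinetics.t0_slow)
    y = np.asarray(y, dtype=float)
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    y = np.clip(y, 1e-9, None)
    y = y / y[0]
    sigmas = np.full_like(y, max(noise_sigma, 1e-3))
    return FociTimeSeries(times=t, intensities=y, sigmas=sigmas)


# --------------------------------------------------------------------------
# Phantom dose-component fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Water-equivalent block phantom with a spherical tumor in a forward beam.

    Each component's dose rate decays exponentially with depth along the beam
    axis (per-component attenuation length, mm) and falls off laterally with
    a Gaussian profile; a small multiplicative noise emulates Monte Carlo
    statistical fluctuations of the transport output. The boron grid is the
    per-ppm dose rate; ROI concentrations scale it at conversion time.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    spacing: float = 2.5  # mm, isotropic
    beam_axis: int = 2
    surface_rates: dict = field(
        default_factory=lambda: {
            # Gy/min at the entrance, on the beam axis; boron entry is per ppm
            "boron_per_ppm": 0.010,
            "neutron_thermal": 0.030,
            "neutron_fast": 0.040,
            "photon": 0.050,
        }
    )
    attenuation_mm: dict = field(
        default_factory=lambda: {
            "boron_per_ppm": 30.0,
            "neutron_thermal": 30.0,
            "neutron_fast": 12.0,
            "photon": 70.0,
        }
    )
    lateral_sigma_mm: float = 15.0
    tumor_center_mm: tuple[float, float, float] = (30.0, 30.0, 20.0)
    tumor_radius_mm: float = 10.0
    boron_ppm: dict = field(default_factory=lambda: {"tumor": 40.0, "brain": 13.6})
    noise_rel: float = 0.01

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape) or self.spacing <= 0:
            raise InvalidInputError("phantom dimensions must be positive")
        if self.beam_axis not in (0, 1, 2):
            raise InvalidInputError("beam_axis must be 0, 1 or 2")
        side = [n * self.spacing for n in self.shape]
        c, r = self.tumor_center_mm, self.tumor_radius_mm
        if r <= 0 or any(c[i] - r < 0 or c[i] + r > side[i] for i in range(3)):
            raise InvalidInputError("tumor sphere must lie inside the phantom")
        for d in (self.surface_rates, self.attenuation_mm):
            if any(v <= 0 for v in d.values()):
                raise InvalidInputError("rates and attenuation lengths must be positive")


def generate_phantom_field(
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> tuple[DoseComponentField, list[ROIMask]]:
    """Deterministic phantom field plus its tumor and brain ROI masks."""
    rng = np.random.default_rng(seed)
    # voxel-center coordinates in mm
    coords = [(np.arange(n) + 0.5) * spec.spacing for n in spec.shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    pos = (xx, yy, zz)
    depth = pos[spec.beam_axis]
    lateral_axes = [i for i in range(3) if i != spec.beam_axis]
    beam_center = [spec.tumor_center_mm[i] for i in lateral_axes]
    rho2 = sum(
        (pos[a] - c) ** 2 for a, c in zip(lateral_axes, beam_center)
    )
    lateral = np.exp(-rho2 / (2.0 * spec.lateral_sigma_mm**2))

    grids = {}
    for name, r0 in spec.surface_rates.items():
        profile = r0 * np.exp(-depth / spec.attenuation_mm[name]) * lateral
        if spec.noise_rel > 0:
            profile = profile * (1.0 + spec.noise_rel * rng.standard_normal(profile.shape))
            profile = np.clip(profile, 0.0, None)
        grids[name] = profile

    field_ = DoseComponentField(
        spacing=(spec.spacing,) * 3,
        origin=(0.0, 0.0, 0.0),
        units_mode="rate",
        **grids,
    )
    r2 = sum((pos[i] - spec.tumor_center_mm[i]) ** 2 for i in range(3))
    tumor = r2 <= spec.tumor_radius_mm**2
    brain = ~tumor
    rois = [
        ROIMask(mask=tumor, name="GTV", boron_concentration=spec.boron_ppm["tumor"]),
        ROIMask(mask=brain, name="brain", boron_concentration=spec.boron_ppm["brain"]),
    ]
    return field_, rois
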