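"""Radiobiological model kernel for BNCT mixed-field dosimetry.

Implements the modified linear-quadratic (MLQ) cell-survival model with
dose-protraction (Lea-Catcheside) G factors under dual-kinetics sub-lethal
damage (SLD) repair, for a reference photon radiation and for the three-term
BNCT mixed field (boron capture, neutron, photon components), plus the
bi-exponential foci-decay intensity used to calibrate the repair times.

Units: times in minutes, doses in Gy, alpha in 1/Gy, beta in 1/Gy^2.
An irradiation duration of zero encodes the acute limit (G = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "LetClass",
    "RepairKinetics",
    "LQParameters",
    "IrradiationProtocol",
    "MixedFieldDose",
    "GFactors",
    "g_single",
    "g_dual",
    "g_cross",
    "g_factors",
    "survival_reference",
    "log_kill_mixed",
    "survival_mixed_field",
    "foci_intensity",
]


class LetClass(str, Enum):
    """Linear-energy-transfer class selecting which SLD-repair proportions apply."""

    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class RepairKinetics:
    """Dual-kinetics SLD repair: characteristic times and fast-repair fractions.

    ``t0_fast``/``t0_slow`` are the fast and slow characteristic repair times in
    minutes; ``frac_fast_low_let``/``frac_fast_high_let`` are the proportions of
    sublesions repaired with the fast kinetics for low- and high-LET radiation
    (the slow proportion is ``1 - fast`` by construction).
    """

    t0_fast: float
    t0_slow: float
    frac_fast_low_let: float
    frac_fast_high_let: float

    def __post_init__(self) -> None:
        if not (0.0 < self.t0_fast <= self.t0_slow):
            raise InvalidParameterError(
                f"repair times must satisfy 0 < t0_fast <= t0_slow, got "
                f"({self.t0_fast}, {self.t0_slow})"
            )
        for name in ("frac_fast_low_let", "frac_fast_high_let"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")

    def fast_fraction(self, let_class: LetClass | str) -> float:
        let_class = LetClass(let_class)
        if let_class is LetClass.LOW:
            return self.frac_fast_low_let
        return self.frac_fast_high_let


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic parameters (alpha, beta) of one radiation component."""

    alpha: float
    beta: float
    let_class: LetClass = LetClass.LOW

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidParameterError(
                f"alpha and beta must be non-negative, got ({self.alpha}, {self.beta})"
            )
        object.__setattr__(self, "let_class", LetClass(self.let_class))


@dataclass(frozen=True)
class IrradiationProtocol:
    """Constant-dose-rate delivery over ``duration`` minutes.

    ``duration == 0`` encodes an acute exposure (protraction factor G = 1).
    ``dose_rate`` (Gy/min) is only needed when the *reference* radiation is
    itself protracted, in which case the reference irradiation time is derived
    from the dose as ``theta = D / dose_rate``.
    """

    duration: float
    delivery: str = "constant_rate"
    dose_rate: float | None = None

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise InvalidParameterError(f"duration must be >= 0, got {self.duration}")
        if self.delivery != "constant_rate":
            raise InvalidParameterError(f"unsupported delivery mode {self.delivery!r}")
        if self.dose_rate is not None and self.dose_rate <= 0:
            raise InvalidParameterError(f"dose_rate must be > 0, got {self.dose_rate}")


ACUTE = IrradiationProtocol(duration=0.0)


@dataclass(frozen=True)
class MixedFieldDose:
    """Absorbed doses (Gy) of the three BNCT field terms: boron, neutron, photon."""

    d_boron: float = 0.0
    d_neutron: float = 0.0
    d_photon: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d_boron", "d_neutron", "d_photon"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def total(self) -> float:
        return self.d_boron + self.d_neutron + self.d_photon


# --------------------------------------------------------------------------
# Lea-Catcheside protraction factors
# --------------------------------------------------------------------------

def g_single(theta, t0: float):
    """Lea-Catcheside factor G(theta, t0) for a constant dose rate.

    G = 2(t0/theta) [1 - (t0/theta)(1 - exp(-theta/t0))], continuous at
    theta = 0 where G = 1 (acute limit). Accepts scalar or array ``theta``.
    """
    if t0 <= 0:
        raise InvalidParameterError(f"characteristic repair time must be > 0, got {t0}")
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0):
        raise InvalidInputError("irradiation duration must be >= 0")
    x = th / t0
    # series for small x avoids catastrophic cancellation in x - 1 + e^-x
    small = x < 1e-3
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(
            small,
            1.0 - x / 3.0 + x**2 / 12.0 - x**3 / 60.0,
            2.0 * (x - 1.0 + np.exp(-np.where(small, 1.0, x))) / np.where(small, 1.0, x) ** 2,
        )
    if np.ndim(theta) == 0:
        return float(g)
    return g


def g_dual(protocol, kinetics: RepairKinetics, let_class: LetClass | str):
    """Dual-kinetics protraction factor: the fast/slow convex combination
    ``a_f G(theta, t0f) + a_s G(theta, t0s)`` with LET-class proportions."""
    theta = protocol.duration if isinstance(protocol, IrradiationProtocol) else protocol
    a_fast = kinetics.fast_fraction(let_class)
    return a_fast * g_single(theta, kinetics.t0_fast) + (1.0 - a_fast) * g_single(
        theta, kinetics.t0_slow
    )


def g_cross(
    protocol,
    kinetics: RepairKinetics,
    let_a: LetClass | str,
    let_b: LetClass | str,
):
    """Protraction factor for a quadratic cross term between two components.

    All components are delivered simultaneously over the same duration, so the
    cross factor uses the arithmetic mean of the two components' fast-repair
    proportions. For equal LET classes this reduces exactly to ``g_dual``.
    """
    theta = protocol.duration if isinstance(protocol, IrradiationProtocol) else protocol
    a_fast = 0.5 * (kinetics.fast_fraction(let_a) + kinetics.fast_fraction(let_b))
    return a_fast * g_single(theta, kinetics.t0_fast) + (1.0 - a_fast) * g_single(
        theta, kinetics.t0_slow
    )


@dataclass(frozen=True)
class GFactors:
    """The six protraction factors entering the mixed-field survival model."""

    photon: float = 1.0
    neutron: float = 1.0
    boron: float = 1.0
    boron_neutron: float = 1.0
    boron_photon: float = 1.0
    photon_neutron: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "photon",
            "neutron",
            "boron",
            "boron_neutron",
            "boron_photon",
            "photon_neutron",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise InvalidParameterError(f"G factor {name} must lie in (0, 1], got {v}")


ACUTE_G = GFactors()


def g_factors(protocol, kinetics: RepairKinetics) -> GFactors:
    """All six G factors for a shared constant-rate delivery.

    Photon is low LET; neutron and boron are high LET; cross terms use the
    mean fast-fraction rule of :func:`g_cross`.
    """
    return GFactors(
        photon=g_dual(protocol, kinetics, LetClass.LOW),
        neutron=g_dual(protocol, kinetics, LetClass.HIGH),
        boron=g_dual(protocol, kinetics, LetClass.HIGH),
        boron_neutron=g_cross(protocol, kinetics, LetClass.HIGH, LetClass.HIGH),
        boron_photon=g_cross(protocol, kinetics, LetClass.HIGH, LetClass.LOW),
        photon_neutron=g_cross(protocol, kinetics, LetClass.LOW, LetClass.HIGH),
    )


# --------------------------------------------------------------------------
# Survival models
# --------------------------------------------------------------------------

def survival_reference(dose, params: LQParameters, g_factor: float = 1.0):
    """Reference-radiation MLQ survival S = exp(-(alpha D + beta G D^2))."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise InvalidInputError("dose must be >= 0")
    if not (0.0 < g_factor <= 1.0):
        raise InvalidParameterError(f"g_factor must lie in (0, 1], got {g_factor}")
    s = np.exp(-(params.alpha * d + params.beta * g_factor * d * d))
    if np.ndim(dose) == 0:
        return float(s)
    return s


def log_kill_mixed(
    d_boron,
    d_neutron,
    d_photon,
    photon: LQParameters,
    neutron: LQParameters,
    boron: LQParameters,
    g: GFactors = ACUTE_G,
):
    """Negative log-survival of the mixed field (the MLQ exponent).

    E = aB DB + an Dn + ag Dg
        + GB bB DB^2 + Gn bn Dn^2 + Gg bg Dg^2
        + 2 GBn sqrt(bB bn) DB Dn + 2 GBg sqrt(bB bg) DB Dg
        + 2 Ggn sqrt(bg bn) Dg Dn

    The quadratic cross terms carry the synergy between simultaneously
    delivered components. Accepts scalars or broadcastable arrays.
    """
    db = np.asarray(d_boron, dtype=float)
    dn = np.asarray(d_neutron, dtype=float)
    dg = np.asarray(d_photon, dtype=float)
    if np.any(db < 0) or np.any(dn < 0) or np.any(dg < 0):
        raise InvalidInputError("dose components must be >= 0")
    lin = boron.alpha * db + neutron.alpha * dn + photon.alpha * dg
    quad = (
        g.boron * boron.beta * db * db
        + g.neutron * neutron.beta * dn * dn
        + g.photon * photon.beta * dg * dg
    )
    mq = (
        2.0 * g.boron_neutron * math.sqrt(boron.beta * neutron.beta) * db * dn
        + 2.0 * g.boron_photon * math.sqrt(boron.beta * photon.beta) * db * dg
        + 2.0 * g.photon_neutron * math.sqrt(photon.beta * neutron.beta) * dg * dn
    )
    return lin + quad + mq


def survival_mixed_field(
    dose: MixedFieldDose,
    photon: LQParameters,
    neutron: LQParameters,
    boron: LQParameters,
    g: GFactors = ACUTE_G,
) -> float:
    """Mixed-field MLQ surviving fraction exp(-E) with E from :func:`log_kill_mixed`.

    With exactly one nonzero component and the matching G this reduces exactly
    to :func:`survival_reference` for that component's parameters.
    """
    return float(
        np.exp(
            -log_kill_mixed(
                dose.d_boron, dose.d_neutron, dose.d_photon, photon, neutron, boron, g
            )
        )
    )


def foci_intensity(t, frac_fast: float, t0_fast: float, t0_slow: float):
    """Bi-exponential repair intensity I(t) = c e^(-t/t0f) + (1-c) e^(-t/t0s).

    Normalized DNA-damage foci decay; I(0) = 1 and I is strictly decreasing.
    """
    if t0_fast <= 0 or t0_slow <= 0:
        raise InvalidParameterError("repair times must be > 0")
    if not (0.0 <= frac_fast <= 1.0):
        raise InvalidParameterError(f"frac_fast must lie in [0, 1], got {frac_fast}")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise InvalidInputError("time must be >= 0")
    out = frac_fast * np.exp(-tt / t0_fast) + (1.0 - frac_fast) * np.exp(-tt / t0_slow)
    if np.ndim(t) == 0:
        return float(out)
    return out
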