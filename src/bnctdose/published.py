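"""Published radiobiological constants for U87 glioblastoma BNCT dosimetry.

Fitted MLQ parameters for the U87 human glioblastoma cell line (clonogenic
survival under Co-60 gamma, low-energy x-ray, thermal-neutron beam-only and
BPA-BNCT irradiation), the dual-kinetics sub-lethal-damage repair constants,
and the fixed RBE/CBE weights used in clinical BNCT practice (derived from the
rat 9L gliosarcoma model). These are the parameter sets a user feeds to the
photon isoeffective and RBE-weighted dose models.
"""

from __future__ import annotations

from .core import LetClass, LQParameters, RepairKinetics
from .dosimetry import RadiobiologicalParameterSet, RBEWeights

__all__ = [
    "U87_KINETICS",
    "CO60_PHOTON",
    "XRAY_PHOTON",
    "NEUTRON_CO60_REF",
    "NEUTRON_XRAY_REF",
    "BORON_BPA",
    "GBM_U87_CO60",
    "GBM_U87_XRAY",
    "CLINIC_WEIGHTS",
]

# Fast/slow characteristic repair times (min) from the bi-exponential fit of
# U87 foci-decay data; fast-repair proportions for low- and high-LET radiation.
U87_KINETICS = RepairKinetics(
    t0_fast=91.0,
    t0_slow=1238.0,
    frac_fast_low_let=0.77,
    frac_fast_high_let=0.2,
)

# Reference photon radiations (alpha in 1/Gy, beta in 1/Gy^2)
CO60_PHOTON = LQParameters(alpha=0.21, beta=0.02, let_class=LetClass.LOW)
XRAY_PHOTON = LQParameters(alpha=0.46, beta=0.03, let_class=LetClass.LOW)

# Beam (proton + 14C recoil) component, fitted jointly with each reference
NEUTRON_CO60_REF = LQParameters(alpha=0.5, beta=0.5, let_class=LetClass.HIGH)
NEUTRON_XRAY_REF = LQParameters(alpha=0.1, beta=0.5, let_class=LetClass.HIGH)

# Boron-capture (alpha + 7Li) component with BPA; beta sits on its zero bound
BORON_BPA = LQParameters(alpha=3.0, beta=0.0, let_class=LetClass.HIGH)

#: Full parameter set for the isoeffective model, Co-60 reference (the set
#: recommended for in-patient dosimetry).
GBM_U87_CO60 = RadiobiologicalParameterSet(
    photon=CO60_PHOTON,
    neutron=NEUTRON_CO60_REF,
    boron=BORON_BPA,
    kinetics=U87_KINETICS,
    label="GBM-U87/Co-60",
)

#: Same, with the low-energy x-ray irradiator as the reference radiation.
GBM_U87_XRAY = RadiobiologicalParameterSet(
    photon=XRAY_PHOTON,
    neutron=NEUTRON_XRAY_REF,
    boron=BORON_BPA,
    kinetics=U87_KINETICS,
    label="GBM-U87/x-ray",
)

#: Fixed factors used in clinical BNCT dosimetry for brain tumors
#: (gliosarcoma-derived): CBE 3.8 for the boron dose, RBE 3.2 for neutrons.
CLINIC_WEIGHTS = RBEWeights(w_boron=3.8, w_neutron=3.2, w_photon=1.0, label="clinic")

BUILTIN_PARAMETER_SETS = {
    "gbm-u87-co60": GBM_U87_CO60,
    "gbm-u87-xray": GBM_U87_XRAY,
}

BUILTIN_WEIGHTS = {
    "clinic": CLINIC_WEIGHTS,
}
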