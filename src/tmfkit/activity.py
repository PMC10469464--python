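"""Fugacity-ratio correction, apparent chemical activity, concentration
normalization schemes, and the pairwise biomagnification factor (BMF).

Unit chain: measured concentrations enter as ng/g wet weight.  Conversion to
mol/m^3 assumes a configurable tissue density (default 1 g/cm^3):

    C [mol/m^3] = c_ww [ng/g] * density [g/cm^3] * 1e-3 / molar_mass [g/mol]

Apparent activity is then ``a = F * C / (S_W * capacity)`` where ``F`` is the
fugacity ratio, ``S_W`` the water solubility (mol/m^3) and ``capacity`` the
water-relative sorptive capacity of the tissue mixture.  Since the conversion
factor is a per-sample positive constant, TMFs are invariant to whether mass
or molar units are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chem import ChemicalRecord
from .errors import DomainError, NonNormalizableSampleError
from .partitioning import TissueComposition, sorptive_capacity

#: Walden's-rule default for the entropy of fusion over R.
DEFAULT_ENTROPY_RATIO = 6.79

#: Default tissue density, g/cm^3.
DEFAULT_TISSUE_DENSITY = 1.0

#: Concentration-normalization schemes (activity is handled separately).
NORMALIZATION_SCHEMES = ("wet", "total_protein", "albumin", "polar_lipid", "total_lipid")

#: All TMF schemes, activity first.
ALL_SCHEMES = ("activity",) + NORMALIZATION_SCHEMES

_SCHEME_PHI = {
    "total_protein": lambda c: c.phi_P,
    "albumin": lambda c: c.phi_ALB,
    "polar_lipid": lambda c: c.phi_PL,
    "total_lipid": lambda c: c.phi_L,
}


@dataclass(frozen=True)
class ActivityResult:
    sample_id: str
    analyte: str
    apparent_activity: float
    fugacity_ratio: float
    capacity: float
    body_temperature: float


@dataclass(frozen=True)
class BMFResult:
    predator_id: str
    prey_id: str
    analyte: str
    scheme: str
    bmf: float


def fugacity_ratio(
    melting_point: float,
    body_temperature: float,
    entropy_ratio: float = DEFAULT_ENTROPY_RATIO,
) -> float:
    """Fugacity ratio F treating a solid chemical as a sub-cooled liquid.

    ``F = 1`` when the chemical is liquid at body temperature
    (melting point <= body temperature); otherwise
    ``F = exp(-entropy_ratio * (melting_point / body_temperature - 1))``.
    Always in (0, 1].
    """
    if melting_point <= 0 or body_temperature <= 0:
        raise DomainError("temperatures must be positive kelvin")
    if melting_point <= body_temperature:
        return 1.0
    return math.exp(-entropy_ratio * (melting_point / body_temperature - 1.0))


def mass_to_molar(c_ww: float, molar_mass: float, density: float = DEFAULT_TISSUE_DENSITY) -> float:
    """ng/g wet weight -> mol/m^3 at the given tissue density (g/cm^3)."""
    return c_ww * density * 1e-3 / molar_mass


def apparent_activity(
    c_ww: float,
    comp: TissueComposition,
    chem: ChemicalRecord,
    body_temperature: float,
    *,
    sample_id: str = "",
    entropy_ratio: float = DEFAULT_ENTROPY_RATIO,
    density: float = DEFAULT_TISSUE_DENSITY,
    molar: bool = True,
    fits=(),
) -> ActivityResult:
    """Apparent chemical activity of a wet-weight concentration.

    ``a = F * C / (S_W * capacity)`` with C the (molar) volumetric
    concentration; linear in ``c_ww``.  With ``molar=False`` the mass
    concentration is used directly — a per-analyte constant that cancels in
    any TMF or BMF.

    Raises
    ------
    DomainError
        Negative concentration, nonpositive capacity or solubility.
    """
    if c_ww < 0:
        raise DomainError("c_ww must be >= 0")
    capacity = sorptive_capacity(comp, chem, fits)
    if capacity <= 0:
        raise DomainError("sorptive capacity must be > 0")
    if chem.water_solubility <= 0:
        raise DomainError("water solubility must be > 0")
    F = fugacity_ratio(chem.melting_point, body_temperature, entropy_ratio)
    conc = mass_to_molar(c_ww, chem.molar_mass, density) if molar else c_ww
    a = F * conc / (chem.water_solubility * capacity)
    return ActivityResult(
        sample_id=sample_id,
        analyte=chem.name,
        apparent_activity=a,
        fugacity_ratio=F,
        capacity=capacity,
        body_temperature=body_temperature,
    )


def activity_factor(
    comp: TissueComposition,
    chem: ChemicalRecord,
    body_temperature: float,
    *,
    entropy_ratio: float = DEFAULT_ENTROPY_RATIO,
    density: float = DEFAULT_TISSUE_DENSITY,
    molar: bool = True,
    fits=(),
) -> float:
    """Per-sample multiplier turning c_ww (ng/g ww) into apparent activity.

    Applied identically to measured values and quantification limits so
    censoring thresholds stay consistent across samples.
    """
    return apparent_activity(
        1.0,
        comp,
        chem,
        body_temperature,
        entropy_ratio=entropy_ratio,
        density=density,
        molar=molar,
        fits=fits,
    ).apparent_activity


def normalize_concentration(c_ww: float, comp: TissueComposition, scheme: str) -> float:
    """Normalize a wet-weight concentration to a tissue fraction.

    ``wet`` returns c_ww unchanged; the other schemes divide by the scheme's
    phase fraction (total protein, albumin, polar lipid, total lipid).

    Raises
    ------
    NonNormalizableSampleError
        The scheme's fraction is zero for this sample; callers exclude the
        sample from that scheme with a logged warning.
    """
    if c_ww < 0:
        raise DomainError("c_ww must be >= 0")
    if scheme == "wet":
        return c_ww
    try:
        phi = _SCHEME_PHI[scheme](comp)
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {NORMALIZATION_SCHEMES}")
    if phi <= 0.0:
        raise NonNormalizableSampleError(f"scheme {scheme!r}: phase fraction is zero")
    return c_ww / phi


def normalization_factor(comp: TissueComposition, scheme: str) -> float:
    """Per-sample multiplier for ``scheme`` (1 for wet, 1/phi otherwise)."""
    return normalize_concentration(1.0, comp, scheme)


def compute_bmf(value_predator: float, value_prey: float, scheme_label: str,
                *, predator_id: str = "predator", prey_id: str = "prey",
                analyte: str = "") -> BMFResult:
    """Predator/prey ratio of same-scheme activities or normalized concentrations.

    BMF > 1 indicates biomagnification; < 1 biodilution.
    """
    if value_prey <= 0:
        raise DomainError("prey value must be > 0 for a defined BMF")
    if value_predator < 0:
        raise DomainError("predator value must be >= 0")
    return BMFResult(
        predator_id=predator_id,
        prey_id=prey_id,
        analyte=analyte,
        scheme=scheme_label,
        bmf=value_predator / value_prey,
    )
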