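"""Sorptive capacity of a tissue mixture and chemical mass distribution
among the five tissue phases (neutral lipid, polar lipid, albumin,
structural protein, water), plus the logD sensitivity sweep for TMFs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import ChemicalRecord, LogD, resolve_logD
from .errors import DegenerateCompositionError, MissingPropertyError

#: Order of the five mass-distribution phases.
MASS_PHASES = ("NL", "PL", "ALB", "SP", "W")


@dataclass(frozen=True)
class TissueComposition:
    """Mass fractions (g/g wet sample) of the five modeled tissue phases.

    The fractions may sum to less than 1; residual mass (carbohydrate, ash)
    is allowed and excluded from the capacity sum.
    """

    phi_NL: float
    phi_PL: float
    phi_ALB: float
    phi_SP: float
    phi_W: float

    def __post_init__(self):
        for name in ("phi_NL", "phi_PL", "phi_ALB", "phi_SP", "phi_W"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.phi_NL + self.phi_PL + self.phi_ALB + self.phi_SP + self.phi_W
        if total > 1.0 + 1e-9:
            raise ValueError(f"phase fractions sum to {total} > 1")

    @property
    def phi_P(self) -> float:
        """Total protein fraction (albumin + structural)."""
        return self.phi_ALB + self.phi_SP

    @property
    def phi_L(self) -> float:
        """Total lipid fraction (neutral + polar)."""
        return self.phi_NL + self.phi_PL


@dataclass(frozen=True)
class MassDistribution:
    """Fraction of total chemical mass residing in each tissue phase."""

    NL: float
    PL: float
    ALB: float
    SP: float
    W: float

    def __post_init__(self):
        vals = self.as_dict().values()
        if any(v < -1e-15 or v > 1 + 1e-12 for v in vals):
            raise ValueError("mass fractions must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("mass fractions must sum to 1")

    def as_dict(self) -> dict:
        return {"NL": self.NL, "PL": self.PL, "ALB": self.ALB, "SP": self.SP, "W": self.W}


def _phase_products(comp: TissueComposition, chem: ChemicalRecord, fits=()):
    """phi_i * D_i for the five phases, with D_W == 1."""
    try:
        d = {p: 10.0 ** resolve_logD(chem, p, fits) for p in ("NLW", "PLW", "ALBW", "SPW")}
    except MissingPropertyError:
        raise
    return {
        "NL": comp.phi_NL * d["NLW"],
        "PL": comp.phi_PL * d["PLW"],
        "ALB": comp.phi_ALB * d["ALBW"],
        "SP": comp.phi_SP * d["SPW"],
        "W": comp.phi_W * 1.0,
    }


def sorptive_capacity(comp: TissueComposition, chem: ChemicalRecord, fits=()) -> float:
    """Water-relative sorptive capacity of the mixture for the chemical.

    ``phi_NL*D_NLW + phi_PL*D_PLW + phi_ALB*D_ALBW + phi_SP*D_SPW + phi_W``
    with ``D = 10**logD``.  Dimensionless (relative to the chemical's water
    solubility); pure water has capacity 1.

    Raises
    ------
    MissingPropertyError
        If any of the four phase-water logD values cannot be resolved.
    """
    return float(sum(_phase_products(comp, chem, fits).values()))


def mass_distribution(comp: TissueComposition, chem: ChemicalRecord, fits=()) -> MassDistribution:
    """Distribute the chemical's mass among the five phases.

    Fraction in phase i is ``phi_i * D_i / capacity`` (``D_W == 1``); the
    fractions sum to 1 exactly up to floating point.

    Raises
    ------
    DegenerateCompositionError
        All five fractions are zero (capacity 0).
    """
    products = _phase_products(comp, chem, fits)
    capacity = sum(products.values())
    if capacity <= 0.0:
        raise DegenerateCompositionError(
            "composition has zero capacity (all phase fractions zero?)"
        )
    return MassDistribution(**{k: v / capacity for k, v in products.items()})


def logD_sensitivity(
    samples,
    chem_table: dict,
    analyte: str,
    phase: str,
    logD_values,
    reference_logD: float,
    scheme: str = "activity",
    **tmf_kwargs,
):
    """Recompute the TMF of ``analyte`` under substituted logD values.

    Each value in ``logD_values`` (plus ``reference_logD``) replaces the
    analyte's logD for ``phase`` *globally* — for every sample at once — and
    the scheme's TMF is recomputed.  Percent change is reported against the
    TMF at ``reference_logD``; CI overlap with the reference fit is flagged.

    Returns a list of dict rows:
    ``{"logD": v, "tmf": t, "pct_change": p, "ci_low", "ci_high",
    "overlaps_reference": bool}``.
    """
    from .tmf import compute_tmf  # deferred import; tmf depends on this module

    def _tmf_at(value: float):
        table = dict(chem_table)
        table[analyte] = table[analyte].with_logD(
            phase, LogD(value=value, provenance="measured", source="sensitivity")
        )
        return compute_tmf(samples, analyte, scheme, table, **tmf_kwargs)

    ref = _tmf_at(reference_logD)
    rows = []
    for v in logD_values:
        res = _tmf_at(v)
        overlap = not (res.ci95[0] > ref.ci95[1] or res.ci95[1] < ref.ci95[0])
        rows.append(
            {
                "logD": float(v),
                "tmf": res.tmf,
                "pct_change": 100.0 * (res.tmf - ref.tmf) / ref.tmf,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
                "overlaps_reference": bool(overlap),
            }
        )
    return rows
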