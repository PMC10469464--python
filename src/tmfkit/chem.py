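"""Chemical property registry and QSPR prediction of phase-water distribution
coefficients from molar volume.

Each analyte carries, per tissue phase, a base-10 log distribution
coefficient (``logD``) relative to water.  Values are either *measured*
(taken verbatim from a laboratory source) or *predicted* from a per-class
linear regression of measured logD on molar volume.  Measured values always
take precedence over predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ExtrapolationWarning, MissingPropertyError, UnfitTableError

#: Tissue phases with a phase-water distribution coefficient.  Water itself
#: has D == 1 by definition and is not listed.
PHASES = ("NLW", "PLW", "ALBW", "SPW")

#: Recognized analyte classes (perfluoroalkyl carboxylic / sulfonic acids).
ANALYTE_CLASSES = ("PFCA", "PFSA")


@dataclass(frozen=True)
class LogD:
    """One log10 phase-water distribution coefficient with provenance."""

    value: float
    provenance: str = "measured"  # 'measured' | 'predicted'
    source: str = ""

    def __post_init__(self):
        if self.provenance not in ("measured", "predicted"):
            raise ValueError(f"provenance must be measured|predicted, got {self.provenance!r}")


@dataclass
class ChemicalRecord:
    """Identity and physicochemical properties of one analyte.

    Parameters
    ----------
    name : str
        Analyte label, e.g. ``"PFOS"``.
    analyte_class : str
        ``"PFCA"`` or ``"PFSA"``; selects which QSPR fit applies.
    chain_length : int
        Number of carbons in the perfluoroalkyl chain.
    molar_mass : float
        g/mol.
    molar_volume : float
        cm^3/mol; the QSPR descriptor.
    melting_point : float
        K; used for the fugacity-ratio correction.
    water_solubility : float
        mol/m^3 at the reference temperature in ``solubility_temperature``.
    logD : dict
        Mapping phase -> :class:`LogD` for phases in :data:`PHASES`.
        Missing entries mean "predict me".
    """

    name: str
    analyte_class: str
    chain_length: int
    molar_mass: float
    molar_volume: float
    melting_point: float
    water_solubility: float
    logD: dict = field(default_factory=dict)
    solubility_temperature: float = 298.0

    def __post_init__(self):
        if self.analyte_class not in ANALYTE_CLASSES:
            raise ValueError(
                f"{self.name}: analyte_class must be one of {ANALYTE_CLASSES}, "
                f"got {self.analyte_class!r}"
            )
        if not self.molar_volume > 0:
            raise ValueError(f"{self.name}: molar_volume must be > 0")
        if not self.water_solubility > 0:
            raise ValueError(f"{self.name}: water_solubility must be > 0")
        if not self.melting_point > 0:
            raise ValueError(f"{self.name}: melting_point must be > 0")
        for phase, ld in self.logD.items():
            if phase not in PHASES:
                raise ValueError(f"{self.name}: unknown phase {phase!r}")
            if not isinstance(ld, LogD):
                raise TypeError(f"{self.name}: logD[{phase!r}] must be a LogD instance")

    def with_logD(self, phase: str, logd: LogD) -> "ChemicalRecord":
        """Return a copy with one logD entry replaced (used by sensitivity sweeps)."""
        new = dict(self.logD)
        new[phase] = logd
        return ChemicalRecord(
            name=self.name,
            analyte_class=self.analyte_class,
            chain_length=self.chain_length,
            molar_mass=self.molar_mass,
            molar_volume=self.molar_volume,
            melting_point=self.melting_point,
            water_solubility=self.water_solubility,
            logD=new,
            solubility_temperature=self.solubility_temperature,
        )


@dataclass(frozen=True)
class QSPRFit:
    """Linear fit of logD on molar volume for one (analyte class, phase) pair."""

    analyte_class: str
    phase: str
    slope: float  # per (cm^3/mol)
    intercept: float  # log10 units
    n_points: int
    residual_sd: float  # log10 units, n-2 dof (0 when n == 2)
    volume_range: tuple  # (min, max) molar volume of the fitted points

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("QSPRFit requires n_points >= 2")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


def fit_logD_qspr(measured_points, analyte_class: str, phase: str) -> QSPRFit:
    """Ordinary least squares of logD on molar volume for one class and phase.

    Parameters
    ----------
    measured_points : sequence of (molar_volume, logD) pairs
        All from a single analyte class and a single phase.
    analyte_class, phase : str
        Recorded on the fit; fits never mix classes.

    Returns
    -------
    QSPRFit

    Raises
    ------
    UnfitTableError
        Fewer than 2 points, or all molar volumes identical.
    """
    pts = np.asarray(list(measured_points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise UnfitTableError(
            f"QSPR fit for class={analyte_class} phase={phase}: need >= 2 points, "
            f"got {0 if pts.size == 0 else pts.shape[0]}"
        )
    v, y = pts[:, 0], pts[:, 1]
    if np.ptp(v) == 0:
        raise UnfitTableError(
            f"QSPR fit for class={analyte_class} phase={phase}: all molar volumes identical"
        )
    n = len(v)
    slope, intercept = np.polyfit(v, y, 1)
    resid = y - (slope * v + intercept)
    residual_sd = 0.0 if n == 2 else float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return QSPRFit(
        analyte_class=analyte_class,
        phase=phase,
        slope=float(slope),
        intercept=float(intercept),
        n_points=n,
        residual_sd=residual_sd,
        volume_range=(float(v.min()), float(v.max())),
    )


def predict_logD(chem: ChemicalRecord, fits, phase: str) -> LogD:
    """Resolve the logD of ``chem`` for ``phase``: measured value if present,
    QSPR prediction otherwise.

    Measured values pass through untouched.  Predictions are
    ``slope * molar_volume + intercept`` from the fit matching
    ``(chem.analyte_class, phase)``; a molar volume outside the fitted range
    triggers an :class:`ExtrapolationWarning` but still returns the value.

    Raises
    ------
    MissingPropertyError
        No measured value and no applicable fit.
    """
    existing = chem.logD.get(phase)
    if existing is not None and existing.provenance == "measured":
        return existing
    fit = next(
        (f for f in fits if f.analyte_class == chem.analyte_class and f.phase == phase),
        None,
    )
    if fit is None:
        if existing is not None:  # a prior prediction with no fit to redo it
            return existing
        raise MissingPropertyError(
            f"{chem.name}: no measured logD_{phase} and no QSPR fit for "
            f"class={chem.analyte_class} phase={phase}"
        )
    lo, hi = fit.volume_range
    if not (lo <= chem.molar_volume <= hi):
        warnings.warn(
            f"{chem.name}: molar volume {chem.molar_volume:g} cm3/mol outside "
            f"fitted range [{lo:g}, {hi:g}] for class={chem.analyte_class} "
            f"phase={phase}; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    value = fit.slope * chem.molar_volume + fit.intercept
    return LogD(value=float(value), provenance="predicted", source=f"qspr:{chem.analyte_class}:{phase}")


def resolve_logD(chem: ChemicalRecord, phase: str, fits=()) -> float:
    """Numeric logD for ``phase``, measured or predicted; raises if unresolvable."""
    ld = chem.logD.get(phase)
    if ld is not None:
        return ld.value
    return predict_logD(chem, fits, phase).value
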