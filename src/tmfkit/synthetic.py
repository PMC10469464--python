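"""Synthetic food-web generator.

Produces datasets with the statistical structure the analysis pipeline
assumes: tissue-phase mass fractions trending linearly with trophic
position, log-normal apparent-activity noise around a configurable true
TMF per analyte, and left-censoring at a quantification limit.  The
generator draws on the *activity* scale and inverts the activity equation
back to wet-weight concentrations, so the configured TMF is the ground
truth for the activity scheme by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .activity import (
    DEFAULT_ENTROPY_RATIO,
    DEFAULT_TISSUE_DENSITY,
    activity_factor,
)
from .censored import CensoredMeasurement
from .errors import ClippingWarning, TmfkitError
from .partitioning import TissueComposition
from .tmf import BiotaSample, compute_tmf

# Body temperatures by thermal guild: poikilotherm prey vs endotherm predators.
INVERTEBRATE_BODY_T = 291.0
AVIAN_BODY_T = 313.0

# Default per-trophic-level composition slopes (fraction per TP unit); the
# albumin and neutral-lipid fractions climb roughly 1 % per trophic level,
# polar lipid roughly 0.4 %.
DEFAULT_COMPOSITION_MODEL = {
    "phi_ALB": (0.002, 0.0096),
    "phi_SP": (0.008, 0.0050),
    "phi_NL": (0.002, 0.0093),
    "phi_PL": (0.0005, 0.0041),
    "phi_W": (0.75, 0.0),
}


@dataclass(frozen=True)
class AnalyteTruth:
    """Generating truth for one analyte."""

    true_tmf: float
    baseline_activity: float  # activity at TP == 0 (regression intercept scale)
    ln_sd: float = 0.4  # residual sd of ln(activity)
    mloq_ng_g_ww: float | None = None  # explicit limit; None -> use censoring_fraction
    censoring_fraction: float = 0.3  # target nondetect share when mloq is None

    def __post_init__(self):
        if self.true_tmf <= 0 or self.baseline_activity <= 0:
            raise ValueError("true_tmf and baseline_activity must be > 0")
        if self.ln_sd < 0:
            raise ValueError("ln_sd must be >= 0")


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic food web."""

    n_samples: int = 74
    tp_range: tuple = (1.0, 4.0)
    tp_jitter: float = 0.15
    composition_model: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION_MODEL))
    analytes: dict = field(default_factory=dict)  # name -> AnalyteTruth
    chem_table: dict | None = None  # name -> ChemicalRecord; None -> starter table
    predator_tp_cutoff: float = 2.5  # TP above which samples are avian
    entropy_ratio: float = DEFAULT_ENTROPY_RATIO
    density: float = DEFAULT_TISSUE_DENSITY
    molar: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if not self.analytes:
            self.analytes = {"PFOS": AnalyteTruth(true_tmf=2.0, baseline_activity=1e-10)}


def _resolve_chem_table(config: SyntheticConfig) -> dict:
    if config.chem_table is not None:
        return config.chem_table
    from .io import load_starter_chemicals

    return load_starter_chemicals()


def _build_composition(tp: float, model: dict) -> TissueComposition:
    phis = {}
    clipped = []
    for name, (intercept, slope) in model.items():
        v = intercept + slope * tp
        if v < 0.0 or v > 1.0:
            clipped.append(f"{name}={v:.4f}")
            v = min(max(v, 0.0), 1.0)
        phis[name] = v
    total = sum(phis.values())
    if total > 1.0:
        clipped.append(f"sum={total:.4f}")
        phis = {k: v / total for k, v in phis.items()}
    if clipped:
        warnings.warn(
            f"composition clipped at TP={tp:.2f}: {', '.join(clipped)}",
            ClippingWarning,
            stacklevel=2,
        )
    return TissueComposition(**phis)


def generate_foodweb(config: SyntheticConfig):
    """Generate one synthetic dataset.

    Returns ``(samples, truth)`` where ``truth`` records the generating
    parameters (per-analyte true TMF, realized quantification limits and
    censoring fractions, seed).  Identical config + seed gives an identical
    dataset.

    Raises
    ------
    TmfkitError
        If the composition model leaves no valid sample.
    """
    rng = np.random.default_rng(config.seed)
    chem_table = _resolve_chem_table(config)
    for name in config.analytes:
        if name not in chem_table:
            raise TmfkitError(f"analyte {name!r} not in chemical table")

    lo, hi = config.tp_range
    tp = np.linspace(lo, hi, config.n_samples) + rng.normal(0, config.tp_jitter, config.n_samples)
    tp = np.clip(tp, 1.0, None)

    samples = []
    for i, t in enumerate(tp):
        comp = _build_composition(float(t), config.composition_model)
        if comp.phi_W + comp.phi_P + comp.phi_L <= 0:
            raise TmfkitError("composition model produced an all-zero sample")
        avian = t >= config.predator_tp_cutoff
        samples.append(
            BiotaSample(
                sample_id=f"S{i:03d}",
                species="avian" if avian else "invertebrate",
                composition=comp,
                body_temperature=AVIAN_BODY_T if avian else INVERTEBRATE_BODY_T,
                trophic_position=float(t),
            )
        )

    truth = {
        "seed": config.seed,
        "n_samples": config.n_samples,
        "analytes": {},
    }
    for name, spec in config.analytes.items():
        chem = chem_table[name]
        ln_a = (
            math.log(spec.baseline_activity)
            + math.log(spec.true_tmf) * tp
            + rng.normal(0, spec.ln_sd, config.n_samples)
        )
        # Invert the activity equation per sample: c_ww = a / factor.
        factors = np.array(
            [
                activity_factor(
                    s.composition,
                    chem,
                    s.body_temperature,
                    entropy_ratio=config.entropy_ratio,
                    density=config.density,
                    molar=config.molar,
                )
                for s in samples
            ]
        )
        c_ww = np.exp(ln_a) / factors

        if spec.mloq_ng_g_ww is not None:
            mloq = float(spec.mloq_ng_g_ww)
        else:
            mloq = float(np.quantile(c_ww, spec.censoring_fraction))
        censored = c_ww < mloq
        for s, c, is_cen in zip(samples, c_ww, censored):
            if is_cen:
                s.measurements[name] = CensoredMeasurement(value=mloq, censored=True, limit=mloq)
            else:
                s.measurements[name] = CensoredMeasurement(value=float(c), censored=False, limit=mloq)
        truth["analytes"][name] = {
            "true_tmf": spec.true_tmf,
            "baseline_activity": spec.baseline_activity,
            "ln_sd": spec.ln_sd,
            "mloq_ng_g_ww": mloq,
            "realized_censoring": float(censored.mean()),
        }
    return samples, truth


def recovery_experiment(config: SyntheticConfig, n_reps: int, schemes=("activity",)):
    """Repeated generate -> estimate cycles; aggregates bias and CI coverage.

    For each analyte and scheme over ``n_reps`` replicates (child seeds
    spawned deterministically from ``config.seed``):

    * ``median_rel_bias_ln`` — median over replicates of the relative error
      of the estimated ln TMF; when the true ln TMF is 0 (TMF == 1) the
      absolute error of ln TMF is used instead (same ~fractional scale).
    * ``coverage95`` — share of replicates whose Wald 95 % CI covers the
      true TMF.

    Returns a list of dict rows.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    chem_table = _resolve_chem_table(config)
    estimates: dict = {
        (a, s): {"ln_tmf": [], "covered": []} for a in config.analytes for s in schemes
    }
    for rep in range(n_reps):
        rep_config = replace(config, seed=int(np.random.default_rng([config.seed, rep]).integers(2**31)))
        samples, truth = generate_foodweb(rep_config)
        for analyte, spec in config.analytes.items():
            for scheme in schemes:
                res = compute_tmf(
                    samples,
                    analyte,
                    scheme,
                    chem_table,
                    entropy_ratio=config.entropy_ratio,
                    density=config.density,
                    molar=config.molar,
                    apply_detection_filter=False,
                )
                box = estimates[(analyte, scheme)]
                box["ln_tmf"].append(math.log(res.tmf))
                box["covered"].append(res.ci95[0] <= spec.true_tmf <= res.ci95[1])

    rows = []
    for (analyte, scheme), box in estimates.items():
        true_ln = math.log(config.analytes[analyte].true_tmf)
        ln_est = np.array(box["ln_tmf"])
        if true_ln != 0.0:
            rel = (ln_est - true_ln) / true_ln
        else:
            rel = ln_est - true_ln
        rows.append({
            "analyte": analyte,
            "scheme": scheme,
            "true_tmf": config.analytes[analyte].true_tmf,
            "mean_estimate": float(np.exp(ln_est).mean()),
            "median_rel_bias_ln": float(np.median(rel)),
            "coverage95": float(np.mean(box["covered"])),
            "n_reps": n_reps,
        })
    return rows
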