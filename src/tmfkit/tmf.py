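"""The trophic-magnification pipeline: trophic positions from delta-15N,
the detection-frequency gate, per-analyte TMFs under each normalization
scheme, and cross-scheme CI-overlap comparison.

A TMF is ``e**m`` where ``m`` is the slope of a censored linear regression
of ln(transformed concentration) on trophic position.  The transform — to
apparent chemical activity or to a tissue-normalized concentration — is a
per-sample positive constant, so it shifts only the intercept when
composition is spatially constant; all schemes then agree exactly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .activity import (
    ALL_SCHEMES,
    DEFAULT_ENTROPY_RATIO,
    DEFAULT_TISSUE_DENSITY,
    activity_factor,
    normalization_factor,
)
from .censored import CensoredMeasurement, censored_linregress
from .errors import (
    DetectionFrequencyError,
    DomainError,
    ExclusionWarning,
    InsufficientDataError,
    NonNormalizableSampleError,
    UnknownAnalyteError,
)
from .partitioning import TissueComposition

logger = logging.getLogger(__name__)

#: Default isotopic enrichment per trophic level, permil.
DEFAULT_ENRICHMENT = 2.88

#: Default detection-frequency gate (strict "more than").
DEFAULT_DETECTION_THRESHOLD = 0.60


@dataclass
class BiotaSample:
    """One sampled organism or pooled sample.

    One of ``trophic_position`` or ``delta15N`` must be present; an explicit
    trophic position takes precedence over the isotope-derived one.
    """

    sample_id: str
    species: str
    composition: TissueComposition
    body_temperature: float
    trophic_position: float | None = None
    delta15N: float | None = None
    group: str = ""
    measurements: dict = field(default_factory=dict)  # analyte -> CensoredMeasurement

    def __post_init__(self):
        if self.trophic_position is None and self.delta15N is None:
            raise ValueError(f"{self.sample_id}: need trophic_position or delta15N")
        if self.trophic_position is not None and self.trophic_position < 1:
            raise ValueError(f"{self.sample_id}: trophic_position must be >= 1")
        if not (270.0 <= self.body_temperature <= 320.0):
            raise ValueError(
                f"{self.sample_id}: body_temperature {self.body_temperature} K "
                "outside plausible range [270, 320]"
            )


@dataclass(frozen=True)
class TMFResult:
    """TMF of one analyte under one scheme, with its regression diagnostics."""

    analyte: str
    scheme: str
    slope: float
    slope_se: float
    tmf: float
    ci95: tuple
    p_value: float
    n_total: int
    n_censored: int
    n_excluded: int
    detection_frequency: float


@dataclass(frozen=True)
class ComparisonTable:
    """Pairwise CI-overlap flags and point-estimate ratios for TMF results."""

    labels: tuple
    overlap: np.ndarray  # bool, square
    ratio: np.ndarray  # tmf_i / tmf_j


def trophic_position(
    delta15N: float,
    baseline_delta15N: float,
    baseline_tp: float = 1.0,
    enrichment: float = DEFAULT_ENRICHMENT,
) -> float:
    """Trophic position from a delta-15N measurement.

    ``TP = baseline_tp + (delta15N - baseline_delta15N) / enrichment``.
    """
    if enrichment <= 0:
        raise DomainError("enrichment must be > 0 permil per trophic level")
    return baseline_tp + (delta15N - baseline_delta15N) / enrichment


def resolve_trophic_position(
    sample: BiotaSample,
    baseline_delta15N: float = 0.0,
    baseline_tp: float = 1.0,
    enrichment: float = DEFAULT_ENRICHMENT,
) -> float:
    """Explicit TP if present, else the delta-15N transform."""
    if sample.trophic_position is not None:
        return sample.trophic_position
    return trophic_position(sample.delta15N, baseline_delta15N, baseline_tp, enrichment)


def detection_frequency(samples, analyte: str) -> float:
    """Fraction of samples carrying ``analyte`` in which it was quantified."""
    carrying = [s for s in samples if analyte in s.measurements]
    if not carrying:
        raise UnknownAnalyteError(f"analyte {analyte!r} absent from every sample")
    detected = sum(1 for s in carrying if not s.measurements[analyte].censored)
    return detected / len(carrying)


def detection_filter(samples, analyte: str, threshold: float = DEFAULT_DETECTION_THRESHOLD):
    """(include, frequency): include iff frequency strictly exceeds threshold."""
    freq = detection_frequency(samples, analyte)
    return freq > threshold, freq


def compute_tmf(
    samples,
    analyte: str,
    scheme: str,
    chem_table: dict,
    *,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    baseline_delta15N: float = 0.0,
    baseline_tp: float = 1.0,
    enrichment: float = DEFAULT_ENRICHMENT,
    entropy_ratio: float = DEFAULT_ENTROPY_RATIO,
    density: float = DEFAULT_TISSUE_DENSITY,
    molar: bool = True,
    fits=(),
    apply_detection_filter: bool = True,
) -> TMFResult:
    """Estimate the TMF of ``analyte`` under one normalization ``scheme``.

    Each sample's measurement *and its quantification limit* are multiplied
    by the same per-sample transform (activity conversion or 1/phi), then
    ln-transformed and regressed on trophic position with the left-censored
    Gaussian likelihood.  ``TMF = e**slope`` with a Wald 95 % CI.

    Samples whose scheme fraction is zero are dropped for that scheme with a
    warning and counted in ``n_excluded``.

    Raises
    ------
    UnknownAnalyteError, DetectionFrequencyError, InsufficientDataError
        and regression errors from :func:`censored_linregress`.
    """
    if scheme not in ALL_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {ALL_SCHEMES}")
    include, freq = detection_filter(samples, analyte, threshold)
    if apply_detection_filter and not include:
        raise DetectionFrequencyError(
            f"{analyte}: detection frequency {freq:.0%} does not exceed "
            f"threshold {threshold:.0%}"
        )

    if scheme == "activity":
        if analyte not in chem_table:
            raise UnknownAnalyteError(f"analyte {analyte!r} missing from chemical table")
        chem = chem_table[analyte]

    y, x = [], []
    n_excluded = 0
    mixed_tp_sources = set()
    for s in samples:
        if analyte not in s.measurements:
            continue
        m = s.measurements[analyte]
        try:
            if scheme == "activity":
                factor = activity_factor(
                    s.composition,
                    chem,
                    s.body_temperature,
                    entropy_ratio=entropy_ratio,
                    density=density,
                    molar=molar,
                    fits=fits,
                )
            else:
                factor = normalization_factor(s.composition, scheme)
        except NonNormalizableSampleError as exc:
            warnings.warn(
                f"{s.sample_id}/{analyte}: excluded from scheme {scheme!r} ({exc})",
                ExclusionWarning,
                stacklevel=2,
            )
            logger.warning("excluded %s/%s from scheme %s: %s", s.sample_id, analyte, scheme, exc)
            n_excluded += 1
            continue
        ln_value = math.log(m.value * factor)
        if m.censored:
            y.append(CensoredMeasurement(value=ln_value, censored=True, limit=ln_value))
        else:
            y.append(CensoredMeasurement(value=ln_value, censored=False))
        x.append(
            resolve_trophic_position(s, baseline_delta15N, baseline_tp, enrichment)
        )
        mixed_tp_sources.add("explicit" if s.trophic_position is not None else "delta15N")

    if len(mixed_tp_sources) > 1:
        logger.info("%s/%s: mixing explicit and delta15N-derived trophic positions", analyte, scheme)
    if len(y) < 3:
        raise InsufficientDataError(
            f"{analyte}/{scheme}: only {len(y)} usable samples after exclusions"
        )

    fit = censored_linregress(y, x)
    m_hat, se = fit.slope, fit.slope_se
    return TMFResult(
        analyte=analyte,
        scheme=scheme,
        slope=m_hat,
        slope_se=se,
        tmf=math.exp(m_hat),
        ci95=(math.exp(m_hat - 1.96 * se), math.exp(m_hat + 1.96 * se)),
        p_value=fit.p_value,
        n_total=fit.n_total,
        n_censored=fit.n_censored,
        n_excluded=n_excluded,
        detection_frequency=freq,
    )


def compare_tmfs(results) -> ComparisonTable:
    """Pairwise 95 %-CI overlap and TMF ratios for a list of results.

    Two results "do not differ" in the CI-overlap sense when their intervals
    intersect.
    """
    rs = list(results)
    if len(rs) < 2:
        raise InsufficientDataError("need >= 2 results to compare")
    k = len(rs)
    overlap = np.ones((k, k), dtype=bool)
    ratio = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            lo_i, hi_i = rs[i].ci95
            lo_j, hi_j = rs[j].ci95
            overlap[i, j] = not (lo_i > hi_j or hi_i < lo_j)
            ratio[i, j] = rs[i].tmf / rs[j].tmf
    labels = tuple(f"{r.analyte}:{r.scheme}" for r in rs)
    return ComparisonTable(labels=labels, overlap=overlap, ratio=ratio)
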