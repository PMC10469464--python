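import math

import numpy as np
import pytest

from tmfkit.activity import ALL_SCHEMES
from tmfkit.censored import CensoredMeasurement
from tmfkit.errors import (
    DetectionFrequencyError,
    DomainError,
    ExclusionWarning,
    InsufficientDataError,
    UnknownAnalyteError,
)
from tmfkit.partitioning import TissueComposition
from tmfkit.synthetic import AnalyteTruth, SyntheticConfig, generate_foodweb
from tmfkit.tmf import (
    BiotaSample,
    TMFResult,
    compare_tmfs,
    compute_tmf,
    detection_filter,
    trophic_position,
)

COMP = TissueComposition(phi_NL=0.02, phi_PL=0.01, phi_ALB=0.02, phi_SP=0.01, phi_W=0.9)


def make_samples(n, analyte="A", values=None, censored=None, comps=None, tps=None):
    tps = tps if tps is not None else np.linspace(1, 4, n)
    values = values if values is not None else np.ones(n)
    censored = censored if censored is not None else [False] * n
    comps = comps or [COMP] * n
    out = []
    for i in range(n):
        if censored[i]:
            m = CensoredMeasurement(value=values[i], censored=True, limit=values[i])
        else:
            m = CensoredMeasurement(value=values[i])
        out.append(
            BiotaSample(
                sample_id=f"s{i}", species="sp", composition=comps[i],
                body_temperature=291.0, trophic_position=float(tps[i]),
                measurements={analyte: m},
            )
        )
    return out


class TestTrophicPosition:
    def test_at_baseline(self):
        assert trophic_position(10.0, 10.0, baseline_tp=2.0) == 2.0

    def test_one_enrichment_step(self):
        assert trophic_position(12.88, 10.0, baseline_tp=1.0, enrichment=2.88) == pytest.approx(2.0)

    def test_two_steps(self):
        assert trophic_position(15.76, 10.0, baseline_tp=1.0, enrichment=2.88) == pytest.approx(3.0)

    def test_bad_enrichment(self):
        with pytest.raises(DomainError):
            trophic_position(10.0, 5.0, enrichment=0.0)

    def test_delta15N_fallback(self):
        s = BiotaSample(
            sample_id="s", species="sp", composition=COMP,
            body_temperature=291.0, delta15N=12.88,
        )
        from tmfkit.tmf import resolve_trophic_position

        assert resolve_trophic_position(s, baseline_delta15N=10.0) == pytest.approx(2.0)

    def test_explicit_tp_wins(self):
        s = BiotaSample(
            sample_id="s", species="sp", composition=COMP,
            body_temperature=291.0, trophic_position=3.0, delta15N=10.0,
        )
        from tmfkit.tmf import resolve_trophic_position

        assert resolve_trophic_position(s, baseline_delta15N=10.0) == 3.0


class TestDetectionFilter:
    def test_61_of_100_included(self):
        samples = make_samples(100, censored=[False] * 61 + [True] * 39,
                               values=np.ones(100))
        include, freq = detection_filter(samples, "A")
        assert include and freq == pytest.approx(0.61)

    def test_60_of_100_excluded(self):
        samples = make_samples(100, censored=[False] * 60 + [True] * 40,
                               values=np.ones(100))
        include, freq = detection_filter(samples, "A")
        assert not include and freq == pytest.approx(0.60)

    def test_all_detected(self):
        include, freq = detection_filter(make_samples(10), "A")
        assert include and freq == 1.0

    def test_unknown_analyte(self):
        with pytest.raises(UnknownAnalyteError):
            detection_filter(make_samples(5), "ZZZ")


class TestComputeTMF:
    def test_noiseless_tmf_2(self, starter_chemicals):
        """ln(value) = ln(2) * TP + c exactly -> TMF 2 within 1e-6."""
        n = 20
        tps = np.linspace(1, 4, n)
        values = np.exp(math.log(2.0) * tps - 3.0)
        samples = make_samples(n, values=values, tps=tps)
        res = compute_tmf(samples, "A", "wet", starter_chemicals)
        assert res.tmf == pytest.approx(2.0, abs=1e-6)
        assert res.n_censored == 0

    def test_null_slope(self, starter_chemicals):
        rng = np.random.default_rng(11)
        n = 80
        values = np.exp(rng.normal(0, 0.3, n))
        samples = make_samples(n, values=values)
        res = compute_tmf(samples, "A", "wet", starter_chemicals)
        assert res.tmf == pytest.approx(1.0, abs=0.15)
        assert res.p_value > 0.05

    def test_scheme_equivalence_constant_composition(self, starter_chemicals):
        config = SyntheticConfig(
            n_samples=40, seed=3,
            composition_model={
                "phi_ALB": (0.02, 0.0), "phi_SP": (0.01, 0.0),
                "phi_NL": (0.02, 0.0), "phi_PL": (0.01, 0.0), "phi_W": (0.9, 0.0),
            },
            analytes={"PFOS": AnalyteTruth(true_tmf=2.0, baseline_activity=1e-10, ln_sd=0.3)},
            predator_tp_cutoff=99.0,  # single body temperature too
        )
        samples, _ = generate_foodweb(config)
        tmfs = [
            compute_tmf(samples, "PFOS", scheme, starter_chemicals).tmf
            for scheme in ALL_SCHEMES
        ]
        for t in tmfs[1:]:
            assert t == pytest.approx(tmfs[0], abs=1e-9)

    def test_detection_gate_enforced(self, starter_chemicals):
        samples = make_samples(10, values=np.ones(10),
                               censored=[True] * 5 + [False] * 5)
        with pytest.raises(DetectionFrequencyError):
            compute_tmf(samples, "A", "wet", starter_chemicals)

    def test_gate_bypass(self, starter_chemicals):
        rng = np.random.default_rng(2)
        samples = make_samples(10, values=np.exp(rng.normal(0, 0.1, 10)),
                               censored=[True] * 5 + [False] * 5)
        res = compute_tmf(samples, "A", "wet", starter_chemicals,
                          apply_detection_filter=False)
        assert isinstance(res, TMFResult)
        assert res.detection_frequency == 0.5

    def test_non_normalizable_samples_dropped(self, starter_chemicals):
        no_pl = TissueComposition(phi_NL=0.02, phi_PL=0.0, phi_ALB=0.02, phi_SP=0.01, phi_W=0.9)
        rng = np.random.default_rng(5)
        n = 12
        comps = [no_pl if i < 3 else COMP for i in range(n)]
        samples = make_samples(n, values=np.exp(rng.normal(0, 0.1, n)), comps=comps)
        with pytest.warns(ExclusionWarning):
            res = compute_tmf(samples, "A", "polar_lipid", starter_chemicals)
        assert res.n_excluded == 3
        assert res.n_total == n - 3

    def test_insufficient_data(self, starter_chemicals):
        samples = make_samples(2)
        with pytest.raises(InsufficientDataError):
            compute_tmf(samples, "A", "wet", starter_chemicals,
                        apply_detection_filter=False)

    def test_ci_straddles_tmf(self, starter_chemicals):
        rng = np.random.default_rng(9)
        samples = make_samples(30, values=np.exp(rng.normal(0, 0.4, 30) + 0.5 * np.linspace(1, 4, 30)))
        res = compute_tmf(samples, "A", "wet", starter_chemicals)
        assert res.ci95[0] < res.tmf < res.ci95[1]


class TestCompareTMFs:
    @staticmethod
    def result(tmf, lo, hi, scheme="wet"):
        return TMFResult(
            analyte="A", scheme=scheme, slope=math.log(tmf), slope_se=0.1,
            tmf=tmf, ci95=(lo, hi), p_value=0.5, n_total=10, n_censored=0,
            n_excluded=0, detection_frequency=1.0,
        )

    def test_identical_results(self):
        r = self.result(2.0, 1.5, 2.7)
        table = compare_tmfs([r, r])
        assert table.overlap.all()
        assert np.allclose(table.ratio, 1.0)

    def test_disjoint_cis(self):
        table = compare_tmfs([self.result(1.5, 1.1, 2.0), self.result(2.5, 2.1, 3.0)])
        assert not table.overlap[0, 1] and not table.overlap[1, 0]

    def test_touching_cis_overlap(self):
        table = compare_tmfs([self.result(1.6, 1.1, 2.2), self.result(2.5, 2.1, 3.0)])
        assert table.overlap[0, 1] and table.overlap[1, 0]

    def test_needs_two(self):
        with pytest.raises(InsufficientDataError):
            compare_tmfs([self.result(2.0, 1.5, 2.7)])


class TestSampleValidation:
    def test_needs_tp_or_d15n(self):
        with pytest.raises(ValueError, match="trophic_position or delta15N"):
            BiotaSample(sample_id="s", species="sp", composition=COMP, body_temperature=291.0)

    def test_tp_lower_bound(self):
        with pytest.raises(ValueError, match=">= 1"):
            BiotaSample(sample_id="s", species="sp", composition=COMP,
                        body_temperature=291.0, trophic_position=0.5)

    def test_body_temperature_range(self):
        with pytest.raises(ValueError, match="body_temperature"):
            BiotaSample(sample_id="s", species="sp", composition=COMP,
                        body_temperature=250.0, trophic_position=2.0)
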