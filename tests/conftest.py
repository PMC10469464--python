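import numpy as np
import pytest

from tmfkit.censored import censored_neg_loglik
from tmfkit.chem import ChemicalRecord, LogD
from tmfkit.io import load_starter_chemicals
from tmfkit.partitioning import TissueComposition


@pytest.fixture(scope="session")
def starter_chemicals():
    return load_starter_chemicals()


@pytest.fixture
def avian_composition():
    # Bird-like whole-body sample: ~60% of total protein as albumin.
    return TissueComposition(phi_NL=0.03, phi_PL=0.005, phi_ALB=0.03, phi_SP=0.016, phi_W=0.85)


@pytest.fixture
def simple_chem():
    """A fully-measured synthetic chemical (values chosen for easy arithmetic)."""
    return ChemicalRecord(
        name="X1",
        analyte_class="PFCA",
        chain_length=8,
        molar_mass=400.0,
        molar_volume=260.0,
        melting_point=350.0,
        water_solubility=10.0,
        logD={
            "NLW": LogD(-1.0),
            "PLW": LogD(3.0),
            "ALBW": LogD(4.0),
            "SPW": LogD(2.0),
        },
    )


def grid_search_slope(x, y, cens, center, half_width=1.0, n_rounds=5, n_grid=41):
    """Independent maximizer of the censored Gaussian likelihood.

    Dense 3-D grid over (intercept, slope, ln sigma), iteratively zoomed
    around the best cell.  Deliberately brute-force: shares only the
    likelihood *definition* with the estimator under test, not its optimizer.
    """
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cens = np.asarray(cens, bool)
    b0_c, b1_c, ls_c = center
    w0, w1, wl = half_width, half_width, 1.5
    best = None
    for _ in range(n_rounds):
        b0s = np.linspace(b0_c - w0, b0_c + w0, n_grid)
        b1s = np.linspace(b1_c - w1, b1_c + w1, n_grid)
        lss = np.linspace(ls_c - wl, ls_c + wl, n_grid)
        # evaluate the censored-Gaussian NLL on the whole grid at once
        mu = b0s[:, None, None, None] + b1s[None, :, None, None] * x[None, None, None, :]
        s = np.exp(lss)[None, None, :, None]
        z = (y[None, None, None, :] - mu) / s  # (g, g, g, n) via broadcasting
        terms = np.where(
            cens[None, None, None, :],
            stats.norm.logcdf(z),
            stats.norm.logpdf(z) - np.log(s),
        )
        vals = -terms.sum(axis=3)
        i, j, k = np.unravel_index(np.argmin(vals), vals.shape)
        best = (b0s[i], b1s[j], lss[k], vals[i, j, k])
        b0_c, b1_c, ls_c = b0s[i], b1s[j], lss[k]
        w0 *= 2.2 / (n_grid - 1)  # keep a cushion around the best cell
        w1 *= 2.2 / (n_grid - 1)
        wl *= 2.2 / (n_grid - 1)
    return {"intercept": best[0], "slope": best[1], "ln_sigma": best[2], "nll": best[3]}
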