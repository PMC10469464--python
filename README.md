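# tmfkit

Chemical-activity-based trophic magnification analysis for perfluoroalkyl
substances (PFAS) in food webs.

Measured wet-weight concentrations are poor proxies of a chemical's
thermodynamic escaping tendency when species differ in tissue composition.
`tmfkit` converts concentrations to **apparent chemical activities** — using
the sorptive capacity of each sample's tissue mixture (neutral lipid, polar
lipid, albumin, structural protein, water) and a fugacity-ratio correction
for solids — or to tissue-normalized equivalents (total protein, albumin,
polar lipid, total lipid), and estimates **trophic magnification factors
(TMFs)** by regressing ln(transformed concentration) on trophic position
with a left-censored Gaussian (Tobit-type) likelihood, so nondetects below
the quantification limit are handled correctly.

## Features

- **`tmfkit.chem`** — chemical property records; QSPR prediction of missing
  phase–water log distribution coefficients from molar volume (separate
  linear fits per analyte class), with provenance tracking and
  extrapolation warnings.
- **`tmfkit.partitioning`** — sorptive capacity of a tissue mixture;
  distribution of chemical mass among the five phases; logD sensitivity
  sweeps for TMFs.
- **`tmfkit.activity`** — fugacity ratio, apparent chemical activity, the
  five concentration-normalization schemes, pairwise biomagnification
  factors (BMFs).
- **`tmfkit.censored`** — Helsel/Hirsch–Stedinger regression-on-order-
  statistics (ROS) summary means and maximum-likelihood left-censored
  linear regression with Wald and likelihood-ratio tests.
- **`tmfkit.tmf`** — trophic positions from δ¹⁵N (default enrichment
  2.88‰/level), the >60 % detection-frequency gate, TMFs per analyte ×
  scheme, CI-overlap comparison across schemes.
- **`tmfkit.synthetic`** — food-web simulator (composition trends with
  trophic position, log-normal activity noise, censoring) plus parameter-
  recovery experiments.
- **`tmfkit.io` / `tmfkit.cli`** — CSV readers/writers with row-level
  validation, and a `tmfkit` command line.

## Quick start

```bash
# simulate a 74-sample food web with a true activity-TMF of 2
tmfkit simulate --out sim/ --seed 1 --analyte PFOS --true-tmf 2.0

# estimate TMFs under all six schemes
tmfkit tmf --samples sim/samples.csv --measurements sim/measurements.csv \
           --chemicals sim/chemicals.csv --out results/

# chemical mass distribution among tissue phases
tmfkit massdist --samples sim/samples.csv --measurements sim/measurements.csv \
                --chemicals sim/chemicals.csv --out massdist.csv

# QSPR fill-in of missing log D values
tmfkit qspr --chemicals sim/chemicals.csv --out logd.csv
```

Python API:

```python
from tmfkit import SyntheticConfig, generate_foodweb, compute_tmf
from tmfkit.io import load_starter_chemicals

chems = load_starter_chemicals()
samples, truth = generate_foodweb(SyntheticConfig(seed=1))
result = compute_tmf(samples, "PFOS", "activity", chems)
print(result.tmf, result.ci95, result.p_value)
```

## Input schemas

Comma-delimited UTF-8 with a header row; units are fixed:

- `samples.csv`: `sample_id, species, group, delta15N, trophic_position,
  body_temperature_K, phi_NL, phi_PL, phi_ALB, phi_SP, phi_W`
  (mass fractions g/g wet weight; one of `trophic_position` / `delta15N`
  required).
- `measurements.csv`: `sample_id, analyte, conc_ng_g_ww, censored (0/1),
  mloq_ng_g_ww`.
- `chemicals.csv`: `name, class (PFCA|PFSA), chain_length, molar_mass,
  molar_volume_cm3_mol, melting_point_K, water_solubility_mol_m3,
  logD_NLW, logD_PLW, logD_ALBW, logD_SPW` plus `*_source` columns; empty
  logD cells are predicted by QSPR.

A starter chemical table ships with the package
(`tmfkit/data/chemicals_starter.csv`). Its property values are editable
placeholders of realistic magnitude — replace them with measured values
from your preferred sources before drawing chemical-specific conclusions.

## Tests and acceptance

```bash
python -m pytest -q                       # unit + property + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-runs the pipeline's property-based checks
(scheme-equivalence identity, censored-regression grid oracle, parameter
recovery, mass conservation, fugacity-ratio bounds, ROS degeneracy, Wald
calibration, end-to-end determinism) and writes a JSON report. There are no
numeric acceptance targets: the map written to `--out` is empty by design,
with per-check outcomes in a `.checks.json` sidecar.
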