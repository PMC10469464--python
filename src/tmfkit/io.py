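"""Readers and writers for the three canonical input tables and results.

All interchange is comma-delimited UTF-8 text with a header row.  Schemas
(units are fixed, never inferred):

* ``samples.csv`` — sample_id, species, group, delta15N, trophic_position,
  body_temperature_K, phi_NL, phi_PL, phi_ALB, phi_SP, phi_W
* ``measurements.csv`` — sample_id, analyte, conc_ng_g_ww, censored (0/1),
  mloq_ng_g_ww
* ``chemicals.csv`` — name, class, chain_length, molar_mass,
  molar_volume_cm3_mol, melting_point_K, water_solubility_mol_m3,
  logD_NLW, logD_PLW, logD_ALBW, logD_SPW plus matching ``*_source``
  columns; empty logD cells mean "predict me".
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import pandas as pd

from .censored import CensoredMeasurement
from .chem import PHASES, ChemicalRecord, LogD
from .errors import ValidationError
from .partitioning import TissueComposition
from .tmf import BiotaSample

@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one TMF run.

    Defaults follow the standard analysis choices: detection threshold 0.60
    (strict "more than"), isotopic enrichment 2.88 permil per trophic level,
    entropy-of-fusion ratio 6.79, tissue density 1.0 g/cm^3.
    """

    samples: str = ""
    measurements: str = ""
    chemicals: str = ""
    out: str = "results"
    schemes: tuple = ("activity", "wet", "total_protein", "albumin", "polar_lipid", "total_lipid")
    threshold: float = 0.60
    enrichment: float = 2.88
    baseline_d15n: float = 0.0
    baseline_tp: float = 1.0
    entropy_ratio: float = 6.79
    density: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold {self.threshold} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load from a YAML mapping; keyword overrides (CLI flags) win."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError([f"{path}: unknown config key(s) {', '.join(sorted(unknown))}"])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "schemes" in raw and raw["schemes"] is not None:
            raw["schemes"] = tuple(raw["schemes"])
        return cls(**raw)


SAMPLE_COLUMNS = [
    "sample_id", "species", "group", "delta15N", "trophic_position",
    "body_temperature_K", "phi_NL", "phi_PL", "phi_ALB", "phi_SP", "phi_W",
]
MEASUREMENT_COLUMNS = ["sample_id", "analyte", "conc_ng_g_ww", "censored", "mloq_ng_g_ww"]
CHEMICAL_COLUMNS = [
    "name", "class", "chain_length", "molar_mass", "molar_volume_cm3_mol",
    "melting_point_K", "water_solubility_mol_m3",
] + [f"logD_{p}" for p in PHASES] + [f"logD_{p}_source" for p in PHASES]


def _require_columns(df: pd.DataFrame, required, path, errors):
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"{path}: missing column(s) {', '.join(missing)}")
    return not missing


def _isna(v) -> bool:
    return pd.isna(v)


def read_chemicals(path) -> dict:
    """Read a chemical property table into ``{name: ChemicalRecord}``."""
    path = Path(path)
    df = pd.read_csv(path)
    errors: list[str] = []
    if not _require_columns(df, CHEMICAL_COLUMNS[:7], path, errors):
        raise ValidationError(errors)
    table: dict[str, ChemicalRecord] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        logd = {}
        for p in PHASES:
            col = f"logD_{p}"
            if col in df.columns and not _isna(row.get(col)):
                src = row.get(f"{col}_source")
                logd[p] = LogD(
                    value=float(row[col]),
                    provenance="measured",
                    source="" if _isna(src) else str(src),
                )
        try:
            rec = ChemicalRecord(
                name=str(row["name"]),
                analyte_class=str(row["class"]),
                chain_length=int(row["chain_length"]),
                molar_mass=float(row["molar_mass"]),
                molar_volume=float(row["molar_volume_cm3_mol"]),
                melting_point=float(row["melting_point_K"]),
                water_solubility=float(row["water_solubility_mol_m3"]),
                logD=logd,
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"{path}:{line}: {exc}")
            continue
        table[rec.name] = rec
    if errors:
        raise ValidationError(errors)
    if not table:
        raise ValidationError([f"{path}: no chemicals parsed"])
    return table


def load_starter_chemicals() -> dict:
    """The bundled, editable starter property table."""
    ref = importlib.resources.files("tmfkit") / "data" / "chemicals_starter.csv"
    with importlib.resources.as_file(ref) as p:
        return read_chemicals(p)


def read_dataset(samples_path, measurements_path, chemicals_path):
    """Read and cross-validate the three input tables.

    Returns ``(samples, chem_table)`` where ``samples`` is a list of
    :class:`~tmfkit.tmf.BiotaSample` carrying their censored measurements.

    Raises
    ------
    ValidationError
        With one message per offending row (line numbers included).
    """
    chem_table = read_chemicals(chemicals_path)
    errors: list[str] = []

    sdf = pd.read_csv(samples_path)
    if not _require_columns(sdf, SAMPLE_COLUMNS, samples_path, errors):
        raise ValidationError(errors)
    samples: dict[str, BiotaSample] = {}
    for idx, row in sdf.iterrows():
        line = idx + 2
        try:
            comp = TissueComposition(
                phi_NL=float(row["phi_NL"]),
                phi_PL=float(row["phi_PL"]),
                phi_ALB=float(row["phi_ALB"]),
                phi_SP=float(row["phi_SP"]),
                phi_W=float(row["phi_W"]),
            )
            tp = None if _isna(row["trophic_position"]) else float(row["trophic_position"])
            d15n = None if _isna(row["delta15N"]) else float(row["delta15N"])
            sample = BiotaSample(
                sample_id=str(row["sample_id"]),
                species=str(row["species"]),
                group="" if _isna(row["group"]) else str(row["group"]),
                composition=comp,
                body_temperature=float(row["body_temperature_K"]),
                trophic_position=tp,
                delta15N=d15n,
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"{samples_path}:{line}: {exc}")
            continue
        if sample.sample_id in samples:
            errors.append(f"{samples_path}:{line}: duplicate sample_id {sample.sample_id!r}")
            continue
        samples[sample.sample_id] = sample

    mdf = pd.read_csv(measurements_path)
    if not _require_columns(mdf, MEASUREMENT_COLUMNS, measurements_path, errors):
        raise ValidationError(errors)
    if len(mdf) == 0:
        errors.append(f"{measurements_path}: no measurements (empty table)")
    n_attached = 0
    for idx, row in mdf.iterrows():
        line = idx + 2
        sid = str(row["sample_id"])
        if sid not in samples:
            errors.append(f"{measurements_path}:{line}: unknown sample_id {sid!r}")
            continue
        try:
            censored = bool(int(row["censored"]))
            value = float(row["conc_ng_g_ww"])
            if value <= 0:
                raise ValueError(f"conc_ng_g_ww must be > 0, got {value}")
            if censored:
                if _isna(row["mloq_ng_g_ww"]):
                    raise ValueError("censored row lacks mloq_ng_g_ww")
                limit = float(row["mloq_ng_g_ww"])
                meas = CensoredMeasurement(value=limit, censored=True, limit=limit)
            else:
                limit = float("nan") if _isna(row["mloq_ng_g_ww"]) else float(row["mloq_ng_g_ww"])
                meas = CensoredMeasurement(value=value, censored=False, limit=limit)
        except (ValueError, TypeError) as exc:
            errors.append(f"{measurements_path}:{line}: {exc}")
            continue
        samples[sid].measurements[str(row["analyte"])] = meas
        n_attached += 1

    if not errors and n_attached == 0:
        errors.append(f"{measurements_path}: no measurements attached to any sample")
    if errors:
        raise ValidationError(errors)
    return list(samples.values()), chem_table


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_samples(samples, path) -> None:
    rows = []
    for s in samples:
        c = s.composition
        rows.append({
            "sample_id": s.sample_id, "species": s.species, "group": s.group,
            "delta15N": s.delta15N, "trophic_position": s.trophic_position,
            "body_temperature_K": s.body_temperature,
            "phi_NL": c.phi_NL, "phi_PL": c.phi_PL, "phi_ALB": c.phi_ALB,
            "phi_SP": c.phi_SP, "phi_W": c.phi_W,
        })
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False)


def write_measurements(samples, path) -> None:
    rows = []
    for s in samples:
        for analyte, m in s.measurements.items():
            rows.append({
                "sample_id": s.sample_id, "analyte": analyte,
                "conc_ng_g_ww": m.value, "censored": int(m.censored),
                "mloq_ng_g_ww": m.limit,
            })
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def write_chemicals(chem_table: dict, path) -> None:
    rows = []
    for rec in chem_table.values():
        row = {
            "name": rec.name, "class": rec.analyte_class,
            "chain_length": rec.chain_length, "molar_mass": rec.molar_mass,
            "molar_volume_cm3_mol": rec.molar_volume,
            "melting_point_K": rec.melting_point,
            "water_solubility_mol_m3": rec.water_solubility,
        }
        for p in PHASES:
            ld = rec.logD.get(p)
            row[f"logD_{p}"] = ld.value if ld else None
            row[f"logD_{p}_source"] = ld.source if ld else None
        rows.append(row)
    pd.DataFrame(rows, columns=CHEMICAL_COLUMNS).to_csv(path, index=False)


def tmf_results_frame(results) -> pd.DataFrame:
    """One row per analyte x scheme with every TMFResult field."""
    rows = []
    for r in results:
        rows.append({
            "analyte": r.analyte, "scheme": r.scheme, "slope": r.slope,
            "slope_se": r.slope_se, "tmf": r.tmf,
            "ci95_low": r.ci95[0], "ci95_high": r.ci95[1],
            "p_value": r.p_value, "n_total": r.n_total,
            "n_censored": r.n_censored, "n_excluded": r.n_excluded,
            "detection_frequency": r.detection_frequency,
        })
    return pd.DataFrame(rows)


def mass_distribution_frame(records) -> pd.DataFrame:
    """Long-format (sample_id, analyte, phase, fraction) table."""
    rows = []
    for sample_id, analyte, dist in records:
        for phase, fraction in dist.as_dict().items():
            rows.append({
                "sample_id": sample_id, "analyte": analyte,
                "phase": phase, "fraction": fraction,
            })
    return pd.DataFrame(rows, columns=["sample_id", "analyte", "phase", "fraction"])
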