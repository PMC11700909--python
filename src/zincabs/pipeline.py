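"""End-to-end orchestration: generate/load → absorb → derive → report.

``run_pipeline`` produces the four survey-style report tables plus the
benchmark test report and a manifest:

* ``table1.csv`` — intake and phytate:zinc summaries per stratum;
* ``table2.csv`` — % below each EAR/RDA standard per stratum;
* ``table3.csv`` — absorbed zinc (TAZ) and fractional absorption (FAZ)
  summaries with mean ± SD and range, against RAZ and the IOM rates;
* ``table4.csv`` — model-derived EAR_M/RDA_M against IOM and Colombian
  reference intakes;
* ``tests.csv``  — every Wilcoxon benchmark comparison;
* ``manifest.json`` — seed, config echo, row accounting and a SHA-256
  hash per output so a rerun can be verified byte for byte.

All value columns are written at full precision with a one-decimal
``*_1dp`` companion, so downstream checks are independent of display
rounding.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .absorption import CovariateSpec, ModelParams, absorb_frame
from .adequacy import adequacy_table
from .config import (
    load_generator_config,
    load_model_config,
    load_standards_config,
    packaged_path,
)
from .dri import DEFAULT_STANDARDS, ReferenceStandards, add_dri_columns
from .intake import (
    AgeBand,
    Sex,
    add_derived_columns,
    read_intake_table,
    records_to_frame,
)
from .popstats import benchmark_comparisons, quartile_summary, results_to_frame
from .synthetic import default_configs, generate_cohort

log = logging.getLogger(__name__)

_SUMMARY_METRICS_T1 = ("zinc_mg", "phytate_mg", "protein_g", "calcium_mg", "pz_ratio")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one input source."""

    out_dir: str | Path
    input_csv: str | Path | None = None
    generator_config: str | Path | None = None
    n_per_stratum: int | None = None
    model_config: str | Path = field(default_factory=lambda: packaged_path("model_reference.yaml"))
    standards_config: str | Path | None = None
    seed: int = 0
    rounding: int = 1
    strict: bool = True

    def __post_init__(self) -> None:
        have_csv = self.input_csv is not None
        have_gen = self.generator_config is not None or self.n_per_stratum is not None
        if have_csv and self.generator_config is not None:
            raise ValueError("give either input_csv or a generator config, not both")
        self.use_generator = not have_csv
        del have_gen


def _strata_iter(df: pd.DataFrame):
    """Yield (sex, band, sub-frame) for the six cells, per-sex totals and overall."""
    for sex in (Sex.MALE, Sex.FEMALE):
        sex_mask = df["sex"] == sex.value
        for band in (AgeBand.Y19_30, AgeBand.Y31_50, AgeBand.Y51_70):
            yield sex.value, band.value, df[sex_mask & (df["age_band"] == band.value)]
        yield sex.value, AgeBand.ALL.value, df[sex_mask]
    yield "all", AgeBand.ALL.value, df


def _with_rounded(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    """Append one-decimal reporting companions for every float column."""
    out = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            out[f"{col}_1dp"] = df[col].round(decimals)
    return out


def build_table1(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sex, band, sub in _strata_iter(df):
        row = {"sex": sex, "age_band": band, "n": len(sub)}
        for metric in _SUMMARY_METRICS_T1:
            values = sub[metric].dropna()
            if values.empty:
                continue
            s = quartile_summary(values, metric)
            row[f"{metric}_median"], row[f"{metric}_q1"], row[f"{metric}_q3"] = (
                s.median, s.q1, s.q3,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def build_table3(df: pd.DataFrame, standards: ReferenceStandards) -> pd.DataFrame:
    rows = []
    for sex, band, sub in _strata_iter(df):
        if sex == "all" or sub.empty:
            continue
        taz = quartile_summary(sub["taz_mg"], "taz_mg")
        faz = quartile_summary(100.0 * sub["faz"], "faz_pct", extras=True)
        rows.append(
            {
                "sex": sex, "age_band": band, "n": len(sub),
                "raz_mg": standards.raz(Sex(sex)),
                "taz_median": taz.median, "taz_q1": taz.q1, "taz_q3": taz.q3,
                "iom_absorption_pct": standards.iom_absorption_pct(Sex(sex)),
                "faz_median": faz.median, "faz_q1": faz.q1, "faz_q3": faz.q3,
                "faz_mean": faz.mean, "faz_sd": faz.sd,
                "faz_min": faz.min, "faz_max": faz.max,
            }
        )
    return pd.DataFrame(rows)


def build_table4(df: pd.DataFrame, standards: ReferenceStandards) -> pd.DataFrame:
    rows = []
    for sex, band, sub in _strata_iter(df):
        if sex == "all" or sub.empty:
            continue
        ear = quartile_summary(sub["ear_m"], "ear_m")
        rda = quartile_summary(sub["rda_m"], "rda_m")
        rows.append(
            {
                "sex": sex, "age_band": band, "n": len(sub),
                "ear_iom": standards.ear("iom", Sex(sex)),
                "rda_iom": standards.rda("iom", Sex(sex)),
                "ear_col": standards.ear("col", Sex(sex)),
                "rda_col": standards.rda("col", Sex(sex)),
                "ear_m_median": ear.median, "ear_m_q1": ear.q1, "ear_m_q3": ear.q3,
                "rda_m_median": rda.median, "rda_m_q1": rda.q1, "rda_m_q3": rda.q3,
            }
        )
    return pd.DataFrame(rows)


def analyse_cohort(
    cohort: pd.DataFrame,
    params: ModelParams,
    spec: CovariateSpec = CovariateSpec(),
    standards: ReferenceStandards = DEFAULT_STANDARDS,
) -> pd.DataFrame:
    """Derived columns + absorption + per-individual DRIs in one pass."""
    df = add_derived_columns(cohort)
    df = absorb_frame(df, params, spec)
    df = add_dri_columns(df, standards)
    return df


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write the artifact bundle.

    Returns a name → path mapping of everything written.
    """
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    params, spec = load_model_config(config.model_config)
    standards = (
        load_standards_config(config.standards_config)
        if config.standards_config
        else DEFAULT_STANDARDS
    )

    if config.use_generator:
        if config.generator_config is not None:
            gen_configs = load_generator_config(config.generator_config)
            if config.n_per_stratum:
                raise ValueError("n_per_stratum conflicts with an explicit generator config")
        else:
            gen_configs = default_configs(n_override=config.n_per_stratum)
        cohort = generate_cohort(gen_configs, seed=config.seed)
        rows_in = len(cohort)
        rows_dropped = 0
    else:
        records = read_intake_table(config.input_csv, strict=config.strict)
        cohort = records_to_frame(records)
        rows_in = len(records)
        rows_dropped = 0  # read_intake_table already enforced/accounted drops
    if cohort.empty:
        raise ValueError("no records to analyse")

    df = analyse_cohort(cohort, params, spec, standards)
    assert len(df) == rows_in - rows_dropped, "silent row drop in analysis"

    outputs = {
        "table1.csv": _with_rounded(build_table1(df), config.rounding),
        "table2.csv": _with_rounded(adequacy_table(df, standards), config.rounding),
        "table3.csv": _with_rounded(build_table3(df, standards), config.rounding),
        "table4.csv": _with_rounded(build_table4(df, standards), config.rounding),
        "tests.csv": results_to_frame(benchmark_comparisons(df, standards)),
        "cohort_analysed.csv": df,
    }
    paths: dict[str, Path] = {}
    for name, frame in outputs.items():
        path = out_dir / name
        frame.to_csv(path, index=False)
        paths[name] = path
        log.info("wrote %s (%d rows)", path, len(frame))

    manifest = {
        "package": "zincabs",
        "version": __version__,
        "seed": config.seed,
        "input": str(config.input_csv) if config.input_csv else "synthetic-generator",
        "model_config": str(config.model_config),
        "standards_config": str(config.standards_config or "packaged defaults"),
        "rows_in": rows_in,
        "rows_dropped": rows_dropped,
        "rows_processed": len(df),
        "outputs": {name: _sha256(path) for name, path in paths.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    paths["manifest.json"] = manifest_path
    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return paths
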