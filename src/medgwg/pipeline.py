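"""End-to-end study orchestration: simulate/ingest -> clean -> derive ->
impute -> mediate -> report, plus Table-1-style bivariate summaries.

A single seed governs every stochastic stage; running the same config
twice produces byte-identical reports.  Exclusion accounting is exact:
``rows_in = rows_analyzed + sum(per-rule exclusions)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anthropometry import derive_analysis_rows
from .cleaning import CleaningConfig, clean_growth_table
from .errors import ConfigError, SchemaError
from .imputation import ImputationConfig, fcs_impute, pooled_decomposition
from .lms import LMSTable, synthetic_lms_table
from .mediation import Contrast, ModelSpec, bootstrap_decomposition
from .synthetic import GeneratorConfig, generate_cohort, inject_errors

logger = logging.getLogger(__name__)

MOTHER_COLUMNS = (
    "mother_id", "race", "education", "smoking", "gdm", "cohort_period",
    "parity", "age_delivery", "cesarean", "gestational_age_days",
    "birth_weight_g", "child_sex", "height_cm", "weight_prepreg_kg",
    "weight_lmp_kg", "weight_delivery_kg", "delivery_gap_days")
GROWTH_COLUMNS = ("child_id", "sex", "age_months", "height_cm", "weight_kg")

#: Table-1 variables: (column, kind) with kind in {continuous, categorical}.
TABLE1_VARIABLES = (
    ("child_z", "continuous"),
    ("birth_weight_g", "continuous"),
    ("child_sex", "categorical"),
    ("age_delivery", "continuous"),
    ("education", "categorical"),
    ("race", "categorical"),
    ("bmi", "continuous"),
    ("maternal_category", "categorical"),
    ("gwg_category", "categorical"),
    ("smoking", "categorical"),
    ("gdm", "categorical"),
    ("cesarean", "categorical"),
    ("gestational_age_days", "continuous"),
    ("parity", "categorical"),
)


@dataclass
class StudyConfig:
    """Everything needed to run the full study once.

    Exactly one of ``generator`` (simulate a cohort) or
    ``mothers_path``/``growth_path`` (ingest CSVs) must be supplied.
    """

    generator: GeneratorConfig | None = None
    mothers_path: str | None = None
    growth_path: str | None = None
    lms_path: str | None = None       # None -> packaged synthetic reference
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    interaction: bool = True
    contrast: Contrast = field(default_factory=Contrast)
    bootstrap_b: int = 1000
    seed: int = 0
    out_dir: str | None = None
    welch: bool = False

    def validate(self):
        has_gen = self.generator is not None
        has_paths = self.mothers_path is not None or self.growth_path is not None
        if has_gen == has_paths:
            raise ConfigError(
                "supply exactly one of generator config or input paths")
        if has_paths and (self.mothers_path is None or self.growth_path is None):
            raise ConfigError("both mothers_path and growth_path are required")
        if self.bootstrap_b < 0:
            raise ConfigError("bootstrap_b must be >= 0")


@dataclass
class Table1Summary:
    """Bivariate summary of analysis rows by child weight status."""

    rows: list            # dicts: variable, level, stats per stratum, pvalue
    n_lean: int           # underweight + normal children
    n_overob: int         # overweight + obese children

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_text(self) -> str:
        lines = [f"{'Variable':<28}{'Normal/Under':>18}{'Over/Obese':>18}"
                 f"{'p':>10}",
                 f"{'n':<28}{self.n_lean:>18}{self.n_overob:>18}{'':>10}"]
        for r in self.rows:
            label = r["variable"] if r["level"] is None else f"  {r['level']}"
            p = "" if r["pvalue"] is None or not np.isfinite(r["pvalue"]) \
                else f"{r['pvalue']:.3f}"
            lines.append(f"{label:<28}{r['lean']:>18}{r['overob']:>18}{p:>10}")
        return "\n".join(lines)


def _cont_row(name, x0, x1, pvalue):
    def fmt(x):
        return f"{np.mean(x):.1f} ({np.std(x, ddof=1):.1f})" if len(x) > 1 else "-"
    return {"variable": name, "level": None, "lean": fmt(x0), "overob": fmt(x1),
            "pvalue": pvalue,
            "mean_lean": float(np.mean(x0)) if len(x0) else np.nan,
            "mean_overob": float(np.mean(x1)) if len(x1) else np.nan}


def summarize_table1(rows: pd.DataFrame, welch: bool = False) -> Table1Summary:
    """Compare children by weight status (normal/underweight vs
    overweight/obese): t-tests for continuous variables, Pearson
    chi-square (no continuity correction) for categorical ones.

    Percents use the per-stratum non-missing count as denominator and
    are rounded to integers for display; counts are stored exactly.
    """
    overob = rows["child_category"].isin(["overweight", "obese"])
    g0, g1 = rows[~overob], rows[overob]
    out = []
    for var, kind in TABLE1_VARIABLES:
        if var not in rows.columns:
            continue
        if kind == "continuous":
            x0 = pd.to_numeric(g0[var], errors="coerce").dropna().to_numpy()
            x1 = pd.to_numeric(g1[var], errors="coerce").dropna().to_numpy()
            if len(x0) > 1 and len(x1) > 1:
                if np.var(x0) + np.var(x1) == 0:
                    p = 1.0 if np.mean(x0) == np.mean(x1) else 0.0
                else:
                    p = float(stats.ttest_ind(x0, x1, equal_var=not welch).pvalue)
            else:
                p = None
            out.append(_cont_row(var, x0, x1, p))
        else:
            s0, s1 = g0[var].dropna(), g1[var].dropna()
            levels = sorted(set(s0.unique()) | set(s1.unique()), key=str)
            counts = np.array([[int((s0 == lev).sum()), int((s1 == lev).sum())]
                               for lev in levels])
            if counts.size and counts.sum(axis=0).min() > 0 and len(levels) > 1:
                keep = counts.sum(axis=1) > 0
                table = counts[keep].T
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                p = float(p)
            else:
                p = None
            out.append({"variable": var, "level": None, "lean": "", "overob": "",
                        "pvalue": p, "mean_lean": np.nan, "mean_overob": np.nan})
            n_tot = len(s0) + len(s1)
            for lev, (c0, c1) in zip(levels, counts):
                pct0 = round(100.0 * c0 / len(s0)) if len(s0) else 0
                pct1 = round(100.0 * c1 / len(s1)) if len(s1) else 0
                out.append({"variable": var, "level": str(lev),
                            "lean": f"{c0} ({pct0})",
                            "overob": f"{c1} ({pct1})",
                            "pvalue": None,
                            "count_lean": int(c0), "count_overob": int(c1),
                            "pct_lean": pct0, "pct_overob": pct1,
                            "count_total": int(c0 + c1),
                            "pct_total": round(100.0 * (c0 + c1) / n_tot)
                            if n_tot else 0})
    return Table1Summary(rows=out, n_lean=int((~overob).sum()),
                         n_overob=int(overob.sum()))


def read_cohort(mothers_path, growth_path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read and validate the two cohort CSVs.

    Malformed lines are skipped and counted; a header that does not
    contain the documented columns raises a schema error listing them.
    """
    rejected = {"mothers": 0, "growth": 0}

    def read(path, required, key):
        bad = []
        frame = pd.read_csv(path, engine="python",
                            on_bad_lines=lambda row: bad.append(row))
        rejected[key] = len(bad)
        for line in bad:
            logger.warning("%s: skipped malformed line: %r", path, line[:5])
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        return frame

    mothers = read(mothers_path, MOTHER_COLUMNS, "mothers")
    growth = read(growth_path, GROWTH_COLUMNS, "growth")
    for col in ("age_months", "height_cm", "weight_kg"):
        growth[col] = pd.to_numeric(growth[col], errors="coerce")
    for col in ("height_cm", "weight_prepreg_kg", "weight_lmp_kg",
                "weight_delivery_kg", "delivery_gap_days"):
        mothers[col] = pd.to_numeric(mothers[col], errors="coerce")
    return mothers, growth, rejected


def run_study(config: StudyConfig) -> dict:
    """Execute every stage in order and return the report dict."""
    config.validate()
    report: dict = {"seed": config.seed, "stages": {}}

    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(gen)
        cohort = inject_errors(cohort, gen)
        mothers, growth = cohort.mothers, cohort.growth
        report["truth"] = cohort.truth
        report["stages"]["simulate"] = {
            "n_pairs": int(gen.n_pairs),
            "n_corrupted_heights": int(len(cohort.corruptions)),
            "n_missing_cells": int(len(cohort.missing_log))}
    else:
        mothers, growth, rejected = read_cohort(config.mothers_path,
                                                config.growth_path)
        report["stages"]["ingest"] = {"n_mothers": int(len(mothers)),
                                      "n_growth_records": int(len(growth)),
                                      "rejected_lines": rejected}

    cleaned, changes = clean_growth_table(growth, config.cleaning)
    report["stages"]["clean"] = {"n_imputed_heights": int(len(changes)),
                                 "no_op": bool(len(changes) == 0)}

    lms = synthetic_lms_table() if config.lms_path is None \
        else LMSTable.from_csv(config.lms_path)
    rows, exclusions = derive_analysis_rows(mothers, cleaned, lms)
    report["stages"]["derive"] = {
        "rows_in": int(len(mothers)),
        "rows_analyzed": int(len(rows)),
        "exclusions": {k: int(v) for k, v in exclusions.items()},
    }
    assert len(mothers) == len(rows) + sum(exclusions.values())

    report["table1"] = summarize_table1(rows, welch=config.welch).rows

    impute_cols = [c for c in config.imputation.predictors if c in rows.columns]
    any_missing = bool(rows[impute_cols].isna().any().any())
    if any_missing:
        imp = dataclasses.replace(config.imputation, seed=config.seed)
        tables = fcs_impute(rows, imp)
        report["stages"]["impute"] = {"no_op": False, "m": imp.m,
                                      "cycles": imp.cycles}
    else:
        tables = [rows]
        report["stages"]["impute"] = {"no_op": True, "m": 1, "cycles": 0}

    for label, covset in (("minimal", "minimal"), ("extended", "extended")):
        spec = ModelSpec(covariate_set=covset, interaction=config.interaction)
        if len(tables) > 1:
            dec = pooled_decomposition(tables, spec, config.contrast,
                                       B=config.bootstrap_b, seed=config.seed)
        elif config.bootstrap_b >= 1:
            dec = bootstrap_decomposition(tables[0], spec, config.contrast,
                                          B=config.bootstrap_b,
                                          seed=[config.seed, 0xB007])
        else:
            from .mediation import (decompose_effects, fit_mediator_model,
                                    fit_outcome_model)
            dec = decompose_effects(fit_outcome_model(tables[0], spec),
                                    fit_mediator_model(tables[0], spec),
                                    config.contrast)
        report[f"decomposition_{label}"] = dec.to_dict()

    report["contrast"] = {"a": config.contrast.a, "a_star": config.contrast.a_star,
                          "m_cde": config.contrast.m_cde}
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of a study report."""
    lines = ["medgwg study report", "===================", ""]
    d = report["stages"].get("derive", {})
    lines.append(f"rows in: {d.get('rows_in')}  analyzed: {d.get('rows_analyzed')}")
    for rule, n in d.get("exclusions", {}).items():
        lines.append(f"  excluded ({rule}): {n}")
    for label in ("minimal", "extended"):
        dec = report.get(f"decomposition_{label}")
        if not dec:
            continue
        lines += ["", f"Effect decomposition ({label} covariate set, "
                      f"BMI {report['contrast']['a']:g} vs "
                      f"{report['contrast']['a_star']:g}):"]
        for eff, key in (("CDE", "cde"), ("NDE", "nde"), ("NIE", "nie"),
                         ("Total effect", "te")):
            ci = dec.get(f"ci_{key}")
            ci_txt = f"  ({ci[0]:.3f}, {ci[1]:.3f})" if ci else ""
            lines.append(f"  {eff:<14}{dec[key]:.3f}{ci_txt}")
        pm = dec["proportion_mediated"]
        ci = dec.get("ci_pm")
        ci_txt = f"  ({100*ci[0]:.1f}%, {100*ci[1]:.1f}%)" if ci else ""
        lines.append(f"  {'Prop mediated':<14}{100*pm:.2f}%{ci_txt}")
    if "truth" in report:
        t = report["truth"]
        lines += ["", "Generating truth: "
                  f"CDE {t['cde']:.3f}  NDE {t['nde']:.3f}  NIE {t['nie']:.3f}  "
                  f"TE {t['te']:.3f}  PM {100*t['proportion_mediated']:.2f}%"]
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=default)
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(report))
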