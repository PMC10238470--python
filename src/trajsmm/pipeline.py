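"""End-to-end orchestration: I/O, validation, descriptives, reporting.

``run_pipeline`` chains the full analysis the package exists for:

    simulate/load -> descriptive table -> class-count selection ->
    relabel -> baseline-weight crosstab -> odds-ratio estimation ->
    CSV/JSON artifacts, figures and a markdown report.

Everything is deterministic given the configuration (simulation is seeded;
the E-M fit has no randomness of its own).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml
from statsmodels.stats.diagnostic import lilliefors

from . import __version__
from .association import DEFAULT_COVARIATES, run_association
from .errors import DataValidationError, PipelineError
from .smm import SmoothingMixtureModel, crosstab
from .synthetic_data import (
    CohortConfig,
    default_outcome_config,
    generate_cohort,
    generate_covariates,
    generate_outcomes,
)

__all__ = [
    "RunConfig",
    "read_long_csv",
    "write_long_csv",
    "read_outcomes_csv",
    "summarize",
    "baseline_grouping",
    "run_pipeline",
    "write_report",
]

log = logging.getLogger("trajsmm")

LONG_COLUMNS = ("subject_id", "month", "weight_kg")
MAX_WEIGHT_KG = 250.0


def read_long_csv(path) -> pd.DataFrame:
    """Read and validate a tidy longitudinal weight table.

    Expects columns ``subject_id, month, weight_kg``. Months must be
    integers; weights positive and below 250 kg; duplicate
    (subject, month) pairs are rejected. Errors cite 1-based data row
    numbers (header = row 1).
    """
    df = pd.read_csv(path)
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    month_num = pd.to_numeric(df["month"], errors="coerce")
    bad = df.index[month_num.isna() | (month_num != month_num.round())]
    if len(bad):
        raise DataValidationError(
            f"{path}: non-integer month at row {int(bad[0]) + 2}"
        )
    df["month"] = month_num.astype(int)
    weight = pd.to_numeric(df["weight_kg"], errors="coerce")
    bad = df.index[weight.isna() | (weight <= 0) | (weight >= MAX_WEIGHT_KG)]
    if len(bad):
        raise DataValidationError(
            f"{path}: weight_kg must be in (0, {MAX_WEIGHT_KG}) kg; "
            f"violation at row {int(bad[0]) + 2}"
        )
    df["weight_kg"] = weight
    dup = df.duplicated(["subject_id", "month"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise DataValidationError(
            f"{path}: duplicate (subject_id, month) observation at row {row}"
        )
    return df[list(LONG_COLUMNS)]


def write_long_csv(data: pd.DataFrame, path) -> None:
    data[list(LONG_COLUMNS)].to_csv(path, index=False)


def read_outcomes_csv(path) -> pd.DataFrame:
    """Read a per-subject outcome/covariate table indexed by subject_id."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise DataValidationError(f"{path}: missing subject_id column")
    if df["subject_id"].duplicated().any():
        raise DataValidationError(f"{path}: duplicate subject_id rows")
    return df.set_index("subject_id")


def _continuous_row(name: str, values: np.ndarray, normality: bool) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    row = {
        "variable": name,
        "type": "continuous",
        "n": values.size,
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }
    if normality and values.size >= 4:
        sw_stat, sw_p = scipy.stats.shapiro(values)
        ks_stat, ks_p = lilliefors(values, dist="norm")
        row.update(
            shapiro_w=float(sw_stat),
            shapiro_p=float(sw_p),
            ks_lilliefors=float(ks_stat),
            ks_p=float(ks_p),
        )
    return row


def summarize(data: pd.DataFrame, outcomes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Descriptive table: mean/SD/median/quartiles for each monthly weight
    (with Shapiro-Wilk and Lilliefors-corrected Kolmogorov-Smirnov
    normality tests) and the continuous covariates; count/percent for each
    binary outcome."""
    if data.empty:
        raise DataValidationError("empty longitudinal table")
    rows = []
    for month, grp in data.groupby("month"):
        rows.append(
            _continuous_row(
                f"maternal_weight_m{month}", grp["weight_kg"].to_numpy(), True
            )
        )
    if outcomes is not None:
        for col in outcomes.columns:
            vals = outcomes[col].dropna()
            uniq = set(pd.unique(vals))
            if uniq <= {0, 1}:
                count = int(vals.sum())
                rows.append(
                    {
                        "variable": col,
                        "type": "binary",
                        "n": int(vals.size),
                        "count": count,
                        "percent": 100.0 * count / vals.size,
                    }
                )
            else:
                rows.append(_continuous_row(col, vals.to_numpy(), False))
    return pd.DataFrame(rows)


def baseline_grouping(data: pd.DataFrame, K: int) -> pd.Series:
    """K-quantile grouping on the first observed month's weight (rank
    based, so ties split deterministically); this is the 'initial
    grouping' the concordance table compares against."""
    first_month = data["month"].min()
    base = (
        data[data["month"] == first_month]
        .set_index("subject_id")["weight_kg"]
        .sort_index()
    )
    ranks = base.rank(method="first")
    groups = pd.qcut(ranks, K, labels=False) + 1
    return groups.astype(int).rename("class_index")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``long_csv``/``outcomes_csv`` point at existing data, or
    ``simulate=True`` generates a synthetic cohort with the given seed.
    """

    out_dir: str = "trajsmm_run"
    simulate: bool = True
    long_csv: str | None = None
    outcomes_csv: str | None = None
    n_subjects: int = 877
    seed: int = 0
    k_range: tuple = (2, 3, 4, 5)
    parsimony: str = "elbow"
    bic_margin: float = 0.01
    n_basis: int = 6
    degree: int = 3
    penalty_order: int = 2
    random_intercept: bool = False
    bic_n: str = "observations"
    covariates: tuple = DEFAULT_COVARIATES
    force_adjust: bool = False
    make_figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        ks = tuple(int(k) for k in self.k_range)
        if not ks or min(ks) < 1 or max(ks) > 10:
            raise DataValidationError("k_range must lie within 1..10")
        self.k_range = ks
        if not self.simulate and (self.long_csv is None or self.outcomes_csv is None):
            raise DataValidationError(
                "when simulate is false, long_csv and outcomes_csv are required"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name, manifest, func, *args, **kwargs):
    t0 = time.perf_counter()
    log.info("stage %s ...", name)
    try:
        result = func(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(name, exc) from exc
    dt = time.perf_counter() - t0
    manifest["timings_s"][name] = round(dt, 4)
    log.info("stage %s done in %.2fs", name, dt)
    return result


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-step analysis and write all artifacts.

    Returns the run manifest (artifact paths, timings, key results).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "timings_s": {},
        "artifacts": {},
    }

    def artifact(key, path):
        manifest["artifacts"][key] = str(path)
        return path

    # ---- data ---------------------------------------------------------- #
    truth = None
    if config.simulate:
        def simulate():
            ccfg = CohortConfig(n_subjects=config.n_subjects, seed=config.seed)
            long, labels = generate_cohort(ccfg)
            cov = generate_covariates(config.n_subjects, seed=config.seed + 1)
            ocfg = default_outcome_config(seed=config.seed + 2)
            outcomes = generate_outcomes(labels, cov, ocfg)
            return long, outcomes, labels

        data, outcomes, truth = _stage("simulate", manifest, simulate)
        write_long_csv(data, artifact("long_csv", out / "long.csv"))
        outcomes.to_csv(artifact("outcomes_csv", out / "outcomes.csv"))
        truth.to_frame().to_csv(artifact("true_labels_csv", out / "true_labels.csv"))
    else:
        data = _stage("read_long", manifest, read_long_csv, config.long_csv)
        outcomes = _stage("read_outcomes", manifest, read_outcomes_csv, config.outcomes_csv)

    # ---- descriptives ---------------------------------------------------#
    desc = _stage("summarize", manifest, summarize, data, outcomes)
    desc.to_csv(artifact("descriptives_csv", out / "descriptives.csv"), index=False)

    # ---- classification ------------------------------------------------ #
    model = SmoothingMixtureModel(
        data,
        n_basis=config.n_basis,
        degree=config.degree,
        penalty_order=config.penalty_order,
        random_intercept=config.random_intercept,
        bic_n=config.bic_n,
    )
    selection = _stage(
        "select_K",
        manifest,
        model.select,
        config.k_range,
        parsimony=config.parsimony,
        bic_margin=config.bic_margin,
    )
    selection.table.to_csv(
        artifact("selection_table_csv", out / "selection_table.csv"), index=False
    )
    fit = selection.selected.relabel()
    manifest["selected_k"] = selection.selected_k
    manifest["best_k_bic"] = selection.best_k_bic
    manifest["parsimony_note"] = selection.parsimony_note
    manifest["total_ll"] = fit.total_ll
    manifest["bic"] = fit.bic

    fit.assignment_frame().to_csv(artifact("assignments_csv", out / "assignments.csv"))
    fit.predicted_curves().to_csv(artifact("curves_csv", out / "curves.csv"))
    (out / "fit_summary.json").write_text(fit.to_json())
    artifact("fit_summary_json", out / "fit_summary.json")

    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        manifest["ari_vs_truth"] = float(
            adjusted_rand_score(truth.to_numpy(), fit.assignment.to_numpy())
        )

    # ---- concordance with a baseline-weight grouping -------------------- #
    def concordance():
        base = baseline_grouping(data, fit.n_classes)
        return crosstab(base, fit.assignment)

    table, conc = _stage("crosstab", manifest, concordance)
    table.to_csv(artifact("crosstab_csv", out / "crosstab.csv"))
    manifest["concordance_pct"] = conc

    # ---- associations --------------------------------------------------- #
    or_table = _stage(
        "association",
        manifest,
        run_association,
        fit,
        outcomes,
        covariates=config.covariates,
        force_adjust=config.force_adjust,
    )
    or_table.to_csv(artifact("association_csv", out / "association.csv"), index=False)

    # ---- figures (best effort) ------------------------------------------ #
    if config.make_figures:
        try:
            from . import plots

            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            plots.spaghetti(
                data, frac=0.5, seed=config.seed, path=figdir / "spaghetti.png"
            )
            plots.predicted_trajectories(fit, path=figdir / "predicted_trajectories.png")
            artifact("spaghetti_png", figdir / "spaghetti.png")
            artifact("trajectories_png", figdir / "predicted_trajectories.png")
        except Exception as exc:  # pragma: no cover - plotting is best effort
            log.warning("figure generation skipped: %s", exc)

    # ---- report ---------------------------------------------------------- #
    report = write_report(out, manifest, desc, selection.table, table, conc, or_table, fit)
    artifact("report_md", report)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    artifact("manifest_json", out / "manifest.json")
    return manifest


def write_report(out, manifest, desc, selection_table, xtab, concordance, or_table, fit):
    """Assemble the markdown analysis report from the computed tables."""
    path = Path(out) / "report.md"
    parts = [
        "# Maternal weight trajectory analysis",
        "",
        f"trajsmm {__version__} — selected {manifest['selected_k']} trajectory "
        f"classes (BIC minimum at K={manifest['best_k_bic']}).",
    ]
    if manifest.get("parsimony_note"):
        parts.append(f"\n> {manifest['parsimony_note']}")
    parts += [
        "",
        "## Descriptive statistics",
        "```",
        desc.to_string(index=False),
        "```",
        "## Class-count selection",
        "```",
        selection_table.to_string(index=False),
        "```",
        "## Fitted model",
        "```",
        fit.summary(),
        "```",
        "## Baseline-weight grouping vs model classes",
        f"Concordance: {concordance:.1f}%",
        "```",
        xtab.to_string(),
        "```",
        "## Odds ratios (crude and adjusted)",
        "```",
        or_table.to_string(index=False),
        "```",
        "",
    ]
    path.write_text("\n".join(parts))
    return path
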