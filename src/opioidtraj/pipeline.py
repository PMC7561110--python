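"""Stage functions tying the pipeline together (the CLI is a thin shell).

Stages communicate through delimited-text artifacts in a working directory:

    simulate  → region/practice/staff/patient/therapy/conditions/denominators
    prepare   → therapy_clean.csv, rx_exclusions.csv
    cohort    → cohort.csv, attrition.csv
    outcomes  → long_term.csv, transitions_long.csv, transition_flows.csv
    trends    → trends.csv
    model     → fixed_effects.csv, variance_components.csv, unit_summary.csv
    report    → summary.json

Every stage appends to ``manifest.json`` (stage, seed, config hash, output
digests) so a run's lineage is fully described.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import exposure, io, multilevel, outcomes, simulate

MODEL_BINARY_FLAGS = list(cohort_mod.DIAGNOSIS_FLAGS) + list(cohort_mod.DRUG_FLAGS)

#: Categorical model terms and their reference levels (reference-coded).
MODEL_CATEGORICALS = {
    "age_model_band": "<35",
    "sex": "M",
    "townsend_quintile": "1",
}


class StageError(RuntimeError):
    pass


def _manifest(out_dir) -> io.RunManifest:
    return io.RunManifest(Path(out_dir) / "manifest.json")


def stage_simulate(config: simulate.SimConfig, out_dir) -> dict:
    study = simulate.simulate_study(config)
    paths = simulate.write_study(study, out_dir)
    _manifest(out_dir).record(
        "simulate",
        {k: p for k, p in paths.items()},
        seed=config.seed,
        config_hash=io.config_hash(config.to_dict()),
    )
    return paths


def stage_prepare(in_dir, out_dir, conversion_path=None, rules: exposure.CleaningRules | None = None) -> dict:
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    therapy_path = in_dir / "therapy.csv"
    if not therapy_path.exists():
        raise StageError(f"missing input table {therapy_path}")
    if conversion_path is not None:
        conversion_path = Path(conversion_path)
        if not conversion_path.exists():
            raise StageError(f"missing conversion table {conversion_path}")
        table = exposure.ConversionTable.from_csv(conversion_path)
    else:
        table = exposure.ConversionTable.default()
    raw = io.read_table(therapy_path)
    clean, log = exposure.clean_prescriptions(raw, rules=rules, conversion=table)
    clean = exposure.add_mme(clean, table)
    clean = clean.assign(issue_date=clean["issue_date"].dt.strftime("%Y-%m-%d"))
    paths = {
        "therapy_clean": io.write_table(clean, out_dir / "therapy_clean.csv", schema="therapy_clean"),
        "rx_exclusions": io.write_table(log, out_dir / "rx_exclusions.csv", schema="rx_exclusions"),
    }
    _manifest(out_dir).record("prepare", paths)
    return paths


def _study_span(in_dir):
    den = io.read_table(Path(in_dir) / "denominators.csv")
    years = den["year"].astype(int)
    return pd.Timestamp(int(years.min()), 1, 1), pd.Timestamp(int(years.max()), 12, 31)


def stage_cohort(in_dir, out_dir, settings: cohort_mod.CohortSettings | None = None) -> dict:
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    for name in ("patient.csv", "conditions.csv"):
        if not (in_dir / name).exists():
            raise StageError(f"missing input table {in_dir / name}")
    clean_path = out_dir / "therapy_clean.csv"
    if not clean_path.exists():
        clean_path = in_dir / "therapy_clean.csv"
    if not clean_path.exists():
        raise StageError("run the prepare stage first: therapy_clean.csv not found")
    patients = io.read_table(in_dir / "patient.csv")
    rx = io.read_table(clean_path)
    conditions = io.read_table(in_dir / "conditions.csv")
    start, end = _study_span(in_dir)
    cohort, attrition_log = cohort_mod.derive_new_users(patients, rx, conditions, start, end, settings)

    # index-day MME/day (summed over index-day prescriptions)
    rx_dt = rx.assign(issue_date=pd.to_datetime(rx["issue_date"]))
    idx = cohort.set_index("patient_id")["index_date"]
    on_index = rx_dt[rx_dt["patient_id"].isin(idx.index)]
    on_index = on_index[on_index["issue_date"] == on_index["patient_id"].map(idx)]
    index_mme = on_index.groupby("patient_id")["mme_per_day"].sum()

    cohort = cohort_mod.derive_covariates(cohort, conditions, patients, settings, index_mme=index_mme)
    cohort["index_date"] = cohort["index_date"].dt.strftime("%Y-%m-%d")
    cohort["follow_up_end"] = pd.to_datetime(cohort["follow_up_end"]).dt.strftime("%Y-%m-%d")

    attrition = attrition_log.groupby("reason").size().rename("count").reset_index()
    paths = {
        "cohort": io.write_table(cohort, out_dir / "cohort.csv", schema="cohort"),
        "attrition": io.write_table(attrition, out_dir / "attrition.csv", schema="attrition"),
        "attrition_log": io.write_table(attrition_log, out_dir / "attrition_log.csv", schema="attrition_log"),
    }
    _manifest(out_dir).record("cohort", paths)
    return paths


def _timelines_for(cohort: pd.DataFrame, rx: pd.DataFrame, horizon: int = 728) -> dict:
    rx = rx.assign(issue_date=pd.to_datetime(rx["issue_date"]))
    idx = cohort.set_index("patient_id")["index_date"]
    rx = rx[rx["patient_id"].isin(idx.index)]
    rx = rx.assign(day=(rx["issue_date"] - rx["patient_id"].map(idx)).dt.days)
    follow = {
        row.patient_id: min(horizon, int(row.follow_up_days))
        for row in cohort.itertuples(index=False)
    }
    rx = rx[rx["day"] < rx["patient_id"].map(follow)]
    timelines = exposure.build_timelines(rx, follow)
    # pad to the horizon; days beyond follow-up stay uncovered (off state)
    for tl in timelines.values():
        if len(tl.values) < horizon:
            tl.values = np.pad(tl.values, (0, horizon - len(tl.values)))
    return timelines


def stage_outcomes(in_dir, out_dir, convention: str = "covered") -> dict:
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    cohort = io.read_table(out_dir / "cohort.csv")
    cohort["index_date"] = pd.to_datetime(cohort["index_date"])
    rx = io.read_table(out_dir / "therapy_clean.csv")

    lt = outcomes.classify_long_term_table(rx, cohort)
    timelines = _timelines_for(cohort, rx)
    result = outcomes.build_transition_table(cohort, timelines, convention=convention)

    paths = {
        "long_term": io.write_table(lt, out_dir / "long_term.csv", schema="long_term"),
        "transitions_long": io.write_table(result.long, out_dir / "transitions_long.csv", schema="transitions_long"),
        "transition_flows": io.write_table(result.flows, out_dir / "transition_flows.csv", schema="transition_flows"),
        "state_sequences": io.write_table(result.sequences, out_dir / "state_sequences.csv", schema="state_sequences"),
    }
    _manifest(out_dir).record("outcomes", paths)
    return paths


def stage_trends(in_dir, out_dir) -> dict:
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    rx_path = out_dir / "therapy_clean.csv"
    rx = io.read_table(rx_path if rx_path.exists() else in_dir / "therapy.csv")
    den = io.read_table(in_dir / "denominators.csv")
    trends = multilevel.annual_prescription_rate(rx, den)
    paths = {"trends": io.write_table(trends, out_dir / "trends.csv", schema="trends")}
    _manifest(out_dir).record("trends", paths)
    return paths


def collapse_age_band(band: str) -> str:
    return "<35" if band in ("18-24", "25-34") else band


def build_design(cohort: pd.DataFrame, binary_flags=None, categoricals=None) -> pd.DataFrame:
    """Reference-coded fixed-effect design matrix from cohort covariates."""
    binary_flags = MODEL_BINARY_FLAGS if binary_flags is None else list(binary_flags)
    categoricals = dict(MODEL_CATEGORICALS if categoricals is None else categoricals)
    df = cohort.copy()
    if "age_model_band" in categoricals and "age_model_band" not in df.columns:
        df["age_model_band"] = df["age_group"].map(collapse_age_band)
    parts = [df[binary_flags].astype(float)]
    for col, ref in categoricals.items():
        dummies = pd.get_dummies(df[col].astype(str), prefix=col, dtype=float)
        ref_col = f"{col}_{ref}"
        if ref_col in dummies.columns:
            dummies = dummies.drop(columns=[ref_col])
        parts.append(dummies)
    if "index_mme" in df.columns:
        parts.append(df[["index_mme"]].astype(float))
    return pd.concat(parts, axis=1)


def stage_model(in_dir, out_dir, seed: int = 0, n_sims: int = 1000) -> dict:
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    cohort = io.read_table(out_dir / "cohort.csv")
    lt = io.read_table(out_dir / "long_term.csv")
    patients = io.read_table(in_dir / "patient.csv")
    staff = io.read_table(in_dir / "staff.csv")
    practice = io.read_table(in_dir / "practice.csv")

    df = cohort.merge(lt[["patient_id", "is_long_term"]], on="patient_id")
    link = (
        patients[["patient_id", "staff_id"]]
        .merge(staff, on="staff_id")
        .merge(practice, on="practice_id")
    )
    df = df.merge(link, on="patient_id")

    X = build_design(df)
    y = df["is_long_term"].to_numpy()
    groups = df[["region_id", "practice_id", "staff_id"]]

    model = multilevel.NestedLogisticRegression()
    model.fit(X, y, groups)
    draws = multilevel.simulate_random_effects(model, n_sims=n_sims, seed=seed)
    anchor = float(np.mean(y))
    summary = multilevel.summarize_and_flag(draws, model, population_reference=anchor)

    fe = model.fixed_effects_frame()
    vc = pd.DataFrame(
        {
            "level": ["region", "practice", "prescriber", "residual_latent"],
            "sigma2": [
                model.sigma2_region_,
                model.sigma2_practice_,
                model.sigma2_prescriber_,
                model.residual_latent_variance_,
            ],
            "share_pct": [
                model.explained_variation()[k] for k in ("region", "practice", "prescriber", "residual")
            ],
        }
    )
    paths = {
        "fixed_effects": io.write_table(fe, out_dir / "fixed_effects.csv", schema="fixed_effects"),
        "variance_components": io.write_table(vc, out_dir / "variance_components.csv", schema="variance_components"),
        "unit_summary": io.write_table(summary, out_dir / "unit_summary.csv", schema="unit_summary"),
    }
    _manifest(out_dir).record(
        "model",
        paths,
        seed=seed,
        extra={"n_sims": n_sims, "anchor": anchor, "converged": model.converged_},
    )
    return paths


def stage_report(in_dir, out_dir, plot: bool = False) -> dict:
    out_dir = Path(out_dir)
    cohort = io.read_table(out_dir / "cohort.csv")
    lt = io.read_table(out_dir / "long_term.csv")
    vc = io.read_table(out_dir / "variance_components.csv")
    summary_units = io.read_table(out_dir / "unit_summary.csv")

    report = {
        "cohort_size": int(len(cohort)),
        "long_term_proportion": float(lt["is_long_term"].mean()) if len(lt) else float("nan"),
        "index_strength_counts": cohort["index_strength_class"].value_counts().to_dict(),
        "variance_partition_pct": dict(zip(vc["level"], vc["share_pct"])),
        "high_risk_units": {
            level: int(((summary_units["level"] == level) & (summary_units["flag"] == "high")).sum())
            for level in multilevel.LEVELS
        },
    }
    path = out_dir / "summary.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(report, indent=1, sort_keys=True))
    tmp.replace(path)
    paths = {"summary": path}
    if plot:
        paths["caterpillar"] = _caterpillar_plot(summary_units, out_dir / "caterpillar_prescriber.png")
    _manifest(out_dir).record("report", paths)
    return paths


def _caterpillar_plot(summary_units: pd.DataFrame, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary_units[summary_units["level"] == "prescriber"].sort_values("rank")
    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(sub))
    ax.errorbar(
        x,
        sub["or_estimate"],
        yerr=[sub["or_estimate"] - sub["or_lo"], sub["or_hi"] - sub["or_estimate"]],
        fmt="o",
        ms=2,
        lw=0.5,
    )
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_yscale("log")
    ax.set_xlabel("prescriber rank")
    ax.set_ylabel("adjusted OR of long-term use")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def run_pipeline(config: simulate.SimConfig, workdir, seed: int | None = None, n_sims: int = 500) -> dict:
    """Run simulate → prepare → cohort → outcomes → trends → model → report."""
    workdir = Path(workdir)
    paths = {}
    paths.update(stage_simulate(config, workdir))
    paths.update(stage_prepare(workdir, workdir))
    paths.update(stage_cohort(workdir, workdir))
    paths.update(stage_outcomes(workdir, workdir))
    paths.update(stage_trends(workdir, workdir))
    paths.update(stage_model(workdir, workdir, seed=config.seed if seed is None else seed, n_sims=n_sims))
    paths.update(stage_report(workdir, workdir))
    return paths
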