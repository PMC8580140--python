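"""End-to-end experiment pipelines with seeded, manifest-logged stages.

``run_experiment`` wires the synthetic cohort generator, GLM, MVB boost
comparison, MVPA finger decoding (free-selection only) and lifespan
statistics into one report bundle shaped like the study's result tables:

* univariate age-effect table (ROI means, weight spreads),
* behavioral compensation-interaction tables with null Bayes factors,
* MVB boost category table with ordinal age regression and directional
  Bayes factor,
* MVPA accuracy/boost report.

Every random stage consumes a sub-seed derived from the config seed, and
a manifest records seeds, thresholds and problem sizes so a report can be
reproduced exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import boost as boost_mod
from . import cohort as coh
from . import glm, mvpa, stats

__all__ = ["PipelineConfig", "run_experiment", "make_fixture"]


@dataclass
class PipelineConfig:
    """Configuration of one experiment-shaped pipeline run."""

    experiment: str = "sensorimotor"
    scenario: str = "haroldnull"
    n_subjects: int = 30
    n_voxels: int = 16
    n_scans: int | None = 140
    n_trials: int | None = 56
    seed: int = 0
    n_shuffles: int = 6
    modes: tuple[str, ...] = ("main",)
    boost_threshold: float = boost_mod.BOOST_THRESHOLD
    chance_pct: float = mvpa.CHANCE_LEVEL_PCT
    alpha: float = stats.ALPHA
    run_mvpa: bool = True
    per_roi_spread: bool = True
    output_dir: str | None = None

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "modes" in raw:
            raw["modes"] = tuple(raw["modes"])
        return PipelineConfig(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["modes"] = list(d["modes"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def cohort_spec(self) -> coh.CohortSpec:
        return coh.CohortSpec.preset(
            self.scenario,
            design=self.experiment,
            n_subjects=self.n_subjects,
            seed=self.seed,
            n_voxels=self.n_voxels,
            n_scans=self.n_scans,
            n_trials=self.n_trials,
        )


def _stat_to_dict(res: stats.StatResult) -> dict:
    out = {
        "block": res.block_name,
        "F": res.block_F,
        "p": res.block_p,
        "df": list(res.block_df),
        "r2_pct": res.r2_pct,
        "significant": res.block_significant,
        "model": res.model,
        "coefficients": res.coefficients.to_dict(orient="index"),
    }
    if res.odds_ratios is not None:
        out["odds_ratios"] = res.odds_ratios.to_dict(orient="index")
    if res.bf01 is not None:
        out["bf01"] = res.bf01
    if res.notes:
        out["notes"] = res.notes
    return out


def _univariate_report(table: pd.DataFrame, age: stats.AgeTerms) -> dict:
    """Table-1-shaped age effects on ROI means and weight spreads."""
    report = {}
    measures = [("contra_mean", "univariate_contralateral"),
                ("ipsi_mean", "univariate_ipsilateral")]
    if "spread_contra" in table.columns:
        measures += [("spread_contra", "spread_contralateral"),
                     ("spread_ipsi", "spread_ipsilateral")]
    for col, name in measures:
        res = stats.age_effect(table[col].to_numpy(), age)
        report[name] = _stat_to_dict(res)
    return report


def _behavioral_report(table: pd.DataFrame, age: stats.AgeTerms) -> dict:
    """Tables-2/3-shaped compensation models with BF01 columns."""
    report = {}
    ipsi = table["ipsi_mean"].to_numpy()
    contra = table["contra_mean"].to_numpy()
    ipsi_z = (ipsi - ipsi.mean()) / ipsi.std()
    for col in ("rt_sd", "rt_mean"):
        y = table[col].to_numpy()
        res_age = stats.age_effect(y, age)
        res_int = stats.compensation_interaction(y, ipsi, age)
        X_full = pd.DataFrame(
            {
                "ipsi": ipsi_z,
                "age_lin": age.linear,
                "age_quad": age.quadratic,
                "ipsi_x_age_lin": ipsi_z * age.linear,
                "ipsi_x_age_quad": ipsi_z * age.quadratic,
            }
        )
        X_red = X_full[["ipsi", "age_lin", "age_quad"]]
        res_int.bf01 = stats.bf_continuous_null(y, X_red, X_full)
        res_partial = stats.partial_compensation(y, ipsi, contra, age)
        report[col] = {
            "age_effect": _stat_to_dict(res_age),
            "interaction": _stat_to_dict(res_int),
            "interaction_bf01_label": stats.interpret_bf(res_int.bf01),
            "partial_compensation": _stat_to_dict(res_partial),
        }
    return report


def _boost_report(
    table: pd.DataFrame, summary: dict, seed: int
) -> dict:
    """Table-4 / Fig-4C-shaped categorical age analysis."""
    inc = table[table["included"]]
    out = {"summary": summary}
    if len(inc) >= 10 and inc["category"].nunique() >= 2:
        age_inc = stats.age_terms(inc["age"].to_numpy())
        res_lin = stats.ordinal_boost_regress(
            inc["category"].to_numpy(), age_inc
        )
        out["ordinal_linear"] = _stat_to_dict(res_lin)
        try:
            res_quad = stats.ordinal_boost_regress(
                inc["category"].to_numpy(), age_inc, quadratic=True
            )
            out["ordinal_quadratic"] = _stat_to_dict(res_quad)
        except Exception as err:  # quadratic model may not converge
            out["ordinal_quadratic"] = {"error": str(err)}
        if inc["category"].eq("boost").nunique() == 2:
            bf, diag = stats.bf_directional_categorical(
                inc["category"].to_numpy(), age_inc, seed=seed
            )
            out["bf01_directional"] = bf
            out["bf01_label"] = stats.interpret_bf(bf)
            out["bf01_diagnostics"] = diag
    else:
        out["ordinal_linear"] = {
            "error": "too few included participants or categories"
        }
    return out


def _mvpa_subject(
    spec: coh.CohortSpec, i: int, seed: int
) -> dict:
    """Trial-wise finger decoding for one free-selection participant."""
    truth = coh.subject_truth(spec, i)
    schedule = coh.generate_event_schedule(
        spec.design, seed=seed * 1009 + i, n_scans=spec.n_scans,
        tr=spec.tr, n_trials=spec.n_trials,
    )
    session = coh.simulate_bold(truth, schedule, spec)
    betas = glm.lss_betas(session.data, schedule)
    labels = np.asarray(schedule.fingers())
    V = spec.n_voxels
    sets = {
        "contralateral": betas.betas[:, :V],
        "bilateral": betas.betas,
    }
    accs = {}
    for name, B in sets.items():
        ps = mvpa.normalize_patterns(
            mvpa.TrialPatternSet(betas=B, labels=labels)
        )
        accs[name] = mvpa.decode_fingers(ps, folds=4, seed=seed * 7 + i)
    acc_boost = mvpa.accuracy_boost(accs["bilateral"], accs["contralateral"])
    return {
        "participant": i,
        "age": truth.age,
        "acc_contralateral": accs["contralateral"],
        "acc_bilateral": accs["bilateral"],
        "acc_boost": acc_boost,
        "included": mvpa.chance_filter(accs["bilateral"]),
    }


def _mvpa_report(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    spec = config.cohort_spec()
    rows = [
        _mvpa_subject(spec, i, config.seed)
        for i in range(spec.n_subjects)
    ]
    table = pd.DataFrame(rows)
    inc = table[table["included"]]
    report: dict = {
        "n": int(len(table)),
        "n_included": int(len(inc)),
        "mean_acc_contralateral": float(table["acc_contralateral"].mean()),
        "mean_acc_bilateral": float(table["acc_bilateral"].mean()),
        "chance_pct": config.chance_pct,
    }
    if len(inc) >= 10:
        age_inc = stats.age_terms(inc["age"].to_numpy())
        for col in ("acc_contralateral", "acc_bilateral", "acc_boost"):
            res = stats.age_effect(inc[col].to_numpy(), age_inc)
            report[f"age_effect_{col}"] = _stat_to_dict(res)
    return table, report


def run_experiment(config: PipelineConfig) -> dict:
    """Run the configured pipeline; returns (and optionally writes) a bundle.

    The bundle maps stage names to tables/reports; a ``manifest`` entry
    records the config, derived seeds, thresholds and per-stage timing.
    Stage failures are caught and recorded as machine-readable error
    entries so a partial bundle is still returned.
    """
    bundle: dict = {}
    manifest: dict = {
        "config": {**asdict(config), "modes": list(config.modes)},
        "thresholds": {
            "log_evidence": config.boost_threshold,
            "chance_pct": config.chance_pct,
            "alpha": config.alpha,
        },
        "timing_s": {},
        "errors": {},
    }
    t_all = time.time()

    boost_tables: dict[str, pd.DataFrame] = {}
    for mode in config.modes:
        t0 = time.time()
        try:
            table, summary = boost_mod.cohort_boost(
                config.cohort_spec(),
                mode=mode,
                n_shuffles=config.n_shuffles,
                seed=config.seed,
                per_roi_spread=(config.per_roi_spread and mode == "main"),
            )
            boost_tables[mode] = table
            bundle[f"boost_{mode}"] = {
                "table": table,
                "report": _boost_report(table, summary, config.seed),
            }
        except Exception as err:
            manifest["errors"][f"boost_{mode}"] = repr(err)
        manifest["timing_s"][f"boost_{mode}"] = round(time.time() - t0, 2)

    if "main" in boost_tables:
        table = boost_tables["main"]
        age = stats.age_terms(table["age"].to_numpy())
        for stage, fn in (
            ("univariate", _univariate_report),
            ("behavioral", _behavioral_report),
        ):
            t0 = time.time()
            try:
                bundle[stage] = fn(table, age)
            except Exception as err:
                manifest["errors"][stage] = repr(err)
            manifest["timing_s"][stage] = round(time.time() - t0, 2)

    if config.run_mvpa and config.experiment == "free_selection":
        t0 = time.time()
        try:
            mvpa_table, mvpa_rep = _mvpa_report(config)
            bundle["mvpa"] = {"table": mvpa_table, "report": mvpa_rep}
        except Exception as err:
            manifest["errors"]["mvpa"] = repr(err)
        manifest["timing_s"]["mvpa"] = round(time.time() - t0, 2)

    manifest["timing_s"]["total"] = round(time.time() - t_all, 2)
    bundle["manifest"] = manifest
    if config.output_dir is not None:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    reports: dict = {}
    for key, val in bundle.items():
        if isinstance(val, dict) and isinstance(val.get("table"), pd.DataFrame):
            val["table"].to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
            reports[key] = _jsonable(
                {k: v for k, v in val.items() if k != "table"}
            )
        else:
            reports[key] = _jsonable(val)
    with open(outdir / "report.json", "w") as fh:
        json.dump(reports, fh, indent=2)


def make_fixture(size: str = "tiny", **overrides) -> PipelineConfig:
    """Deterministic packaged test cohorts.

    ``tiny``: 12 subjects x 16 voxels/ROI x 120 scans (fast CI runs);
    ``standard``: 100 subjects x 70 voxels/ROI x full-length runs.
    """
    if size == "tiny":
        cfg = PipelineConfig(
            n_subjects=12, n_voxels=16, n_scans=120, n_trials=40, seed=1,
            n_shuffles=4,
        )
    elif size == "standard":
        cfg = PipelineConfig(
            n_subjects=100, n_voxels=70, n_scans=None, n_trials=None,
            seed=1, n_shuffles=20,
        )
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    return replace(cfg, **overrides)
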