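"""End-to-end pipeline: simulate/read -> filter -> transform -> features ->
select -> search -> evaluate -> lead time.

Each stage reads its inputs from and writes its artefacts to a run
directory, so stages can be rerun in isolation; ``run_pipeline`` executes
them in order and finishes with a MANIFEST listing every artefact with its
SHA-256 checksum.  A single global seed expands to per-stage seeds by fixed
offsets (simulation +0, selection +1, evaluation bootstrap +2), so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as co
from . import evaluate as ev
from . import indices as ix
from . import leadtime as lt
from . import models as mo
from . import selection as se
from . import simulate as sim

logger = logging.getLogger(__name__)

SEED_OFFSETS = {"simulate": 0, "select": 1, "evaluate": 2}


@dataclass
class RunConfig:
    out_dir: str = "run"
    cohort_path: str | None = None  # None -> simulate
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    selection: se.SelectionConfig = field(default_factory=se.SelectionConfig)
    specificities: tuple[float, ...] = ev.DEFAULT_SPECIFICITIES
    strata: tuple[str, ...] = ("all", "TypeII")
    windows: tuple[str, ...] = ("within_1yr", "yr1_to_2")
    spec_unit: str = "visit"
    ranking_criterion: str = "cv_sens_at_spec"
    ranking_target: float = 0.903
    top_k: int = 5
    bootstrap_B: int = 2000
    reference_feature: str = "CA125{5}"
    index1_variant: str = "mean"
    index2_variant: str = "trapezoid"
    loess_span: float = lt.DEFAULT_SPAN
    seed: int = 0

    def __post_init__(self):
        for s in self.specificities:
            if not 0 < s < 1:
                raise ValueError(f"specificity {s} outside (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["specificities"] = list(self.specificities)
        d["strata"] = list(self.strata)
        d["windows"] = list(self.windows)
        return d


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "sim" in kwargs:
        simkw = dict(kwargs["sim"])
        if "markers" in simkw:
            simkw["markers"] = [sim.MarkerKinetics(**m) for m in simkw["markers"]]
        kwargs["sim"] = sim.SimConfig(**simkw)
    if "selection" in kwargs:
        kwargs["selection"] = se.SelectionConfig(**kwargs["selection"])
    for key in ("specificities", "strata", "windows"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(RunConfig)}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    simcfg = dataclasses.replace(cfg.sim,
                                 seed=cfg.seed + SEED_OFFSETS["simulate"])
    cohort, truth = sim.generate_cohort(simcfg)
    co.write_cohort(cohort, run_dir / "cohort.csv")
    (run_dir / "ground_truth.json").write_text(truth.to_json() + "\n")


def _load_modelling_cohort(cfg: RunConfig, run_dir: Path) -> co.CohortSet:
    path = Path(cfg.cohort_path) if cfg.cohort_path else run_dir / "cohort.csv"
    cohort = co.read_cohort(path)
    for marker_feature in [cfg.reference_feature]:
        marker, _ = ix.parse_feature_name(marker_feature)
        if marker not in cohort.markers:
            raise ValueError(f"unknown marker {marker!r} in model spec "
                             f"{marker_feature!r}")
    return co.log10_transform(co.modelling_filter(cohort))


def _matrices(cfg: RunConfig, cohort: co.CohortSet, window: str,
              stratum: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(terminal, rolling) feature matrices for one window and stratum."""
    sub = co.evaluation_subset(cohort, window)
    if stratum == "TypeII":
        sub = co.CohortSet(
            subjects=[s for s in sub.subjects
                      if not s.is_case or s.tumour_type == "TypeII"],
            markers=sub.markers, provenance=sub.provenance, scale=sub.scale)
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}")
    kw = dict(index1_variant=cfg.index1_variant,
              index2_variant=cfg.index2_variant)
    terminal = ix.build_feature_matrix(sub, mode="terminal", **kw)
    rolling = ix.build_feature_matrix(sub, mode="rolling", **kw)
    return terminal, rolling


def stage_features(cfg: RunConfig, run_dir: Path) -> None:
    cohort = _load_modelling_cohort(cfg, run_dir)
    terminal, rolling = _matrices(cfg, cohort, "within_1yr", "all")
    terminal.to_csv(run_dir / "features_terminal.csv")
    rolling.to_csv(run_dir / "features_rolling.csv")


def _read_fm(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="unit_id", dtype={"subject_id": str})


def stage_select(cfg: RunConfig, run_dir: Path) -> None:
    fm = _read_fm(run_dir / "features_terminal.csv")
    selcfg = dataclasses.replace(cfg.selection,
                                 seed=cfg.seed + SEED_OFFSETS["select"])
    report = se.select_features(fm, selcfg)
    report.to_csv(run_dir / "selection_report.csv")
    pool = se.consensus_pool(report, selcfg)
    _write_json({"pool": pool, "lasso_lambda": report.lasso_lambda,
                 "config": dataclasses.asdict(selcfg)},
                run_dir / "selection_pool.json")


def stage_search(cfg: RunConfig, run_dir: Path) -> None:
    fm = _read_fm(run_dir / "features_terminal.csv")
    pool = json.loads((run_dir / "selection_pool.json").read_text())["pool"]
    results = mo.search_models(fm, pool, criterion=cfg.ranking_criterion,
                               target=cfg.ranking_target,
                               targets=cfg.specificities)
    mo.ranking_table(results).to_csv(run_dir / "model_ranking.csv", index=False)
    top = results[:cfg.top_k]
    fitted = {r.spec.name: mo.fit_logistic(r.spec, fm) for r in top}
    ref_spec = mo.ModelSpec((cfg.reference_feature,))
    fitted[ref_spec.name] = mo.fit_logistic(ref_spec, fm)
    _write_json({name: f.to_dict() for name, f in sorted(fitted.items())},
                run_dir / "fitted_models.json")


def _load_fitted(run_dir: Path) -> dict[str, mo.FittedModel]:
    raw = json.loads((run_dir / "fitted_models.json").read_text())
    out = {}
    for name, d in raw.items():
        out[name] = mo.FittedModel(
            spec=mo.ModelSpec(tuple(d["features"])),
            intercept=d["intercept"], coefficients=d["coefficients"],
            n=d["n"], converged=d["converged"], separation=d["separation"],
            loglik=float("nan"))
    return out


def stage_evaluate(cfg: RunConfig, run_dir: Path) -> None:
    cohort = _load_modelling_cohort(cfg, run_dir)
    fitted = _load_fitted(run_dir)
    reference = fitted[cfg.reference_feature]
    rows = []
    summaries = {}
    for window in cfg.windows:
        for stratum in cfg.strata:
            terminal, rolling = _matrices(cfg, cohort, window, stratum)
            fm_eval = rolling if cfg.spec_unit == "visit" else terminal
            for name in sorted(fitted):
                summary = ev.evaluate_model(
                    fitted[name], fm_eval,
                    reference=reference, spec_unit=cfg.spec_unit,
                    targets=cfg.specificities, bootstrap_B=cfg.bootstrap_B,
                    seed=cfg.seed + SEED_OFFSETS["evaluate"])
                summaries[f"{window}/{stratum}/{name}"] = summary.to_dict()
                row = {
                    "window": window, "stratum": stratum, "model": name,
                    "n_cases": summary.n_cases,
                    "auc": round(summary.auc, 6),
                    "auc_ci_lo": round(summary.auc_ci[0], 6),
                    "auc_ci_hi": round(summary.auc_ci[1], 6),
                    "hl_p": None if summary.hl_p is None
                            else round(summary.hl_p, 6),
                }
                for t, pt in summary.points.items():
                    row[f"sens@{t:g}"] = round(pt.sensitivity, 6)
                    row[f"sens@{t:g}_ci_lo"] = round(pt.ci.lo, 6)
                    row[f"sens@{t:g}_ci_hi"] = round(pt.ci.hi, 6)
                    row[f"mcnemar_p@{t:g}"] = (
                        None if pt.mcnemar_p is None else round(pt.mcnemar_p, 8))
                rows.append(row)
    pd.DataFrame(rows).to_csv(run_dir / "performance.csv", index=False)
    _write_json(summaries, run_dir / "performance.json")


def stage_leadtime(cfg: RunConfig, run_dir: Path) -> None:
    cohort = _load_modelling_cohort(cfg, run_dir)
    fitted = _load_fitted(run_dir)
    reference = fitted[cfg.reference_feature]
    ranking = pd.read_csv(run_dir / "model_ranking.csv")
    top_name = ranking["name"].iloc[0]
    model = fitted[top_name]

    # thresholds at the primary specificity from within-1yr control visits
    _, rolling = _matrices(cfg, cohort, "within_1yr", "all")
    ctrl = rolling[rolling["label"] == 0]
    target = cfg.specificities[0]
    out = {"span": cfg.loess_span, "target_specificity": target,
           "model": top_name, "reference": cfg.reference_feature}
    curves = {}
    for key, fit in (("model", model), ("reference", reference)):
        thr = ev.threshold_at_specificity(fit.predict(ctrl).values, target)
        # pooled case points: per-visit score vs years to diagnosis
        case_rows = rolling[rolling["label"] == 1]
        scores = fit.predict(case_rows)
        times = []
        for uid in scores.index:
            sid = case_rows.loc[uid, "subject_id"]
            age = case_rows.loc[uid, "visit_age"]
            subj = cohort.subject(sid)
            visit = min(subj.visits, key=lambda v: abs(v.age_years - age))
            times.append(visit.months_to_diagnosis / 12.0)
        curve = lt.fit_trajectory(zip(times, scores.values),
                                  span=cfg.loess_span)
        cross = lt.crossing_time(curve, thr)
        curves[key] = (curve, thr)
        out[key + "_threshold"] = thr
        out[key + "_crossing_years"] = cross.crossing_time
    gain = lt.lead_time_gain(curves["model"][0], curves["reference"][0],
                             curves["model"][1], curves["reference"][1])
    out["lead_time_gain_months"] = gain
    _write_json(out, run_dir / "leadtime.json")


STAGES = {
    "simulate": stage_simulate,
    "features": stage_features,
    "select": stage_select,
    "search": stage_search,
    "evaluate": stage_evaluate,
    "leadtime": stage_leadtime,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all stages in order and write the MANIFEST; returns the run dir."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    cfg_dict.pop("out_dir")  # the run directory itself; keeps reruns of the
    # same analysis byte-identical wherever they are written
    _write_json(cfg_dict, run_dir / "config.json")
    order = list(STAGES)
    if cfg.cohort_path is not None:
        order.remove("simulate")
    completed = []
    try:
        for name in order:
            logger.info("pipeline: stage %s", name)
            STAGES[name](cfg, run_dir)
            completed.append(name)
    except Exception:
        _write_json({"failed_stage": order[len(completed)],
                     "completed": completed},
                    run_dir / "MANIFEST.json")
        raise
    files = sorted(p.name for p in run_dir.iterdir()
                   if p.is_file() and p.name != "MANIFEST.json")
    _write_json({
        "stages": completed,
        "seed": cfg.seed,
        "checksums": {name: _sha256(run_dir / name) for name in files},
    }, run_dir / "MANIFEST.json")
    return run_dir
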