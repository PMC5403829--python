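"""End-to-end analysis pipeline.

Stages (canonical order): ``simulate`` a synthetic cohort (or start from
equivalently formatted CSV exports), ``clean`` the sleep records into
timelines and compliance scores, extract session ``features``, run device
``qc``, ``select`` the metric features by exhaustive BIC wrapper, ``score``
mental acuity per session, ``fit`` the unified model of performance at group
and individual level, and ``report`` the results.  Every stage reads and
writes plain CSV/JSON artifacts under one output directory, stamped with a
config hash and seed so re-runs are reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import actigraphy, cognition, cohort, metric, ump
from ._version import __version__
from .errors import ConfigurationError, DependencyError

log = logging.getLogger("sleepacuity")

STAGES = ("simulate", "clean", "features", "qc", "select", "score", "fit", "report")

__all__ = ["PipelineConfig", "run", "STAGES"]


@dataclass
class CleaningConfig:
    merge_gap_h: float = 1.5
    merge_gap_low_hr_h: float = 3.0
    hr_coverage: float = 0.85
    main_sleep_min_h: float = 3.0
    no_sleep_days: int = 3
    hr_floor: float = 0.5


@dataclass
class FeatureConfig:
    lapse_ms: float = 500.0
    distracted_ms: float = 1250.0
    min_questions: int = 5
    training_half_lives: tuple = (0.67, 1.5, 2.6)


@dataclass
class SelectionConfig:
    correlation_threshold: float = 0.9
    cv_folds: int = 5
    min_assessments: int = 3
    required_prefixes: tuple = ("pvt",)
    max_columns: int = 20
    use_selected_metric: bool = False


@dataclass
class FittingConfig:
    n_starts: int = 8
    n_iter: int = 3
    cross_validate: bool = True
    max_nfev: int | None = None


@dataclass
class PipelineConfig:
    outdir: str = "acuity_run"
    seed: int = 0
    cohort: cohort.CohortSpec = field(default_factory=cohort.CohortSpec)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)

    def validate(self) -> None:
        self.cohort.validate()
        for name in ("merge_gap_h", "merge_gap_low_hr_h", "hr_coverage", "main_sleep_min_h"):
            if getattr(self.cleaning, name) <= 0:
                raise ConfigurationError(f"cleaning.{name} must be positive")
        for name in ("lapse_ms", "distracted_ms"):
            if getattr(self.features, name) <= 0:
                raise ConfigurationError(f"features.{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["device_mix"] = [dataclasses.asdict(x) if not isinstance(x, dict) else x
                                     for x in self.cohort.device_mix]
        return d

    def config_hash(self) -> str:
        payload = yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=str)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        co = dict(d.pop("cohort", {}))
        if "device_mix" in co:
            co["device_mix"] = tuple(
                cohort.DeviceModel(**x) if isinstance(x, dict) else x for x in co["device_mix"]
            )
        if "session_windows" in co:
            co["session_windows"] = tuple(tuple(w) for w in co["session_windows"])
        if "param_ranges" in co:
            co["param_ranges"] = {k: tuple(v) for k, v in co["param_ranges"].items()}
        kw = {
            "cohort": cohort.CohortSpec(**co),
            "cleaning": CleaningConfig(**d.pop("cleaning", {})),
            "features": FeatureConfig(**d.pop("features", {})),
            "selection": SelectionConfig(**d.pop("selection", {})),
            "fitting": FittingConfig(**d.pop("fitting", {})),
        }
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _dirs(config: PipelineConfig) -> dict[str, Path]:
    root = Path(config.outdir)
    return {name: root / name for name in
            ("raw", "clean", "features", "qc", "select", "score", "fit", "report")}


def _require(stage: str, *paths: Path) -> None:
    for p in paths:
        if not p.exists():
            raise DependencyError(
                f"stage {stage!r} is missing upstream artifact {p}; run its producer first"
            )


def _pids(raw: Path) -> list[str]:
    return sorted(p.stem.replace("sessions_", "") for p in raw.glob("sessions_*.csv"))


def _read_events(path: Path) -> list[actigraphy.SleepEvent]:
    df = pd.read_csv(path)
    return [
        actigraphy.SleepEvent(
            start=row["start"], end=row["end"],
            minutes_asleep=int(row["minutes_asleep"]),
            minutes_restless=int(row["minutes_restless"]),
            minutes_awake=int(row["minutes_awake"]),
        )
        for _, row in df.iterrows()
    ]


def _read_timeline(path: Path, origin) -> actigraphy.SleepWakeTimeline:
    df = pd.read_csv(path)
    tl = actigraphy.SleepWakeTimeline(origin=pd.Timestamp(origin))
    tl.intervals = [(r["state"], float(r["start_h"]), float(r["end_h"])) for _, r in df.iterrows()]
    return tl


def _stage_simulate(config: PipelineConfig, d: dict[str, Path]) -> None:
    spec = dataclasses.replace(config.cohort, seed=config.seed)
    data = cohort.generate_cohort(spec)
    cohort.write_cohort(data, d["raw"])


def _stage_clean(config: PipelineConfig, d: dict[str, Path]) -> None:
    raw, out = d["raw"], d["clean"]
    _require("clean", raw)
    out.mkdir(parents=True, exist_ok=True)
    cc = config.cleaning
    rows = []
    exclusions = {}
    for pid in _pids(raw):
        minutes = pd.read_csv(raw / f"minutes_{pid}.csv", parse_dates=["timestamp"])
        events = _read_events(raw / f"sleep_{pid}.csv")
        sessions = pd.read_csv(raw / f"sessions_{pid}.csv", parse_dates=["stimulus_time"])
        merged = actigraphy.merge_fragmented_events(
            events, minutes, gap_h=cc.merge_gap_h,
            gap_low_hr_h=cc.merge_gap_low_hr_h, hr_coverage=cc.hr_coverage,
        )
        start = minutes["timestamp"].min().normalize()
        end = minutes["timestamp"].max() + pd.Timedelta(minutes=1)
        timeline = actigraphy.build_timeline(merged, (start, end))
        pd.DataFrame(
            [{"state": s, "start_h": a, "end_h": b} for s, a, b in timeline.intervals]
        ).to_csv(out / f"timeline_{pid}.csv", index=False)
        comp = actigraphy.compliance_report(
            minutes, merged, sessions, (start, end),
            n_days=config.cohort.n_days,
            sessions_per_day=config.cohort.sessions_per_day,
            questions_per_assessment=config.cohort.questions_per_assessment,
            pvt_minutes=config.cohort.pvt_minutes,
        )
        comp["participant_id"] = pid
        rows.append(comp)
        flags = actigraphy.flag_exclusions(
            minutes, merged, (start, end),
            no_sleep_days=cc.no_sleep_days, hr_floor=cc.hr_floor,
        )
        if flags:
            exclusions[pid] = flags
    pd.DataFrame(rows).set_index("participant_id").to_csv(out / "compliance.csv")
    (out / "exclusions.json").write_text(json.dumps(exclusions, indent=1))


def _stage_features(config: PipelineConfig, d: dict[str, Path]) -> None:
    raw, out = d["raw"], d["features"]
    _require("features", raw)
    out.mkdir(parents=True, exist_ok=True)
    origin = config.cohort.origin
    for pid in _pids(raw):
        sessions = pd.read_csv(raw / f"sessions_{pid}.csv", parse_dates=["stimulus_time"])
        fm = cognition.build_feature_matrix(sessions, origin)
        fm.to_csv(out / f"features_{pid}.csv")


def _stage_qc(config: PipelineConfig, d: dict[str, Path]) -> None:
    raw, out = d["raw"], d["qc"]
    _require("qc", raw)
    out.mkdir(parents=True, exist_ok=True)
    frames = [pd.read_csv(raw / f"sessions_{pid}.csv") for pid in _pids(raw)]
    allr = pd.concat(frames, ignore_index=True)
    pvt = allr[(allr["assessment"] == "pvt") & allr["rt_ms"].notna()]
    groups = {dev: g["rt_ms"].to_numpy() for dev, g in pvt.groupby("device") if len(g) >= 5}
    result: dict = {"n_rts": int(len(pvt))}
    if len(groups) >= 2:
        test = cognition.device_bias_test(groups)
        result["kruskal"] = {
            "H": test["H"], "p": test["p"],
            "pairwise": {f"{a}|{b}": p for (a, b), p in test["pairwise"].items()},
        }
    spacing = {}
    for dev, rts in groups.items():
        if len(rts) >= 200:
            spacing[dev] = cognition.detect_discretization(rts)
    result["discretization_ms"] = spacing
    (out / "qc_devices.json").write_text(json.dumps(result, indent=1))


def _prior_night_minutes(timeline: actigraphy.SleepWakeTimeline, times_h, main_min_h: float) -> np.ndarray:
    """Minutes asleep in the most recent main sleep interval before each time."""
    sleeps = [(a, b) for s, a, b in timeline.intervals if s == "sleep" and (b - a) >= main_min_h]
    out = np.full(len(times_h), np.nan)
    for i, t in enumerate(times_h):
        prior = [(a, b) for a, b in sleeps if b <= t]
        if prior:
            a, b = prior[-1]
            out[i] = (b - a) * 60.0
    return out


def _stage_select(config: PipelineConfig, d: dict[str, Path]) -> None:
    feats, clean, out = d["features"], d["clean"], d["select"]
    _require("select", feats, clean)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.selection
    mats, targets = [], []
    for pid in _pids(d["raw"]):
        fm = pd.read_csv(feats / f"features_{pid}.csv", index_col="time_h")
        tl = _read_timeline(clean / f"timeline_{pid}.csv", config.cohort.origin)
        target = _prior_night_minutes(tl, fm.index.to_numpy(), config.cleaning.main_sleep_min_h)
        mats.append(fm)
        targets.append(target)
    matrix = pd.concat(mats, axis=0)
    target = np.concatenate(targets)
    pruned = metric.prune_features(matrix, sc.correlation_threshold)
    # drop near-constant survivors: no variance to regress on
    cols = [c for c in pruned.columns if "." in c]
    keep = [c for c in cols if np.nanstd(pruned[c].to_numpy(dtype=float)) > 1e-9]
    pruned = pruned[keep]
    if len(keep) > sc.max_columns:
        order = {c: abs(pd.Series(pruned[c]).corr(pd.Series(target))) for c in keep}
        keep = sorted(sorted(keep), key=lambda c: -(order[c] if np.isfinite(order[c]) else 0))
        pruned = pruned[keep[: sc.max_columns]]
    ranked = metric.wrapper_search(
        pruned, target, cv_folds=sc.cv_folds, seed=config.seed, max_columns=sc.max_columns
    )
    pd.DataFrame(
        [{"features": "+".join(r.features), "bic": r.bic, "cv_rmse": r.cv_rmse} for r in ranked]
    ).to_csv(out / "wrapper_ranking.csv", index=False)
    try:
        definition = metric.select_final(
            ranked, matrix, min_assessments=sc.min_assessments,
            required_prefixes=tuple(sc.required_prefixes),
        )
        (out / "metric_definition.json").write_text(json.dumps(definition.to_dict(), indent=1))
    except metric.SelectionError as exc:  # pragma: no cover - data dependent
        log.warning("selection failed: %s", exc)
        (out / "metric_definition.json").write_text(json.dumps({"error": str(exc)}))


def _score_definition(config: PipelineConfig, d: dict[str, Path]) -> metric.MetricDefinition:
    if config.selection.use_selected_metric:
        path = d["select"] / "metric_definition.json"
        _require("score", path)
        payload = json.loads(path.read_text())
        if "features" in payload:
            return metric.MetricDefinition.from_dict(payload)
        log.warning("falling back to the published metric definition")
    return metric.reference_definition()


def _stage_score(config: PipelineConfig, d: dict[str, Path]) -> None:
    feats, out = d["features"], d["score"]
    _require("score", feats)
    out.mkdir(parents=True, exist_ok=True)
    definition = _score_definition(config, d)
    n_excl = cognition.sessions_to_exclude(config.features.training_half_lives)
    for pid in _pids(d["raw"]):
        fm = pd.read_csv(feats / f"features_{pid}.csv", index_col="time_h")
        rows = []
        for t, row in fm.iterrows():
            rows.append({
                "time_h": t,
                "session_id": row["session_id"],
                "session_index": int(row["session_index"]),
                "score": metric.mental_acuity(row, definition),
                "usable": int(row["session_index"]) >= n_excl,
            })
        pd.DataFrame(rows).to_csv(out / f"acuity_{pid}.csv", index=False)


def _stage_fit(config: PipelineConfig, d: dict[str, Path]) -> None:
    score, clean, out = d["score"], d["clean"], d["fit"]
    _require("fit", score, clean)
    out.mkdir(parents=True, exist_ok=True)
    fc = config.fitting
    exclusions = json.loads((clean / "exclusions.json").read_text()) if (clean / "exclusions.json").exists() else {}
    datasets = {}
    for pid in _pids(d["raw"]):
        if pid in exclusions:
            log.warning("excluding %s from modeling: %s", pid, exclusions[pid])
            continue
        ac = pd.read_csv(score / f"acuity_{pid}.csv")
        ac = ac[ac["usable"] == 1]
        tl = _read_timeline(clean / f"timeline_{pid}.csv", config.cohort.origin)
        if len(ac) < 8 or not any(s == "sleep" for s, _, _ in tl.intervals):
            log.warning("excluding %s: insufficient usable data", pid)
            continue
        datasets[pid] = (ac["time_h"].to_numpy(), ac["score"].to_numpy(), tl)

    summary_rows = []
    group = ump.fit_group(
        list(datasets.values()), n_starts=fc.n_starts, seed=config.seed, max_nfev=fc.max_nfev
    ) if len(datasets) >= 1 else None
    for pid, (t, s, tl) in datasets.items():
        res = ump.fit(np.column_stack([t, s]), tl, n_starts=fc.n_starts,
                      seed=config.seed, max_nfev=fc.max_nfev)
        payload = res.to_dict()
        del payload["cost"]
        if fc.cross_validate and len(np.unique(np.floor(t / 24))) >= 4:
            cv = ump.cross_validate_individual(
                t, s, tl, n_iter=fc.n_iter, seed=config.seed,
                n_starts=fc.n_starts, max_nfev=fc.max_nfev,
            )
            payload["cv_fit_quality"] = cv.pooled_fit_quality
        if group is not None:
            gp = ump.predict(group.params, tl, t)
            payload["group_fit_quality"] = ump.fit_quality(s, gp)
        (out / f"fit_{pid}.json").write_text(json.dumps(payload, indent=1))
        summary_rows.append({
            "participant_id": pid, "n_obs": res.n_obs, "rmse": res.rmse,
            "fit_quality": res.fit_quality,
            "group_fit_quality": payload.get("group_fit_quality", float("nan")),
            "cv_fit_quality": payload.get("cv_fit_quality", float("nan")),
            "converged": res.converged,
        })
    if group is not None:
        gpayload = group.to_dict()
        del gpayload["cost"]
        if fc.cross_validate and len(datasets) >= 3:
            gcv = ump.cross_validate_group(
                datasets, n_iter=fc.n_iter, seed=config.seed,
                n_starts=fc.n_starts, max_nfev=fc.max_nfev,
            )
            gpayload["cv_fit_quality"] = gcv.pooled_fit_quality
        (out / "fit_group.json").write_text(json.dumps(gpayload, indent=1))
        summary_rows.append({
            "participant_id": "GROUP", "n_obs": group.n_obs, "rmse": group.rmse,
            "fit_quality": group.fit_quality,
            "group_fit_quality": group.fit_quality,
            "cv_fit_quality": gpayload.get("cv_fit_quality", float("nan")),
            "converged": group.converged,
        })
    pd.DataFrame(summary_rows).to_csv(out / "fit_summary.csv", index=False)


def _stage_report(config: PipelineConfig, d: dict[str, Path]) -> None:
    fit, clean, out = d["fit"], d["clean"], d["report"]
    _require("report", fit / "fit_summary.csv", clean / "compliance.csv")
    out.mkdir(parents=True, exist_ok=True)
    summary = pd.read_csv(fit / "fit_summary.csv")
    compliance = pd.read_csv(clean / "compliance.csv")
    individual = summary[summary["participant_id"] != "GROUP"]
    group = summary[summary["participant_id"] == "GROUP"]
    group_fq = float(group["fit_quality"].iloc[0]) if len(group) else float("nan")

    # per-participant timeline plot data: observations, predictions, sleep spans
    group_params = None
    if (fit / "fit_group.json").exists():
        group_params = ump.UMPParams(**json.loads((fit / "fit_group.json").read_text())["params"])
    for pid in individual["participant_id"]:
        ac = pd.read_csv(d["score"] / f"acuity_{pid}.csv")
        tl = _read_timeline(clean / f"timeline_{pid}.csv", config.cohort.origin)
        params = ump.UMPParams(**json.loads((fit / f"fit_{pid}.json").read_text())["params"])
        t = ac["time_h"].to_numpy()
        frame = pd.DataFrame({
            "time_h": t, "score": ac["score"], "usable": ac["usable"],
            "individual_pred": ump.predict(params, tl, t),
        })
        if group_params is not None:
            frame["group_pred"] = ump.predict(group_params, tl, t)
        frame.to_csv(out / f"timeline_{pid}.csv", index=False)

    payload = {
        "compliance": compliance.to_dict(orient="records"),
        "fit_quality": {
            "individual": dict(zip(individual["participant_id"], individual["fit_quality"])),
            "group": group_fq,
            "median_individual": float(individual["fit_quality"].median()) if len(individual) else float("nan"),
            "n_individual_above_group": int((individual["fit_quality"] > group_fq).sum())
            if np.isfinite(group_fq) else None,
        },
    }
    (out / "report.json").write_text(json.dumps(payload, indent=1))
    lines = ["# Mental-acuity pipeline report", "", "## Compliance (% of ideal)", ""]
    lines.append(compliance.to_string(index=False))
    lines += ["", "## Fit quality (SD of scores / model RMSE; 1 = sleep-independent constant)", ""]
    lines.append(summary.to_string(index=False))
    (out / "report.md").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "clean": _stage_clean,
    "features": _stage_features,
    "qc": _stage_qc,
    "select": _stage_select,
    "score": _stage_score,
    "fit": _stage_fit,
    "report": _stage_report,
}


def run(config: PipelineConfig, stages=("all",)) -> dict:
    """Execute pipeline stages in canonical order; returns the run manifest."""
    config.validate()
    if "all" in stages:
        wanted = list(STAGES)
    else:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        wanted = [s for s in STAGES if s in stages]
    d = _dirs(config)
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    for stage in wanted:
        t0 = time.perf_counter()
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, d)
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
    manifest_path = Path(config.outdir) / "manifest.json"
    existing = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    if existing.get("config_hash") == manifest["config_hash"]:
        existing.get("stages", {}).update(manifest["stages"])
        manifest["stages"] = {**existing.get("stages", {}), **manifest["stages"]}
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
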