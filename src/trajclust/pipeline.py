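"""End-to-end orchestration: simulate/ingest -> filter -> cluster -> report.

``run_pipeline`` threads one configuration object through every stage and
writes a self-contained run directory: the cohort-flow accounting, the
processed trajectory matrix, the elbow scan, the fitted cluster model,
per-user outcomes, the cross-sectional comparison report and the weekly
effect-size report, plus a manifest with the configuration, seed and a
hash of every artifact.  Identical configuration and seed produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as cl
from . import cohort as ch
from . import outcomes as oc
from . import preprocess as pp
from . import stats as st
from . import synth as sy

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("trajclust")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; all fields have working defaults."""

    input_path: str | None = None  # lifelog JSONL; None -> simulate
    synth: sy.SynthConfig = field(default_factory=sy.SynthConfig)
    criteria: ch.EligibilityCriteria = field(default_factory=ch.EligibilityCriteria)
    grid_len: int = pp.GRID_LEN
    window: int = pp.SMOOTHING_WINDOW
    k: int | None = 5  # None -> use the elbow suggestion
    k_range: tuple[int, int] = (2, 10)
    run_elbow: bool = True
    seed: int = 0
    n_init: int = 5
    elbow_n_init: int = 3
    out_dir: str = "trajclust_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["archetype_weights"] = list(d["synth"]["archetype_weights"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "synth" in raw:
            raw["synth"] = sy.SynthConfig.from_dict(raw["synth"])
        if "criteria" in raw:
            c = dict(raw["criteria"])
            if "initial_window" in c:
                c["initial_window"] = tuple(c["initial_window"])
            raw["criteria"] = ch.EligibilityCriteria(**c)
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- ingest or simulate -------------------------------------------------
    truth: dict[str, str] = {}
    if config.input_path is not None:
        cohort = ch.read_lifelogs_jsonl(config.input_path)
        log.info("loaded %d lifelogs from %s", len(cohort), config.input_path)
    else:
        synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
        cohort, labels = sy.generate_cohort(synth_cfg)
        truth = {u.user_id: lab for u, lab in zip(cohort, labels)}
        if any(r > 0 for r in synth_cfg.violation_rates.values()):
            cohort, manifest = sy.inject_violations(cohort, synth_cfg)
            manifest.to_csv(out / "violations.csv", index=False)
        log.info("simulated %d lifelogs (seed %d)", len(cohort), config.seed)

    # --- eligibility --------------------------------------------------------
    included, records, flow = ch.apply_eligibility(cohort, config.criteria)
    flow.write_csv(out / "flow.csv")
    log.info("eligibility: %d of %d users included", len(included), len(cohort))
    if len(included) == 0:
        raise ch.DomainError("pipeline: no eligible users after filtering")

    # --- preprocessing ------------------------------------------------------
    matrix, processed = pp.preprocess_cohort(included, config.grid_len, config.window)
    matrix.round(9).to_csv(out / "processed_matrix.csv")
    with open(out / "processed_provenance.json", "w") as fh:
        json.dump({p.user_id: p.provenance for p in processed}, fh, sort_keys=True, indent=2)

    # --- clustering ---------------------------------------------------------
    k = config.k
    if config.run_elbow:
        lo, hi = config.k_range
        scan = cl.elbow_scan(matrix, range(lo, hi + 1), seed=config.seed,
                             n_init=config.elbow_n_init)
        scan.to_frame().to_csv(out / "elbow.csv", index=False)
        log.info("elbow scan: suggested k=%d%s", scan.suggested_k,
                 " (low confidence)" if scan.low_confidence else "")
        if k is None:
            k = scan.suggested_k
    if k is None:
        raise ch.DomainError("pipeline: k not set and elbow scan disabled")
    model = cl.kmeans_dtw(matrix, k, seed=config.seed, n_init=config.n_init)
    model.write_json(out / "cluster_model.json")
    model.assignments_frame().to_csv(out / "assignments.csv", index=False)
    log.info("k-means (k=%d): inertia %.4f after %d iterations", k, model.inertia, model.n_iter)

    # --- outcomes -----------------------------------------------------------
    rec_by_user = {r.user_id: r for r in records}
    rows = []
    classes: dict[str, str] = {}
    for u in included:
        r = rec_by_user[u.user_id]
        pct = oc.percent_change(r.initial_weight_kg, r.final_weight_kg)
        wclass = oc.classify_weight_change(pct)
        classes[u.user_id] = wclass
        rows.append({
            "user_id": u.user_id, "initial_kg": r.initial_weight_kg,
            "final_kg": r.final_weight_kg, "percent_change": round(pct, 6),
            "weight_class": wclass, "cluster": model.assignments[u.user_id],
            **({"true_archetype": truth[u.user_id]} if truth else {}),
        })
    pd.DataFrame(rows).to_csv(out / "outcomes.csv", index=False)
    oc.contingency_table(model.assignments, classes).to_csv(out / "contingency.csv")

    # --- statistics ---------------------------------------------------------
    summaries = [oc.summarize_usage(u, config.criteria.program_weeks) for u in included]
    usage = oc.usage_frame(summaries)
    usage.round(6).to_csv(out / "usage.csv")
    results, medians = st.compare_clusters_cross_sectional(usage, classes, model.assignments)
    pd.DataFrame([r.to_dict() for r in results]).to_csv(out / "cross_sectional.csv", index=False)
    medians.round(6).to_csv(out / "cluster_medians.csv", index=False)

    present = sorted(set(model.assignments.values()))
    compare = tuple(c for c in (1, 2, 3) if c in present)
    pairs = tuple(p for p in ((1, 3), (2, 3)) if p[0] in present and p[1] in present)
    weekly_path = out / "weekly_effects.csv"
    if len(compare) >= 2 and pairs:
        trajectories = st.weekly_effect_trajectory(
            summaries, model.assignments, compare, pairs,
            program_weeks=config.criteria.program_weeks)
        pd.concat([t.to_frame().assign(curve=t.comparison) for t in trajectories]).round(
            9).to_csv(weekly_path, index=False)
    else:
        pd.DataFrame().to_csv(weekly_path, index=False)
        log.info("weekly comparison skipped: fewer than 2 of clusters 1-3 present")

    # --- manifest -----------------------------------------------------------
    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": RunConfig.to_dict(config),
        "seed": config.seed,
        "n_input": len(cohort),
        "n_included": len(included),
        "k": k,
        "inertia": model.inertia,
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    log.info("run complete in %.1fs -> %s", time.time() - t0, out)
    return out
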