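"""End-to-end pipeline orchestration from a single config file.

A run executes the enabled stages in method order —
simulate -> mine -> score -> adjust -> evaluate — against one output
directory, writing each stage's standard artifact (events TSV, trajectories
JSON, scored JSON, risks TSV, evaluation report JSON) plus a run manifest
with parameters, the seed, and SHA-256 hashes of every artifact, so that
identical config + seed yields identical manifest hashes.

Per-stage seeds are derived deterministically from the single global seed.
All stage parameters default to the method's reference values: minimum
split 5 characters, at most 2 alignment gaps, match/mismatch/gap weights
2/-1/-1, 10 CV folds, 5% minimum itemset support, minimum set size 2,
condensation count 20, Bonferroni family level 25%, 1,000 holdout patients.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import confounder_adjustment, info_scoring, prediction_eval
from .event_model import EventStream, write_event_stream
from .synthetic_data import CohortSpec, ConfounderTriple, make_cohort
from .trajectory_miner import mine_trajectories, save_trajectories

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "derive_seed"]

STAGES = ("simulate", "mine", "score", "adjust", "evaluate")

_DEFAULTS: dict[str, dict] = {
    "simulate": {"n_patients": 2000, "spec": None},
    "mine": {"min_support": 0.05, "min_size": 2, "min_patients": 20},
    "score": {"top": 5},
    "adjust": {"pairs": "all", "min_stratum": 5, "tol": 0.01},
    "evaluate": {"holdout": 1000},
}


@dataclasses.dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    stages: list[str]
    params: dict[str, dict]

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r} (expected subset of {STAGES})")


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline config; unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {"seed", "out_dir", "stages", *STAGES}
    for key in raw:
        if key not in known_top:
            raise ValueError(f"unknown config key {key!r}")
    params = {}
    for stage in STAGES:
        block = dict(_DEFAULTS[stage])
        for key, val in (raw.get(stage) or {}).items():
            if key not in block:
                raise ValueError(f"unknown config key {stage}.{key!r}")
            block[key] = val
        params[stage] = block
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "trajmine_run")),
        stages=list(raw.get("stages", STAGES)),
        params=params,
    )


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from the single global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_cohort_spec(n_patients: int, seed: int) -> CohortSpec:
    """The reference synthetic cohort: a branching acyclic Markov chain plus
    one pure-confounder triple and a terminal death event."""
    # Three mutually exclusive entry concepts, each opening a chain whose
    # node probabilities (given the entry) step down in tiers staggered
    # across chains — 0.85/0.65/0.45/0.25, 0.75/0.55/0.35/0.15 and
    # 0.85/0.65/0.45 — so the cohort exhibits the full range of downstream
    # risks and no concept is universal (as in a real cohort): sequential
    # structure, not marginal frequency, carries the signal. Confounder and
    # death prevalences sit low enough that their chance co-occurrence with
    # chain concepts stays below the 5% mining support, as chance pairings
    # do in a realistically sparse concept space.
    chain_conditionals = {
        "e0": (["a1", "a2", "a3", "a4"], (0.85, 0.65, 0.45, 0.25)),
        "e1": (["b1", "b2", "b3", "b4"], (0.75, 0.55, 0.35, 0.15)),
        "e2": (["g1", "g2", "g3"], (0.85, 0.65, 0.45)),
    }
    concepts = {c: "disease" for entry, (rest, _) in chain_conditionals.items()
                for c in [entry, *rest]}
    concepts.update({"conf_z": "disease", "conf_x": "drug",
                     "conf_y": "disease", "death": "death"})
    transition = {}
    for entry, (rest, conds) in chain_conditionals.items():
        path = [entry, *rest]
        prev = 1.0
        for frm, to, cond in zip(path, path[1:], conds):
            transition[frm] = {to: round(cond / prev, 6)}
            prev = cond
    return CohortSpec(
        n_patients=n_patients,
        concepts=concepts,
        initial_distribution={"e0": 0.35, "e1": 0.35, "e2": 0.30},
        transition_matrix=transition,
        confounder_triples=[
            ConfounderTriple(
                z="conf_z", x="conf_x", y="conf_y",
                p_x_given_z=0.75, p_y_given_z=0.65, p_direct=0.0,
                p_z=0.14, p_x_base=0.15, p_y_base=0.1,
            )
        ],
        death_concept="death",
        p_death=0.08,
        seed=seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    stream: EventStream | None = None
    trajectories = None

    if "simulate" in config.stages:
        p = config.params["simulate"]
        spec = p["spec"] or default_cohort_spec(
            p["n_patients"], derive_seed(config.seed, "simulate")
        )
        stream, truth = make_cohort(spec)
        write_event_stream(stream, out / "events.tsv")
        truth_json = {
            k: ([dataclasses.asdict(t) for t in v]
                if k == "confounder_triples" else v)
            for k, v in truth.items()
        }
        (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
        manifest["stages"]["simulate"] = {"n_patients": spec.n_patients,
                                          "seed": spec.seed}
        manifest["outputs"]["events.tsv"] = _sha256(out / "events.tsv")
        manifest["outputs"]["truth.json"] = _sha256(out / "truth.json")

    holdout_ids: set[str] = set()
    train: EventStream | None = stream
    if "evaluate" in config.stages and stream is not None:
        n_hold = min(config.params["evaluate"]["holdout"],
                     max(1, stream.n_patients // 5))
        rng = np.random.default_rng(derive_seed(config.seed, "holdout"))
        holdout_ids = set(
            rng.choice(stream.patients, size=n_hold, replace=False)
        )
        train = EventStream(
            stream.df[~stream.df["patient_id"].isin(holdout_ids)]
        )

    if "mine" in config.stages:
        if train is None:
            raise RuntimeError("mine stage needs simulated or loaded events")
        p = config.params["mine"]
        trajectories = mine_trajectories(
            train, p["min_support"], p["min_size"], p["min_patients"]
        )
        save_trajectories(trajectories, out / "trajectories.json")
        manifest["stages"]["mine"] = {**p, "n_trajectories": len(trajectories)}
        manifest["outputs"]["trajectories.json"] = _sha256(out / "trajectories.json")

    if "score" in config.stages and trajectories is not None:
        ranked = info_scoring.rank_trajectories(
            trajectories, train, top=config.params["score"]["top"]
        )
        scored = [
            {"nodes": list(t.nodes), "total_gain_bits": g.total,
             "per_event": [dataclasses.asdict(e) for e in g.per_event]}
            for t, g in ranked
        ]
        (out / "scored.json").write_text(json.dumps(scored, indent=1))
        manifest["stages"]["score"] = dict(config.params["score"])
        manifest["outputs"]["scored.json"] = _sha256(out / "scored.json")

    if "adjust" in config.stages and trajectories is not None:
        p = config.params["adjust"]
        pairs = set()
        for t in trajectories:
            for i, x in enumerate(t.nodes):
                for y in t.nodes[i + 1:]:
                    pairs.add((x, y))
        lines = ["x\ty\tk\traw\tadjusted\tconfounded"]
        for x, y in sorted(pairs):
            try:
                r = confounder_adjustment.adjusted_risk(
                    x, y, trajectories, train, min_stratum=p["min_stratum"]
                )
            except ValueError:
                continue
            flag = confounder_adjustment.confounded_flag(r, p["tol"])
            lines.append(f"{x}\t{y}\t{r.k}\t{r.raw:.6f}\t{r.adjusted:.6f}\t{flag}")
        (out / "risks.tsv").write_text("\n".join(lines) + "\n")
        manifest["stages"]["adjust"] = {**{k: v for k, v in p.items()},
                                        "n_pairs": len(lines) - 1}
        manifest["outputs"]["risks.tsv"] = _sha256(out / "risks.tsv")

    if "evaluate" in config.stages and trajectories is not None:
        holdout = EventStream(
            stream.df[stream.df["patient_id"].isin(holdout_ids)]
        )
        model, null = prediction_eval.evaluate_with_null(
            holdout, trajectories, train,
            derive_seed(config.seed, "evaluate"),
            training_patients=set(train.patients),
        )
        report = {
            "model": dataclasses.asdict(model),
            "null": dataclasses.asdict(null),
            "n_holdout_patients": len(holdout_ids),
        }
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
        manifest["stages"]["evaluate"] = {"holdout": len(holdout_ids)}
        manifest["outputs"]["report.json"] = _sha256(out / "report.json")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
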