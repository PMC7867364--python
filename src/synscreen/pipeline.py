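"""End-to-end orchestration: load -> QC -> normalize -> score -> report.

``run_pipeline`` reads a screen directory, gates plates by Z'-factor,
normalizes retained plates to percent activity, computes drug-gene
delta scores and hit calls, optionally scores a combination experiment,
and writes all tables plus a config snapshot and a plain-text summary
into the output directory. Tables are sorted on stable keys and floats
written with 6 significant digits, so re-running a config reproduces
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .interaction import DEFAULT_HIT_THRESHOLD, call_hits_frame, score_interactions_frame
from .normalization import normalize_screen
from .qc import DEFAULT_ZPRIME_THRESHOLD, GatePolicy, gate_plates, qc_screen, zprime_frame
from .screen_model import Screen, enumerate_datapoints, enumerate_pairs, load_screen
from .synergy import read_combination, score_combination, synergy_summary

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    qc_threshold: float = DEFAULT_ZPRIME_THRESHOLD
    qc_on_fail: str = "exclude"  # "exclude" | "warn"
    hit_threshold: float = DEFAULT_HIT_THRESHOLD
    require_both_readouts: bool = False
    combination_file: str | None = None
    n_permutations: int = 10_000
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    out_dir: Path
    summary: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("synscreen")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())
    try:
        return _run(config, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> PipelineResult:
    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"[{name}] {exc}") from exc

    screen: Screen = stage("load", load_screen, config.input_dir)
    design = screen.design

    z_results = stage("qc", qc_screen, screen.layouts, screen.measurements,
                      design, config.qc_threshold)
    qc_df = zprime_frame(z_results)
    _write_table(qc_df, out_dir / "qc_report.tsv")
    policy = GatePolicy(threshold=config.qc_threshold, on_fail=config.qc_on_fail)
    retained = stage("qc", gate_plates, z_results, policy)
    n_failed = len(screen.layouts) - len(retained)

    activities = stage("normalize", normalize_screen, screen.layouts,
                       screen.measurements, z_results, retained)
    _write_table(activities, out_dir / "activities.tsv")
    n_extreme = int(((activities["percent_activity"] < 0)
                     | (activities["percent_activity"] > 100)).sum())

    scores = stage("score", score_interactions_frame, activities, design)
    _write_table(scores, out_dir / "interaction_scores.tsv")
    hits = stage("score", call_hits_frame, scores, config.hit_threshold,
                 config.require_both_readouts)
    _write_table(hits, out_dir / "hits.tsv")

    synergy_text = None
    if config.combination_file:
        exp = stage("synergy", read_combination, config.combination_file)
        result = stage("synergy", score_combination, exp,
                       config.n_permutations, config.seed)
        _write_table(
            pd.DataFrame([{
                "effect_a": result.effect_a,
                "effect_b": result.effect_b,
                "effect_combo": result.effect_combo,
                "expected_additive": result.expected_additive,
                "expected_bliss": result.expected_bliss,
                "excess_additive": result.excess_additive,
                "excess_bliss": result.excess_bliss,
                "p_value_combo_vs_singles": result.p_value_combo_vs_singles,
                "p_exact": result.p_exact,
            }]),
            out_dir / "synergy_results.tsv",
        )
        synergy_text = synergy_summary(result)

    n_pairs_designed = len(enumerate_pairs(design))
    n_pairs_scored = int(scores.groupby(["compound_id", "gene_symbol"]).ngroups)
    n_points_scored = int(
        scores.groupby(["compound_id", "gene_symbol", "concentration_uM"]).ngroups
    )
    summary = {
        "plates_analyzed": len(screen.layouts),
        "plates_failed_qc": n_failed,
        "plates_retained": len(retained),
        "pairs_designed": n_pairs_designed,
        "datapoints_designed": enumerate_datapoints(design),
        "pairs_scored": n_pairs_scored,
        "datapoints_scored": n_points_scored,
        "activities_out_of_0_100": n_extreme,
        "hits_called": int(hits["is_hit"].sum()),
        "hit_threshold": config.hit_threshold,
        "qc_threshold": config.qc_threshold,
    }

    with open(out_dir / "run_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")

    lines = ["synscreen pipeline summary", "=========================="]
    lines += [f"{k}: {v}" for k, v in summary.items()]
    if synergy_text:
        lines += ["", "combination synergy", "-------------------", synergy_text]
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    for ln in lines:
        logger.info(ln)
    return PipelineResult(out_dir=out_dir, summary=summary)
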