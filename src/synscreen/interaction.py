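"""Drug-gene interaction scoring and hit selection.

The screen's interaction statistic is the delta score: percent activity
of a compound on a targeted-knockdown line minus its percent activity
on the control-shRNA line, at the same concentration and readout.
Positive delta means the compound kills the knockdown line harder than
the control line -- the additive/synergistic sensitization the screen
looks for.

Hit calling summarizes each (compound, gene) pair across readouts and
concentrations: readout deltas are averaged, the best concentration is
the one maximizing that average, and a pair is a hit when its best
delta clears the threshold (optionally requiring both readouts to clear
it individually at the best concentration). Pairs are ranked densely by
best delta, ties broken lexicographically by (gene, compound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .normalization import ActivityRecord, records_to_frame
from .screen_model import ScreenDesign

DEFAULT_HIT_THRESHOLD = 20.0  # percentage points of delta activity

SCORE_COLUMNS = [
    "compound_id", "gene_symbol", "concentration_uM", "readout",
    "activity_targeted", "activity_ctrl", "delta",
]


@dataclass(frozen=True)
class InteractionScore:
    compound_id: str
    gene_symbol: str
    concentration_uM: float
    readout: str
    activity_targeted: float
    activity_ctrl: float
    delta: float


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    gene_symbol: str
    best_delta: float
    best_concentration_uM: float
    readout_deltas: dict[str, float]  # per-readout delta at the best concentration
    concordant: bool
    is_hit: bool
    rank: int


def score_interactions_frame(
    activities: pd.DataFrame, design: ScreenDesign
) -> pd.DataFrame:
    """Delta scores as a table (vectorized pipeline path).

    ``activities`` is the normalization output. Replicate plates of the
    same line are combined by the well-count-weighted mean (equivalent
    to the unweighted mean over all replicate wells) before
    subtraction. Raises if a targeted-line record lacks its
    control-line counterpart at the same (compound, concentration,
    readout).
    """
    roles = {ln.line_id: ln.role for ln in design.lines}
    genes = {ln.line_id: ln.gene_symbol for ln in design.lines}
    df = activities.copy()
    unknown = sorted(set(df["line_id"]) - set(roles))
    if unknown:
        raise ValueError(f"activities reference unknown line_id(s): {unknown}")
    df["role"] = df["line_id"].map(roles)
    df["gene_symbol"] = df["line_id"].map(genes)

    # weighted mean over replicate plates = unweighted mean over wells
    df["wsum"] = df["percent_activity"] * df["n_replicate_wells"]
    agg = (
        df.groupby(["role", "gene_symbol", "compound_id", "concentration_uM", "readout"],
                   sort=True, as_index=False)
        .agg(wsum=("wsum", "sum"), n=("n_replicate_wells", "sum"))
    )
    agg["activity"] = agg["wsum"] / agg["n"]

    targeted = agg.loc[agg["role"] == "targeted"]
    ctrl = agg.loc[agg["role"] == "control",
                   ["compound_id", "concentration_uM", "readout", "activity"]]
    merged = targeted.merge(
        ctrl, on=["compound_id", "concentration_uM", "readout"],
        how="left", suffixes=("_targeted", "_ctrl"),
    )
    if merged["activity_ctrl"].isna().any():
        bad = merged.loc[merged["activity_ctrl"].isna()].iloc[0]
        raise ValueError(
            "no control-line activity for "
            f"(compound {bad.compound_id!r}, {bad.concentration_uM} uM, "
            f"readout {bad.readout!r}) needed by gene {bad.gene_symbol!r}"
        )
    merged["delta"] = merged["activity_targeted"] - merged["activity_ctrl"]
    out = merged[SCORE_COLUMNS].sort_values(
        ["compound_id", "gene_symbol", "concentration_uM", "readout"], kind="stable"
    )
    return out.reset_index(drop=True)


def score_interactions(
    activities: Sequence[ActivityRecord] | pd.DataFrame, design: ScreenDesign
) -> list[InteractionScore]:
    """Delta scores as records; thin wrapper over the table path."""
    if not isinstance(activities, pd.DataFrame):
        activities = records_to_frame(activities)
    df = score_interactions_frame(activities, design)
    return [
        InteractionScore(
            compound_id=r.compound_id,
            gene_symbol=r.gene_symbol,
            concentration_uM=float(r.concentration_uM),
            readout=r.readout,
            activity_targeted=float(r.activity_targeted),
            activity_ctrl=float(r.activity_ctrl),
            delta=float(r.delta),
        )
        for r in df.itertuples()
    ]


def scores_to_frame(scores: Sequence[InteractionScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores], columns=SCORE_COLUMNS)


def call_hits_frame(
    scores: pd.DataFrame,
    threshold_percent: float = DEFAULT_HIT_THRESHOLD,
    require_both_readouts: bool = False,
) -> pd.DataFrame:
    """Pair-level hit table from the delta-score table.

    Columns: compound_id, gene_symbol, best_delta, best_concentration_uM,
    one ``delta_<readout>`` column per readout (at the best
    concentration), concordant, is_hit, rank. Sorted by best_delta
    descending, ties broken by (gene_symbol, compound_id); rank is a
    dense ranking of best_delta.
    """
    if scores.empty:
        raise ValueError("no interaction scores to call hits on")
    readouts = sorted(scores["readout"].unique())
    wide = scores.pivot_table(
        index=["compound_id", "gene_symbol", "concentration_uM"],
        columns="readout", values="delta",
    ).reset_index()
    wide.columns.name = None
    delta_cols = [c for c in readouts]
    wide["mean_delta"] = wide[delta_cols].mean(axis=1)
    wide["all_above"] = (wide[delta_cols] >= threshold_percent).all(axis=1)

    # best concentration = argmax of across-readout mean delta
    # (ties resolved toward the lowest concentration)
    wide = wide.sort_values(["compound_id", "gene_symbol", "concentration_uM"],
                            kind="stable")
    idx = wide.groupby(["compound_id", "gene_symbol"], sort=True)["mean_delta"].idxmax()
    best = wide.loc[idx].copy()
    concordant = (
        wide.groupby(["compound_id", "gene_symbol"], sort=True)["all_above"]
        .any().rename("concordant").reset_index()
    )
    best = best.merge(concordant, on=["compound_id", "gene_symbol"])
    best = best.rename(
        columns={"mean_delta": "best_delta", "concentration_uM": "best_concentration_uM"}
    )
    best["is_hit"] = best["best_delta"] >= threshold_percent
    if require_both_readouts:
        best["is_hit"] &= best[delta_cols].ge(threshold_percent).all(axis=1)
    best = best.sort_values(
        ["best_delta", "gene_symbol", "compound_id"],
        ascending=[False, True, True], kind="stable",
    ).reset_index(drop=True)
    best["rank"] = best["best_delta"].rank(method="dense", ascending=False).astype(int)
    cols = (
        ["compound_id", "gene_symbol", "best_delta", "best_concentration_uM"]
        + delta_cols + ["concordant", "is_hit", "rank"]
    )
    out = best[cols].rename(columns={r: f"delta_{r}" for r in readouts})
    return out


def call_hits(
    scores: Sequence[InteractionScore] | pd.DataFrame,
    threshold_percent: float = DEFAULT_HIT_THRESHOLD,
    require_both_readouts: bool = False,
) -> list[HitCall]:
    """Hit calls as records; thin wrapper over the table path."""
    if not isinstance(scores, pd.DataFrame):
        scores = scores_to_frame(scores)
    readouts = sorted(scores["readout"].unique())
    df = call_hits_frame(scores, threshold_percent, require_both_readouts)
    return [
        HitCall(
            compound_id=r.compound_id,
            gene_symbol=r.gene_symbol,
            best_delta=float(r.best_delta),
            best_concentration_uM=float(r.best_concentration_uM),
            readout_deltas={
                ro: float(getattr(r, f"delta_{ro}")) for ro in readouts
            },
            concordant=bool(r.concordant),
            is_hit=bool(r.is_hit),
            rank=int(r.rank),
        )
        for r in df.itertuples()
    ]
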