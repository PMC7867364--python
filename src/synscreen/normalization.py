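"""Control-anchored percent-activity normalization.

For each test plate and readout, the mean of the plate's own DMSO
negative-control wells defines 0% activity and the mean of its
positive-control wells (CX-4945 at 20 uM) defines 100%:

    activity(raw) = 100 * (raw - mu_neg) / (mu_pos - mu_neg)

The map is affine in the raw signal, so any common gain/offset applied
to a plate cancels exactly, and it is direction-agnostic: the positive
control may read below (viability dyes) or above the negative control.
Values outside [0, 100] are real signal (stronger-than-control kill,
or growth stimulation) and are reported unclamped.

Replicate wells of the same (compound, concentration) on a plate are
averaged with the unweighted mean; the record carries the well count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .qc import ZPrimeResult
from .screen_model import PlateLayout, layouts_to_frame

ACTIVITY_COLUMNS = [
    "plate_id", "line_id", "compound_id", "concentration_uM",
    "readout", "n_replicate_wells", "percent_activity",
]


@dataclass(frozen=True)
class ActivityRecord:
    """Percent activity of one (compound, concentration, readout) on one plate."""

    plate_id: str
    line_id: str
    compound_id: str
    concentration_uM: float
    readout: str
    n_replicate_wells: int
    percent_activity: float


def percent_activity(raw, mu_neg: float, mu_pos: float):
    """Affine control-anchored map; accepts scalars or arrays.

    Raises if the control means coincide (no dynamic range; such a plate
    should have been excluded by QC with Z' = -inf).
    """
    if mu_neg == mu_pos:
        raise ValueError(
            "negative- and positive-control means coincide; "
            "the plate has no dynamic range (QC should have excluded it)"
        )
    return 100.0 * (np.asarray(raw, dtype=float) - mu_neg) / (mu_pos - mu_neg)


def normalize_screen(
    layouts: Sequence[PlateLayout],
    measurements: pd.DataFrame,
    z_results: Sequence[ZPrimeResult],
    retained_plates: set[str] | None = None,
) -> pd.DataFrame:
    """Activity table for all retained plates (vectorized pipeline path).

    Control means are the ones QC computed from the same plate and
    readout, so QC and normalization cannot disagree about the anchors.
    Returns one row per (plate, compound, concentration, readout); the
    control wells themselves produce no rows.
    """
    if retained_plates is None:
        retained_plates = {zr.plate_id for zr in z_results}
    anchors = pd.DataFrame(
        [
            (zr.plate_id, zr.readout, zr.mu_neg, zr.mu_pos)
            for zr in z_results
            if zr.plate_id in retained_plates
        ],
        columns=["plate_id", "readout", "mu_neg", "mu_pos"],
    )
    if not anchors.empty and (anchors["mu_neg"] == anchors["mu_pos"]).any():
        bad = anchors.loc[anchors["mu_neg"] == anchors["mu_pos"]].iloc[0]
        raise ValueError(
            f"plate {bad.plate_id!r} readout {bad.readout!r}: control means "
            "coincide; exclude the plate at QC"
        )
    lay = layouts_to_frame(layouts)
    cpd = lay.loc[
        (lay["kind"] == "compound") & lay["plate_id"].isin(retained_plates),
        ["plate_id", "line_id", "well", "compound_id", "concentration_uM"],
    ]
    merged = cpd.merge(measurements, on=["plate_id", "well"], how="left")
    if merged["raw_value"].isna().any():
        bad = merged.loc[merged["raw_value"].isna()].iloc[0]
        raise ValueError(
            f"compound well without measurement: plate {bad.plate_id!r} "
            f"well {bad.well} readout {bad.readout!r}"
        )
    merged = merged.merge(anchors, on=["plate_id", "readout"], how="inner")
    merged["percent_activity"] = (
        100.0 * (merged["raw_value"] - merged["mu_neg"])
        / (merged["mu_pos"] - merged["mu_neg"])
    )
    out = (
        merged.groupby(
            ["plate_id", "line_id", "compound_id", "concentration_uM", "readout"],
            sort=True, as_index=False,
        )
        .agg(
            n_replicate_wells=("percent_activity", "size"),
            percent_activity=("percent_activity", "mean"),
        )
    )
    return out[ACTIVITY_COLUMNS].reset_index(drop=True)


def normalize_plate(
    layout: PlateLayout,
    measurements: pd.DataFrame,
    z_results: Sequence[ZPrimeResult],
) -> list[ActivityRecord]:
    """ActivityRecords for one QC-passed plate (all readouts).

    ``z_results`` must contain this plate's per-readout QC results; their
    stored control means are the normalization anchors.
    """
    mine = [zr for zr in z_results if zr.plate_id == layout.plate_id]
    if not mine:
        raise ValueError(f"no QC result for plate {layout.plate_id!r}")
    df = normalize_screen([layout], measurements, mine, {layout.plate_id})
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[ActivityRecord]:
    return [
        ActivityRecord(
            plate_id=r.plate_id,
            line_id=r.line_id,
            compound_id=r.compound_id,
            concentration_uM=float(r.concentration_uM),
            readout=r.readout,
            n_replicate_wells=int(r.n_replicate_wells),
            percent_activity=float(r.percent_activity),
        )
        for r in df.itertuples()
    ]


def records_to_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=ACTIVITY_COLUMNS)
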