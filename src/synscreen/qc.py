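"""Plate quality control by the Z'-factor.

The Z'-factor summarizes how well a plate's positive and negative
control wells separate:

    Z' = 1 - 3 * (sd_pos + sd_neg) / |mean_pos - mean_neg|

Z' = 1 only for zero-dispersion controls; Z' >= 0.5 is the conventional
"excellent assay" band. Standard deviations are sample (n-1) estimates,
appropriate for the 8 control wells per group. A plate with coincident
control means carries no dynamic range at all; its Z' is reported as
-inf and it never passes.

Plates are assessed per readout; a plate is retained for normalization
only if every readout passes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .screen_model import PlateLayout, ScreenDesign, layouts_to_frame

logger = logging.getLogger(__name__)

DEFAULT_ZPRIME_THRESHOLD = 0.5


@dataclass(frozen=True)
class ZPrimeResult:
    plate_id: str
    readout: str
    mu_neg: float
    sd_neg: float
    mu_pos: float
    sd_pos: float
    z_prime: float
    passed: bool


@dataclass(frozen=True)
class GatePolicy:
    """How QC failures gate downstream analysis.

    ``exclude`` drops failing plates; ``warn`` retains them but logs the
    failure (useful when re-processing a screen with a known soft plate).
    """

    threshold: float = DEFAULT_ZPRIME_THRESHOLD
    on_fail: str = "exclude"  # "exclude" | "warn"

    def __post_init__(self) -> None:
        if self.on_fail not in ("exclude", "warn"):
            raise ValueError(f"on_fail must be 'exclude' or 'warn', got {self.on_fail!r}")


def compute_z_prime(
    neg_values: Sequence[float],
    pos_values: Sequence[float],
    *,
    plate_id: str = "",
    readout: str = "",
    threshold: float = DEFAULT_ZPRIME_THRESHOLD,
) -> ZPrimeResult:
    """Z'-factor of one plate/readout from its raw control values.

    Requires at least two finite values per group (a dispersion estimate
    needs n >= 2). Coincident group means give z_prime = -inf and
    passed = False.
    """
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    for name, arr in (("negative", neg), ("positive", pos)):
        if arr.size < 2:
            raise ValueError(
                f"Z'-factor needs >= 2 {name}-control values, got {arr.size}"
                + (f" (plate {plate_id!r}, readout {readout!r})" if plate_id else "")
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name}-control value(s)")
    mu_neg, sd_neg = float(neg.mean()), float(neg.std(ddof=1))
    mu_pos, sd_pos = float(pos.mean()), float(pos.std(ddof=1))
    sep = abs(mu_pos - mu_neg)
    if sep == 0.0:
        z = -math.inf
    else:
        z = 1.0 - 3.0 * (sd_pos + sd_neg) / sep
    return ZPrimeResult(
        plate_id=plate_id,
        readout=readout,
        mu_neg=mu_neg,
        sd_neg=sd_neg,
        mu_pos=mu_pos,
        sd_pos=sd_pos,
        z_prime=z,
        passed=bool(z >= threshold),
    )


def qc_screen(
    layouts: Sequence[PlateLayout],
    measurements: pd.DataFrame,
    design: ScreenDesign,
    threshold: float = DEFAULT_ZPRIME_THRESHOLD,
) -> list[ZPrimeResult]:
    """One ZPrimeResult per (plate, readout), selecting control wells by layout kind."""
    lay = layouts_to_frame(layouts)
    controls = lay.loc[lay["kind"].isin(["neg_control", "pos_control"]),
                       ["plate_id", "well", "kind"]]
    merged = controls.merge(measurements, on=["plate_id", "well"], how="left")
    if merged["raw_value"].isna().any():
        bad = merged.loc[merged["raw_value"].isna()].iloc[0]
        raise ValueError(
            f"control well without measurement: plate {bad.plate_id!r} well {bad.well}"
        )
    results: list[ZPrimeResult] = []
    grouped = merged.groupby(["plate_id", "readout"], sort=True)
    values = {key: grp for key, grp in grouped}
    for lay_plate in layouts:
        for readout in design.readouts:
            grp = values.get((lay_plate.plate_id, readout))
            if grp is None:
                raise ValueError(
                    f"no control measurements for plate {lay_plate.plate_id!r} "
                    f"readout {readout!r}"
                )
            neg = grp.loc[grp["kind"] == "neg_control", "raw_value"].to_numpy()
            pos = grp.loc[grp["kind"] == "pos_control", "raw_value"].to_numpy()
            results.append(
                compute_z_prime(
                    neg, pos,
                    plate_id=lay_plate.plate_id, readout=readout, threshold=threshold,
                )
            )
    return results


def gate_plates(
    z_results: Iterable[ZPrimeResult],
    policy: GatePolicy | None = None,
) -> set[str]:
    """Plate ids retained under the policy (a plate must pass on every readout)."""
    policy = policy or GatePolicy()
    by_plate: dict[str, list[ZPrimeResult]] = {}
    for zr in z_results:
        by_plate.setdefault(zr.plate_id, []).append(zr)
    retained: set[str] = set()
    for plate_id, results in by_plate.items():
        failing = [zr for zr in results if not zr.z_prime >= policy.threshold]
        if failing:
            for zr in failing:
                logger.warning(
                    "plate %s readout %s failed QC: Z' = %.3f (threshold %.3f)",
                    plate_id, zr.readout, zr.z_prime, policy.threshold,
                )
            if policy.on_fail == "warn":
                retained.add(plate_id)
        else:
            retained.add(plate_id)
    return retained


def zprime_frame(z_results: Sequence[ZPrimeResult]) -> pd.DataFrame:
    """QC report table: one row per (plate, readout)."""
    df = pd.DataFrame([vars(zr) for zr in z_results])
    if df.empty:
        df = pd.DataFrame(columns=["plate_id", "readout", "mu_neg", "sd_neg",
                                   "mu_pos", "sd_pos", "z_prime", "passed"])
    return df.sort_values(["plate_id", "readout"], kind="stable").reset_index(drop=True)
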