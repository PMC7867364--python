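"""Drug-combination synergy scoring against additive and Bliss nulls.

A combination experiment has four arms -- vehicle, each single agent,
and the combination -- with replicate cell-death fractions per arm.
Effects are vehicle-subtracted arm means. Two null expectations for the
combination effect are computed from the single-agent effects a and b
(fractions in [0, 1]):

    additive ("cumulative"):  min(a + b, 1)
    Bliss independence:       a + b - a*b

The excess score is observed minus expected; a positive excess over the
additive null indicates synergy beyond a plain cumulative impact (the
screen's headline combination shows 0.37 observed against a 0.10
additive expectation, an excess of 0.27). Bliss never exceeds the capped
sum, so the additive null is the stricter synergy bar.

Significance of the combination against the pooled single agents comes
from a one-sided label-permutation test on the mean difference: exact
enumeration when the number of arrangements is small (<= 20,000),
seeded Monte-Carlo otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

CONDITIONS = ("vehicle", "drug_a", "drug_b", "combination")
MAX_EXACT_ARRANGEMENTS = 20_000


@dataclass
class CombinationExperiment:
    """Replicate cell-death fractions for the four arms of one experiment."""

    values: dict[str, np.ndarray]  # condition -> replicate fractions in [0, 1]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.values]
        if missing:
            raise ValueError(f"missing condition(s): {missing}")
        clean = {}
        for cond in CONDITIONS:
            arr = np.asarray(self.values[cond], dtype=float)
            if arr.size < 1:
                raise ValueError(f"condition {cond!r} has no replicates")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"condition {cond!r} has non-finite values")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(
                    f"condition {cond!r} has values outside [0, 1]; "
                    "declare percent units in the file header for auto-conversion"
                )
            clean[cond] = arr
        self.values = clean


@dataclass(frozen=True)
class SynergyResult:
    effect_a: float
    effect_b: float
    effect_combo: float
    expected_additive: float
    expected_bliss: float
    excess_additive: float
    excess_bliss: float
    p_value_combo_vs_singles: float
    p_exact: bool
    n_replicates: dict[str, int]


def _check_fraction(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be a fraction in [0, 1], got {x!r}")
    return arr if arr.ndim else float(arr)


def additive_expectation(effect_a, effect_b):
    """Cumulative-impact null: capped sum min(a + b, 1)."""
    a = _check_fraction(effect_a, "effect_a")
    b = _check_fraction(effect_b, "effect_b")
    out = np.minimum(np.asarray(a) + np.asarray(b), 1.0)
    return float(out) if out.ndim == 0 else out


def bliss_expectation(effect_a, effect_b):
    """Bliss-independence null: a + b - a*b."""
    a = _check_fraction(effect_a, "effect_a")
    b = _check_fraction(effect_b, "effect_b")
    a, b = np.asarray(a), np.asarray(b)
    out = a + b - a * b
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=16)
def _combination_index_array(n: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def permutation_pvalue(
    group: Sequence[float],
    reference: Sequence[float],
    *,
    alternative: str = "greater",
    n_permutations: int = 10_000,
    seed: int | None = None,
    max_exact: int = MAX_EXACT_ARRANGEMENTS,
) -> tuple[float, bool]:
    """One-sided p for mean(group) - mean(reference) by label permutation.

    Exact enumeration of all C(n, k) relabelings when that count is at
    most ``max_exact`` (p = fraction of arrangements with a statistic at
    least as extreme, the observed labeling included); otherwise seeded
    Monte-Carlo with the add-one estimator. Returns (p, exact_flag).
    """
    x = np.asarray(group, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("permutation test needs >= 2 replicates per group")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    sign = 1.0 if alternative == "greater" else -1.0
    combined = np.concatenate([x, y])
    n, k = combined.size, x.size
    observed = sign * (x.mean() - y.mean())
    total = combined.sum()
    n_arr = math.comb(n, k)
    tol = 1e-12 * max(1.0, abs(observed))
    if n_arr <= max_exact:
        idx = _combination_index_array(n, k)
        gsum = combined[idx].sum(axis=1)
        stats = sign * (gsum / k - (total - gsum) / (n - k))
        p = float(np.count_nonzero(stats >= observed - tol)) / n_arr
        return p, True
    rng = np.random.default_rng(seed)
    count = 0
    block = 2000
    done = 0
    while done < n_permutations:
        m = min(block, n_permutations - done)
        # random permutations via argsort of uniforms, first k labels = group
        order = np.argsort(rng.random((m, n)), axis=1)[:, :k]
        gsum = combined[order].sum(axis=1)
        stats = sign * (gsum / k - (total - gsum) / (n - k))
        count += int(np.count_nonzero(stats >= observed - tol))
        done += m
    p = (1.0 + count) / (1.0 + n_permutations)
    return float(p), False


def score_combination(
    exp: CombinationExperiment,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> SynergyResult:
    """Score one combination experiment against both nulls.

    Effects are vehicle-subtracted arm means, clipped into [0, 1] before
    the null expectations are evaluated (a slightly negative
    vehicle-subtracted effect is noise around zero, not protection).
    The permutation test compares the combination arm's replicates with
    the pooled single-agent replicates, one-sided for stronger killing.
    """
    for cond in CONDITIONS:
        if exp.values[cond].size < 2:
            raise ValueError(
                f"condition {cond!r} has {exp.values[cond].size} replicate(s); "
                ">= 2 are required"
            )
    vehicle_mean = float(exp.values["vehicle"].mean())
    effect = {
        cond: float(np.clip(exp.values[cond].mean() - vehicle_mean, 0.0, 1.0))
        for cond in ("drug_a", "drug_b", "combination")
    }
    expected_additive = additive_expectation(effect["drug_a"], effect["drug_b"])
    expected_bliss = bliss_expectation(effect["drug_a"], effect["drug_b"])
    singles = np.concatenate([exp.values["drug_a"], exp.values["drug_b"]])
    p, exact = permutation_pvalue(
        exp.values["combination"], singles,
        alternative="greater", n_permutations=n_permutations, seed=seed,
    )
    return SynergyResult(
        effect_a=effect["drug_a"],
        effect_b=effect["drug_b"],
        effect_combo=effect["combination"],
        expected_additive=expected_additive,
        expected_bliss=expected_bliss,
        excess_additive=effect["combination"] - expected_additive,
        excess_bliss=effect["combination"] - expected_bliss,
        p_value_combo_vs_singles=p,
        p_exact=exact,
        n_replicates={c: int(exp.values[c].size) for c in CONDITIONS},
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_combination(path: str | Path) -> CombinationExperiment:
    """Read a combination experiment TSV.

    Format: optional ``# key: value`` header lines (``units`` is
    ``fraction`` by default; ``percent`` values are divided by 100),
    then a header row ``condition<TAB>replicate_id<TAB>value``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    body_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            if ":" in ln:
                key, _, val = ln.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    header = lines[body_start].split("\t")
    expected = ["condition", "replicate_id", "value"]
    if header[:3] != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {header}")
    for ln in lines[body_start + 1:]:
        cond, rep, val = ln.split("\t")[:3]
        rows.append((cond, rep, float(val)))
    units = meta.get("units", "fraction").lower()
    if units not in ("fraction", "percent"):
        raise ValueError(f"{path}: units must be 'fraction' or 'percent', got {units!r}")
    scale = 0.01 if units == "percent" else 1.0
    values: dict[str, list[float]] = {}
    for cond, _rep, val in rows:
        values.setdefault(cond, []).append(val * scale)
    meta.pop("units", None)
    return CombinationExperiment(
        values={c: np.asarray(v) for c, v in values.items()}, metadata=meta
    )


def write_combination(
    exp: CombinationExperiment, path: str | Path, units: str = "fraction"
) -> None:
    if units not in ("fraction", "percent"):
        raise ValueError("units must be 'fraction' or 'percent'")
    scale = 100.0 if units == "percent" else 1.0
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        for key, val in sorted(exp.metadata.items()):
            fh.write(f"# {key}: {val}\n")
        fh.write("condition\treplicate_id\tvalue\n")
        for cond in CONDITIONS:
            for i, v in enumerate(exp.values[cond], start=1):
                fh.write(f"{cond}\t{i}\t{float(v) * scale!r}\n")


def synergy_summary(result: SynergyResult) -> str:
    """Human-readable one-experiment summary."""
    lines = [
        f"single-agent effects: a = {result.effect_a:.4f}, b = {result.effect_b:.4f}",
        f"combination effect:   {result.effect_combo:.4f}",
        f"additive (cumulative) expectation: {result.expected_additive:.4f}"
        f"  -> excess {result.excess_additive:+.4f}",
        f"Bliss expectation:                 {result.expected_bliss:.4f}"
        f"  -> excess {result.excess_bliss:+.4f}",
        f"permutation p (combo vs pooled singles, one-sided): "
        f"{result.p_value_combo_vs_singles:.4g}"
        f" ({'exact' if result.p_exact else 'Monte-Carlo'})",
    ]
    return "\n".join(lines)
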