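"""Seeded synthetic screens and combination experiments with known ground truth.

The generator emulates the statistical structure of the assay the
analysis assumes:

* one cell line per 96-well plate; one plate per (line, concentration,
  replicate block); negative controls (DMSO) in column 1, positive
  controls in column 12, compounds in columns 2-11 in manifest order;
* per-well true kill fraction composed from a Hill-curve compound
  effect k_c, a knockdown baseline k_g, Bliss-independent combination
  k = 1 - (1 - k_c)(1 - k_g), plus an additive planted interaction
  excess for the listed (gene, compound) pairs, clipped to [0, 1];
* raw fluorescence = mu_neg_raw * (1 - k) * eps with eps lognormal of
  mean 1 and the configured coefficient of variation -- viable-cell
  signal, so the positive control (k = kill_max) reads *low*;
* both readouts are driven by the same ground-truth kill with
  independent noise draws.

Randomness is a single seeded stream with per-plate substreams derived
from (seed, plate index), so any plate is reproducible in isolation and
a fixed config + seed gives byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import library
from .screen_model import (
    MEASUREMENT_COLUMNS,
    PlateLayout,
    Screen,
    ScreenDesign,
    ScreenValidationError,
    WellContent,
    write_screen,
)
from .synergy import CombinationExperiment, bliss_expectation
from .wells import format_well

N_COMPOUND_SLOTS = 80  # columns 2-11 of a 96-well plate


@dataclass
class GroundTruth:
    """True kill fractions and their decomposition, per (line, compound, conc).

    ``table`` columns: line_id, gene_symbol, compound_id,
    concentration_uM, kill_compound, kill_knockdown, kill_interaction,
    kill_total with kill_total = clip(1 - (1-k_c)(1-k_g) + k_i, 0, 1).
    ``planted`` lists the (gene_symbol, compound_id, delta_kill) trios.
    """

    table: pd.DataFrame
    planted: list[tuple[str, str, float]]

    def expected_delta_percent(self, kill_max: float) -> pd.DataFrame:
        """Noise-free pipeline delta implied by the ground truth.

        Percent activity of a well with kill k is 100*k/kill_max, so the
        expected delta for (gene, compound, conc) is
        100*(k_total(targeted) - k_total(ctrl))/kill_max.
        """
        t = self.table
        ctrl = t.loc[t["gene_symbol"] == "CTL",
                     ["compound_id", "concentration_uM", "kill_total"]]
        merged = t.loc[t["gene_symbol"] != "CTL"].merge(
            ctrl, on=["compound_id", "concentration_uM"], suffixes=("", "_ctrl")
        )
        merged["expected_delta"] = (
            100.0 * (merged["kill_total"] - merged["kill_total_ctrl"]) / kill_max
        )
        return merged[["gene_symbol", "compound_id", "concentration_uM",
                       "expected_delta"]]


@dataclass
class SimulationConfig:
    """All knobs of the screen generator; defaults are the full-scale screen."""

    design: ScreenDesign = field(default_factory=library.default_design)
    mu_neg_raw: dict[str, float] = field(
        default_factory=lambda: {"hoechst": 52000.0, "prestoblue": 31000.0}
    )
    kill_max: float = 0.9  # kill fraction achieved by the positive control
    compound_params: dict[str, tuple[float, float, float]] = field(
        default_factory=library.default_potency_params
    )  # compound_id -> (Emax, EC50 uM, Hill)
    knockdown_kill: dict[str, float] = field(
        default_factory=library.default_knockdown_kill
    )  # gene_symbol -> baseline kill fraction
    interactions: list[tuple[str, str, float]] = field(default_factory=list)
    noise_cv: float = 0.05  # lognormal CV of the well-level signal
    replicate_wells: int = 1
    empty_background: float = 0.02  # empty-well signal as a fraction of mu_neg_raw
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.kill_max <= 1.0):
            raise ScreenValidationError("kill_max must be in (0, 1]")
        if self.noise_cv < 0:
            raise ScreenValidationError("noise_cv must be >= 0")
        if self.replicate_wells < 1:
            raise ScreenValidationError("replicate_wells must be >= 1")
        for r in self.design.readouts:
            if r not in self.mu_neg_raw:
                raise ScreenValidationError(f"mu_neg_raw missing readout {r!r}")
            if self.mu_neg_raw[r] <= 0:
                raise ScreenValidationError("mu_neg_raw values must be positive")
        known_c = set(self.design.compound_ids)
        known_g = {ln.gene_symbol for ln in self.design.targeted_lines}
        for cid in self.design.compound_ids:
            if cid not in self.compound_params:
                raise ScreenValidationError(f"no potency parameters for {cid!r}")
            emax, ec50, hill = self.compound_params[cid]
            if not (0.0 <= emax <= 1.0) or ec50 <= 0 or hill <= 0:
                raise ScreenValidationError(f"bad potency parameters for {cid!r}")
        for ln in self.design.targeted_lines:
            kg = self.knockdown_kill.get(ln.gene_symbol)
            if kg is None or not (0.0 <= kg <= 1.0):
                raise ScreenValidationError(
                    f"knockdown_kill for gene {ln.gene_symbol!r} missing or outside [0, 1]"
                )
        for gene, cid, delta in self.interactions:
            if gene not in known_g:
                raise ScreenValidationError(f"interaction gene {gene!r} not in panel")
            if cid not in known_c:
                raise ScreenValidationError(f"interaction compound {cid!r} not in library")
            if not (0.0 <= delta <= 1.0):
                raise ScreenValidationError("interaction delta_kill must be in [0, 1]")
        n_per_block = len(self.design.compounds)
        if n_per_block * self.replicate_wells > N_COMPOUND_SLOTS:
            raise ScreenValidationError(
                f"{n_per_block} compounds x {self.replicate_wells} replicate wells "
                f"exceed the {N_COMPOUND_SLOTS} compound slots of a plate"
            )


def hill_kill(emax: float, ec50: float, hill: float, conc_uM: float) -> float:
    """Single-agent kill fraction at one concentration (Hill curve)."""
    c = conc_uM ** hill
    return emax * c / (ec50 ** hill + c)


# default planted interactions for the full-scale preset: the headline
# CK2alpha-knockdown x ATM-inhibitor pair plus two weaker trios,
# delta_kill 0.35 / 0.30 / 0.25 excess kill on top of the Bliss baseline
def default_interactions() -> list[tuple[str, str, float]]:
    return [
        ("CSNK2A1", library.compound_id_of("KU-60019"), 0.35),
        ("ATM", library.compound_id_of("SGC-CK2-1"), 0.30),
        ("CHEK1", library.compound_id_of("gefitinib"), 0.25),
    ]


def paper_scale_config(seed: int = 0, interactions: list | None = None,
                       noise_cv: float = 0.05) -> SimulationConfig:
    """Full-scale preset: 80 x 36 x 3 concentrations, 3 planted interactions."""
    return SimulationConfig(
        interactions=default_interactions() if interactions is None else interactions,
        noise_cv=noise_cv,
        seed=seed,
    )


def null_config(seed: int = 0, noise_cv: float = 0.05) -> SimulationConfig:
    """Full-scale null preset: no interactions *and* no knockdown baseline
    kill, so every true delta is exactly zero."""
    return SimulationConfig(
        knockdown_kill={g: 0.0 for g in library.GENE_PANEL},
        interactions=[],
        noise_cv=noise_cv,
        seed=seed,
    )


def demo_config(seed: int = 0) -> SimulationConfig:
    """Tiny demo: 3 compounds x (2 targeted + 1 control) lines x 20 uM,
    4 replicate wells, one planted interaction (CSNK2A1 x KU-60019)."""
    compounds = [c for c in library.default_compounds()
                 if c.name in ("KU-60019", "sunitinib", "palbociclib")]
    lines = [ln for ln in library.default_lines()
             if ln.gene_symbol in ("CTL", "CSNK2A1", "CDK4")]
    design = ScreenDesign(compounds=compounds, lines=lines, concentrations=(20.0,))
    params = library.default_potency_params()
    return SimulationConfig(
        design=design,
        compound_params={c.compound_id: params[c.compound_id] for c in compounds},
        knockdown_kill={g: k for g, k in library.default_knockdown_kill().items()
                        if g in ("CSNK2A1", "CDK4")},
        interactions=[("CSNK2A1", library.compound_id_of("KU-60019"), 0.30)],
        replicate_wells=4,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    design = config.design
    inter = {(g, c): d for g, c, d in config.interactions}
    rows = []
    for ln in design.lines:
        kg = 0.0 if ln.role == "control" else config.knockdown_kill[ln.gene_symbol]
        for cid in design.compound_ids:
            emax, ec50, hill = config.compound_params[cid]
            for conc in design.concentrations:
                kc = hill_kill(emax, ec50, hill, conc)
                ki = 0.0 if ln.role == "control" else inter.get((ln.gene_symbol, cid), 0.0)
                total = float(np.clip(1.0 - (1.0 - kc) * (1.0 - kg) + ki, 0.0, 1.0))
                rows.append((ln.line_id, ln.gene_symbol, cid, conc, kc, kg, ki, total))
    table = pd.DataFrame(
        rows,
        columns=["line_id", "gene_symbol", "compound_id", "concentration_uM",
                 "kill_compound", "kill_knockdown", "kill_interaction", "kill_total"],
    )
    return GroundTruth(table=table, planted=list(config.interactions))


def _build_plate_layout(plate_id: str, line_id: str, conc: float,
                        config: SimulationConfig) -> PlateLayout:
    design = config.design
    wells: dict[str, WellContent] = {}
    # controls: negatives down column 1, positives down column 12
    for i in range(design.n_neg_controls_per_plate):
        wells[format_well(i, 0)] = WellContent("neg_control")
    for i in range(design.n_pos_controls_per_plate):
        wells[format_well(i, 11)] = WellContent("pos_control")
    # compounds row-major across columns 2-11, manifest order, replicate blocks
    slots = [format_well(r, c) for r in range(8) for c in range(1, 11)]
    contents = [
        WellContent("compound", cid, conc)
        for _rep in range(config.replicate_wells)
        for cid in design.compound_ids
    ]
    for addr, content in zip(slots, contents):
        wells[addr] = content
    for addr in slots[len(contents):]:
        wells[addr] = WellContent("empty")
    return PlateLayout(plate_id=plate_id, line_id=line_id, wells=wells)


def _lognormal_eps(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_screen(config: SimulationConfig) -> tuple[Screen, GroundTruth]:
    """Generate a complete screen (layouts + measurements) and its ground truth."""
    design = config.design
    truth = _ground_truth(config)
    kill_lut = {
        (r.line_id, r.compound_id, r.concentration_uM): r.kill_total
        for r in truth.table.itertuples()
    }
    layouts: list[PlateLayout] = []
    frames: list[pd.DataFrame] = []
    plate_index = 0
    for ln in design.lines:
        for conc in design.concentrations:
            plate_id = f"{ln.line_id}-c{conc:g}"
            layout = _build_plate_layout(plate_id, ln.line_id, conc, config)
            layouts.append(layout)
            addrs = list(layout.wells)
            viable = np.empty(len(addrs))
            for i, addr in enumerate(addrs):
                w = layout.wells[addr]
                if w.kind == "neg_control":
                    viable[i] = 1.0
                elif w.kind == "pos_control":
                    viable[i] = 1.0 - config.kill_max
                elif w.kind == "compound":
                    viable[i] = 1.0 - kill_lut[(ln.line_id, w.compound_id,
                                                w.concentration_uM)]
                else:  # empty well: residual background fluorescence
                    viable[i] = np.nan
            rng = np.random.default_rng([config.seed, plate_index])
            for readout in design.readouts:
                base = config.mu_neg_raw[readout]
                signal = np.where(np.isnan(viable),
                                  config.empty_background * base, viable * base)
                raw = signal * _lognormal_eps(rng, config.noise_cv, len(addrs))
                frames.append(pd.DataFrame({
                    "plate_id": plate_id,
                    "well": addrs,
                    "readout": readout,
                    "raw_value": raw,
                }))
            plate_index += 1
    measurements = pd.concat(frames, ignore_index=True)[MEASUREMENT_COLUMNS]
    screen = Screen(design=design, layouts=layouts, measurements=measurements)
    return screen, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_simulated_screen(screen: Screen, truth: GroundTruth,
                           directory: str | Path) -> None:
    """Emit the screen in the standard formats plus ground_truth.tsv."""
    directory = Path(directory)
    write_screen(screen, directory)
    write_ground_truth(truth, directory / "ground_truth.tsv")


# ---------------------------------------------------------------------------
# Combination-experiment simulation
# ---------------------------------------------------------------------------


def simulate_combination(
    effect_a: float,
    effect_b: float,
    interaction_excess: float = 0.0,
    n_replicates: int = 3,
    noise_sd: float = 0.03,
    seed: int | None = None,
    background_death: float = 0.1,
) -> CombinationExperiment:
    """Four-arm combination experiment with Gaussian replicate noise.

    True arm means: vehicle = background_death, singles = background +
    effect, combination = background + bliss(a, b) + interaction_excess.
    Replicates are truth + N(0, noise_sd), truncated into [0, 1].
    """
    for name, v in (("effect_a", effect_a), ("effect_b", effect_b)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    combo_truth = bliss_expectation(effect_a, effect_b) + interaction_excess
    if not (0.0 <= combo_truth + background_death <= 1.0):
        raise ValueError(
            f"combination true mean {combo_truth + background_death:.3f} outside [0, 1]"
        )
    rng = np.random.default_rng(seed)
    means = {
        "vehicle": background_death,
        "drug_a": background_death + effect_a,
        "drug_b": background_death + effect_b,
        "combination": background_death + combo_truth,
    }
    values = {}
    for cond, mu in means.items():
        draws = mu + noise_sd * rng.standard_normal(n_replicates)
        values[cond] = np.clip(draws, 0.0, 1.0)
    return CombinationExperiment(
        values=values,
        metadata={
            "true_effect_a": effect_a,
            "true_effect_b": effect_b,
            "true_interaction_excess": interaction_excess,
            "noise_sd": noise_sd,
        },
    )
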