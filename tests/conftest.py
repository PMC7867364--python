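from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synscreen.screen_model import CellLineRecord, CompoundRecord, ScreenDesign
from synscreen.simulate import SimulationConfig

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


def make_small_design(n_compounds: int, n_targeted: int,
                      concentrations=(1.0, 20.0)) -> ScreenDesign:
    compounds = [
        CompoundRecord(f"C{i:02d}", f"cpd-{i}", "synthetic", i % 3 == 0)
        for i in range(1, n_compounds + 1)
    ]
    lines = [CellLineRecord("shCTL", "CTL", "control")] + [
        CellLineRecord(f"shG{i}", f"G{i}", "targeted") for i in range(1, n_targeted + 1)
    ]
    return ScreenDesign(compounds=compounds, lines=lines,
                        concentrations=concentrations)


def make_small_config(rng: np.random.Generator, *, noise_cv: float = 0.05,
                      interactions=None, knockdown_kill=None,
                      n_compounds: int | None = None,
                      n_targeted: int | None = None) -> SimulationConfig:
    """Random small simulated-screen config for oracle-equivalence tests."""
    n_compounds = n_compounds or int(rng.integers(2, 5))
    n_targeted = n_targeted or int(rng.integers(1, 4))
    design = make_small_design(n_compounds, n_targeted)
    params = {
        cid: (float(rng.uniform(0.0, 0.6)),
              float(rng.uniform(0.5, 30.0)),
              float(rng.uniform(0.8, 2.0)))
        for cid in design.compound_ids
    }
    if knockdown_kill is None:
        knockdown_kill = {ln.gene_symbol: float(rng.uniform(0.0, 0.05))
                          for ln in design.targeted_lines}
    return SimulationConfig(
        design=design,
        compound_params=params,
        knockdown_kill=knockdown_kill,
        interactions=interactions or [],
        noise_cv=noise_cv,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@pytest.fixture(scope="session")
def demo_screen():
    from synscreen.datasets import load_demo_screen

    return load_demo_screen()


@pytest.fixture(scope="session")
def paper_scale_run():
    """One full-scale simulated screen pushed through every stage."""
    import synscreen as ss
    from synscreen.simulate import paper_scale_config, simulate_screen

    cfg = paper_scale_config(seed=1234)
    screen, truth = simulate_screen(cfg)
    z = ss.qc_screen(screen.layouts, screen.measurements, screen.design)
    retained = ss.gate_plates(z)
    acts = ss.normalize_screen(screen.layouts, screen.measurements, z, retained)
    scores = ss.score_interactions_frame(acts, screen.design)
    hits = ss.call_hits_frame(scores)
    return {"config": cfg, "screen": screen, "truth": truth, "z": z,
            "retained": retained, "activities": acts, "scores": scores,
            "hits": hits}
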