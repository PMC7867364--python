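import dataclasses

import numpy as np
import pandas as pd
import pytest

import synscreen as ss
from synscreen.interaction import call_hits, call_hits_frame, score_interactions
from synscreen.normalization import ActivityRecord, records_to_frame
from synscreen.simulate import paper_scale_config, simulate_screen

from conftest import make_small_config, make_small_design


def _activity(line, compound, conc, readout, value, plate=None, n=1):
    return ActivityRecord(
        plate_id=plate or f"{line}-c{conc:g}", line_id=line, compound_id=compound,
        concentration_uM=conc, readout=readout, n_replicate_wells=n,
        percent_activity=value,
    )


def brute_force_scores(activities, design):
    """Naive quadruple loop over (compound, gene, concentration, readout)."""
    lookup = {}
    for r in activities:
        key = (r.line_id, r.compound_id, r.concentration_uM, r.readout)
        assert key not in lookup, "oracle expects one record per condition"
        lookup[key] = r.percent_activity
    ctrl_id = design.control_line.line_id
    out = {}
    for c in design.compounds:
        for ln in design.targeted_lines:
            for conc in design.concentrations:
                for readout in design.readouts:
                    t = lookup[(ln.line_id, c.compound_id, conc, readout)]
                    ctl = lookup[(ctrl_id, c.compound_id, conc, readout)]
                    out[(c.compound_id, ln.gene_symbol, conc, readout)] = (t, ctl, t - ctl)
    return out


class TestScoreInteractions:
    def test_direct_subtraction(self):
        design = make_small_design(1, 1, concentrations=(5.0,))
        acts = [
            _activity("shG1", "C01", 5.0, r, v)
            for r, v in (("hoechst", 60.0), ("prestoblue", 60.0))
        ] + [
            _activity("shCTL", "C01", 5.0, r, 25.0)
            for r in ("hoechst", "prestoblue")
        ]
        scores = score_interactions(acts, design)
        assert all(s.delta == pytest.approx(35.0) for s in scores)
        assert all(s.activity_targeted == 60.0 and s.activity_ctrl == 25.0
                   for s in scores)

    def test_equal_activities_give_zero_delta(self):
        design = make_small_design(1, 1, concentrations=(5.0,))
        acts = [_activity(line, "C01", 5.0, r, 42.0)
                for line in ("shG1", "shCTL") for r in ("hoechst", "prestoblue")]
        assert all(s.delta == 0.0 for s in score_interactions(acts, design))

    def test_missing_control_counterpart_is_an_error(self):
        design = make_small_design(1, 1, concentrations=(5.0,))
        acts = [_activity("shG1", "C01", 5.0, "hoechst", 60.0),
                _activity("shG1", "C01", 5.0, "prestoblue", 60.0)]
        with pytest.raises(ValueError, match="no control-line activity"):
            score_interactions(acts, design)

    @pytest.mark.parametrize("trial", range(5))
    def test_oracle_equivalence_on_random_screens(self, trial):
        rng = np.random.default_rng(100 + trial)
        cfg = make_small_config(rng)
        screen, _ = simulate_screen(cfg)
        z = ss.qc_screen(screen.layouts, screen.measurements, screen.design)
        acts_df = ss.normalize_screen(screen.layouts, screen.measurements, z)
        scores = score_interactions(acts_df, screen.design)
        oracle = brute_force_scores(ss.normalization.frame_to_records(acts_df),
                                    screen.design)
        assert len(scores) == len(oracle)
        for s in scores:
            t, ctl, delta = oracle[(s.compound_id, s.gene_symbol,
                                    s.concentration_uM, s.readout)]
            assert s.activity_targeted == t
            assert s.activity_ctrl == ctl
            assert s.delta == t - ctl  # exact: same subtraction, same floats

    def test_replicate_plates_combined_by_well_weighted_mean(self):
        design = make_small_design(1, 1, concentrations=(5.0,))
        acts = [
            _activity("shG1", "C01", 5.0, "hoechst", 30.0, plate="p1", n=1),
            _activity("shG1", "C01", 5.0, "hoechst", 60.0, plate="p2", n=2),
            _activity("shCTL", "C01", 5.0, "hoechst", 10.0, plate="p3", n=1),
        ]
        design = dataclasses.replace(design, readouts=("hoechst",))
        (score,) = score_interactions(acts, design)
        assert score.activity_targeted == pytest.approx(50.0)  # (30 + 2*60)/3
        assert score.delta == pytest.approx(40.0)


class TestCallHits:
    def _scores_frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["compound_id", "gene_symbol", "concentration_uM", "readout",
                     "activity_targeted", "activity_ctrl", "delta"],
        )

    def test_best_concentration_selected_by_max_mean_delta(self):
        rows = []
        for conc, delta in zip((1.0, 5.0, 20.0), (10.0, 35.0, 22.0)):
            for r in ("hoechst", "prestoblue"):
                rows.append(("C01", "G1", conc, r, 0.0, 0.0, delta))
        (hit,) = call_hits(self._scores_frame(rows), threshold_percent=20.0)
        assert hit.best_delta == 35.0
        assert hit.best_concentration_uM == 5.0
        assert hit.is_hit and hit.concordant and hit.rank == 1

    def test_all_zero_deltas_yield_no_hits(self):
        rows = [("C01", "G1", c, r, 0.0, 0.0, 0.0)
                for c in (1.0, 5.0) for r in ("hoechst", "prestoblue")]
        (hit,) = call_hits(self._scores_frame(rows))
        assert not hit.is_hit

    def test_require_both_readouts(self):
        rows = [("C01", "G1", 5.0, "hoechst", 0, 0, 45.0),
                ("C01", "G1", 5.0, "prestoblue", 0, 0, 5.0)]
        df = self._scores_frame(rows)
        (relaxed,) = call_hits(df, threshold_percent=20.0,
                               require_both_readouts=False)
        (strict,) = call_hits(df, threshold_percent=20.0,
                              require_both_readouts=True)
        assert relaxed.is_hit  # mean delta 25 >= 20
        assert not strict.is_hit
        assert not strict.concordant

    def test_rank_is_dense_and_ties_break_lexicographically(self):
        rows = [("C02", "G2", 5.0, "hoechst", 0, 0, 30.0),
                ("C01", "G2", 5.0, "hoechst", 0, 0, 30.0),
                ("C01", "G1", 5.0, "hoechst", 0, 0, 10.0)]
        hits = call_hits_frame(self._scores_frame(rows), threshold_percent=20.0)
        assert list(hits["rank"]) == [1, 1, 2]
        assert list(hits["compound_id"]) == ["C01", "C02", "C01"]
        assert list(hits["gene_symbol"]) == ["G2", "G2", "G1"]

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError, match="no interaction scores"):
            call_hits_frame(self._scores_frame([]))


class TestPlantedRecovery:
    def test_planted_pair_carries_maximal_delta(self, paper_scale_run):
        """The screen's headline interaction (CK2alpha knockdown x KU-60019)
        is planted strongest and must top the ranking."""
        hits = paper_scale_run["hits"]
        planted = {(g, c) for g, c, _ in paper_scale_run["truth"].planted}
        top3 = set(zip(hits["gene_symbol"].head(3), hits["compound_id"].head(3)))
        assert top3 == planted
        assert hits["is_hit"].head(3).all()

    def test_rank_monotone_in_planted_effect_size(self):
        """Doubling a planted excess kill never worsens the pair's rank
        (identical seed, identical noise draws)."""
        from synscreen.library import compound_id_of

        pair = ("CSNK2A1", compound_id_of("KU-60019"))
        ranks = {}
        for delta in (0.25, 0.35):
            cfg = paper_scale_config(seed=77, interactions=[(*pair, delta)])
            screen, _ = simulate_screen(cfg)
            z = ss.qc_screen(screen.layouts, screen.measurements, screen.design)
            acts = ss.normalize_screen(screen.layouts, screen.measurements, z)
            hits = ss.call_hits_frame(
                ss.score_interactions_frame(acts, screen.design))
            row = hits.loc[(hits["gene_symbol"] == pair[0])
                           & (hits["compound_id"] == pair[1])]
            ranks[delta] = int(row["rank"].iloc[0])
        assert ranks[0.35] <= ranks[0.25]

    def test_null_screen_mean_delta_near_zero(self):
        """Screen with zero interaction and knockdown terms: the mean delta
        over all pairs sits within 3 standard errors of 0, and the count of
        false hits at the 20-point threshold stays within the Gaussian-tail
        expectation implied by the observed delta noise."""
        from synscreen.simulate import null_config

        screen, _ = simulate_screen(null_config(seed=9))
        z = ss.qc_screen(screen.layouts, screen.measurements, screen.design)
        acts = ss.normalize_screen(screen.layouts, screen.measurements, z)
        scores = ss.score_interactions_frame(acts, screen.design)
        # deltas within a screen share plate-level control-anchor noise, so
        # estimate the SE from the 6 independent (concentration, readout)
        # blocks rather than from the raw per-delta scatter
        blocks = scores.groupby(["concentration_uM", "readout"])["delta"].mean()
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(blocks.mean()) < 3 * se
        hits = ss.call_hits_frame(scores, threshold_percent=20.0)
        pair_sigma = (
            scores.groupby(["compound_id", "gene_symbol", "concentration_uM"])
            ["delta"].mean().std(ddof=1)
        )
        from scipy.stats import norm
        n_pairs = len(hits)
        n_concs = len(screen.design.concentrations)
        p_tail = n_concs * norm.sf(20.0 / pair_sigma)
        expected_fp = n_pairs * p_tail
        assert hits["is_hit"].sum() <= expected_fp + 3 * np.sqrt(expected_fp) + 2
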