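# synscreen

Analysis pipeline for chemo-genetic **drug × shRNA viability screens** of the
kind used to find synthetic-lethal drug–gene combinations in VHL-deficient
clear cell renal cell carcinoma (ccRCC) models: a panel of engineered
knockdown cell lines (one gene per line, plus a control-shRNA line) is
screened against a targeted-compound library on 96-well plates, read out with
two viability dyes (vital Hoechst and PrestoBlue), and mined for compounds
that kill a knockdown line harder than the control line.

`synscreen` implements the full desk side of such a screen:

1. **Plate QC** — per plate and readout, the Z′-factor from the plate's own
   control wells (8 DMSO negative, 8 CX-4945 20 µM positive):

   `Z′ = 1 − 3(σ₊ + σ₋)/|µ₊ − µ₋|`

   Plates must pass on every readout (default threshold 0.5) to enter
   normalization.

2. **Percent-activity normalization** — each raw well value is mapped
   affinely so the plate's DMSO mean is 0 % and its positive-control mean is
   100 %: `a = 100·(raw − µ₋)/(µ₊ − µ₋)`. Unclamped, per plate, per readout.

3. **Interaction (delta) scoring** — for each (compound, gene,
   concentration, readout), `Δ = a(targeted) − a(control line)`. Positive Δ
   means the knockdown sensitizes the cells to the compound. Hit calling
   summarizes each pair across readouts (mean) and concentrations (max),
   ranks pairs by best Δ, and applies a configurable threshold (default
   20 points).

4. **Combination synergy** — for four-arm validation experiments
   (vehicle / drug A / drug B / combination, replicate cell-death fractions),
   vehicle-subtracted effects are compared against two nulls: the additive
   ("cumulative") expectation `min(a + b, 1)` and Bliss independence
   `a + b − a·b`, with a one-sided label-permutation test (exact enumeration
   at small n) for combination-vs-pooled-singles significance.

5. **Synthetic screens** — a seeded generator produces complete screens
   (layouts, dual-readout measurements, ground truth) with Hill-curve
   compound potencies, knockdown baseline effects, Bliss-composed
   combination kills, planted interaction excesses, and lognormal
   measurement noise, so every stage is verifiable by parameter recovery.

At full scale the default design is 80 compounds (22 FDA-approved) × 36
knockdown lines × 3 concentrations (1, 5, 20 µM), i.e. 2880 drug–gene pairs
and 8640 concentration-level data points. The compound/gene manifest shipped
here is a realistic but synthetic stand-in panel, not any published screen's
library.

## Worked example

The package ships a tiny seed-fixed demo screen (3 compounds ×
2 knockdown lines + control, 20 µM, 4 replicate wells, one planted
interaction between the CSNK2A1 knockdown and the ATM inhibitor KU-60019):

```sh
synscreen run --in src/synscreen/data/demo --out demo_out
```

prints

```
synscreen pipeline summary
==========================
plates_analyzed: 3
plates_failed_qc: 0
plates_retained: 3
pairs_designed: 6
datapoints_designed: 6
pairs_scored: 6
datapoints_scored: 6
activities_out_of_0_100: 0
hits_called: 1
hit_threshold: 20.0
qc_threshold: 0.5
```

All three plates pass Z′ QC, all 6 drug–gene pairs are scored, and exactly
one hit is called — the planted pair, topping `demo_out/hits.tsv`:

```
compound_id  gene_symbol  best_delta  best_concentration_uM  ...  is_hit  rank
CPD023       CSNK2A1      37.0431     20                          True    1
CPD001       CSNK2A1      7.03875     20                          False   2
...
```

`best_delta ≈ 37` means the KU-60019 analog (CPD023) kills the CK2α-knockdown
line about 37 activity points harder than the control line, close to the
planted excess kill of 0.30 mapped through the activity scale
(100·0.30/0.9 ≈ 33) plus this seed's noise; the non-planted pairs sit near 0.

The same flow at full scale:

```sh
synscreen simulate --preset paper-scale --seed 1 --out screen
synscreen run --in screen --out out        # 111 plates, 2880 pairs, 8640 points
```

For a combination experiment, a TSV with arms `vehicle`, `drug_a`, `drug_b`,
`combination` scored with `synscreen synergy combo.tsv` reports the
vehicle-subtracted effects, both null expectations, the excesses and the
permutation p-value. For example, single agents killing 4 % and 6 % with an
observed 37 % combination kill give an additive expectation of 10 % and an
excess of +27 points — strong synergy.

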