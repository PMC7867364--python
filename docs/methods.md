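# Methods

## The screen and its analysis model

The pipeline analyses a chemo-genetic synergy screen: isogenic cell lines,
each stably expressing one shRNA (36 gene-targeted lines plus one
control-shRNA line), are exposed to a library of 80 targeted agents at
1, 5 and 20 µM on 96-well plates and read after 48 h with two viability
readouts (vital Hoechst fluorescence, a cell-count proxy; PrestoBlue, a
metabolic-activity proxy). Each plate carries one cell line, eight DMSO
negative-control wells and eight positive-control wells (the CK2 inhibitor
CX-4945 at 20 µM, a near-maximal-kill reference). The analysis makes three
modelling commitments:

* **Per-plate control anchoring.** Raw fluorescence is converted to percent
  activity with the plate's own control means (DMSO = 0 %, positive
  control = 100 %), per readout. The map is affine, so common plate-level
  gain/offset artifacts cancel exactly, and it is direction-agnostic (the
  positive control may read below or above the negative control). Activities
  are deliberately not clamped to [0, 100]: out-of-range values are real
  signal (super-positive kill, growth stimulation) or pathology, and the
  pipeline counts them in its summary instead of hiding them.

* **Difference-of-activities interaction score.** The interaction statistic
  is Δ = activity(targeted line) − activity(control line) at matched
  compound, concentration and readout. "Taken from" is implemented as
  arithmetic subtraction with this sign so that positive Δ = more killing in
  the knockdown line (sensitization), which is the effect a synthetic-lethal
  screen wants ranked on top.

* **Screen-then-confirm.** The primary screen carries no replicate-based
  per-pair inference (one well per condition at full scale); candidate pairs
  are confirmatory-tested as four-arm combination experiments, where
  replication exists and a permutation test applies. Accordingly no
  multiple-testing correction is applied to screen deltas.

## Plate QC

Z′ = 1 − 3(σ₊ + σ₋)/|µ₊ − µ₋| with **sample** (n−1) standard deviations —
with only 8 wells per control group the extra variance of the population
estimator is not worth the bias. Z′ = 1 iff both dispersions vanish; plates
with coincident control means have no dynamic range, get a −∞ sentinel, and
can never pass. The pass threshold defaults to 0.5 (the conventional
"excellent assay" band) and is configurable; a plate must pass on **every**
readout because both readouts feed hit calling. The gate policy `warn`
retains failing plates while logging them, for forensic re-runs. The
pipeline functions when zero or all plates fail.

## Hit calling

Per pair, per concentration the two readout deltas are averaged (the assay
gives no reason to weight a cell-count proxy differently from a metabolic
proxy); the pair summary is the **maximum** over concentrations of that
mean — a pair is interesting if any tested dose sensitizes. Pairs are ranked
densely by best Δ, ties broken lexicographically by (gene, compound) for
deterministic output. The default hit threshold is 20 percentage points —
an openly arbitrary but stated screening bar, configurable; an optional
concordance requirement demands both readouts individually clear the
threshold at the best concentration.

## Combination synergy

Arm effects are vehicle-subtracted means of cell-death fractions, clipped
into [0, 1] before the nulls are evaluated (a slightly negative
vehicle-subtracted effect is noise around zero, not protection). Two nulls
are reported: the additive "cumulative impact" expectation min(a + b, 1) —
the plain-sum reasoning behind "37 % observed where ~10 % was expected" —
and Bliss independence a + b − a·b, the standard independence null, included
because a capped sum is non-standard. Bliss never exceeds the capped sum on
[0, 1], so additive excess is the stricter synergy claim. Significance of
the combination arm against the pooled single-agent replicates uses a
one-sided permutation test on the difference of means: exact enumeration of
all C(n, k) relabelings when that count is ≤ 20 000 (p = fraction of
arrangements at least as extreme, observed labeling included, so p ≥ 1/N),
otherwise seeded Monte-Carlo with the add-one estimator. Ties in the
permutation statistic are counted as extreme (tolerance 1e-12 relative),
keeping the test conservative.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes — and
only that:

* **Signal model.** Raw signal = µ_neg · (1 − kill) · ε per well, with ε
  lognormal of mean 1 and CV `noise_cv` (default 0.05): fluorescence is
  strictly positive and plate-reader noise is naturally multiplicative.
  Viability is the measured quantity, so the positive control
  (kill = `kill_max`, default 0.9) reads *low*; the normalization stage must
  not, and does not, assume a direction. Readout baselines default to
  µ_neg = 52 000 (Hoechst) and 31 000 (PrestoBlue) arbitrary units; both
  readouts are driven by the same true kill with independent noise.

* **Effect composition.** Compound kill follows a Hill curve
  k_c = Emax·cʰ/(EC50ʰ + cʰ); the synthetic 80-compound panel draws
  Emax ∈ [0.05, 0.6], EC50 log-uniform on [0.5, 50] µM and Hill ∈ [0.8, 2.0]
  once from a fixed panel seed (typical 48-h single-agent potencies, far
  from the positive control's near-max kill). Knockdown baseline kill is
  small (uniform [0, 0.05] per gene — stable lines are viable by
  construction). Compound and knockdown combine Bliss-independently,
  k = 1 − (1 − k_c)(1 − k_g), which makes "no interaction" well-defined;
  planted interactions add `delta_kill` excess on top, clipped to [0, 1].
  The full-scale preset plants three pairs at 0.35/0.30/0.25 excess kill,
  the strongest being the CK2α-knockdown × ATM-inhibitor pair the assay
  design is built around. A noise-free planted excess δ on an otherwise
  inert pair surfaces as a pipeline delta of exactly 100·δ/kill_max points,
  which the tests use as a closed-form oracle.

* **Geometry and determinism.** One plate per (line, concentration):
  negative controls down column 1, positives down column 12, the 80
  compounds row-major across columns 2–11 in manifest order (the demo preset
  fills unused slots with measured empty wells at 2 % background signal).
  Per-plate RNG substreams derive from (seed, plate index), so a plate is
  reproducible in isolation and a fixed config + seed yields byte-identical
  output files.

* **What it does not emulate.** Spatial/edge effects, incubation kinetics,
  carry-over, readout-specific biology (the two dyes share one true kill
  here; in real data they can diverge), or plate-to-plate drift. Passing
  parameter recovery therefore demonstrates the pipeline's correctness under
  the assay's idealized noise model, not robustness to systematic artifacts
  a B-score/loess correction would target — such corrections are explicitly
  out of scope.

* Combination experiments are simulated as four arms with Gaussian replicate
  noise truncated to [0, 1] around vehicle = background (default 0.1),
  singles = background + effect, combination = background + Bliss + excess.

## Calibration and recovery experiments

* **Parameter recovery.** At default conditions (noise CV 5 %, 8 + 8 control
  wells, kill_max 0.9, three planted pairs with excess ≥ 0.25 among 2880),
  the pipeline must recall all three planted pairs at the 20-point threshold
  and rank them in the top 5 in ≥ 95 of 100 seeds. The planted deltas map to
  ≈ 28–39 activity points against a per-pair noise scale of ≈ 6 points, so
  this is a demanding but attainable bar; it is verified over 100 seeds in
  the test suite and reported over 20 seeds by the acceptance script.

* **Null calibration.** On screens with all interaction *and* knockdown
  terms zero, every true delta is zero. Deltas within one screen are
  correlated — each plate's control-well anchor error is shared by all its
  wells, and the single control line enters every delta — so the standard
  error of the screen-level mean delta is estimated **across independent
  screens** (or, within one screen, across the six independent
  concentration × readout blocks), never from the raw per-delta scatter,
  which would understate it by an order of magnitude.

* **Permutation-test calibration.** The combo-vs-pooled-singles permutation
  test is exact under exchangeability of the arms. A Bliss-independent
  experiment with non-zero single-agent effects is *not* exchangeable
  (Bliss ≠ pooled-singles mean), so the uniformity check runs at the global
  null (all effects and excess zero) with 5 replicates per arm, where exact
  enumeration (C(15, 5) = 3003 arrangements) gives a p-grid fine enough for
  a KS test against U(0, 1) at α = 0.01 over 1000 seeded experiments.

* **Z′ compatibility.** Default noise must describe a "validated" assay:
  null screens at CV 5 % give Z′ concentrated around 0.83, comfortably above
  the 0.5 gate (checked distributionally in the tests).

## Numerical and interface choices

* Sorting keys and float formats are fixed (6 significant digits in derived
  tables; shortest-round-trip representation for raw measurement files so
  write → read is exact), making pipeline re-runs byte-identical and diffs
  meaningful.
* Well addresses accept both "A1" and "A01" dialects on input and are
  zero-padded on output; the parser accepts exactly A1–H12.
* Replicate wells are averaged with the unweighted mean; replicate plates
  combine by well-count weighting (equivalent to the unweighted mean over
  all wells). Records carry their replicate counts.
* Control-well values are never trimmed; a corrupted control well should
  fail QC, not be silently repaired.
* Percent-unit combination files are auto-converted to fractions via the
  `# units: percent` header.
* Problem sizes in the shipped experiments (100 recovery seeds in the test
  suite, 20 in the acceptance script; 1000 permutation experiments; 5–8 null
  screens) were chosen to give the calibration checks adequate statistical
  resolution while keeping a full run of suite + script in the low minutes
  on one CPU.

## Known limitations

* The delta score inherits the control line's noise into every pair; a
  screen with a noisy control plate degrades globally. The QC gate is the
  only guard.
* With one well per condition at full scale, a single aberrant well becomes
  a pair-level delta outlier; the confirm-stage design, not the screen
  statistics, is the remedy.
* The additive ("cumulative") null saturates at 1 and is non-standard below
  saturation; Bliss is reported alongside for comparability with the wider
  synergy literature. Loewe/ZIP/Chou–Talalay response-surface models are out
  of scope (they need dose–response surfaces the screen design does not
  collect).
* The synthetic compound/gene panel is a stand-in with realistic names and
  geometry; conclusions about any real library require real manifests.
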