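# Methods

This note records the models, parameter choices and numerical conventions
behind `berrymet`, and what the synthetic-data tests do and do not
demonstrate about real instrument data.

## The experiment being modelled

A split-plot phytotron design: three constant ripening temperatures
(12, 18, 24 °C, main plots) crossed with three photoperiods (natural long
day LD, 10 h short day SD, and SD with a 3 h night interruption, SD+NI;
sub-plots), in four randomised replicate blocks, plus an outdoor ambient
group grown under natural LD only — 40 biological samples per
electrospray polarity. Each polarity's analytical block additionally
carries 11 pooled-QC injections (an equal mix of all samples) and 2 blank
injections. All intensities are ultimately expressed as peak-response
ratios to a morin internal standard (C₁₅H₁₀O₇, monoisotopic 302.0427 Da;
[M+H]⁺ 303.0499, [M−H]⁻ 301.0354) spiked into every extract.

## Annotation

**Grouping.** Features are linked when they elute within ±10 s and their
intensities correlate with Pearson r > 0.8 over at least 3 shared
non-missing samples (all non-blank injections are used); groups are the
single-linkage connected components of that graph. Constant features are
never linked.

**Roles.** Within a group, each candidate parent ion is scored by how
many co-members it explains: isotopologues at +k·1.003355 Da (k = 1, 2;
±0.005 Da, intensity below the parent), adduct partners at the mass
difference of two table species (±0.005 Da; defaults [M+H]⁺, [M+Na]⁺,
[M+K]⁺, [M+NH₄]⁺, [2M+H]⁺, [M]⁺ and [M−H]⁻, [M+Cl]⁻, [M+HCOO]⁻, [2M−H]⁻),
and dimers by direct arithmetic on the inferred neutral mass. The
best-scoring member is the base ion (ties: preferred species, then
highest mean intensity, then lowest m/z — logged); the procedure then
*repeats on the unexplained remainder*, because a correlation group can
legitimately contain several co-eluting compounds. Leftover members that
no parent explains keep role `unassigned` and are retained (matching
practice: only demonstrable isotope/adduct/fragment redundancy is
removed).

**Neutral mass and library matching.** An unpaired base ion is read as
the default protonated/deprotonated species; in positive mode, if that
neutral mass finds no library hit, the intrinsic-cation interpretation
[M]⁺ (electron mass 0.000549 Da) is tried — anthocyanins ionise as
flavylium cations. A library hit requires agreement within 5 ppm at or
above 300 Da, or within 0.015 Da below (the crossover keeps the absolute
window from being tighter than instrument accuracy at low mass). Hits are
ranked by |ppm|, ties by name.

**In-source fragments and MSI levels.** A leftover lower-mass co-member
whose m/z matches a reference MS2 fragment of the subgroup's best library
hit (±0.01 Da) is flagged an in-source fragment; that match also serves
as the MS2 evidence flag. Confidence levels: 1 = mass ∧ RT (±0.2 min vs a
reference standard) ∧ MS2 (∧ MS3 when a reference exists); 2+ = mass ∧
MS2 without an RT standard; 2 = unique accurate-mass match; 3 = ambiguous
(isomeric) mass match; 4 = unknown. The package holds no measured MS2
spectra (spectral acquisition is out of scope), so MS2 evidence is
operationalised through the fragment-ion rule above.

## QC cascade

Stage order: RT trim → blank rule → annotation → IS normalisation →
QC-RSD filter → redundancy collapse → polarity merge → imputation. Every
stage writes to a ledger enforcing n_in = n_removed + n_out, chained per
polarity.

* **RT trim**: keep the closed window [2, 29] min of a 35-min gradient
  (the polar front and wash are diverted to waste).
* **Blank rule**: remove a feature when its highest blank intensity
  strictly exceeds 2× its highest biological intensity (missing = 0 for
  maxima; raw areas, since blanks carry no IS context). Boundary cases
  survive.
* **Normalisation**: divide by the sample's morin intensity (located at
  the polarity's expected IS m/z ± 0.01); errors if the IS is missing or
  zero anywhere. The IS row is removed and counted in the ledger.
* **QC-RSD**: remove features whose RSD (100·sd/mean, sample sd with
  n−1) across the pooled-QC injections strictly exceeds 20 %, computed on
  normalised ratios; fewer than 3 observed QC values or a zero mean also
  removes. Exactly 20 % survives.
* **Merge**: both polarity row sets are stacked (never fused); a feature
  is flagged corroborated when the other polarity infers the same neutral
  mass within 0.005 Da.
* **Imputation**: missing cells become (global minimum observed
  ratio)/3. Note this can be far below a high-abundance feature's own
  range; see limitations.

## Statistics

**Friedman / BH.** For the temperature factor, blocks are the four
replicate blocks and the cell value is the mean ratio over photoperiods
within (temperature, block); ambient enters as a fourth treatment level
(a variant without ambient is provided, since either reading of the
design is defensible). For the day-length factor, blocks are the twelve
temperature × replicate cells and ambient is excluded. The statistic uses
mid-ranks and the tie-correction factor; p comes from the χ² upper tail.
With n = 4 blocks and k = 4 levels the null distribution is coarsely
discrete — the smallest attainable p is ≈ 0.0074 — which bounds what any
FDR procedure can resolve at this design size. BH q-values use the
step-up rule; rejection is q < 0.05 (strict, per convention here).

**PCA.** Columns are mean-centred and unit-variance scaled (the default
of the chemometrics software this emulates; pareto/none available),
decomposed by full SVD; TEVᵢ = σᵢ²/Σσ²·100. Zero-variance columns are
dropped with a warning under uv scaling. Sign convention everywhere: the
largest-|element| of each loading vector is positive, making outputs
backend-independent.

**Multiblock hierarchical (consensus) PCA.** The matrix is globally
uv-scaled, then centred within each block (one block per cultivation
temperature), removing the temperature main effect. Per component the
scheme iterates: block scores t_b = X_b·p_T; block loadings
p_b = X_bᵀt_b/(t_bᵀt_b); the super loading p_T is the first left singular
vector of the block-loading bundle weighted by ‖t_b‖, unit-normalised;
initialisation is the dominant right singular vector of the concatenated
matrix (deterministic), convergence at ‖Δp_T‖ < 1e-10, then each block is
deflated by t_b·p_Tᵀ. With one block this reduces exactly to PCA (tested
to 1e-8). Non-convergence raises with the iteration trace.

**Selection and trends.** A feature is temperature-selected when
q_temp < 0.05 and its |PC1| or |PC2| loading reaches the 60th percentile
of that component's |loadings| (the prominence percentile is a declared
configurable; "prominent" is not quantified in the source protocol);
day-length-selected when q_day < 0.05 and the |HPCA PC1 super loading|
reaches the same percentile. Trend classes on temperature group means:
strictly increasing 12→18→24 °C is temperature-up; strictly decreasing is
temperature-down; ambient mean above 1.5× the highest controlled mean is
ambient-elevated ("far higher" is operationalised by the configurable
1.5); priority in that order, everything else none. Unselected features
are never classified.

## Synthetic-data generator

Each planted compound has a formula (CHO space, 6–30 carbons), an RT
uniform on [2, 29] min (so the trim removes nothing unless planted
outside), a baseline ratio 10^N(−1.5, 0.7), a polarity (positive /
negative / both; anthocyanin-class compounds are positive-only intrinsic
cations), and one of six mutually exclusive effect classes:

| class | controlled 12/18/24 °C | ambient | photoperiod |
|---|---|---|---|
| temp-up | 1, f, f² | 1 | — |
| temp-down | 1, 1/f, 1/f² | 1 | — |
| temp-peak | 1, f, 1/f | 1 | — |
| ambient-up | 1, 1, 1 | 2.0 | — |
| daylength | 1, 1, 1 | 1 | f^±1 on one level |
| null | 1, 1, 1 | 1 | — |

with f = `fold_step` (default 1.5). The non-monotone temp-peak class
carries the elevated-then-suppressed pattern the most abundant
anthocyanins show, and lets a 365-strong temperature-affected set coexist
with exactly 100 strictly increasing and 42 strictly decreasing features.
The ascorbic-acid entry is planted with its known mean ratio profile
0.0062 / 0.0048 / 0.0046 directly.

Intensity model per ion and sample: expected ratio × biological abundance
factor (log-normal, `biological_cv`, shared by *all* ions of a compound
in both polarities; pooled-QC extracts average it away and draw from the
biological grand mean) × IS scale (2·10⁶) × injection factor (log-normal,
`injection_cv` = 0.15 — run-to-run ESI drift is the reason peak-ratio
normalisation exists, and the factor cancels exactly after it) ×
analytical noise (mean-one log-normal, `noise_cv`). Satellite ions are
scalar multiples (adduct/isotope/fragment relative abundance; isotope
abundance = the first-order (A+1)/A formula sum) of the realised base
intensity with independent analytical noise. Blanks contain only planted
contaminant features (10× the biological level); morin appears in every
non-blank injection. Missing values are injected uniformly at random
among the lowest-abundance tercile of compounds, as absent cells.
`biological_cv` defaults to `noise_cv` — the largest value at which the
planted-effect recovery property (sensitivity/precision ≥ 0.9 at
fold 1.5, noise 0.1) still holds, and enough shared variance that a
compound's ions correlate above the grouping threshold — so the
`noise_cv = 0` limit remains exactly deterministic.

The **study stand-in** (`blackcurrant_standin`) instantiates the study's
own published accounting as generator inputs: 469 retained features
(199 ESI⁺ / 270 ESI⁻), 100/42/189/34/18 effect-class counts, plus 48
QC-unstable extra features so the QC stage reproduces the ~549 → ~469
bookkeeping. Its analytical noise is 0.05 (ratio RSD ≈ 9 %): the retained
features by definition passed the 20 % QC-RSD filter with only a ~9 %
failure rate overall, which pins the analytical spread well below the
threshold. Biological replicate variability is 0.10.

**What passing tests do not show.** The generator's features are
statistically independent given the design (no pathway co-regulation),
its noise is exactly log-normal, missingness is random rather than
abundance-censored, and MS2 evidence is reduced to in-source fragment
arithmetic. Consequences measured on the stand-in: (i) emergent
quantities of the real data's covariance — PC1/PC2 explained variance,
the exact 365 significant count, the exact 18 day-length count — are
reproduced in scale but not to the printed digits; (ii) the
consensus-PCA noise floor of 469 independent features is comparable to an
18-feature 1.5-fold day-length signal, so the prominence rule passes
~13 of the 18 planted features (Friedman+BH alone finds ~17/18); (iii)
random missingness + global-min/3 imputation plants extreme outlier
cells that cost roughly 5–10 % of low-abundance responders their
significance. These are properties of the emulation conditions, not of
the inference code, and the corresponding study-scale tests are allowed
to fail while the property-based suite must pass.

## Numerical conventions and degenerate inputs

Monoisotopic masses to 1e-6 Da from IUPAC values; proton 1.007276 Da,
electron 0.000549 Da included for intrinsic cations. RT is minutes
everywhere (second-valued windows are converted at call sites). Missing
intensities are absent cells, never zero; zeros are measured values.
Degenerate cases: all-tied Friedman blocks give Q = 0, p = 1; an
all-missing matrix refuses imputation; a missing or zero internal
standard is an error naming the samples; absent blanks skip the blank
stage with a warning (the QC stage, by contrast, is mandatory);
zero-variance columns cannot be uv-scaled and are dropped with a warning.
Problem sizes throughout the suite (469-compound stand-in, 200-compound
recovery run, 40-compound null batteries over 20 seeds) keep the full
test suite and the acceptance script within seconds to a couple of
minutes on one CPU.
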