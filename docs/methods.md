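# Methods

## Model and procedure

The analysis treats a cohort of donors with (a) a functional readout —
the percentage of cellular histamine released on IgE-receptor
crosslinking — and (b) per-donor expression levels of a small gene panel
measured by qPCR. Three stages follow:

**Stratification.** Donor release values are summarized by the sample
mean and sample SD (n−1 denominator; the estimator choice is a
convention, the source data do not dictate one). The cutoffs mean ± SD
define the Average range; classification uses strict inequalities, so a
value exactly on a cutoff is Average. Cutoffs fitted on one cohort may
be applied to another — this is how patient-derived samples are referred
to a normal-donor baseline — and the API keeps fitting and classification
separate for that reason.

**PEEP.** For each gene, the pooled Average+Low donors are the control
set; their Log2-level mean `M_ctrl` and sample SD `SD_ctrl` define a
normal range `M_ctrl ± SD_ctrl`. A donor's level strictly above the
upper cutoff is "Up", strictly below the lower is "Down", otherwise
"Norm"; "Perturbed" = Up or Down. The ±1 SD width is part of the method
definition, not a tunable here (no multi-SD or quantile variants are
offered). Under a normal null where test samples are drawn from the
control distribution itself, the expected perturbed rate is
2·(1−Φ(1)) ≈ 31.7%; group summaries should therefore be read against
that baseline, not against 0. High responders never contribute to the
control range. Percentages are reported to one decimal with half-up
rounding, which reproduces the conventional rounding of the reference
tables (e.g. 14/17 → 82.4).

**Barcodes.** The ordered Up/Norm/Down statuses of a k-gene panel
collapse to the count triple (n_up, n_norm, n_down), written
`xUyNzD`. Gene order never matters. The pattern space is the set of weak
compositions of k into three parts, size (k+1)(k+2)/2 — 15 at k=4, 45 at
k=8. Categories are induced by a rule rather than a lookup table, so any
panel size works: ≥1 Up with no Down → "n-Up"; exactly one Up and one
Down → "1-Up-1-Down"; everything else → "Others". At k=4 this partitions
the 15 patterns as {4-Up, 3-Up, 2-Up, 1-Up, 1-Up-1-Down: 1 each;
Others: 10}.

## qPCR normalization

Quantities are the canonical representation; Ct input goes through a
fitted standard curve (least-squares line of Ct on log10 quantity,
inverted as `10**((ct−intercept)/slope)`). Per plate and target gene the
reference-control quantities define `NFq = Qc/mean_plates(Qc)` and
`NFg = Gc/mean_plates(Gc)`; "average of all Qc" is read as the unweighted
mean over the plates that ran that gene, one control per plate × gene.
The normalized level `(Qs/NFq)/(Gs/NFg)` is Log2-converted. Zero or
negative quantities are an error, never imputed, because no
limit-of-detection rule is defined for this assay.

One algebraic point worth stating: a multiplicative effect applied to a
single plate is *not* annihilated exactly — the cross-plate control
means inside NFq/NFg shift too, so all donors' Log2 levels for that gene
move by a common constant. Every downstream quantity (PEEP statuses,
fold changes, barcodes) is invariant under such per-gene additive
shifts, so the construction is plate-robust where it matters. Rescaling
the control channel globally cancels exactly.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes, so
that every stage is testable without the restricted donor data:

- **Histamine release**: a normal distribution truncated to [0, 100],
  with the underlying loc/scale solved numerically so the *truncated*
  distribution has the configured mean and SD (defaults 24.1% and
  15.1%). Without moment matching the truncation would bias the mean by
  about +1.8 at these defaults. This is the simplest unimodal family on
  the valid range with the right first two moments.
- **Expression**: donor d, gene g gets
  `baseline_log2(g) + high_shift_log2(g)·[d is High] + N(0, noise_sd²)`.
  Default panel: the eight signature genes, six shifted up in High
  responders (NELL2, ITM2C, AKAP12, IL13RA1, CALB2, TMEM255B) and two
  down (GADD45B, DPP4). Defaults `high_shift_log2 = ±1.2`,
  `noise_sd = 0.6` were fixed once so the implied per-gene Up rate among
  High donors, Φ(shift/σ − 1) ≈ 84%, sits in the upper range observed
  for real signature genes; no published effect sizes exist to copy.
- **Plate data**: donors are assigned to plates round-robin; plate
  controls Qc, Gc are log-normal with log-SD `plate_factor_sd`
  (multiplicative plate effects — exactly the kind the ratio
  normalization handles); donor GAPDH quantities Gs are log-normal
  around 10; Qs is then *solved* from the normalization equation so the
  pipeline recovers the generating Log2 matrix to floating-point
  accuracy. Triplicate-level replicates, amplification efficiency and
  fluorescence traces are not modelled: the normalization consumes only
  triplicate means, so nothing downstream could see them.

What passing tests on this generator do **not** show: real cohorts have
non-Gaussian expression heterogeneity, correlated genes, batch structure
beyond multiplicative plate effects, and measurement error that survives
normalization. Synthetic results validate the arithmetic and the
qualitative behaviour (e.g. all-up barcodes concentrating in High
responders when shifts are real), not biological effect sizes.

## Marker screen

The screen is a deliberately simple surrogate for a full microarray
mixed-model analysis (out of scope; the raw array data are not
available): per gene, the linear fold change `2**(Δ of Log2 means)`
folded to a signed convention (−1/ratio below 1, so |fc| ≥ 1 and a
"fold-change < −1.2" cutoff is meaningful), and a two-sided Welch t-test
on the Log2 levels. Selection requires p < 0.05 and |fc| > 1.2, both
strict, with no multiple-testing correction — matching the screening
convention the pipeline feeds. Its role is panel selection on synthetic
data, not rediscovery of any published gene list.

## Numerical choices and degenerate inputs

- Sample SDs use the n−1 denominator throughout; fitting requires ≥ 2
  observations and fails loudly otherwise.
- All threshold comparisons are strict; ties go to the "unremarkable"
  state (Ave, Norm, not-selected).
- Percentages are rounded half-up via decimal arithmetic to avoid
  banker's-rounding surprises; fractions are also reported unrounded.
- A zero-variance control set gives a degenerate normal range where any
  deviation is perturbed; this is allowed, not an error.
- Identical constant case/control groups in the screen get p = 1 rather
  than the NaN a t-test would produce.
- Seeds: every stochastic routine takes an integer seed; the cohort
  simulator spawns independent child streams (NumPy `SeedSequence`) for
  release values, expression noise and plate effects, so outputs are
  bit-for-bit reproducible per seed.

## Problem sizes used in the shipped tests

Worked-example checks use the printed six-donor table and count tables
directly. Statistical properties use cohorts of 60–400 simulated donors,
5000-draw moment checks, 400–600-gene null screens, and brute-force
pattern enumeration up to 8 genes — sizes chosen to keep Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

- The responder-group proportions of any real cohort are not
  reproducible from summary statistics alone; the generator only matches
  the release distribution's first two moments.
- One observation per donor × gene is assumed; donors contributing
  multiple cultures would need aggregation upstream.
- The category rule generalizes the published 4-gene table to other
  panel sizes by induction; other generalizations (e.g. distinguishing
  multi-Down patterns) are possible but unsupported.
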