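# Methods

This note documents the models, parameter choices and numerical decisions
behind hdxfold, and what the synthetic-data tests do and do not demonstrate
about real HDX-MS data.

## Intrinsic exchange rates

`k_chem` for the amide of residue *i* is the three-limb sum
`k_A·[D⁺] + k_B·[OD⁻] + k_W`, evaluated from the poly-DL-alanine reference
constants for protium→deuterium exchange in D₂O (log₁₀ k_A = 1.62,
log₁₀ k_B = 10.05 M⁻¹min⁻¹, log₁₀ k_W = −1.5 min⁻¹ at 293.15 K, pK_D = 15.05)
with log-additive side-chain corrections from the residue owning the amide
and its N-terminal neighbor, plus terminal corrections for the amide of
residue 2 (protonated amine) and the C-terminal amide (carboxylate). The
parameter table ships as `data/intrinsic_rate_factors.tsv` with provenance
comments; ionizable side chains use their dominant near-neutral-pD forms
(Asp/Glu ionized, His neutral), which restricts validity to roughly
pD 5–9 — the acid limb below pD 4 is out of scope.

Decisions that matter:

- **pD convention.** pD = pD_read + 0.4. The offset cancels in all
  condition ratios but is applied for absolute rates.
- **Temperature.** Arrhenius scaling with E_a = 14 / 17 / 19 kcal/mol
  (acid / base / water) is applied to the catalytic constants only; pK_D is
  held at its reference value. With a temperature-dependent pK_D the
  (pD 7.1, 25 °C)/(pD 6.1, 0 °C) rate ratio would land near 10³; holding it
  fixed yields 1.4 × 10², consistent with the dual-condition merging factor
  this package is designed around. The package computes the factor it uses
  (138.1 for the default conditions) rather than hard-coding 140.
- **Urea.** `k_chem` is multiplied by `0.5^(M/4)`: log-linear in molarity,
  anchored at the well-established ~50% slowing at 4 M. This is an
  extrapolation outside 0–4 M.
- **Protein-level τ_chem.** 1 / arithmetic-mean per-residue rate. Any
  averaging convention gives the same *ratio* between conditions (the only
  quantity consumed downstream), because the condition change rescales every
  residue's base-catalyzed rate by a near-common factor.

## Normalization and time-axis merging

Corrections are applied in a fixed order — subtract the in-exchange
centroid, divide by the labeling deuterium fraction, rescale so the
maximally labeled control equals the exchange-competent residue count —
which makes both control endpoints exact by construction. The
exchange-competent count is peptide length − 2 − (prolines past position 2):
the first two residues lose their label completely during quench and
digestion, and proline has no amide proton. Region names follow the
third-residue convention (`Region_{start+2}–{end}`).

Slow-condition labeling times are divided by the intrinsic-rate ratio and
merged onto the reference axis. Under EX2 with condition-independent
protection factors the merged curve is single-valued; overlapping effective
times disagreeing by more than 3 pooled SD raise a warning rather than an
error, since real data are only "mostly" EX2. Corrected values are clipped
to [0, n_exchangeable]: control noise can push them marginally outside the
physical range.

## Curve fitting

**Stretched exponential** `A(1 − exp(−(kt)^β))`, β ∈ (0.05, 1], weighted by
the curve's pooled replicate SD. Only the characteristic-rate ratio between
states is interpreted (`ΔΔG = R T ln(k_a/k_b)`); β is reported as a
dispersion diagnostic but never converted to thermodynamics — the stretched
summary is a deliberately rough peptide-level estimator. Peptides below 10%
deuteration at the longest labeling time (≥10⁴ s required) are excluded from
fitting; the 10% boundary is inclusive.

**Sum of exponentials** `Σ aᵢ(1 − e^(−kᵢt))` with free non-negative
amplitudes. Rates are constrained to [10⁻⁸, 10³] s⁻¹. Numerical choices:

- χ² uses the curve's pooled (RMS) replicate SD as a uniform weight, floored
  at 0.06 Da when no replicates exist. Per-timepoint SDs from 2–3 replicates
  are too noisy to weight with individually and cause overfitting.
- Multi-start initialization: rates log-spaced across the sampled window,
  five seeded random jitters (default seed 20230606), plus nested starts
  that reproduce the best (n−1)-fit with a vanishing extra component. With
  zero amplitude floor the nested start guarantees χ² is non-increasing in
  n.
- Each accepted component must carry ≥ 0.4 Da of amplitude — about half an
  exchange-competent residue — so noise blips cannot become rate classes.
- For back-exchange-corrected curves a pseudo-observation anchors the total
  amplitude at n_exchangeable (the full-D control pins the plateau), which
  removes the rate/amplitude degeneracy of slow components sampled by only
  a few points.
- Model selection: starting at n = 1, a larger model is accepted while it
  converges, keeps every relative rate error `sd(kᵢ)/kᵢ < 1` (from the
  scaled approximate covariance of the least-squares solution), and lowers
  χ² by ≥ 5% — ties break toward smaller n, and a χ² already at numerical
  zero is never refined further. If n = 1 itself fails the error screen it
  is returned flagged as a fallback.

## Residue assignment and σ_ΔG

Rates are assigned to residues by fraying direction: the helix terminus
declared least stable (from the structure-derived annotation table, never
inferred from the data) receives the fastest rate, and stability increases
inward. With n rates and m residues, residues are partitioned into n
contiguous blocks of ⌊m/n⌋; the m mod n leftover residues sit on block
boundaries (nearest the fraying end first) and take the geometric mean
`(kᵢ·kᵢ·kᵢ₊₁)^(1/3)` — for 8 residues and 3 rates this reproduces the
canonical pattern `k₁,k₁,(k₁²k₂)^⅓,k₂,k₂,(k₂²k₃)^⅓,k₃,k₃`. When the fit
also provides amplitude estimates, block sizes come from the amplitudes
instead (largest-remainder rounding of `aᵢ/Σa·m`), which reduces to the
equal-block scheme for equal amplitudes and substantially improves σ_ΔG
accuracy when rate classes carry unequal numbers of residues.

Per-residue stability is `ΔG = −R T ln(k_chem/kᵢ − 1)` at T = 298.15 K
(R = 1.987 × 10⁻³ kcal mol⁻¹ K⁻¹); the formula is undefined at PF ≤ 1, and
such unprotected residues are excluded from σ_ΔG with a logged count rather
than clamped. σ_ΔG is the **sample** (n−1) standard deviation of the finite
per-residue ΔG — the sample convention is what makes the 4-residue/5-decade
construction evaluate to 2.9 and the 8-residue/3-rate/2-decade construction
to 1.1 kcal/mol. Classification thresholds are configurable and default to
< 0.5 cooperative, 0.5–1.5 mildly cooperative, > 1.5 fraying. σ_ΔG is
invariant under a common rate factor in the high-PF limit (a uniform ΔG
shift).

## Differential analysis

The hybrid test flags a (peptide, time) cell only if |ΔD| exceeds the global
threshold `z₁₋α/₂·√2·SD_pooled` (0.166 Da at the 0.06 Da repeatability and
α = 0.05) *and* a Welch unequal-variance t-test on the replicate groups
rejects at α. SD_pooled is the RMS of all per-cell replicate SDs; with no
replicates anywhere the test is undefined and errors. No multiple-testing
correction is applied beyond the two-criterion conjunction, matching
standard practice for this test. Heatmap differences use
deuterium-fraction-corrected uptake (a flag disables this). Residue ΔΔG is
the arithmetic mean over covering peptides' exchange-competent spans;
uncovered residues are absent, not zero. Structure maps write values into
the B-factor column (sentinel 0.00 for unmapped residues), bit-exact to PDB
precision of two decimals.

## Synthetic data

The generator emulates: per-residue EX2 uptake
`d·(1 − exp(−k_chem·t/PF))`; overlapping peptide maps with mean length 12.2
and mean coverage redundancy 4.3 (duplicate spans suppressed); per-peptide
back-exchange from a logit-normal matched numerically to mean 0.27 /
IQR 0.14 and in-exchange matched to mean 0.031 / IQR 0.020 (only these
moments are specified; logit-normal keeps draws in (0,1) with realistic
skew); Gaussian replicate noise of SD 0.06 Da; and control rows generated
from the same per-peptide draws. In-exchange is modeled as quench-time
labeling of the not-yet-exchanged amides, which makes the correction exactly
invertible in the noiseless limit. All randomness flows through one seed.

Two study designs are bundled. The *cooperativity study* places a frayed
peptide (4 competent residues, target rates evenly log-spaced over five
decades and anchored inside the dual-condition observation window, giving a
generating σ_ΔG of 3.1 kcal/mol) and a cooperative poly-Ala peptide
(8 residues sharing one stability with variance-exact 0.3 kcal/mol jitter,
so the realized unit dispersion equals the nominal one) on a 60-residue
construct, sampled on the dual-condition grid (1/10/90 s slow;
6 s–27 h fast). The *binding study* stabilizes a 120-residue span of a
220-residue random sequence by `R T ln(1 + [L]/K_d)` (thermodynamic
linkage; 1.8 kcal/mol by default). Micelle shielding (a constant
apparent-PF multiplier, default 100, for unfolded spans with restricted
catalyst access) and EX1-like spans (opening-limited exchange that does not
scale with k_chem; used only to exercise the EX2-consistency warning) are
available and off by default.

What the synthetic tests show: the pipeline's corrections are exactly
invertible, model selection finds the generating number of exponentials
when rates are resolvable within the sampled window, σ_ΔG is recovered
within 0.3 kcal/mol (median over three seeded replicate studies, which
damps single-draw Monte-Carlo noise), and a uniform binding perturbation is
recovered within 0.2 kcal/mol on ≥ 80% of densely covered site residues.
What they do not show: robustness to chromatographic carryover, peptide
misassignment, EX1/EX2 mixtures beyond the centroid level, pH mis-reading,
or residue-level deconvolution across overlapping peptides — the last is
deliberately out of scope, replaced by the fraying assignment scheme.

## Known limitations

- The side-chain correction table is a fixed-form transcription; positions
  flanked by ionizable residues near their pK are less accurate.
- ΔΔG from stretched-exponential rate ratios is approximate: β ≠ 1 means
  the characteristic rate conflates dispersion with stability shifts.
- Rates near the edge of the sampled time window (a single informative
  timepoint) fail the relative-error screen by design and are absorbed into
  the nearest resolvable class, biasing σ_ΔG downward for extreme fraying.
- The time-axis merge assumes condition-independent protection factors; for
  proteins whose stability differs between labeling conditions the EX2
  warning will fire, and the merged curve is not meaningful.
- Problem sizes in the test suite (60–320 residue constructs, ≤ ~80
  peptides per state) were chosen to exercise every code path with dense
  coverage; the algorithms scale linearly in peptides and timepoints.
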