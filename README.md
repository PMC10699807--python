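# hdxfold

Peptide-level analysis of hydrogen–deuterium exchange mass spectrometry
(HDX-MS) for proteins whose function hinges on a local folding equilibrium —
the motivating case being membrane transporters whose anion-binding site
folds upon ligand binding. The package turns centroid deuterium-uptake
tables into per-peptide and per-residue thermodynamics: protection factors,
unfolding free energies, ligand-linked ΔΔG maps, and a per-peptide
cooperativity statistic that distinguishes helix fraying from concerted
(foldon-like) unfolding.

## What it computes

Under EX2 exchange, an amide's observed rate is `k_obs = k_chem / PF`, where
`k_chem` is the intrinsic rate of the unstructured chain (computed here from
the standard poly-DL-alanine reference parameters with neighbor, terminal,
pD, temperature and urea corrections) and `PF` is the protection factor of
the opening equilibrium. The package implements:

- **Condition merging.** Labeling performed at pD_read 6.1 / 0 °C is mapped
  onto the pD_read 7.1 / 25 °C time axis by the mean intrinsic-rate ratio of
  the two conditions (≈ 1.4 × 10² for these condition pairs: a factor 10
  from one pD unit and ≈ 14 from Arrhenius scaling of base catalysis),
  stretching the observable dynamic range to ~7 log units.
- **Normalization.** In-exchange subtraction, deuterium-fraction correction,
  and back-exchange rescaling against the maximally labeled control, in that
  order, so that the full-D control maps exactly onto the exchange-competent
  residue count (peptide length − 2 − prolines past position 2).
- **Peptide ΔΔG.** Each state's uptake curve is summarized by a stretched
  exponential `A(1 − exp(−(kt)^β))`; between states,
  `ΔΔG = R T ln(k_a / k_b)`, averaged onto residues over all covering
  peptides.
- **Multi-exponential model selection.** `D(t) = Σ aᵢ(1 − e^(−kᵢ t))` with
  the number of exponentials chosen by χ² improvement and the requirement
  that every rate's relative error stays below one.
- **Cooperativity (σ_ΔG).** Fitted rates are assigned to residues by helix
  fraying direction (fastest at the frayed end; geometric means on block
  boundaries), converted to `ΔG = −R T ln(k_chem/kᵢ − 1)`, and the sample
  standard deviation of the per-residue ΔG is reported: σ_ΔG ≈ 0 means a
  concerted unit, large σ_ΔG means fraying.
- **Differential significance.** A hybrid test at α = 0.05: a global
  threshold `z₀.₉₇₅·√2·SD_pooled` on |ΔD| plus a per-cell Welch t-test.
  Residue ΔΔG maps can be written into the B-factor column of a PDB/mmCIF.
- **Synthetic ground truth.** A seeded generator produces EX2 datasets with
  realistic experiment statistics (peptide maps of mean length ~12 and
  redundancy ~4, back-exchange mean 27%/IQR 14%, in-exchange ~3%, replicate
  SD 0.06 Da), so every stage is testable without instrument data.

## Worked example

Simulate a ligand-binding study (a 220-residue synthetic protein whose
binding-site span is uniformly stabilized by 1.8 kcal/mol through
thermodynamic linkage) and run the full pipeline:

```bash
hdxfold simulate --study binding --seed 1 --out demo
cd demo && hdxfold run config.yaml
```

This writes `results/` with normalized curves, stretched-exponential fits,
peptide and residue ΔΔG tables, the differential heatmap with hybrid-test
flags, and a provenance log. With seed 1 the recovered binding-site residues
average ΔΔG = 1.77 kcal/mol against the generating 1.8, with 93% of covered
site residues within 0.2 kcal/mol.

The cooperativity study simulates one frayed peptide (4 exchange-competent
residues, rates spanning five decades) and one cooperative peptide
(8 residues sharing a stability within 0.3 kcal/mol jitter):

```bash
hdxfold simulate --study cooperativity --seed 1 --out demo2
cd demo2 && hdxfold run config.yaml
cat results/cooperativity.csv
```

```
peptide,n_residues,n_unprotected,sigma_dg_kcal_mol,classification
Peptide_11-17,4,0,2.793286989495026,fraying
Peptide_31-40,8,0,0.3303587598161465,cooperative
```

The frayed peptide is fit with four exponentials and σ_ΔG ≈ 2.8 kcal/mol
(generating value 3.1); the cooperative peptide needs only two closely
spaced rates and σ_ΔG ≈ 0.33 (generating value 0.30).

As library calls, the anchor computations are one-liners:

```python
from hdxfold import ExchangeConditions, condition_time_factor
fast = ExchangeConditions(pD_read=7.1, temperature=298.15, d_fraction=0.93)
slow = ExchangeConditions(pD_read=6.1, temperature=273.15, d_fraction=0.93)
condition_time_factor(fast, slow)   # 138.1 -> "factor of 140"
```

## Layout

- `src/hdxfold/chem_rates.py` — intrinsic rates, condition ratios, urea
- `src/hdxfold/hdx_io.py` — state tables, peptide/region bookkeeping
- `src/hdxfold/normalize.py` — corrections and time-axis merging
- `src/hdxfold/uptake_models.py` — stretched/multi-exponential fitting
- `src/hdxfold/cooperativity.py` — rate assignment, ΔG, σ_ΔG
- `src/hdxfold/differential.py` — hybrid test, residue maps, structures
- `src/hdxfold/synthetic_data.py` — seeded EX2 ground-truth generator
- `src/hdxfold/cli.py` — `hdxfold` command-line workflow
- `docs/methods.md` — model assumptions, parameter choices, limitations
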