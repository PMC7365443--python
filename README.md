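# mammoquant

Differential-abundance statistics for 4-plex isobaric-reporter (iTRAQ-style)
proteomics, gene-set enrichment, and the metabolic functional-assay arithmetic
that typically accompanies such studies — enzyme initial velocities, glycolytic
flux, intact-cell respirometry and sphere-formation efficiency — together with
synthetic-data generators that carry ground truth, so the whole chain can be
validated end to end without any external download.

It is written for proteomics/metabolism labs running small paired designs
(two replicate experiments, treatment vs control in each), where the usual
large-n statistical machinery does not apply and inference instead leans on a
fitted null of the ratio distribution.

## The statistical core

Peptide-level reporter intensities come in four channels; the default pairing
is experiment 1 = channel 115 (treated) over 114 (control) and experiment 2 =
117 over 116. For each experiment:

1. **Peptide ratios.** r = log2(I_treat / I_ctrl) per peptide; peptides
   failing the 1 % identification-FDR flag, or with a non-positive required
   intensity, are excluded from that experiment.
2. **Gaussian null.** The histogram of peptide log2 ratios (100 bins over
   median ± 5·1.4826·MAD) is fitted by nonlinear least squares with
   A·exp(−(x−µ)²/2σ²). The fitted (µ, σ) absorb systematic mixing/labelling
   offsets and set the ratio noise scale.
3. **Protein roll-up.** Protein ratio = median of its peptide ratios;
   proteins with fewer than two quantitated peptides are not quantified.
4. **p and q.** z = (r_protein − µ)/(σ/√n_peptides), two-sided normal p,
   Benjamini–Hochberg q ("quantitation FDR").
5. **Two-tier call.** *differential*: q < 0.05 in at least one experiment;
   *differential_concordant*: q < 0.05 in **both** experiments with the same
   ratio sign — the set conclusions are drawn from.

Enrichment uses the weighted Kolmogorov–Smirnov running-sum statistic on
proteins ranked by mean log2 ratio, with a gene-set permutation null
(p = (1 + #{|ES_null| ≥ |ES|}) / (1 + n_perm)) and BH q across sets.

The assay calculators implement: slope → enzyme units
(U = |slope|/(ε·l) · V, ε = 6.22 mM⁻¹cm⁻¹ for NAD(P)H at 340 nm, 1 U = 1 µmol
min⁻¹); glucose consumption and lactate production in µmol·h⁻¹·mg⁻¹ with the
lactate/glucose ratio checked against the glycolytic ceiling of 2;
respirometry summaries Cr (routine), CrO (oligomycin leak), CrU (FCCP-uncoupled
maximum), each corrected by residual non-mitochondrial respiration, plus spare
capacity CrU′ − Cr′ and coupling efficiency (Cr′ − CrO′)/Cr′; SFE % =
100·spheres/seeded; and the pooled two-tail Student t-test with the usual
star annotation.

## Worked example

```python
import mammoquant as mq

cfg = mq.ProteomicsSimConfig(n_proteins=300, frac_diff=0.05, seed=1)
peptides, truth = mq.generate_itraq_experiment(cfg)
classified, funnel, nulls = mq.quantify(peptides)
print(funnel)
print({e: (round(m.mu, 3), round(m.sigma, 3)) for e, m in nulls.items()})
```

prints

```
{'n_proteins': 300, 'n_quantified': 289, 'n_differential': 14, 'n_concordant': 13, 'n_up': 6, 'n_down': 7}
{'exp1': (0.005, 0.308), 'exp2': (0.001, 0.32)}
```

Fifteen of the 300 simulated proteins carry a true ±1 log2 effect; 289 are
quantified with ≥2 peptides in both experiments, 13 survive the concordance
filter (6 up, 7 down), and both fitted nulls recover the generating noise
(µ ≈ 0, σ ≈ 0.3). The same chain is available from the shell:

```sh
mammoquant simulate proteomics --seed 1 --out sim/
mammoquant quant --peptides sim/peptides.tsv --out quant/
mammoquant gsea --proteins quant/proteins.tsv --gmt my_sets.gmt --out gsea.tsv
mammoquant pipeline --seed 1 --out out/
```

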