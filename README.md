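# breedpanel

Design and evaluation of small SNP panels for breed-proportion
estimation in crossbred cattle.

## The problem

Crossbred dairy cattle in smallholder systems typically descend from
many unrecorded generations of crossing between exotic taurine dairy
breeds (Holstein, Friesian, Jersey) and indigenous indicine cattle.
High-density genotypes estimate the breed composition of such animals
accurately, but are far too expensive for routine use; a few hundred
well-chosen ancestry-informative markers can recover almost the same
estimates at a fraction of the cost.  `breedpanel` implements the full
design loop for such panels:

1. **QC** of PLINK/VCF genotypes: marker and animal call rates, IBS
   duplicate removal, autosome restriction.
2. **Marker ranking** by absolute allele-frequency difference |Δp|
   between reference groups (exotic vs indicine; Holstein-Friesian vs
   Jersey; Holstein vs Friesian).
3. **Physical-distance pruning**: greedy selection down the ranked list
   with a minimum distance between same-chromosome markers, including
   *step-wise* schedules that relax the distance in blocks (e.g.
   100 SNPs at 8.5 Mb, then 100 each at 7.5, 6.5, 4.5 and 3.5 Mb), so
   the panel stays spread across the genome while the list is deep
   enough to fill every block.
4. **Panel combination** of the two optimized panels in a stated ratio
   (e.g. 25% exotic-vs-indicine : 75% HF-vs-Jersey markers) so one
   assay resolves the deep split *and* the within-taurine axis.
5. **Supervised admixture**: per-animal ancestry proportions q on the
   K-simplex by maximizing the binomial admixture log-likelihood
   `sum_l [x_l log(sum_k q_k p_kl) + (2-x_l) log(sum_k q_k (1-p_kl))]`
   with an EM algorithm, holding the ancestral frequencies `p_kl` fixed
   at reference-sample estimates.
6. **Evaluation**: squared Pearson correlation (r²), linear bias and
   dispersion of panel estimates against full-marker estimates,
   overall and within subgroups.

Supporting machinery includes per-population allele frequencies,
Hudson and Weir–Cockerham F_ST, the VanRaden genomic relationship
matrix `GRM = ZZ' / (2 Σ p_l (1-p_l))` with PCA, and a
Balding–Nichols simulator of the whole system (drift-calibrated
reference breeds plus crossbreds with known ancestry) so every stage
can be exercised and validated without access to proprietary data.

## Worked example

```python
from breedpanel import (
    DEFAULT_SCHEDULES, abs_freq_diff, allele_frequencies, combine_panels,
    estimate_cohort, global_fst, make_evaluator, rank_markers, stepwise_select,
)
from breedpanel.simulate import study_preset, simulate_cohort

# a drift-calibrated cohort: 173 reference animals + 60 crossbreds
config = study_preset(seed=1, n_target=60, L=8000)
gm, truth, _ = simulate_cohort(config)

refs = ["H", "F", "J", "IND"]
pooled = {"EXO": ["H", "F", "J"], "HF": ["H", "F"]}
ref_gm = gm.subset_samples(gm.samples["population"].isin(refs).to_numpy())
pf = allele_frequencies(ref_gm, pooled=pooled)
print("F_ST(J,H) =", round(global_fst(pf, "J", "H"), 3))

full = estimate_cohort(gm, refs)                      # all-marker estimates
ranked_deep = rank_markers(abs_freq_diff(pf, "EXO", "IND"), pf.markers, "EXO_vs_IND")
ranked_taur = rank_markers(abs_freq_diff(pf, "HF", "J"), pf.markers, "HF_vs_J")
panel_deep = stepwise_select(ranked_deep, DEFAULT_SCHEDULES["EXO_vs_IND"])
panel_taur = stepwise_select(ranked_taur, DEFAULT_SCHEDULES["HF_vs_J"])
panel = combine_panels(panel_deep, panel_taur, total_size=500, ratio_a_percent=25)

metrics = make_evaluator(gm, refs, full)(panel)
for ancestry in ("IND", "HF", "J"):
    print(f"{ancestry}: r2 = {metrics[f'r2_{ancestry}']:.3f}, "
          f"bias = {metrics[f'bias_{ancestry}']:+.4f}")
```

Output:

```
F_ST(J,H) = 0.161
IND: r2 = 0.991, bias = -0.0024
HF: r2 = 0.991, bias = +0.0032
J: r2 = 0.873, bias = -0.0008
```

The Jersey–Holstein differentiation of the simulated references sits at
F_ST ≈ 0.16.  The combined 500-SNP panel (125 deep-split markers, 375
HF-vs-Jersey markers) recovers the full-marker indicine and
Holstein-Friesian proportions with r² ≈ 0.99 and the harder Jersey
proportion with r² ≈ 0.87 on this small cohort, with negligible linear
bias.  At the full study scale (200 crossbreds, 20,000 markers) the
Jersey accuracy rises to ≈ 0.95 (see below).

A command-line interface wraps the same stages
(`breedpanel simulate | qc | freqs | rank | select | combine |
estimate | evaluate | run-all`); `run-all` executes the whole workflow
from a YAML config and writes per-stage TSVs plus a JSON manifest with
output hashes for reproducibility.

## Layout

- `src/breedpanel/genotype_io.py` — PLINK/VCF readers and writers, QC filters
- `src/breedpanel/popgen.py` — allele frequencies, |Δp|, F_ST, GRM, PCA
- `src/breedpanel/panels.py` — ranking, distance pruning, schedules, combination
- `src/breedpanel/admixture.py` — supervised EM ancestry estimation
- `src/breedpanel/evaluation.py` — r², linear bias, subgroup reports
- `src/breedpanel/simulate.py` — calibrated Balding–Nichols generator
- `src/breedpanel/pipeline.py`, `cli.py` — workflow runner and CLI
- `docs/methods.md` — models, assumptions and design choices
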