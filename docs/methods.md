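# Methods

This note documents the models, conventions and design choices behind
`breedpanel`, in the order the workflow runs them.

## Genotype substrate and QC

Genotypes are diploid biallelic autosomal SNP calls stored as dosages
of the counted allele (PLINK A1 / VCF ALT) in {0, 1, 2} with a missing
sentinel.  All populations live in one merged matrix, so frequency
comparisons are orientation-consistent without strand handling;
merging across chips is the caller's concern and out of scope.

QC conventions:

- **Call-rate filter** (default > 0.9 for both markers and animals):
  markers are filtered first on the input matrix, then animals on the
  marker-filtered matrix — one pass each.  The order is a convention
  (common practice), logged per run.  The filter is idempotent on
  typical data; adversarial missingness patterns could in principle
  expose new low-call-rate markers after animal removal, which a
  second explicit pass would catch.
- **IBS duplicates** (threshold 0.98, strict `>`): per-locus IBS is
  `1 - |x_i - x_j|/2`, averaged over jointly non-missing loci.  The
  later-indexed member of a flagged pair is removed, deterministically.
- **Autosomes**: chromosome labels are opaque strings; the default
  autosome set is "1".."29" (cattle).
- An intensity-based genotype-confidence filter (Illumina GenCall)
  cannot be applied to hard calls and is assumed done upstream.

## Population-genetic summaries

Allele frequencies are computed per labeled group, with pooled groups
(EXO = H+F+J, HF = H+F) computed over the union of member samples.
Frequencies are undefined (NaN) where a group has no non-missing call;
undefined loci propagate as undefined differences and are excluded
from ranking.

**F_ST** defaults to Hudson's estimator in ratio-of-averages form,

    N_l = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
    D_l = pA(1-pB) + pB(1-pA)
    F_ST = sum(N_l) / sum(D_l)

with n counted in alleles and loci with n <= 1 alleles in either group
skipped.  Hudson is chosen for low bias and freedom from
within-population weighting choices; a two-population Weir–Cockerham
estimator (which additionally uses observed heterozygosity, hence
works from genotypes) is provided because global F_ST values are
estimator-dependent.  Note the ratio-of-averages form is unbiased only
for *independent* samples: feeding it two copies of the same animals
returns about -1/(n-1), not 0, because the sampling-noise correction
is then subtracting noise that is shared.

**GRM**: VanRaden method 1.  Missing calls are replaced by the
per-locus mean genotype; `Z = (M - 1) - 2(p - 0.5)` with p computed
over all samples of the analyzed matrix (references plus targets
pooled — whether the original analysis centred on references only is
not determinable, so the pooled convention is used and stated);
monomorphic loci contribute nothing and are excluded from the scaling
sum `2 Σ p(1-p)`.  PCA is the eigendecomposition of the GRM; scores
are eigenvectors scaled by sqrt(eigenvalue), variance fractions are
taken over positive eigenvalues only, and each component's sign is
fixed by making its largest-magnitude loading positive.

## Marker ranking and distance pruning

Markers are ranked by |Δp| descending; ties are broken by (chromosome,
position, marker id) ascending so ranking is a total order.  Pruning
is a greedy scan down the ranked list: a candidate is accepted iff its
distance to *every* accepted marker on the same chromosome is at least
the pruning distance.  Conventions, each tested:

- distance is `|pos_i - pos_j|` between 1-based bp positions, and the
  threshold is inclusive (exactly d apart is accepted);
- step-wise schedules (`(n, d)` blocks with strictly decreasing d)
  enforce each step's distance against **all** previously accepted
  markers, which makes step outputs nested prefixes of the final panel;
- markers rejected at a wide-distance step are reconsidered at later,
  narrower steps (the full ranked list is rescanned each step);
- a step that cannot reach its quota raises an error rather than
  silently relaxing the distance — schedules are designed precisely so
  each block can be filled, and a silent fallback would hide that the
  schedule no longer fits the data;
- `combine_panels(total, ratio)` takes `round(total*ratio/100)` from
  panel A then fills from panel B, preserving each panel's internal
  order; a marker in both panels is kept once (from A) and B
  contributes one extra so the total is exact.

The default schedules are 100@8.5 / 100@7.5 / 100@6.5 / 100@4.5 /
100@3.5 Mb for the exotic-vs-indicine comparison and 100@5 / 200@4 /
200@3 Mb for HF-vs-Jersey; the distance-sweep grid is 1–10 Mb in
0.5 Mb steps, panel sizes 100–500 and A:B ratios 50:50 down to 10:90
in 5-point steps.

## Supervised admixture

The likelihood of dosage x_l for an individual with ancestry q on the
K-simplex and fixed ancestral frequencies p_kl is binomial with
success probability `Σ_k q_k p_kl`; missing loci are skipped (not
imputed — unlike the GRM, where mean imputation is the stated
convention; the two stages intentionally differ).  Frequencies are
clamped into [1e-6, 1 - 1e-6] so loci fixed in a reference group
cannot produce infinite log-likelihoods.

Estimation is EM from a uniform start:

    q_k <- (1 / 2 L_obs) Σ_l [ x_l a_kl + (2 - x_l) b_kl ]

with a/b the posterior allocation of reference and alternate allele
copies to ancestries.  The update stays on the simplex without
projection and the log-likelihood is non-decreasing every iteration
(asserted in tests, and verified against an exhaustive 0.01-step
simplex grid search on small instances).  Default stopping rule:
log-likelihood gain < 1e-8 or 2,000 iterations; both are exposed, and
non-convergence is reported in the output rather than raised.  At
20,000 loci a minority of individuals near the simplex boundary hit
the iteration cap with gains of order 1e-7; their estimates are stable
to well below the reporting precision.

Supervision is a *fixed-P projection*: reference frequencies are point
estimates from the labeled reference samples and are never
re-estimated from the targets.  This keeps every animal's estimate
deterministic and independent of the composition or ordering of the
target cohort, at the cost of ignoring reference-frequency sampling
noise that a joint supervised model would propagate.  Higher-order
proportions (HF = H + F, EXO = H + F + J) are sums of components.

## Evaluation

Panel accuracy is the squared Pearson correlation between panel and
full-marker estimates (not regression R² through the origin); linear
bias is the mean of (panel - full) deviations and dispersion their
sample SD (n-1).  The dispersion column is the quantity reported as
the standard error of panel estimates in subgroup tables.  Subgroup
filters (e.g. "Jersey < 30%") are strict inequalities evaluated on the
full-marker estimates; subgroups with fewer than two animals or
degenerate variance are flagged rather than fatal.  Restricting a
subgroup shrinks the variance of the minor ancestry and therefore its
r², with little effect on the deviation SD — the expected and observed
pattern.

## Synthetic cohorts

The generator exists so the whole pipeline can be exercised and
validated without proprietary genotypes.  Structure: a rooted
population tree with Balding–Nichols drift on each branch — child
frequencies `Beta(p(1-F)/F, (1-p)(1-F)/F)` around the parent's p —
with ancestral frequencies Uniform(0.05, 0.95) per locus and the
topology (IND, (J, (H, F))).  Under this model the pairwise Hudson
F_ST between two leaves is approximately half the summed drift on
their connecting path, and the expected value of the two-population
check (both branches at F) is F itself.

The shipped preset calibrates the five free branch drifts by
sequential bisection on realized population-level F_ST at 50,000 loci
(two passes: deep scale, H/F scale at a ratio fixed by the J-H vs J-F
asymmetry, then the Jersey branch), targeting 0.16 (J-H), 0.137 (J-F),
0.074 (H-F) and ~0.35 for the indicine/taurine split, with a ±0.02
acceptance band.  Calibrated values are cached per process.

Preset study conditions, chosen once: reference panels of 24 Holstein,
24 Friesian, 24 Jersey and 101 indicine animals; 200 crossbred
targets; 20,000 markers uniformly placed on 29 autosomes spanning
160 Mb down to 40 Mb; 1% uniformly missing calls.  Target ancestry:
the indicine fraction is Uniform(0.01, 0.99) — crossbred cohorts of
this kind span essentially the whole indicine range — and the taurine
remainder is split by a two-component mixture of cross types,
93.6% Holstein-Friesian-type crosses (Dirichlet(4.6, 4.4, 1.0) over
H, F, J) and 6.4% Jersey-type crosses (Dirichlet(1.0, 2.5, 3.1)),
matching the relative cohort sizes and within-type breed-share means
and spreads of the field data the design targets.  Marker counts and
target numbers are scaled to desk hardware; accuracy results at this
scale track the full-density figures closely because panel accuracy is
limited by panel size, not by the density of the full set.

Loci are independent given frequencies — no background LD.  Because
distance pruning exists precisely to defeat local LD, a
*clustered-informativeness* mode plants, for each of the top loci by
deep-split |Δp| (default 150), four near-copies spaced 0.7 Mb apart
whose genotypes copy the parent locus with probability 0.95 (else an
independent draw), i.e. tight clusters of highly correlated, highly
ranked markers spanning ~2.8 Mb.  A 1 Mb pruning distance then still
admits several copies per cluster (redundant panels, lower accuracy)
while a ≥ 4 Mb distance admits one — reproducing the qualitative
benefit of wide pruning.  This is a stand-in for real LD structure,
not a model of any particular chip or population: passing tests show
the selection machinery responds correctly to clustered redundancy,
not that real-genome LD decays at these scales.

What the simulation does *not* emulate: linkage and recombination
(hence no realistic decay of LD with distance), ascertainment bias of
array content, genotyping error beyond uniform missingness,
within-breed substructure or relatedness among reference animals.
Accuracies obtained on synthetic cohorts therefore validate the
machinery and its qualitative behaviour, not field performance of any
specific panel.

## Numerical conventions

- Frequency clamp 1e-6 in the likelihood; EM tolerance 1e-8 on
  absolute log-likelihood gain; iteration cap 2,000.
- Calibration bisection: 22 iterations per knob, two sequential
  passes, ±0.02 acceptance band.
- Panel sizes/ratios `round()` to integers; rank ties broken by genome
  coordinate; IBS and call-rate thresholds compared with strict
  inequalities as stated above.
- All randomness flows from a single integer seed per simulation
  through `numpy.random.default_rng`; identical seeds reproduce
  cohorts bit-for-bit.

## Known limitations

- The supervised model ignores uncertainty in reference frequencies;
  with 24-animal reference panels the Jersey axis is the noisiest.
- Hudson F_ST assumes independent sampling of the two groups (see
  above); the Weir–Cockerham option mitigates estimator dependence but
  not that assumption.
- `combine_panels` does not re-check distance constraints *between*
  the two source panels; the combined panel inherits each source's
  internal spacing only.  The ratio sweep evaluates the combined panel
  as-is, which matches how such panels are assembled in practice.
- No strand/allele harmonization across filesets; inputs must already
  share allele orientation.
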