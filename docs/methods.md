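# Methods

`carrierscan` implements a carrier-based discovery-and-validation analysis
for rare deleterious germline variants in a case-control design, together
with a synthetic-cohort generator that supplies the statistical structure
the analysis assumes. This note records the models, the defaults and why
they are what they are, the numerical conventions, and what the synthetic
data can and cannot establish.

## The analysis model

All association machinery works on *carrier status*: a sample carries a
variant if its genotype is 1 or 2 (dominant coding). For rare alleles
(MAF ≪ 1%) homozygotes are vanishingly rare, so carrier coding loses almost
nothing and keeps every contingency table 2×2:

|               | carrier | non-carrier |
|---------------|---------|-------------|
| cases         | a       | b           |
| controls      | c       | d           |

Single-variant inference is Fisher's exact test, two-sided by
probability-mass summation: p = Σ P(X = x) over all tables with the
observed margins whose hypergeometric probability does not exceed the
observed table's. Two-sided exact tests have dialects; this one is stated
explicitly because the test suite pins it against full enumeration. The
odds ratio is (a·d)/(b·c); when any cell is zero, 0.5 is added to **all
four** cells (Haldane–Anscombe) before computing both the OR and its Wald
variance 1/a + 1/b + 1/c + 1/d. The 95% interval uses z = 1.959964
throughout the package.

### Filtering cascade

Variants enter association testing only if they pass, in order:

1. **Rarity** — reference-panel MAF strictly < 1% (`max_ref_maf`).
2. **Class** — consequence in missense ∪ protein-truncating (stop-gain,
   frameshift, essential splice, start-loss) ∪ UTR, with indel length
   ≤ 21 bp (`max_indel_len`).
3. **Deleteriousness consensus** — at least 4 of 6 prediction-tool
   verdicts deleterious (`min_deleterious_votes`); protein-truncating
   variants pass unconditionally, and missing verdicts count as
   non-deleterious (the conservative reading; the tools' behaviour on
   missing predictions is otherwise unspecified).

Rare variants classified pathogenic / likely pathogenic / VUS in ClinVar
are unioned back into the candidate set regardless of steps 2–3; the
rescue deliberately does **not** bypass the rarity step. Every step
reports survivor counts, and membership is pinned in tests against a
brute-force set-logic oracle.

### Call and sample QC

Call-level: quality ≥ 20, depth ≥ 10, and allele balance ≥ 0.2 for
heterozygous calls — all inclusive boundaries, failures set to missing,
never altered otherwise. Variant-level: post-QC call rate ≥ 0.85, no
overlap with low-complexity/segmental-duplication masks (BED convention,
0-based half-open). Sample-level: completion ≥ 0.95; heterozygosity-rate
outliers beyond mean ± 3 SD; sex discordance via X-heterozygosity
(< 0.2 ⇒ male, a conventional threshold); and relatedness via pairwise
rare-allele IBS sharing > 0.10, dropping the pair member with lower
completion.

Two guards exist because QC statistics degrade on small panels: the
relatedness rule requires ≥ 20 informative pairwise sites
(`min_ibs_sites`) — on a handful of rare variants, two unrelated samples
sharing a single allele would otherwise score IBS 1.0 — and the
heterozygosity rule requires ≥ 50 variants (`min_het_sites`), since on a
small rare-variant panel every multi-carrier is an apparent outlier.
Both rules are meant for exome-scale input, and the guards make that
explicit rather than silently misfiring.

### Gene-burden tests

**CMC** collapses a gene's qualifying variants to a binary
carries-any indicator and applies the exact carrier test above; the crude
Haldane-corrected OR is the primary estimate. When covariates are
supplied, a maximum-likelihood logistic fit reports an adjusted OR
*alongside* the crude one — both are retained because neither is uniformly
the published convention.

**KBAC** enumerates the distinct non-reference multi-site genotype
vectors ("patterns") over the gene. Pattern i, carried by n_i samples of
whom x_i are cases, gets the hypergeometric-kernel weight
w_i = P(X ≤ x_i), X ~ Hypergeom(N, n_cases, n_i) — the null probability of
at most the observed case enrichment — and the statistic is

    S = Σ_i w_i (x_i / n_cases − (n_i − x_i) / n_controls).

Significance is one-sided (risk direction) by label permutation with
weights recomputed under each permuted labeling, p = (1 + hits)/(1 + B).
Because patterns partition the samples, permuting labels is *exactly*
equivalent to drawing per-pattern case counts from a multivariate
hypergeometric distribution, which is how permutations are sampled — this
is an exact reformulation, not an approximation, and it makes each
permutation O(#patterns). Per-pattern CDF lookup tables are precomputed
once. Permutation stops early when the accumulated hit count already
guarantees the full-run p-value would exceed `early_stop_p` (default 0.1);
the reported p is then computed on the permutations actually run and is
itself above the threshold, so rejection decisions at conventional α are
unaffected. Default B = 10,000 with a mandatory seed. Samples missing any
call in the gene are excluded listwise for that gene (treating missing as
reference would deflate the burden).

### Sparse-count meta-analysis

Validation strata are carrier 2×2 tables from heterogeneous cohorts, some
case-only paired with control-only cohorts. Per stratum: if any cell is
zero, add 0.5 to all four cells, then ln OR and variance as above;
0/0-carrier strata are *retained*, contributing a near-null, heavily
down-weighted effect rather than vanishing. Pooling is inverse-variance
fixed-effects (one common true OR): pooled = Σ wᵢ ln ORᵢ / Σ wᵢ with
wᵢ = 1/varᵢ, SE = (Σ wᵢ)^(−1/2), Wald p via the complementary error
function, Cochran's Q and I² = max(0, (Q − df)/Q) for heterogeneity.

This exact scheme — all-cell correction, per-stratum only, zero strata
retained — reproduces the published pooled ORs and CI bounds for all five
validated candidates from their printed carrier counts. Alternatives
(dropping zero strata, single-cell correction, Peto) do not, which is why
it is fixed as the package default rather than offered as an option. Two
documented edge facts: the ATM upper CI bound computes to 75.8 against a
printed 75.6, and the MLNR pooled OR reproduces only over the three
sequencing strata while its printed *total carrier frequencies* include
the genotyping-array stratum. Hence the default stratum set is the
sequencing pairs (`include_array_strata=False`), while aggregate carrier
frequencies always sum the uncorrected counts of every supplied stratum.

### Prioritization and assay utilities

A gene is flagged constraint-intolerant iff the upper bound of its LoF
observed/expected 90% CI is strictly below 0.35. Ranking is deterministic:
evidence-flag count desc, burden FDR q asc, phenotype-relevance score
desc, gene symbol asc. Phenotype-relevance scores are consumed as inputs;
the ontology tooling that produces them is out of scope.

The assay helpers are closed-form: relative expression 2^−ΔΔCt with
replicate Ct values aggregated by arithmetic mean and no efficiency
correction, and the flow-cytometry damage ratio (Q2/Q3)/(Q1/Q4), undefined
when a background quadrant is empty.

## The synthetic-cohort generator

Real cohorts of this design are controlled-access, so the generator
emulates their structure:

* **MAFs** log-uniform on (1e-4, 0.01] by default — rare-variant studies
  span orders of magnitude in frequency, and log-uniform puts mass across
  all of them.
* **Genotypes** Hardy–Weinberg binomial(2, MAF) per variant; no inbreeding
  structure is modeled.
* **Disease** logistic: logit P(case) = β₀ + Σ β_v·carrier_v +
  Σ γ_c·covariate_c + Σ δ·carrier·exposure. The intercept β₀ is calibrated
  (Monte-Carlo average over 20,000 draws, Brent root-finding) so the
  population case fraction equals n_cases/(n_cases + n_controls); sampling
  then retains exactly the requested counts. Because the odds ratio is
  invariant under this retrospective sampling, the carrier OR recovered
  downstream equals exp(planted log-OR). An unreachable case fraction
  raises a calibration error.
* **Covariates** patterned on a smoking-enriched lung-cancer design:
  age ~ N(62, 11²) clipped to [20, 95]; 58% male; 75% ever-smokers;
  pack-years ~ Gamma(2, 20) among smokers and exactly 0 for never-smokers;
  family history yes/unknown/no at 25/10/65%. Defaults carry no effect on
  disease unless effects are configured, which keeps the marginal carrier
  OR collapsible for parameter-recovery checks.
* **Call metadata** quality ~ N(60, 15²) truncated at 0, depth ~
  Poisson(52) (a realistic mean on-target exome coverage), allele balance
  ~ Beta(20, 20) for heterozygous calls; missingness completely at random
  (no informative-missingness model is described for this design).
* **Validation strata** are all drawn from the one generative model fixed
  by the config, so a single true OR is common across strata — the
  fixed-effects assumption holds by construction. Case-only cohorts pair
  with the next control-only cohort in design order; an unpaired case
  cohort is a configuration error.

Everything is deterministic under the config seed, using independent
numbered substreams (`default_rng([seed, stream])`) so that, e.g.,
annotation simulation and genotype simulation see consistent MAFs.

**What passing tests on synthetic data do and do not show.** The generator
produces independent variants (no linkage disequilibrium — reasonable for
rare variants, which exhibit little LD), clean Hardy–Weinberg sampling, no
population structure or batch effects across cohorts, and family history
as a covariate only (cases in the real design were *ascertained* for
family history; no ascertainment model is published, so none is
simulated). Calibration and recovery results therefore validate the
statistical machinery under the model's own assumptions; they do not
certify behaviour under stratification, differential missingness, or
platform artifacts.

## Numerical conventions and test problem sizes

* z = 1.959964 for all 95% Wald intervals; normal tails via erfc.
* Permutation tie handling: permuted statistics within 1e-12 of the
  observed value count as hits (conservative).
* Exact-test oracle equivalence is verified exhaustively for every 2×2
  table with N ≤ 30 and over deterministically sampled margins up to
  N = 60; enumeration and the implementation must agree to 1e-9 relative.
* Burden-test calibration runs 600 null cohorts (300 cases / 300 controls,
  10 variants, MAF 0.02–0.05, 1000 permutations): carrier counts dense
  enough that exact-test discreteness does not dominate the attained
  level. Power monotonicity uses a 3-point planted log-OR grid (0, 0.8,
  1.6) at 60 replicates per point; OR-recovery coverage uses 200
  replicates of 20,000 + 20,000 samples at MAF 0.005 with planted OR 4.48.
* Derived per-gene permutation seeds come from `SeedSequence([seed, i])`
  reduced below 2³¹.

## Known limitations

* The KBAC implementation is the one-sided risk-direction test; protective
  gene effects are better read from the CMC OR.
* The G×E model is a logistic fit with a product term (the published
  description of the interaction model is ambiguous); degenerate tables
  fall back to a stratified exact comparison, and the two methods are
  labeled in the result, not interchangeable.
* Aggregate carrier frequencies and pooled ORs may legitimately use
  different stratum sets (see meta-analysis section); reports carry both
  conventions explicitly.
* The cascade classifies in-frame indels as not qualifying under the
  class step (they can still enter via ClinVar rescue); they are a
  borderline category in published practice.
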