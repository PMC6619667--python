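# Methods

## Count model and differential expression

Counts for gene *g* in sample *j* are modelled as negative binomial with
mean `s_j · m_g(group_j)` and variance `μ + α_g μ²`. Size factors `s_j` are
median-of-ratios: the median over reference genes (positive counts in all
samples) of the ratio of a sample's count to the gene's geometric mean;
with an even number of reference genes the median is the midpoint of the
two central ratios. Normalized counts are `K_gj / s_j`.

**Filtering.** Two low-count rules are implemented because they answer
different questions. The default `min_rule` keeps a gene only if it has
≥ 10 normalized counts in *every* sample of a comparison — the conservative
rule, which also removes genes expressed in only one group. `any_rule`
discards a gene only when it is below threshold *everywhere*. Both
boundaries are inclusive. Each pairwise comparison computes its own size
factors and filter, so different comparisons legitimately have different
gene universes; the inheritance classifier runs on their intersection.

**Testing.** The engine is deliberately plain: gene-wise ML dispersion and
an unshrunk Wald test, not an empirical-Bayes implementation. The
downstream classifiers consume only the sign of the log2 fold change and
its BH significance, for which posterior shrinkage of fold changes is
immaterial; no bit-compatibility with any external DE package is promised.
Dispersion is profiled on a log grid (41 points in [0, 10] plus a local
refinement) with group means held at their Poisson fits — a standard
two-step profile that is accurate because the mean score's weights vary
slowly in α. Group means are then re-fit by Newton under the chosen α, and
the Wald statistic for the contrast uses the observed Fisher information
`I_g = Σ_j μ_j/(1+αμ_j)` of each log group mean. An optional shrink of
dispersions toward a fitted `a₀ + a₁/mean` trend is available
(`shrink_to_trend`), default off: at the replicate numbers this design
targets (≥ 6 per parental group pooled into 12-sample comparisons) the
gene-wise estimates are already stable, and the plain estimate keeps the
test's behaviour easy to reason about.

**Degenerate inputs.** An all-zero gene gets α = 0 with a warning. A group
whose counts are all zero has its fitted mean floored at half a count
(0.5/Σs) and the gene is flagged `zero_group_mean`; the reported log2 fold
change then uses a 0.5 pseudocount on the normalized group means, while
the test statistic comes from the floored GLM fit.

## Inheritance classification

With both hybrid comparisons oriented hybrid-over-parent: no significance
vs either parent → *conserved*; significance vs exactly one parent →
*dominant* toward the parent the hybrid matches; significance vs both with
both fold changes positive/negative → *over-/underdominant*; significance
vs both with opposite signs (hybrid between parents) → *additive*. Whether
*additive* should additionally require parent1-vs-parent2 significance is
genuinely ambiguous in the classification scheme's verbal statement; the
default does **not** require it, and `require_parental_de=True` demotes
non-divergent in-between genes to *ambiguous*. A gene significant against
both parents with a fold change of exactly zero on one side (a measure-zero
tie) is *ambiguous*. "Misregulated" in the headline sense is a separate
flag from the hybrid-vs-pooled-parents comparison; the mode partition and
this flag are reported side by side because they answer slightly different
questions (the pooled test has more power but blends the two parental
means). Mode proportions are always printed with numerator and denominator;
because they are computed from the calls themselves, the partition sums to
100% by construction.

## Allele-specific expression

Only sites heterozygous — and covered — in **every** analysed sample enter,
so hybrids and parents are tested at identical sites; default retention
requires total depth ≥ 20 in each sample (per-allele minima of 10 or 100
reproduce the stricter readouts). The per-site test is the exact two-sided
binomial against ½ with the minimum-likelihood convention (identical to R's
`binom.test`; at p₀ = ½ this equals twice the symmetric tail). A gene shows
hybrid ASE when some single site is significant in *all* hybrids with the
same favored allele — the strict reading of "consistent biased expression";
same-direction bias with pooled significance would be more lenient and is
intentionally not the default. A gene shows parental ASE when *any*
parental sample is significant at *any* site. Genes with no retained sites
are absent/unevaluable, never "no ASE".

The gene-level pseudo-phasing test assigns the larger count at each SNP to
a putative major haplotype; the statistic is Σ major / Σ total. Its null
re-applies the same assignment to (beta-)binomial(nᵢ, ½, ρ) draws, which
corrects the selection bias of the assignment, and the p-value uses the
add-one estimator (1 + #{null ≥ obs})/(n_sim + 1) so it can never be zero.
ρ defaults to 0 (pure binomial null); it is exposed for overdispersed data.
The default n_sim = 10,000 gives a minimal attainable p of ~10⁻⁴,
sufficient at the 0.05 working level; increase it when genes must be
ranked deep into the tail.

## Compensatory mechanism calls

The three-criterion rule (no parental DE, hybrid ASE, no parental ASE) is a
pure decision table over its boolean inputs, plus the misregulation flag to
split `compensatory_misregulated` from `compensatory`. Percentages are
reported against the number of evaluable genes without parental DE, with
raw counts alongside, because percentage-only reporting is ambiguous when
several denominators coexist. A full cis/trans/cis+trans decomposition is
deliberately not the default output — it presupposes fixed coding SNPs
between the parental lineages, which very recently diverged species pairs
lack; an optional `cis_consistency` annotation is provided and clearly
labelled as an extra.

## Batch-bias correction and degradation QC

The correction multiplies the raw misregulation percentage by the **count
ratio** `n_matched / n_mismatched` from a calibration pair of comparisons
(same hybrids against same-kit vs other-kit parents). The alternative —
dividing the two calibration *percentages* — is rejected because the two
calibration comparisons have different filtered-gene denominators; with the
canonical calibration inputs (370 matched, 997 mismatched, raw 51.6%) the
count ratio yields 19.1%. Note 370 → 997 is a 169% increase (ratio 0.371);
both numbers are reported rather than a single ambiguous "increase"
figure.

TIN is the entropy-based effective breadth of coverage:
`100·exp(−Σ pᵢ ln pᵢ)/k` over positions with nonzero depth, k = transcript
length. It is scale- and permutation-invariant, 100 for uniform coverage,
100/k for a single covered base. Background-noise subtraction from
alignment-level TIN implementations is out of scope here because the
pipeline consumes coverage vectors, not alignments. Two-group QC metric
comparisons use Welch's t-test, ≥ 3 groups a classical one-way ANOVA;
groups with fewer than two samples skip the metric with a flag. The
ASE-vs-TIN relationship is ordinary least squares with the exact t-test on
the slope, refit on the complement of any exclusion set (≥ 3 points).

## Synthetic data generator

The generator emulates the targeted crossing design: 6 + 6 parental
replicates and 4 hybrids by default, NB totals with log-normal gene means
(median 200 normalized counts, sdlog 1 — a realistic bulk RNA-seq dynamic
range), log-normal gene-wise dispersions (median 0.05, sdlog 0.5, typical
of good bulk libraries), log-normal library sizes (sdlog 0.15). Regulatory
architectures: *conserved* (equal parental means, hybrid allelic ratio ½),
*cis* (divergent means, ratio μ₁/(μ₁+μ₂)), *trans* (divergent means, ratio
½) and *compensatory* (equal means, ratio 2^±e/(1+2^±e) for effect size e;
with probability 0.5 the hybrid total is additionally shifted ±e,
reflecting that compensation predisposes to, but does not guarantee,
misregulation). Hybrid totals for cis/trans genes default to the parental
mean (additive inheritance); a mode mixture can instead draw dominant or
transgressive totals, whose implied means are μ of the matching parent or
the more extreme parent scaled by 2^±e. Effect sizes default to
Uniform(1, 3) log2 units — the detectable range of between-species
divergence at these depths. The default mixture (85/5/5/5) produces a few
percent parental DE and a low single-digit misregulation percentage,
matching a whole-larva-like baseline.

Allele counts are generated **only at sites heterozygous in every sample**
(1 + Poisson(2.9) sites per gene; log-normal depths, median 80, sdlog 0.6,
floored at 2). Parental samples draw balanced alleles — their het sites are
within-population polymorphism unrelated to the divergent regulatory
alleles — while hybrids draw at the architecture's ratio, optionally
beta-binomially overdispersed. The batch effect is a single knob: a
per-gene × per-kit multiplicative log-normal factor (centered per gene
across kits, so a single batch is the identity and the between-kit
log-ratio has SD σ√2); duplicate-read inflation is not modelled separately
because the analysis diagnoses the bias only through count-level
consequences. Degradation scales coverage by `exp(−λ·d/L)` with d the
distance from the 3′ end, and couples to ASE through a single binomial
thinning of allele 2 — a deliberately simple stand-in for composition-
dependent decay. What the generator does *not* emulate: read-level
artifacts (mapping bias, PCR duplicates as such), non-shared het sites,
sequence content, multi-factor designs. Passing tests therefore validate
the statistical machinery under its own model assumptions, not robustness
to alignment-level artifacts.

## Validation experiments (`hybridmisreg.experiments`)

Problem sizes are chosen to mirror the targeted design while running in
minutes on one CPU; all randomness derives from a single seed.

* **Null calibration** — 20 all-conserved replicates of 2,000 genes
  (6/6/4): the pooled-parent misregulation call rate at FDR 0.05 must stay
  within 0.05 + 2 SE (it is ~0.003: BH on an all-null universe rejects
  rarely). The per-site binomial test's attained size on balanced sites is
  ≤ 0.05 by the exact test's discreteness (~0.037 at these depths).
* **Transgressive recovery** — 2,000 genes, 40% cis/trans with 60%
  transgressive totals, effects 1.5–2.5 log2 units at the design's depth:
  ≥ 80% of filtered transgressive-truth genes must be called
  over/underdominant (observed ≈ 100%).
* **Compensatory recovery** — the classifier's sensitivity ceiling is
  `(1−a)^(sites × parental samples)` with *a* ≈ 0.04 the attained size of
  the exact test at depth ~120, because one nominally significant parental
  site excludes the gene. The experiment therefore uses a minimal design —
  one deep site (120×) per gene, allelic ratio 0.8, three replicates per
  parental species, four hybrids — measuring sensitivity against that
  intrinsic ceiling (≈ 0.78) rather than against the exclusion rule's
  multiplicity; requirement: sensitivity ≥ 70%, conserved-gene false
  positives ≤ 5%. Under the full 12-parent, ~4-site design the same
  classifier's sensitivity necessarily drops to ~0.2 — a property of the
  three-criterion rule itself worth remembering when interpreting real
  compensatory-gene counts.
* **Bias-correction validity** — 20 replicates, each with a focal and an
  independent calibration experiment (1,000 genes, ~6% true misregulation,
  kit factor σ = 0.3 between hybrids and parents): the corrected
  percentage must land closer to the batch-free truth than the raw one in
  ≥ 90% of replicates (observed 20/20; raw ≈ 49% vs truth ≈ 6% vs
  corrected ≈ 6.4%).

## Known limitations

* The Wald test is mildly anticonservative at very small replicate numbers
  (3–4 per group) in the far tail, as all unshrunk NB Wald tests are; BH
  keeps the realized null call rate far below the nominal FDR in the
  calibration experiments.
* The pseudo-phasing test's resolution is bounded by n_sim.
* The compensatory classifier's sensitivity degrades geometrically with
  the number of parental tests (see above); it is a conservative screen,
  not an estimator of the compensatory fraction.
* Percentages are rounded to two decimals by default; summaries always
  carry numerator and denominator so no information is lost to rounding.
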