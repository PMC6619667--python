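# hybridmisreg

Analysis of **gene misregulation in F1 hybrids** from bulk RNA-seq counts:
inheritance-mode classification, allele-specific expression (ASE) at shared
heterozygous sites, detection of putative compensatory regulatory divergence,
and correction of misregulation estimates for library-preparation batch bias.
A synthetic-data module generates complete experiments with known truth, so
every stage of the analysis is testable without any sequencing data.

## The scientific problem

When two recently diverged species are crossed, their F1 hybrids combine
*cis*-regulatory elements from both parents in a single *trans* environment.
Stabilizing selection lets opposing cis and trans changes accumulate while
total expression stays at its optimum in each parent; in the hybrid the
mismatched combination no longer compensates, producing **misregulation** —
transgressive expression above (*overdominant*) or below (*underdominant*)
both parents — an early signature of Dobzhansky–Muller incompatibilities.

The pipeline operates on a gene × sample count matrix from parents and
hybrids, plus allele counts at sites heterozygous in every sample:

1. **Normalization & differential expression.** Median-of-ratios size factors
   `s_j = median_g (K_gj / (∏_j K_gj)^{1/n})`, a low-count filter (default:
   ≥ 10 normalized counts in *every* sample), and a negative-binomial Wald
   test per gene, `K_gj ~ NB(s_j m_g(group_j), α_g)`, with gene-wise ML
   dispersion and Benjamini–Hochberg adjustment at FDR 0.05.
2. **Inheritance classification.** From hybrid-vs-parent1, hybrid-vs-parent2
   and parent1-vs-parent2 tests each gene is *conserved*, *additive*,
   *dominant* toward one parent, or transgressive (*over/underdominant*);
   a separate hybrid-vs-pooled-parents comparison flags misregulation.
3. **ASE.** Exact binomial tests of allelic balance per site and sample
   (two-sided, minimum-likelihood convention, as in R's `binom.test`), plus a
   conservative gene-level pseudo-phasing test: the larger-count allele at
   each SNP joins a putative major haplotype and the gene-wide major-allele
   fraction is compared against (beta-)binomial(n, ½) simulations with the
   same assignment.
4. **Compensatory mechanism calls.** A gene is compensatory when it is (1)
   not differentially expressed between the parent species, (2) shows ASE in
   every hybrid with a consistent direction, and (3) shows no ASE in any
   purebred parental sample.
5. **Batch-bias correction & QC.** When hybrids and parents were prepared
   with different library kits, the raw misregulation percentage is rescaled
   by the count ratio `n_matched / n_mismatched` from a calibration pair of
   comparisons; transcript integrity numbers (TIN,
   `100·exp(−Σ pᵢ ln pᵢ)/k`) quantify degradation, and per-sample ASE
   proportions are regressed on median TIN.

## Worked example

Simulate a 500-gene experiment (6 + 6 parents, 4 hybrids), compare the
parental species, and run the whole pipeline:

```bash
hybridmisreg simulate --seed 1 --genes 500 --out-dir sim
hybridmisreg de --counts sim/counts.tsv --samples sim/samples.tsv \
    --group-a parent1 --group-b parent2 --out de_p1p2.tsv
# -> 55 out of 495 genes significant (11.11%)

cat > run.yaml <<EOF
counts: sim/counts.tsv
samples: sim/samples.tsv
allele_counts: sim/allele_counts.tsv
coverage: sim/coverage.tsv
outdir: report
EOF
hybridmisreg report --config run.yaml
```

`report/inheritance_summary.json` then contains the mode partition of the
488 genes passing all three pairwise filters:

```
conserved: 409 out of 488 (83.81%)      additive: 22 out of 488 (4.51%)
dominant_p1: 19 out of 488 (3.89%)      dominant_p2: 26 out of 488 (5.33%)
overdominant: 6 out of 488 (1.23%)      underdominant: 6 out of 488 (1.23%)
misregulated (pooled parents): 12 of 491
```

i.e. most genes are inherited conservatively, a few percent additively or
dominantly, and ~2.5% transgressively — matching the generating mixture
(85% conserved, 5% each cis/trans/compensatory). The mechanism summary
reports 5 compensatory genes of 436 eligible (1.15%), one of which is also
misregulated. The bias correction is available directly:

```bash
hybridmisreg correct-bias --raw 51.6 --matched 370 --mismatched 997
# -> 19.1
```

meaning a raw 51.6% misregulation estimate from a kit-confounded design
shrinks to 19.1% once the calibration pair shows the mismatched design
inflates misregulated-gene counts by 997/370.

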