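# Methods

## Problem and model

`carrierprev` projects the birth prevalence of an autosomal-recessive
disease from heterozygous carriers observed in a population sequencing
cohort. The concrete setting is Niemann–Pick type C: biallelic pathogenic
variants in *NPC1*/*NPC2*, a cohort of 1,016 diploid individuals (2,032
alleles) from a founder population, a gnomAD-NFE-style reference of
55,852 individuals, and 84,200 births per year.

Let AC_i be the cohort alternate-allele count of pathogenic variant *i*
and AN the shared cohort allele number. The pooled pathogenic allele
frequency is

    q = (Σ_i AC_i) / AN,    p = 1 − q.

Under Hardy–Weinberg equilibrium (random mating, no selection or drift
between generations) genotype frequencies are p² + 2pq + q², and with
complete penetrance the expected affected birth incidence is q². The
pooled allele class makes q² automatically include compound heterozygotes
of distinct pathogenic alleles; no separate term is added. Reported
quantities: expected cases/year = q² × births, prevalence per 100,000
births = q² × 10⁵, and the inverse "scenario" rate 10⁵/(k × births) for
one case born every k years.

Uncertainty: q is treated as a binomial proportion AC/AN and receives an
exact Clopper–Pearson interval (beta-quantile form); endpoints are squared
and scaled to a prevalence interval. This is conservative (coverage at or
above nominal) and exact at zero counts. The interval reflects allele
sampling only — not misclassification of pathogenicity, genotyping error,
or departure from panmixia.

## Filter cascade

The candidate set is the conjunction of five clauses, all strict
comparisons: consequence ∈ {missense, indel}; reference-population
AF < 0.01; CADD (PHRED) > 15; damage (1 − SIFT > 0.75 OR
PolyPhen2 > 0.75, SIFT being damaging when low); conservation (GERP > 5
OR phastCons element score > 500 on the 0–1000 scale). Missing scores
fail their own clause but a present OR-partner can rescue the group; a
variant unscored on both members of a group cannot pass. Rarity is judged
on the *reference* frequency: a cohort singleton is 4.9 × 10⁻⁴ of 2,032
alleles, below 1% by construction, so only the reference field
discriminates. Pathogenicity itself (ACMG-style curation) is out of
scope; it enters as a `known_pathogenic` flag, and prevalence uses only
filter-passing flagged variants by default (a switch widens this to all
filter-passing variants).

## Enrichment statistics

Each variant is compared with the reference population through a 2×2
table of alt/ref allele counts. Reference integer counts are
reconstructed from the published frequency as round(AF × 2N), a
reconstruction that round-trips with the printed frequency at its
reported precision but cannot resurrect digits the publication rounded
away — agreement with published p-values is therefore limited by the
precision of the published AF (in practice better than 1% here).

The test is the one-sided Fisher exact test, alternative "cohort
enriched": the central hypergeometric upper tail P(X ≥ a) given the
margins (scipy's stable log-space implementation). The reported odds
ratio is the conditional MLE under Fisher's noncentral hypergeometric
distribution — the value ψ solving E_ψ[X | margins] = a — found by Brent
root-finding on log ψ with relative tolerance 10⁻⁹; the conditional mean
is a log-sum-exp over the (small) support. At the support boundary the
MLE is 0 or +∞ by convention. The sample odds ratio ad/bc is reported
alongside as a diagnostic and is `undefined` (not an exception) when
b·c = 0. Tests verify the estimator against a brute-force maximiser of
the explicitly summed conditional likelihood and against scipy's
independent conditional estimator. No multiple-testing correction is
applied by default (two hypotheses in the motivating design); a
Bonferroni switch exists.

## Founder-haplotype scan

Carriers of a founder variant share a chromosome segment around it.
With unphased cohort genotypes (parental genotypes unavailable, so
phasing is impossible), the scan uses per-marker compatibility: a marker
is compatible iff some single allele could lie on a shared haplotype of
every carrier — alt unless a carrier is homozygous reference, ref unless
a carrier is homozygous alternate. Extension proceeds marker-by-marker
outward from the focal site and stops before the first incompatible
marker per side; boundaries are the outermost compatible markers
(conservative and density-robust, rather than extrapolating into the
flanking gap). Phased mode enumerates one haplotype choice per carrier
(forced at the focal site for heterozygotes) and demands identity across
carriers; it is never more permissive than unphased compatibility.
Genotyping error is not tolerated by default (`max_mismatch = 0`; a
per-side mismatch budget is available). Lengths are reported in Mb to
one decimal. The scan makes no statistical claim about sharing — it is a
descriptive maximal interval, not an IBD test.

## Synthetic cohorts

The generator reproduces the study conditions: 1,016 individuals, a
single ~18 Mb chromosome-18 region, 1,800 background markers (~one per
10 kb) with allele frequencies uniform on (0.2, 0.5) — an informative
common-SNP panel — in linkage equilibrium and Hardy–Weinberg proportions
(two independent haplotypes per individual). Planted variants are
heterozygous; the defaults mirror the motivating design: a 3-carrier
founder variant with a 9.4 Mb shared segment (reference AF 1.79 × 10⁻⁵)
and a 2-carrier independent variant (3.94 × 10⁻⁴). A founder variant
copies one freshly drawn template haplotype onto each carrier's
alt-bearing chromosome across the segment (symmetric around the focal
site, truncated at the region boundary, recorded in the truth sidecar
both in bp and snapped to the outermost typed sites). If an individual
carries a second planted variant inside someone's founder segment, that
allele is placed on the other chromosome so the promised sharing is never
silently interrupted. For estimator-recovery experiments a planted
variant may instead specify a true allele frequency, from which carrier
counts are drawn binomially (heterozygote probability 2q_i).

Annotation profiles are deterministic with respect to the filter:
`pathogenic` draws every score uniformly strictly inside its pass region
(CADD in (15, 50), SIFT in (0, 0.25), PolyPhen2 in (0.75, 1), GERP in
(5, 6.18), phastCons in (500, 1000)); `benign` draws CADD uniformly in
(0, 15), failing that clause with certainty. Background markers carry
consequence `other` and modest scores. All randomness flows from one
seeded `numpy` generator; identical seed and config give bit-identical
cohorts.

What the simulation does **not** emulate: linkage disequilibrium outside
planted segments, recombination gradients, relatedness beyond founder
sharing, genotyping error or allele dropout, realistic score
distributions, and multi-allelic sites. Passing recovery tests therefore
demonstrate correctness of the algorithms under clean conditions, not
robustness to real-data artefacts.

### A note on boundary resolution

With k carriers, a marker just outside the true founder segment is
compatible by chance with probability ≥ p^k + (1−p)^k (phased; the
unphased rule is weaker still), which for k = 3 is at least 0.25 at any
marker frequency p. Overrun past the true boundary is therefore
geometric with a continuation probability that cannot be pushed below
0.25 by any biallelic marker panel in linkage equilibrium: the
probability of stopping within one marker interval on both sides is
bounded by ~0.88 and is ~0.80 under the default panel. Sub-interval
boundary recovery for three carriers is a property of the marker process,
not of the scan; tests assert what is achievable (the recovered segment
always contains the truth-snapped span; overrun is small and geometric)
and the stricter recovery rate is reported honestly where measured.

## Numerical and reporting conventions

* Coordinates 1-based inclusive (VCF convention) everywhere on the
  surface; the haplotype scanner indexes half-open internally.
* Rounding for display is half away from zero: q to 4 decimals, q² to 4
  significant figures, prevalences and cases/year to 2 decimals, p-values
  to 4 and odds ratios to 2–3 significant figures. Full precision is kept
  in all report JSONs alongside the rendered values. (A k = 3-year
  scenario computes 0.396 → 0.40 under this convention.)
* Reference-count reconstruction rounds half away from zero; an = 2N.
* cMLE bracket expansion doubles the log-ψ bracket until the conditional
  mean straddles a; degenerate margins raise instead of returning NaN.
* Empty pathogenic sets yield q = 0 with an explicit warning rather than
  an error; mixed cohort allele numbers are rejected.

## Problem sizes used in the test suite

Simulation-backed checks run at the full cohort width (1,016 individuals)
with marker panels sized to the property under test: dense panels
(1,800 markers) for haplotype recovery (100 replicates), minimal panels
(2–5 markers) for the q-estimator (200 replicates) and interval coverage
(1,000 replicates), since those statistics do not depend on the marker
panel. I/O and CLI plumbing use 30–60 individuals.

## Known limitations

* Prevalence assumes panmixia and complete penetrance; regional founder
  substructure (the very thing the haplotype scan looks for) violates
  panmixia and biases q² downward as an estimate of regional incidence.
* q is restricted to curated pathogenic variants; filter-passing variants
  of uncertain significance are excluded by default, so the projection is
  a lower bound with respect to undiscovered pathogenic alleles.
* The exact-test reconstruction from published frequencies is limited by
  their printed precision (see above).
* The haplotype scan reports compatibility, not significance; with few
  carriers the segment overshoots the true IBD boundary by a geometric
  number of markers.
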