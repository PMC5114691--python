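# Methods

## The null model

A reconstituted-population experiment compares pooled sequencing of the same
isofemale-line panel at two times: immediately after founding (ancestral
populations, APs) and after years of small-census maintenance
(reconstituted ancestral populations, RAPs). `poolsim` models every neutral
source of allele-frequency change (AFC) between the two:

1. **Parental spectrum.** Each SNP's frequency p in the source population
   is drawn from Exponential(λ) truncated to (0, u], sampled by inverse
   CDF: p = −log(1 − U·Z)/λ with Z = 1 − e^{−λu}. This is the standard
   monotone-decreasing shape of a neutral minor-allele frequency spectrum.
2. **Line founding.** Each line descends from one wild-inseminated female,
   i.e. a cross of two parents ⇒ 4 founder chromosomes per locus. Each
   parent's genotype is a trinomial Hardy–Weinberg draw
   (p² : 2 copies, 2pq : 1, q² : 0); the two draws sum to the line's copy
   number k ∈ {0..4}, which is exactly Binomial(4, p). The panel's founder
   frequency is the mean of k/4 over lines.
3. **Within-line fixation.** Decades of generations at census ~20–100
   guarantee loss of heterozygosity, so fixation is applied as a single
   step: a line with k ∈ {1, 2, 3} fixes the focal allele with probability
   k/4 (the neutral fixation probability equals the current frequency).
   This step is a martingale — E[final | panel] = founder frequency — so
   drift adds variance, never bias. No generation-by-generation
   Wright–Fisher within vials is modelled.
4. **Pool-Seq.** Sequencing a pool is modelled as one binomial round:
   coverage c drawn from an empirical (or constant) depth distribution,
   focal reads ~ Binomial(c, f). The pool itself is treated as infinite —
   no intermediate hypergeometric stage for the finite number of pooled
   females — and coverage draws are independent between the two sequencing
   rounds and across SNPs. SNPs are fully independent (no linkage).

AFC is final minus founder panel frequency; its per-SNP variance under
steps 2–3 has the closed form Var(AFC) = (3/4)·p(1−p)/n_lines, because
E[(k/4)(1−k/4)] = (3/4)p(1−p) (verifiable by direct enumeration over
k ∈ {0..4}; the tests do exactly that).

## Parameter defaults

| parameter | default | meaning / why |
|---|---|---|
| λ (spectrum rate) | 20 | With u = 0.5 and 202 lines this reproduces a median drift-only AFC of ~0.006–0.007, the magnitude such panels actually show; the scaling oracle 0.6745·√((3/4)p(1−p)/202) at the spectrum's median p gives 0.0074. |
| u (truncation) | 0.5 | The focal allele is the minor allele of the source population. |
| n_lines | 202 | A realistic panel size for this design (100–200 lines are typical). |
| n_snps | 5×10⁶ (simulator), 10⁵ (synthetic experiments) | Genome-scale vs. desk-scale. |
| coverage bounds | 30–500× per population | Below 30× allele-frequency estimates are too noisy; above 500× sites are mostly repetitive/CNV artefacts. |
| min. minor count | 8, pooled over populations | Guards against sequencing errors; at ε ≤ 0.005 and ≤ 500× total coverage, spurious third alleles essentially never reach 8. |
| target coverage | 30× (or 60×) | Subsampling to the lowest population's coverage equalizes the information per population before testing. |
| coverages (synthetic) | 150/170/40/70× for AP1/AP2/RAP1/RAP2 | Empirical-like constants: APs are sequenced from large pools at high depth, RAPs at lower depth. |
| sequencing error ε | 0 | Optional uniform base-miscall; bounded < 0.01 (beyond that the biallelic model breaks down). |

Note a discreteness effect worth knowing: with n lines the drift-only AFC
lives on a grid of multiples of 1/(4n) (quarter-copies per line). At
n = 202 the grid step is 0.00124, so *median* |AFC| can only take values
0.00619, 0.00743, … — quoted medians in this regime are grid points.

## The testing pipeline

SNP calling pools A/T/C/G counts across populations (N and deletion reads
are never alleles and do not count toward coverage), takes the two most
frequent alleles as major/minor (ties broken A < C < G < T for
replicate-symmetric determinism), and requires every population's allele
coverage within bounds, the pooled minor count ≥ min_count, and **no third
allele** reaching min_count (the CMH stage is defined on 2×2 tables only;
triallelic sites are dropped and logged). The emitted set is the
conjunction of all rules, so filter order cannot matter.

Subsampling to the target coverage is a multivariate hypergeometric draw
per site and population. The batched path derives one uniform deviate per
(chrom, pos, population) by hashing these together with the master seed
(splitmix64 over a crc32 chromosome hash) and inverts the hypergeometric
CDF by the pmf-ratio recurrence — exact, vectorized, and reproducible
independent of record order or chunking. The generic single-site routine
uses numpy's `multivariate_hypergeometric` directly.

Each SNP's CMH stack pairs AP replicates with their RAP counterparts
((AP1, RAP1), (AP2, RAP2)); the statistic is

T = (|Σₖ (aₖ − r₁ₖc₁ₖ/nₖ)| − cc)² / Σₖ r₁ₖr₂ₖc₁ₖc₂ₖ/(nₖ²(nₖ−1)), cc ∈ {0, ½},

with p from the upper tail of χ²₁. Strata with nₖ ≤ 1 or a zero margin
contribute nothing; a SNP with no informative stratum is reported
degenerate with p = 1 (not dropped, so SNP sets stay comparable across
runs). The continuity correction defaults **on**, matching the standard
statistical routines the field delegates to; the uncorrected statistic is a
flag away. With cc = ½ the numerator base is floored at zero, so
|Σ dev| < ½ gives T = 0 exactly — some library implementations square the
negative base instead and report a tiny positive T there.

Dual-mapper runs are emulated as two pipeline passes; the merge keeps only
SNPs present in both and assigns each the **larger** p-value — a SNP is
only as significant as its worse mapper. BH q-values use the usual step-up
q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j capped at 1; significance is strict (q < α).
An optional minor-allele-frequency filter (pooled over all four
populations, post-subsampling) re-runs BH on the retained subset.

## What the synthetic generator does and does not emulate

One line panel per SNP drives all four populations: AP1/AP2 share the
founder truth and RAP1/RAP2 share one fixation realization — sampling the
*same* lines twice is precisely the dependence the CMH strata exploit.
Only sequencing (coverage, binomial reads, optional miscalls) is
independent per population. Not emulated: mapping bias (the dual-mapper
concern enters only through the merge contract), read-level artefacts,
indels and repeats (masks are consumed, not generated), linkage between
SNPs, and finite-pool hypergeometric noise. A green null pipeline
therefore establishes that *drift + binomial sampling* produce no false
positives at FDR 0.01 — it says nothing about mapping artefacts in real
data.

## Numerical and statistical notes

- All randomness flows from explicit integer seeds; stage seeds derive
  from the master seed via splitmix64, and identical configs give
  byte-identical outputs.
- Uncorrected CMH p-values under the null are only asymptotically uniform:
  at 10⁴ SNPs the KS distance to uniform is ~0.08 at 30× subsampled
  coverage, ~0.05 at 60×, and drops below 0.03 only around 250–500×. This
  is pure discreteness (the tests pin these numbers); the corrected
  p-values are conservative by construction, which is the right direction
  for candidate screening.
- BH q-values are monotone in p and ≥ p, but the step-up map is **not**
  idempotent ((0.1, 0.5) → (0.2, 0.5) → (0.4, 0.5)); re-adjusting can only
  raise q-values, never lower them.
- The hypergeometric inversion accumulates the pmf in float64 from the
  lower support bound; for the sample sizes used here (≤ a few hundred)
  the accumulated error is far below one CDF step, and the walk is capped
  at the upper support bound regardless.
- Chromosome coordinates in synthetic data are drawn without replacement
  per chromosome (largest-remainder allocation across six major-arm-like
  chromosomes) and sorted, 1-based, so generated sync files are valid
  inputs for any PoPoolation-style tool.

## Known limitations

- The single-step fixation shortcut is exact only in expectation and for
  the stationary distribution; panels sampled mid-way through inbreeding
  (partial heterozygosity) are not modelled.
- The exponential-spectrum rate is a free parameter of the stated world;
  empirical spectra (e.g. from real site-frequency data) can be emulated
  only by choosing λ, not loaded directly.
- `merge_dual_mappers` is keyed on (chrom, pos) alone; it assumes both
  runs used the same reference and coordinate system.
- At FDR thresholds far below 0.01 the discreteness of low-coverage counts
  makes the BH guarantee increasingly conservative rather than tight.
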