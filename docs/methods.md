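# Methods

## The sampling model

A nuclear family (mother, father, child) is genotyped at one autosomal,
diallelic (optionally multi-allelic) locus. Parental genotypes are drawn
independently under Hardy-Weinberg equilibrium and random mating from
population allele frequencies `q`, and each parent transmits one of its two
alleles to the child with probability 1/2 (Mendelian transmission). The
child's genotype is kept as an ordered pair *(maternally inherited allele,
paternally inherited allele)*: parental origin is what a parent-of-origin
(PoO) analysis estimates, but it is unobservable whenever both parents and
the child are heterozygous. Enumerating every such origin-resolved *cell*
for a diallelic locus gives 16 cells collapsing to 15 observable triad
categories.

Disease risk follows a multiplicative relative-risk penetrance,
`P(affected | genotypes) = B * (product of per-allele relative risks)`:

| model            | penetrance factor                                         |
|------------------|-----------------------------------------------------------|
| child            | `RR_j RR_l RR*_jl` over the child's alleles `j, l`        |
| PoO              | `RRcm_j RRcf_l RR*_jl` (`j` maternal, `l` paternal origin)|
| child + maternal | child factor × `RRm_i RRm_j RRm*_ij` over the mother      |
| PoO + maternal   | PoO factor × maternal factor                              |

`RR = 1` for the reference allele (by default the most frequent allele,
ties broken by lowest index), which keeps the model identifiable. The
double-dose parameters `RR*` measure departure of homozygote risk from the
multiplicative square; they default to 1, are honoured by the simulation
path, and are rejected with an explicit error by the asymptotic path, which
assumes a multiplicative dose-response throughout.

Conditioning on an affected child gives case-family cell probabilities
`pop_prob × penetrance / normalizer`; the baseline `B` cancels. Under the
rare-disease assumption, control families simply follow the population
distribution. Observable categories are obtained by erasing parental origin
and marginalizing members absent from the configuration (`mfc` triads, `mc`
and `fc` dyads, `c` children); hybrid designs such as `mfc-mfc` or `mc-mc`
add unrelated control families as extra strata.

## Likelihood and fitting

Each stratum (case/control × configuration) contributes one multinomial
over its observable categories. On the unconstrained scale the free
parameters are the multinomial logits of the non-reference allele
frequencies (shared across all strata, including control children — a
single population frequency vector) and the log relative risks (case
strata only). Cell log-weights are linear in these parameters, so the model
is a log-linear model whose category probabilities are sums of softmax cell
probabilities; gradients are analytic.

`fit_mle` maximizes the observed-data likelihood directly — summing over
origin-ambiguous cells inside each category, which is equivalent to
resolving the ambiguity by EM (a unit test verifies the EM fixed point
coincides with the direct optimum to 1e-6). The optimizer is a damped
Newton ascent using the analytic gradient and a central-finite-difference
Hessian (step 1e-5 on the log scale); with at most a handful of free
parameters each iteration is cheap and convergence is quadratic, reliably
reaching the stopping rule (relative log-likelihood change < 1e-10 or
gradient max-norm < 1e-8, at most 500 iterations) where quasi-Newton line
searches stall on precision. The start is deterministic: null effects and
sample allele frequencies (allele counting over all observed members, with
a half-count guard). The covariance is the inverse observed information
(negative Hessian at the optimum).

Wald tests use chi-square(1) for each log-scale effect parameter against 0
and for the PoO ratio contrast `log RRR = log RRcm − log RRcf`; tests are
two-sided, one per non-reference allele. The known overparameterized
combination — a pure case-mother-dyad design with the joint PoO + maternal
model — is rejected up front; any other rank deficiency is caught as a
singular expected information, reported with the offending parameter names.

## Asymptotic power

The expected Fisher information of the observable-category multinomial is
`I = Σ_s N_s Σ_i (1/p_si)(∂p_si/∂θ)(∂p_si/∂θ)'` with analytic derivatives
(cross-checked against finite differences and against the mean observed
information over simulated replicates). For a contrast `c`, the Wald
statistic is asymptotically noncentral chi-square(1) with
`ncp = (c'θ_true)² / (c' I⁻¹ c)`, and power is the upper-tail probability
beyond the central chi-square critical value at level `alpha` (default
0.05). Nuisance allele frequencies are always profiled through the full
inverse information — no plug-in shortcut — so hybrid designs gain child-
effect power through the shared frequency parameters, while PoO power is
unchanged by unrelated controls (transmissions are only observed in case
families); both behaviours are asserted in tests.

Because `I` is linear in the family counts, the non-centrality is linear in
a design scale factor `N`. `sample_size` solves the required ncp for the
target power by root-finding and returns the smallest integer `N` with
`power(N) ≥ target` and `power(N−1) < target`.

Reported powers are rounded to 2 decimals in CLI tables (reference allele
printed as `ref`) and kept at full precision in TSV/JSON exports.

## Simulation

`simulate_counts` draws per-stratum multinomial category counts directly —
the fast path used for power estimation. When missingness or PLINK export
is requested, `simulate_families` draws origin-resolved records instead;
`apply_missingness` drops each member independently at its rate, re-bins
the survivors into whichever configuration their present members form, and
discards (with a count) families left without a genotyped child.
`run_replicates` fits every replicate and reports the rejection fraction
per contrast with its binomial standard error `sqrt(p̂(1−p̂)/R)`;
non-converged fits are excluded and counted, with a warning above 1%.

Randomness uses one root seed spawning a `SeedSequence` substream per
replicate (spawn key = replicate index; the missingness draws use a second
key), so results are bit-identical regardless of worker count or
scheduling. PLINK export writes whitespace-delimited text `.ped`/`.map`
(case child phenotype 2, control 1, parents unknown; missing genotype
`0 0`; absent parents pointed to by `0`), the dialect family-based
association tools ingest.

## What the simulations do and do not emulate

The generator reproduces exactly the idealized conditions of the analytic
theory: HWE, random mating, Mendelian transmission, a single locus, and
penetrances constant across families. Agreement between simulated and
asymptotic power (verified at 2000 replicates for the worked scenarios)
therefore validates the implementation and the asymptotic approximation at
these sample sizes — it says nothing about robustness to population
stratification, genotyping error, non-HWE mating structure, linked markers
or phase uncertainty across multiple SNPs, none of which are modelled.

## Numerical choices and problem sizes

- Probability-vector normalization is exact to 1e-12 and asserted in tests.
- Finite-difference steps: 1e-5 (Hessian), 1e-6 (gradient cross-checks).
- A zero contrast gives power exactly `alpha` by construction (ncp = 0).
- Monte-Carlo test sizes were chosen so each check's own sampling error is
  well below its tolerance: 2000 replicates for simulated-vs-asymptotic
  power (3 binomial SE), 200 replicates for the observed-information
  average, 500 replicates at N = 2000 families for estimator bias and
  covariance calibration (15% per entry).
- Multi-allelic loci are supported with per-allele 1-df contrasts; no
  omnibus k−1-df test is offered.

## Known limitations

X-linked inheritance, gene-environment interaction, multi-marker haplotype
phase reconstruction, and mating-type (non-HWE) parameterizations are out
of scope. The asymptotic path deliberately refuses double-dose deviations;
use the simulation path for those. Sample-size results scale the whole
design shape by one integer factor; mixed optimization over configurations
is not attempted.
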