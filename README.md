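# triadpower

Power and sample-size calculation for family-based genetic association
studies: case-parent triads (`mfc`), case-mother/-father dyads (`mc`, `fc`),
case-control children (`c-c`), and hybrid designs that add unrelated control
families (`mfc-mfc`, `mc-mc`, ...). It serves researchers planning studies
of **child effects** (an allele raising disease risk in its carrier),
**parent-of-origin (PoO) effects** (risk depending on whether the allele
came from the mother or the father, as under genomic imprinting), and
**maternal effects** (risk to the child from alleles carried by the
mother), separately or jointly.

## The model

Family genotypes at a diallelic (or multi-allelic) autosomal locus are
enumerated under Hardy-Weinberg equilibrium, random mating and Mendelian
transmission. Disease risk is multiplicative in per-allele relative risks:
a case child with alleles *j, l* has penetrance `B·RR_j·RR_l` (child
model), `B·RRcm_j·RRcf_l` with *j* maternally and *l* paternally inherited
(PoO model), optionally times `RRm_i·RRm_j` over the mother's genotype
(maternal model). Conditioning on the affected child cancels `B`; control
families follow the population distribution (rare-disease assumption).
Each design stratum is a multinomial over observable categories, with
parental origin summed out where ambiguous and shared allele-frequency
nuisance parameters across strata.

Two routes to power:

* **asymptotic** — the Wald statistic for a log-scale contrast `c` is
  noncentral chi-square(1) with `ncp = (c'θ)² / (c' I⁻¹ c)`, where `I` is
  the expected Fisher information; power is the tail beyond the
  chi-square critical value, and sample size inverts the (linear-in-N)
  non-centrality;
* **simulation** — draw family data from the multinomial model, fit each
  replicate by maximum likelihood, and report the fraction of Wald
  p-values below the significance level. The simulation path also handles
  double-dose (non-multiplicative) penetrances, randomly missing family
  members, and PLINK `.ped`/`.map` export.

The PoO effect is tested through the relative-risk ratio
`RRR = RRcm/RRcf` (contrast `log RRcm − log RRcf`, reported as
`RRcm_cf.power`).

## Worked example

Power to detect a child effect of RR = 1.4 at a SNP with minor allele
frequency 0.2, using 500 case-parent triads at significance level 0.05:

```sh
$ triadpower power-asymp --cases mfc=500 --freqs 0.8,0.2 --rr 1,1.4
Allele  RR.power
1       ref
2       0.88
```

The common allele (frequency 0.8) is the reference; the study has 88%
power for the minor allele's effect. A joint PoO + maternal analysis of
the same design:

```sh
$ triadpower power-asymp --cases mfc=500 --freqs 0.8,0.2 \
      --rrcm 1,2 --rrcf 1,1.5 --rr-mat 1,1.2
Allele  RRcm.power  RRcf.power  RRm.power  RRcm_cf.power
1       ref         ref         ref        ref
2       0.99        0.65        0.17       0.20
```

Here the individual maternally/paternally derived risks are detected with
99% and 65% power, but the PoO *ratio* test (RRR = 2/1.5) has only 20%
power, and the maternal effect 17% — separating correlated family effects
costs power. Sample size for a PoO ratio of 1.35 at 80% power:

```sh
$ triadpower sample-size --cases mfc=1 --freqs 0.8,0.2 \
      --rrcm 1,1.35 --rrcf 1,1 --target-power 0.8
N = 1197 x (mfc=1)
```

About 1200 triads are needed — roughly 2.4× the ~500 triads that give 80%
power for a *child* effect of the same magnitude, the price of estimating
an interaction. Empirical confirmation by simulation:

```sh
triadpower power-sim --cases mfc=500 --freqs 0.8,0.2 --rr 1,1.4 \
    --replicates 2000 --seed 7
```

which prints the rejection fraction and its binomial standard error, and
`triadpower simulate ... --prefix out` writes a PLINK pedigree file of one
simulated dataset. The same functionality is available as a library
(`power_asymp`, `sample_size`, `run_replicates`, `write_plink`, ...); see
`docs/methods.md` for the model details and numerical choices.

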