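# denovotrio

Trio-based analysis of germline de novo mutations: conservative SNV/indel
calling from parent-offspring trios, mutation-rate estimation through
probabilistic callability, multi-nucleotide mutation (MNM) cluster detection
against simulation and permutation nulls, mutational-spectrum and motif
analyses, and replication-timing / recombination covariate tests.  A fully
synthetic cohort generator makes every stage testable without access to
restricted human sequencing data.

The package is aimed at statistical geneticists who study the germline
mutation process — its rate, its parental-age dependence, and the extent to
which nearby mutations arise from single multi-nucleotide events rather than
independent hits.

## The model

A candidate site is accepted as a de novo mutation in a trio when seven
criteria hold: the proband's genotype likelihood ratio lik(AR)/lik(RR)
exceeds 10^10; each parent has lik(RR)/lik(AR) > 200; no other sequenced
individual carries the allele (likelihood ratio > 10^4); at least 15
quality (Q≥20) reads cover the proband and ≥8 each parent; alt reads make
up ≥30% of the proband's quality reads; the alt allele appears on both
strands; and GATK-style site metrics are unremarkable (ReadPosRankSum in
[−6, 6], MQRankSum > −6, FS < 20).

Uneven coverage is handled probabilistically rather than with a hard
callable/uncallable mask.  The *callability* C_f(x) is the probability that
a true de novo mutation at site x in family f would pass the filters, under
a binomial read model conditional on the three members' depths (child alt
reads ~ Binomial(d, ½) split across strands, parental alt reads ~
Binomial(d, ε)).  With n_f mutations found in family f and
S_f = Σ_x C_f(x):

    rate_PPPG = Σ_f n_f / (2 Σ_f S_f)
    rate_PPPY = Σ_f n_f / Σ_f (p_f + m_f) S_f

where p_f, m_f are the paternal and maternal ages at conception.
Confidence intervals are Wilson score intervals; the parental-age model is
an OLS regression of per-family counts on both ages jointly.

MNM clusters are same-individual mutations chained at gaps < 20 kb on a
concatenated-chromosome axis.  Their excess over chance is quantified by
permuting individual labels (median over 500 rounds) and by re-simulating
mutation sets under independence, callability-weighted within the three
sequence-context classes (CpG / non-CpG strong / weak).  Tandem events
(adjacent pairs) are screened for the polymerase-ζ signature GC→AA / GA→TT;
clustered C→G and C→T mutations are tested for TCW (APOBEC), DCH and CpG
context enrichment.  Replication timing enters as the mean of five
smoothed signals, tested by decile rates, a context-stratified logistic
regression, and Cochran–Mantel–Haenszel odds ratios of a late/early split;
recombination by permuting family crossover-bin lists.

## Worked example

Simulate a 150-trio cohort on the default 50 Mb two-chromosome genome, run
calling, rates and clustering:

```python
import numpy as np
from denovotrio import denovo_calling as dc, rates, clustering as cl
from denovotrio.core import read_pedigree
from denovotrio.synthetic_cohort import CohortConfig, simulate_cohort, write_cohort

cohort = simulate_cohort(CohortConfig(n_families=150, seed=1))
write_cohort(cohort, "demo")
calls, cb = dc.cohort_call_and_callability("demo")
fams = read_pedigree("demo/pedigree.tsv")
counts = rates.family_counts(calls, fams)
print(rates.rate_pppg(counts, cb.per_family).rate)
```

The run prints (seed 1):

```
families: 150   truth mutations: 10065   calls: 9835
recall: 0.977   false calls: 0
mean callable sites per family: 4.877e+07 of 5e7
SNV rate PPPG: 6.297e-07  (95% CI 6.170e-07-6.427e-07)
SNV rate PPPY: 2.081e-08
paternal slope: 1.66 +/- 0.20 SNVs/yr (p=5.4e-14)
maternal slope: 0.39 +/- 0.20 SNVs/yr (p=0.056)
deletions: 436  insertions: 186  ratio 2.3
clustered fraction (<20 kb): observed 7.24%  permutation-expected 4.95%
MNM clusters: 308   tandem events: 28  (rate 0.30%)
```

Reading the output: 97.7% of the simulated true mutations are recovered
and none of the ~30,000 non-mutated background sites is miscalled; the
callability model says ~97.5% of the genome was effectively surveyed, so
the PPPG rate estimate matches the generator's planted density (the
*absolute* rate is ~50× the human value because study-scale per-family
counts are placed on a 50 Mb desk-scale genome — ratios, slopes and
fractions are the meaningful quantities).  The age regression recovers the
planted paternal (1.7) and maternal (0.34) mutations-per-year slopes; the
observed clustered fraction exceeds the label-permutation expectation by
~2.3 percentage points, close to the planted 3.1% MNM fraction, and the
tandem event rate lands on 0.30% of SNVs.

The same pipeline is scriptable from the shell:

```bash
denovotrio simulate --out demo --seed 1 --n-families 150
denovotrio call --cohort demo --out out
denovotrio rates --calls out/calls.tsv --callability out/callability.tsv \
    --ped demo/pedigree.tsv --out out
denovotrio cluster --calls out/calls.tsv --out out
denovotrio spectra --calls out/calls.tsv --ref demo/genome.fa --out out
denovotrio covariates --calls out/calls.tsv --cohort demo --out out
```

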