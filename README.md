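# ibdphase

Long-range haplotype phasing, identity-by-descent (IBD) detection and
genotype imputation for **founder populations** — cohorts in which a
substantial fraction of a small, recently expanded population has been
genotyped, so most individuals share long chromosome segments inherited
intact from recent common ancestors. It is aimed at statistical geneticists
working with population isolates (dense SNP-array data, hundreds to
thousands of samples, no pedigrees required) who want accurately phased
haplotypes, explicit pairwise IBD segments for linkage-style mapping, and
low-error imputation of sporadically missing genotypes.

## The model

The IBD status of one ordered pair of diploid individuals along a
chromosome is a five-state continuous-time Markov chain with states
`{NONIBD, S11, S12, S21, S22}`, where `Sij` means haplotype *i* of the
first individual is IBD with haplotype *j* of the second. The rate matrix
*Q* has entry rate *g* (split evenly over the four shared states) and exit
rate *l*; transition probabilities over a marker interval of genetic length
*t* Morgans are `exp(tQ)`, with the probability of entering IBD between
adjacent markers capped at the kinship coefficient κ. Given the hidden
state, the pair of diplotypes (ordered allele pairs) *h<sup>a</sup>,
h<sup>b</sup>* follows Hardy–Weinberg at the sample allele frequencies
subject to the identity-by-state constraint of the state — e.g. for one
individual homozygous for a minor allele of frequency *f* and the other
heterozygous, the emission probability is *f*²(1−*f*) if they share a
haplotype and *f*³(1−*f*) if not. Observed genotypes
*g<sup>a</sup><sub>j</sub>* depend on the diplotypes through a symmetric
error model.

For phasing, the pairwise chains are coupled into one network over all
individuals: diplotype variables carry a uniform prior and each pair's IBD
indicator at marker *j* depends on (*h<sup>a</sup><sub>j</sub>*,
*h<sup>b</sup><sub>j</sub>*, *p<sup>ab</sup><sub>j−1</sub>*) through a
Bayes-rule inversion of the emissions — implemented as the likelihood-ratio
factor `T(p_{j−1}→p_j) · E(h|p_j)/E(h|NONIBD)`, which rewards sharing of
rare alleles. Approximate MAP haplotypes and IBD assignments come from
damped, attenuated Min-Sum message passing restricted to *plausible IBD
segments* found by a Forward–Backward prescan of every pair; the method
refuses to call a phase where the max-marginal margin is small. See
`docs/methods.md` for the full account, including the gauge-fixing scheme
and the inference safeguards.

A founder-population simulator (exponential growth from a founder set,
genetic-map recombination, full ancestry tracking) and the standard
accuracy metrics (switch errors per Morgan, yield, genetic-length-weighted
IBD sensitivity/FDR, imputation error, trio-based truth phasing) are
included, so the whole pipeline is testable without any external data.

## Worked example

Simulate a small isolate (50 founders growing to 2,000 in 9 generations,
40 individuals sampled, 800 markers over 0.35 Morgans), phase it with
default parameters and score against the simulator's truth:

```bash
ibdphase full --out demo_run \
    --n-founders 50 --final-size 2000 --generations 9 --sample-size 40 \
    --n-markers 800 --length-morgans 0.35 --seed 42
```

which logs the prescan (`526 plausible segments over 780 pairs`) and prints

```json
{
  "switch_errors_per_morgan": 8.71060514815536,
  "within_segment_errors_per_morgan": 5.327146950111542,
  "yield_fraction": 0.8281761922096833,
  "ibd_sensitivity": 0.9294542300255624,
  "ibd_fdr": 0.06315572982634977
}
```

Reading: 83% of heterozygous sites received a phase call; among called
sites the relative orientation versus truth flips ~8.7 times per Morgan of
chromosome per individual (~3 per individual here, concentrated at IBD
boundary handovers — small, sparsely covered cohorts sit well above the
rates achievable on chromosome-scale dense cohorts); called IBD segments
cover 93% of the true IBD (1 cM floor) with 6% of called length not truly
IBD. `demo_run/` also contains the phased VCF (`|`-separated where phased),
the IBD segment calls,

```
a_id    a_hap  b_id    b_hap  chrom  start_bp  end_bp    n_markers  genetic_length_cM
S0000   2      S0001   2      20     5198688   6917874   72         4.2199
S0000   1      S0001   2      20     7057726   11132467  170        5.1079
```

and a per-site phase-margin table. The subcommands `simulate`, `phase` and
`eval` run the same stages separately on files (VCF or transposed text plus
a HapMap-format genetic map); `ibdphase --help` lists every model parameter
as a flag — e.g. `--expected-nonibd-length 0.5` trades accuracy for yield
on sparsely related cohorts.

As a library:

```python
from ibdphase import ModelParams, run_phasing, simulate_cohort

cohort = simulate_cohort(seed=1)
run = run_phasing(cohort.genotypes, cohort.gmap, ModelParams())
run.phase.diplotypes   # (n, m, 2) called alleles, -1 = no call
run.ibd_calls          # list of IBD segment calls
```

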