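# Methods

## Hierarchical assignment procedure

`codprov` infers the biological source of a low-coverage ancient Atlantic
cod specimen in four stages, each consuming only per-site biallelic read
counts and a modern reference panel:

1. **Genome-wide cluster assignment** (western Atlantic vs eastern
   Atlantic, then Baltic vs non-Baltic within the eastern branch).
2. **Inversion genotyping**: dosage of the inverted arrangement (0/1/2)
   at LG1, LG2, LG7 and LG12.
3. **Composite-genotype affinity**: probability of the called dosages
   under each candidate population's arrangement frequencies, normalized
   into shares over the candidate set.
4. **Interpretation**: local/traded classification, element–origin
   association, calendar conversion of qualitative dates.

### Cluster likelihood

The per-site model treats every read as an independent draw from the
cluster's allele pool: with alt-allele frequency *f* and per-read error
ε, a read reports alt with probability q = f(1−ε) + (1−f)ε and the alt
count at depth *n* is Binomial(*n*, q). This is exact when each site
carries at most a handful of reads relative to the number of sites — the
regime the pipeline targets (mean depth λ ≈ 5 with ≥ 50 informative
sites). At high per-site depth over very few sites the model is
mis-specified, because many reads then resample the *same* diploid
genotype rather than the population frequency; assignments remain
consistent in expectation (the expected per-site log-likelihood ratio
still favours the true cluster, by linearity in the genotype's allele
dosage) but per-specimen variance grows. Linkage between panel sites is
ignored, a standard approximation for sparse genome-wide panels.

This classifier deliberately re-specifies the genome-wide step as an
explicit allele-frequency likelihood rather than a PCA-database
projection: the contract used downstream — posterior membership in the
three clusters — is the same, but numerical parity with PCA-based
assignment software is not claimed, and the modern genome database such
software is trained on is not required.

### Inversion genotyping

All diagnostic SNPs inside one inversion share the specimen's dosage
(recombination is suppressed within the inversion) and are oriented so
alt tags the inverted arrangement. For dosage *d* the expected alt-read
fraction is q_d = (d/2)(1−2ε) + ε. The posterior over {0, 1, 2} uses a
**uniform prior**, not an HWE prior: population arrangement frequencies
enter only in the affinity stage, so frequency information is never
counted twice, and genotype calls stay population-agnostic. A hard call
requires max posterior strictly above the call threshold (default 0.75);
ties and zero-coverage loci stay missing.

### Affinity, shares and aggregation

Under HWE a population with arrangement frequency *f* produces dosage
*d* with probability C(2,d) f^d (1−f)^(2−d); inversions sit on different
chromosomes and are treated as independent, so the composite probability
is the product over called loci. Missing loci are skipped (marginalized)
rather than integrated over the calling posterior — matching a hard-call
workflow; a posterior-weighted variant would be a straightforward
extension but is not the default.

Shares are raw probabilities normalized over the *offered* candidate
set, and are therefore explicitly conditional on it. After stage-1/2
assignment the pipeline conditions the candidate set on the assigned
cluster (eastern specimens are compared against eastern candidates
only). Icelandic coastal and frontal ecotypes merge into one reported
Iceland share. Haplogroup shares (northernmost = Northeast Arctic +
Iceland; north-central = Norwegian Coast, North Sea, Irish Sea, Øresund)
are re-scaled over grouped members so the two groups remain comparable
when ungrouped candidates carry part of the mass. Populations within
`tie_tolerance` (default 0.01) of the top share are reported jointly as
the putative origin.

### QC gates and interpretation

A specimen is eligible for specific assignment when it has strictly more
than 2000 aligned reads and both nuclear coverage and endogenous DNA at
least one order of magnitude (10×) above the negative-control baseline.
The baseline aggregates controls by the **maximum** (conservative); a
zero-valued baseline is an absent contamination floor, so any strictly
positive specimen value passes that ratio gate. Downstream, specific
assignment additionally requires confident calls (posterior > 0.75) at
≥ 3 of the 4 inversions. All thresholds are configuration fields with
these defaults.

Classification: a western-Atlantic genome-wide assignment is traded by
definition (for the European consumption sites modelled); an eastern
specimen needs its strongest haplogroup share ≥ 0.75 to classify at all,
then is local if every putative-origin population lies in the
near-catchment set (North Sea, Irish Sea by default) and traded if none
does — the member population, not the group, drives the sets, so a
north-central specimen whose top population is the Norwegian Coast is
traded. Mixed putative origins stay unclassified.

Fisher's exact test on the cranial/postcranial × local/traded table uses
the conventional two-sided probability-mass ordering (scipy's
implementation); the test suite checks it against an independent
full-enumeration hypergeometric oracle for every table with N ≤ 20.
Because the exact conditional p-value is discrete and stochastically
larger than uniform under independence, calibration is verified as
rejection-rate control at several α levels rather than a
distribution-equality check.

Qualitative dates: century *N* spans (N−1)·100 to N·100 CE; "early"
keeps the first half, "mid" '25–'75, "late" the second half; ranges take
union endpoints ("late fifteenth–early sixteenth centuries" → 1450–1550).

## Synthetic-data generator

The generator emulates the data structure the pipeline consumes, not the
sequencing process: three genome-wide clusters separated by a per-site
frequency contrast (default 0.6, half the sites separating west from
east, half separating Baltic from Atlantic), candidate populations with
configurable inversion arrangement frequencies, HWE-drawn dosages,
Poisson per-site depth (default λ = 5), per-read error (default 0.01)
and an optional damage-like excess error applied to a fixed fraction of
sites. Post-mortem deamination is proxied as this site-class excess
error rather than read-position-dependent C→T substitution, because the
pipeline consumes counts, not reads; the proxy stresses the same failure
mode (systematically biased alt fractions at affected sites). Duplicate
reads, contamination mixtures and reference bias are not modelled, so
passing recovery tests demonstrates statistical correctness of the
assignment machinery under the stated noise model — not robustness to
every artefact of real ancient DNA libraries.

Default geography: 8 eastern populations (Northeast Arctic, the two
Icelandic ecotypes, Norwegian Coast Lofoten and southwest, North Sea,
Irish Sea, Øresund), the Baltic Sea, and 3 western populations
(Placentia Bay, Gulf of St Lawrence, Southern Newfoundland). The default
arrangement frequencies are the package's own choice — chosen once to
mirror the qualitative contrasts of the system (inverted arrangements
common in northernmost populations, rare in north-central ones, with
Iceland distinguished from the Northeast Arctic mainly at LG1, and
intermediate western frequencies) — since no published per-population
table is bundled. Real panels are supplied as TSV + config files.

Bone elements are assigned with a configurable element–origin
association strength *s*: specimens from near-catchment populations are
cranial with probability (1+s)/2, others with (1−s)/2.

All randomness flows from a single integer seed through numpy's
`default_rng`; only integer draws are taken, so cohorts are reproducible
across platforms.

## Numerical choices and problem sizes

* Posterior softmaxes subtract the maximum log-likelihood before
  exponentiation; zero-depth specimens return the prior, flagged
  uninformative.
* Frequencies are written with `repr` round-trip precision and read with
  pandas' `round_trip` float parser, so panel write→read is lossless.
* Ties at the call threshold or at the posterior maximum resolve to
  missing (conservative).
* Error rate ε must lie in [0, 0.5); f = 0 or 1 with contradicting reads
  legitimately yields zero likelihood.
* Test and acceptance runs use 200-specimen cohorts at λ = 5 with 50
  genome-wide and 20 diagnostic sites, and 2000–10 000 replicates for
  calibration checks — sizes chosen to give stable Monte-Carlo estimates
  at interactive runtimes.

## Known limitations

* The genome-wide classifier is not numerically equivalent to PCA-based
  assignment tools; only the posterior-membership contract matches.
* Deep-water Icelandic cod are reported to share LG1 arrangement
  frequencies with the Northeast Arctic, so Iceland vs Northeast Arctic
  assignments deserve caution when that substructure matters; the
  default synthetic panel does not model it.
* Missing-locus marginalization uses hard calls; a fully Bayesian
  treatment would propagate the genotype posterior into the affinity
  product.
* The QC baseline defaults to a global pool of negative controls;
  per-session baselines are supported by passing per-session control
  subsets.
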