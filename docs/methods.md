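# Methods

## Scope and model

`lethascan` screens phased biallelic SNP data for haplotypes depleted of
homozygotes, the classic signature of a linked recessive lethal, and tests
candidate regions for effects on binary reproductive traits. The package is
organised around three estimator-style stages (`DepletionScreen`,
`GibbsThresholdModel`, `MarkerAssociation`, all with scikit-learn `fit`
semantics) plus a gene-drop simulator, pedigree algebra, and file IO.

## Segmentation and haplotype identity

Chromosomes are cut into `ceil(M / max_markers)` contiguous blocks with
sizes `floor(M/n)` or `ceil(M/n)`, larger blocks first, so block sizes
within a chromosome differ by at most one and never exceed the cap
(default 200 markers). For chromosomes whose marker counts are near
multiples of 200 this yields the familiar 194–200-marker segments; for
small M it simply yields shorter blocks. Segment ids run consecutively
across chromosomes in map order.

Haplotype identity is exact string identity over the segment's alleles —
no mismatch tolerance — because the depletion test needs clean counting
semantics: per segment each animal contributes two strings, and for every
distinct string `2·|homozygotes| + |carriers| = copies` with copies summing
to 2N. Haplotypes are ranked within a segment by descending copy count,
ties broken lexicographically, giving deterministic `segment.rank` names.

## Depletion test

Both expectations are closed forms evaluated in log space (`log1p` for
`(1 − f²/4)^N`, `n·log 0.75` for the Bernoulli mating test), so
probabilities as small as 1e−300 are exact to ~1e−12 relative; beyond that
they underflow to 0.0 gracefully.

One convention question deserves a note: the probability formula is
conventionally written `(1 − C²/4)^N` with C "the carrier frequency", but
published screens insert the *haplotype* frequency `f = C/2` into the same
slot. We default to inserting `f` — this reproduces published
probability columns to their printed precision, as the acceptance script
verifies — and expose `phh_convention="carrier"` for the literal reading,
which yields far smaller probabilities (e.g. ~1e−62 instead of ~4e−16 for a
4.8% haplotype in 62k animals).

Filter defaults: haplotype percentage > 2, simple expectation > 1, and
*both* probabilities < 0.6. Requiring both is the conservative reading; the
mating-side bound is typically the binding one for haplotypes with few
resolvable carrier-sire × carrier-MGS pairs. The "carrier mating" unit is
one genotyped progeny with a carrier sire and a carrier maternal grandsire,
consistent with the exponent of the Bernoulli probability; animals with
unknown sire or MGS never count, which makes the mating test conservative
when pedigrees are incomplete.

## Pedigree algebra

Inbreeding is computed by the Meuwissen & Luo recursion (ancestor-path
sums), and the A-inverse by Henderson's rules with the Quaas adjustment
when `use_inbreeding=True` (the default; the unadjusted variant is kept for
comparison). Unknown parents are unrelated base-population founders with
F = 0; unknown-parent groups are not fitted — a deliberate simplification,
listed as a limitation for populations with strong genetic trend. Both
routines are validated against the dense tabular-A oracle.

## Threshold model

The liability model `l = Xβ + Za + e` fixes σ²ₑ = 1 and the threshold at 0
for identifiability; heritability h² = σ²ₐ/(σ²ₐ+1) is scale-free, so
recovery tests remain meaningful whatever liability scale generated the
data. The Gibbs cycle is:

1. truncated-normal draw of each record's liability given its side of the
   threshold (vectorised inverse-CDF sampling);
2. single-site Gauss–Seidel sampling of all CG and animal effects from the
   mixed-model equations `[X'X, X'Z; Z'X, Z'Z + A⁻¹/σ²ₐ]` (numba-compiled
   sweep over a union sparsity pattern, so the λ·A⁻¹ part is a vector
   update per iteration);
3. scaled-inverse-chi-square draw of σ²ₐ with a weakly informative prior
   (ν = 4, scale 0.2; flat priors on β).

Chain defaults are 6,000 iterations, 1,500 burn-in, thinning 5 — sized for
desk-scale fits (a ~3,000-animal, ~3,000-record fit takes a few seconds);
longer chains are a parameter away and change estimates by less than the
posterior SD in our checks. With `observed_liability=True` and the variance
fixed, posterior means coincide with the closed-form MME solution — the
linear-limit oracle used in the tests. Reliability is r² = 1 − PEV/σ̂²ₐ with
PEV the posterior variance of each animal's effect; a configurable cap on
sampled σ²ₐ flags divergent chains.

Deregression follows the Garrick, Taylor & Fernando (2009)
parent-average-removal recipe (formulas in the `deregress` docstring), with
the variance fraction `c = 0.5` by default (the source method leaves it to
the analyst). Animals with both parents unknown have no parent-average
equation and reduce to dEBV = EBV/r². Accuracy is √r² of the deregressed
proof; the default floor of 0.40 mirrors field practice. Animals whose
reliability does not exceed their parent average carry no own information
and are skipped with a log entry.

## Association and annotation

Single-marker association is textbook OLS with an intercept; t uses n−2
degrees of freedom (normal tail by flag), and −log10(p) is computed from
the log survival function so genome-scale significance never underflows.
The fixed −log10(p) > 6 line is applied as a convention rather than
recomputing 0.05/M per panel. Gene annotation takes ±100 kb windows around
significant markers, *inclusive* at exactly 100,000 bp, distance 0 when the
marker lies inside the gene span; the implementation (sorted
`searchsorted` sweep) is tested against a quadratic all-pairs oracle.

## Gene-drop simulator

The simulator is the package's study-condition generator, not a test prop:
founders with per-marker allele frequencies ~ U(0.05, 0.95) (linkage
equilibrium), descent with Poisson(1) crossovers per chromosome at uniform
marker boundaries, discrete generations in which a small set of sires
(default 25 per generation) serves all dams — the AI-style reuse that gives
the mating test its carrier-sire/MGS pairs. The lethal allele is a fixed
allele string over a configurable marker window planted on founder
haplotypes at 5% frequency by default (~9.5–10% carriers); any conceptus
homozygous for the string is removed *before* genotyping, so the genotyped
set never contains a lethal homozygote, for any seed. Pedigree masking
(40.4% unknown sires, 18.7% unknown dams by default) is applied after
transmission: true parentage drives inheritance, the masked pedigree is
what the analysis sees. Binary traits arise from liabilities
`cg + a + e` with a pedigree-consistent additive effect (founders
N(0, h²), offspring midparent plus Mendelian noise), default heritabilities
0.31/0.33/0.41 and incidences 0.593/0.474/0.021 for HR/STAY/PNM, and a
per-trait threshold matched to the configured incidence. An optional
liability penalty for calves of two carrier parents (default off) lets the
association stage see a real PNM signal.

What the simulator does **not** emulate: real linkage disequilibrium
(founders are in equilibrium, so candidate haplotypes only recur at
frequency when a scan segment aligns with the planted window — the tests
therefore scan at the window width), marker-panel heterogeneity and
imputation, selection across generations, and genetic correlations between
traits. Passing tests consequently demonstrate the statistics and their
calibration, not performance under realistic LD.

Because founders are unlinked, the planted haplotype decays by
recombination (~10% per generation for a 20-of-200-marker window at 1
crossover/chromosome), which mildly erodes carrier frequency across
generations — visible in the simulations and accounted for in the test
tolerances.

## Problem sizes and calibration checks

The shipped checks run at sizes chosen for a desk machine: planted-lethal
recovery on ~8,000 genotyped animals (3 seeds; at this size the candidate
list contains exactly the planted haplotype, with no false positives in
lethality-off runs), heritability recovery on ~2,800-record populations
(3 replicates per generating value; mean bias below 0.05 and each posterior
mean within 3 posterior SD), null-GWAS uniformity on 1,500 markers × 400
animals, and the haplotype-association power check at a 0.5-SD carrier
effect among 2,000 scored animals. The mating-method filter needs enough
resolvable carrier-sire × carrier-MGS pairs, so recovery degrades below a
few thousand genotyped animals under heavy parent masking — a property of
the method, not of the implementation.

## Numerical conventions

Marker indices are 0-based half-open internally; bp positions 1-based as in
VCF. Chromosome names are harmonised by stripping `chr`/`BTA` prefixes, and
name mismatches between files raise rather than silently dropping records.
Report display rounds expectations to one decimal and probabilities to
three significant digits; full precision is kept internally and in TSV
outputs. All stochastic stages take explicit seeds and are bit-reproducible
for a fixed seed; tabular outputs carry a `#` header with version, a hash
of the analysis parameters (paths excluded), and the seed.
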