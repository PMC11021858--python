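# Methods

This note documents the models, rules and numerical choices behind
`scatdna`, what the synthetic generator does and does not emulate, and the
design decisions taken where the protocol left room.

## Taxonomic assignment

Reads are scored against every reference sequence by global pairwise
alignment (match +1, mismatch −1, gap open/extend −2, via Biopython's
`PairwiseAligner`); identity is matches over aligned columns, gaps counted
in the denominator, `N` matching nothing, and both strands scored with the
maximum taken. An exhaustive scan of a curated reference FASTA replaces a
remote BLAST search: it removes an external binary and database-version
dependence while preserving the identity-band semantics, and is fast at the
scale of a regional vertebrate panel (tens to hundreds of references).

Rank rules: a unique 100% best hit is a species call; 100% ties confined to
one genus (one family) collapse to that genus (family), ties spanning
families are unassigned. Below 100%, [99, 100) falls to the genus of the
best hit — the protocol names only "100%" and "<99%", so this half-open
band is an explicit package choice, stored in configuration — [90, 99) to
its family, and <90% is unassigned.

Per-sample filtering is replicate consensus first, abundance floor second.
A taxon needs detection in ≥2 of the 3 PCR replicates; with exactly two
successful replicates it must appear in both (the conservative reading of
"at least two of three"), and one successful replicate fails the sample.
The 0.5% relative-abundance floor is strict (< removes, = retains) and its
denominator is the post-consensus read total of the sample summed over
replicates; the protocol does not define the denominator, and this choice
is deterministic and order-stable (both filters are idempotent). The
predator of a scat is the configured canid with the largest read share —
wolf/coyote co-detections are not resolved in the source protocol, so the
larger share decides; configurable contaminant taxa (human, livestock) are
always removed.

## Diet quantification and overlap

A scat's items are its distinct prey categories (two seabird species in one
scat are one item). The alternative species-level counting is available as
a configuration switch but is not the primary definition, because the
quantity of interest is the weighted percent of occurrence *of each
category* and within-scat multiplicity is otherwise undefined.

wPOO gives each scat weight 1 split evenly over its items, so unit profiles
are probability vectors; they depend only on presence, never on read
abundance. Pianka's overlap and Bray–Curtis dissimilarity operate on those
vectors (Bray–Curtis delegates to `scipy.spatial.distance.braycurtis`).
Individual profiles require ≥10 scats; excluded individuals are reported,
not silently dropped.

Pairwise PERMANOVA treats the scat as the sampling unit: Bray–Curtis
distances between per-scat binary category profiles, pseudo-F
`(SS_between/(g−1)) / (SS_within/(n−g))` computed directly from the
distance matrix, and p-values `(1 + #{F* ≥ F}) / (1 + n_perm)` under label
permutation (default 999 permutations, seeded). Pairs with a group of
fewer than two scats are skipped with a flag. Benjamini–Hochberg adjustment
(statsmodels) is applied across all pairs as one family. Note that with
perfectly separated tied clusters the attainable p floor is not
`1/(n_perm+1)` but `(1 + m)/(n_perm+1)` where `m` counts permutations that
reproduce the cluster partition. The pseudo-F agrees with scikit-bio's
PERMANOVA to numerical precision (checked in the test suite; scikit-bio is
never the implementation). NMDS plotting is provided as an unvalidated
convenience only.

## Genotype calling and individual identification

Replicate calls follow the genotyping-in-thousands convention, since the
source protocol prints no thresholds: minimum depth 10, homozygote at an
allele fraction ≥0.9 (≤0.1), heterozygote in [0.3, 0.7], anything else a
no-call. All four numbers are configuration values. Consensus is the
published rule verbatim: heterozygote in ≥2 of 3 replicates, homozygote in
3 of 3, otherwise missing. Sample QC fails strictly above 20% missing
autosomal loci.

Sex: male requires Y-marker depth ≥10 in ≥2 replicates; female requires Y
absence in *all* replicates **and** a QC-passed autosomal genotype — the
extra condition guards against calling females from failed amplifications.
Species is a majority vote of the non-missing diagnostic loci (heterozygous
calls abstain); ties are ambiguous.

Matching joins two QC-passed samples when they share ≥21 co-called loci and
disagree at ≤1; individuals are connected components, their consensus the
per-locus majority (ties missing), and mixed-sex components are flagged,
never silently merged or split. The 21-locus floor is the bound implied by
QC itself: two samples each missing ≤7 of 35 loci always share ≥21, so
every pair of QC-passed duplicates is comparable. A higher floor
(e.g. 28) silently refuses to compare legitimate duplicate pairs and
fragments the roster under realistic missingness. The false-merge risk of
the relaxed floor is bounded by roster² × PIDsibs evaluated at 21 loci —
about 10⁻⁴ per study with frequencies in [0.3, 0.7] — and the one-mismatch
tolerance absorbs a single residual genotyping error, as full siblings
differ at ~12 co-called loci in expectation.

PID uses the expected (frequency-based) estimator; the small-sample
unbiased correction is out of scope. Detection histories flag a year iff a
member sample is dated in it; "year" defaults to the calendar year, with a
biological year starting 1 May available by configuration (the source mixes
both conventions and never states the boundary).

The SNP-matrix filters run in PLINK's order — locus missingness >0.1, MAF
<0.3, exact Hardy–Weinberg p <0.001, then greedy pairwise r² >0.5 pruning
(keeping the lower-missingness locus; no genomic windows, because panel
loci have no meaningful coordinates), then sample missingness >0.3. The
Hardy–Weinberg test is the exact conditional test
`P(h | n, nA) = n!/(nAA! nAB! nBB!) · 2^h · nA! nB!/(2n)!`, summing all
heterozygote counts no more probable than the observed (with a 1 + 10⁻¹²
relative tolerance on the equality comparison).

## Pedigree screening

Opposing homozygosity and trio incompatibility are counted over co-called
loci only. Default tolerances of one mismatching locus absorb a single
genotyping error in field-grade genotypes; error-free screens use zero.
Candidate parents must be detected by the offspring's birth year, not
recorded dead before it, and at least 2 years older (wolves breed from age
two; the source does not define adulthood). `assign_parents` scores all
dam×sire pairs, drops any failing the tolerances, and returns the pair
minimising (trio incompatibilities, summed opposing homozygosity); ties are
reported ambiguous, never forced.

Sequential reconstruction (`reconstruct_pedigree`) processes offspring
oldest-first and excludes candidate pairs that the partial pedigree marks
as first-degree kin of each other (a dam who is the sire's daughter, mother
or full sibling). This encodes the incest avoidance documented in wild wolf
packs and is what separates a pup's adult full sister from its mother —
a distinction pure exclusion statistics cannot make, since such a pair
shows zero incompatibilities across 35 loci with probability ≈0.2. Even so,
an adult full sister of the *dam* occasionally ties the true pair; those
cases are reported ambiguous. On error-free simulations the reconstruction
reaches ≈97% recall with zero wrong confident assignments; perfect
per-offspring recovery is information-theoretically out of reach at this
panel size.

Inbreeding coefficients use the kinship recursion (F of an individual is
the kinship of its parents), which equals Wright's path counting on any
acyclic pedigree and needs no path enumeration; cycles are rejected at
construction.

## Synthetic data generator

The generator emulates the structure of a 7-year island wolf study. A
founder pair colonises in year one and breeds annually (Poisson litters,
mean 4); every individual faces independent annual harvest (0.15) and
natural mortality (0.05) draws; a dead breeding female is replaced by the
oldest adult female not first-degree kin of the sitting male — and if only
his daughters are available, he is deposed in favour of an immigrant male,
the turnover pattern observed in closed island packs; a dead breeding male
is replaced by an immigrant. Genotypes descend by Mendelian gene dropping
from founder Hardy–Weinberg draws at per-locus allele frequencies uniform
on [0.3, 0.7] (immigrants are fresh founders); the Y marker follows sex,
and the diagnostic loci are fixed for the wolf allele.

Diets are Dirichlet draws around a pack mean: the island-like preset uses a
sea-otter-dominated mean (60% sea otter, 13% seabirds) at concentration
α = 60 — tight individual agreement — and the mainland-like preset an
ungulate/vole mean at α = 2.5, giving divergent individual diets; both
means follow the reported composition of the two study packs. Each scat
draws a zero-truncated Poisson (mean 1.5) number of distinct categories
from its owner's diet, a species per category, and triplicate multinomial
read counts at negative-binomial depth (mean 500 per replicate) with the
predator taking half the reads. The default of 4 scats per individual-year
(≈28 per wolf over a study) matches the sampling intensity of analysed
wolves in comparable field studies (mean ≈29 scats). Trace contamination
(5% of scats by default; a stress preset can exceed this) is a foreign
taxon at 0.2% of the sample's reads in a single replicate — strictly inside
what the replicate-consensus and abundance filters are designed to remove.

Genotyping noise: whole-locus amplification failure per sample (0.05,
modelling the degraded-template failure mode in which a locus drops out of
all replicates of an extract), allelic dropout of one allele per
heterozygous replicate (0.1), false-allele leakage (0.01), negative-
binomial replicate depth (mean 200). These defaults make recovery
non-trivial but achievable; all are configurable.

What the generator does *not* emulate: sequence-level errors (noise lives
in count space, not nucleotide space), chimeras and tag jumping, spatial
structure, varying detectability, multi-pack admixture, and diet–condition
feedbacks. Passing recovery tests therefore demonstrates correctness of
the analysis chain under the stated noise model, not robustness to every
artefact of real amplicon data.

## Problem sizes and seeds

Verification experiments use desk-scale sizes chosen to make the checks
sharp: exhaustive truth tables for the consensus rule (all 4³ triples) and
the Hardy–Weinberg test (all configurations to n = 10); brute-force
enumeration oracles for PID/PIDsibs (≤3 alleles, |Δ| < 10⁻¹²); a 20-wolf,
35-locus, 5-samples-each scenario over 10 seeds for individual recovery;
6 wolves × 28 scats over 100 seeds for the island/mainland overlap
contrast; 500 replicates × 199 permutations for PERMANOVA type-I
calibration; and 10 error-free pedigrees (~200 offspring) for parentage.
All randomness flows from explicit seeds; identical seeds give
byte-identical outputs.
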