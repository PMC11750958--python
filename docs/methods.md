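# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `oligobarcode`, and what the synthetic-data tests do and do
not demonstrate about real genomes.

## Probe selection model

A candidate probe is a plus-strand genomic window of `oligo_length` (50 nt)
taken every `step` (5 bp) per chromosome; windows containing non-ACGT
characters are dropped. Three filters follow, each returning a subset of
its input without altering coordinates:

**Homology screen.** A candidate is removed iff some locus other than its
own origin aligns to it over the full oligo length, ungapped, at identity
≥ `homology_threshold` (0.75), on either strand. Gapped homology is out of
scope: the screen models hybridization of a short probe, for which a single
percent-identity knob is the standard operating point. Two implementations
sit behind one interface:

- *exact* — a vectorized all-positions scan over every window of every
  chromosome and strand. Verdicts are guaranteed identical to a brute-force
  definition-level scan; cost is O(candidates × genome), used automatically
  for genomes up to `exact_homology_max_bases` (250 kb).
- *seeded* — exact 12-mer seeding plus full-length ungapped verification of
  every seeded locus. By pigeonhole, any off-target with ≤ 3 mismatches
  (identity ≥ 0.94) necessarily contains a clean seed and is always found;
  lower-identity off-targets are found only when a 12-mer survives by
  chance. This is the genome-scale mode: near-duplicate repeat copies — the
  practically relevant off-targets — sit far above the guarantee floor,
  while a miss just below the 0.75 threshold is both unlikely and
  low-consequence for hybridization. Contiguous-seed designs cannot
  guarantee sensitivity at 0.75 exactly (12 mismatches in 50 nt can leave
  no exact run longer than 3), which is why the exact mode exists and backs
  all oracle-equivalence tests.

Retained candidates carry `max_offtarget_identity`; in seeded mode this is
the maximum over seed-verified loci (0.0 when nothing was verified), in
exact mode the true maximum.

**Read-depth filter.** Each candidate is scored by the mean simulated read
depth of its constituent canonical k-mers (k from the supplied table). A
candidate is retained iff its score lies in the inclusive
[`kmer_q`, `kmer_p`] = [0.1, 0.9] quantile band of all candidate scores
*and* no single k-mer exceeds `kmer_d` (25) times the median candidate
score. The band drops both repeat-depth outliers and dropout/assembly-gap
oligos; the per-k-mer cap catches a locally embedded high-copy element
inside an otherwise average window. The published pipeline names q/p/d
flags without defining their semantics; this quantile-band reading
reproduces their intent and is fully testable. A degenerate all-equal score
distribution retains everything (the band is inclusive at both ends); an
empty table warns and passes candidates through unchanged.

**Density cap.** Windows of `density_window` (1 Mb) tile each chromosome at
`density_step` (1 Mb; tiling, since step = window). A window over
`density_cap` (2500, i.e. 2.5/kb) keeps the size-2500 subset maximizing the
minimum gap between consecutive retained oligos, found by binary search on
the gap with a greedy left-to-right feasibility check — deterministic,
position-based, idempotent. Even coverage maximizes FISH signal uniformity;
no thinning rule is published, so this is the package's choice.

## Barcode signatures

Metaphase chromosomes expose band *order*, *color* and coarse *position*,
not base pairs. A chromosome's signature is its ordered list of
(position-class, color) bands, with the class of a region determined by its
midpoint: pericentromeric when within `pericentromeric_fraction` (0.10) of
the chromosome length around the centromere (checked first, so a region
straddling the centromere classifies there), terminal in the outer
`terminal_fraction` (0.15) of an arm, interstitial otherwise. Both
fractions are package choices, configurable. Two chromosomes are
distinguishable iff their signatures differ as ordered lists; uniqueness
checking is exhaustive pairwise comparison. Oligos are assigned to regions
by full containment so that amplifying a region's group cannot light up
flanking sequence.

## Pool assembly

**Pairing.** Within one amplification group (same chromosome and color by
default — a grouping choice that prevents a group primer from painting two
chromosomes), oligos are paired so each pair is separated by
≥ `min_pair_separation` (200 kb, start-to-start) and each oligo is used at
most once. For sorted positions, a matching of size m exists iff pairing
the i-th smallest with the (n−m+i)-th smallest is feasible, so binary
search on m yields a maximum-cardinality matching in O(n log n); tests
verify optimality against exhaustive enumeration. Each pair becomes one
100-nt genomic insert — the structural realization of halving synthesis
cost.

**Primers.** Three scopes: `FORWARD_COLOR` (one per color, carries the
dye), `REVERSE_GROUP` (nested inner site, one per chromosome group),
`REVERSE_POOL` (outer site shared by the whole pool). With a color forward,
the pool reverse amplifies that color's entire pool and a group reverse
amplifies one chromosome's units of that color. The nested order
(group-site inner, pool-site outer) is a package choice; published
descriptions establish only that the reverse sites are nested. Primers are
drawn by seeded rejection sampling of random 20-mers under: GC ∈
[0.40, 0.60]; nearest-neighbor Tm (SantaLucia & Hicks 2004 unified
parameters via Biopython `Tm_NN`, 50 nM primer / 50 mM Na⁺) within ±2 °C
of the 55 °C set target; no self-hairpin stem ≥ 6 bp (minimum loop 3); 3′
cross-complementarity ≤ 3 bp over all pairs including self; and no perfect
≥ 15-nt match to the target genome on either strand. An exhausted
iteration budget raises an error carrying per-constraint rejection counts.

**In-silico PCR.** A unit amplifies iff the forward primer matches its 5′
site and the reverse primer matches (as reverse complement) a site in its
reverse cassette, each within `max_mismatches` (default 0 — synthesis-grade
exactness; configurable for robustness studies). Unit construction rejects
any primer with a ≥ 15-nt perfect match inside the genomic insert, which
would make amplification ambiguous; with genome-screened primers this
cannot occur by construction.

## Cross-species mapping

Each oligo is placed at its best ungapped position over both strands of the
target; placements below `min_map_identity` (0.9, i.e. 45/50 — the aligner
threshold is not published, so this is the package default) are UNMAPPED.
Seeding uses disjoint exact k-mers with k = ⌊L/(mm+1)⌋ (k = 8 at 50 nt),
so any placement at or above threshold necessarily contains a clean seed: the
reported best placement is exact despite seeding. Ties break by
(chromosome, position, strand) and set a multi-mapping flag. The
non-orthologous rate is reported against both denominators — all designed
oligos and mapped oligos — because published rates use both conventions;
the mapped denominator is the headline value. Window counts bin mapped
placements by start into 100-kb tiles.

## rDNA screening

The query is the ordered composite 18S-ITS1-5.8S-ITS2-25S-IGS unit. The
bundled subunits are synthetic (generated, labeled as such), with
scaled-down but rank-realistic lengths (1000 / 180 / 150 / 200 / 900 /
500 bp; unit 2930 bp). Search is exact 16-mer seeding; around each seeded
diagonal the maximal-scoring ungapped segment (match +1, mismatch −2, the
classic ungapped-HSP drop rule) sets the hit extent. Coverage is the
aligned fraction of the query subunit (a BLAST qcovs analog — "coverage" is
not defined precisely in the source protocol); hits with coverage < 0.8 or
identity < 0.8 are discarded. The +1/−2 scoring keeps extension into
flanking random sequence to a few bases, so an edge-truncated copy
retaining fraction f of its 18S measures coverage ≈ f and the 0.8 boundary
is sharp at the tested 0.79/0.80/0.81 fractions. Same-subunit hits
overlapping or closer than 50 bp resolve to the best-scoring one. Copy
number per chromosome is the count of retained 18S hits, exactly as in the
source protocol; other subunits are reported but not counted. Clusters of
18S hits (gap ≤ 50 kb) are placed on arms — p is the shorter arm — with
terminal/interstitial classes sharing the barcode fractions. The 16-mer
seed is guaranteed sensitive to ~3 % subunit divergence by pigeonhole,
matching the tested robustness regime.

## Synthetic data: what it does and does not emulate

`simgenome` produces i.i.d. uniform background sequence (GC 0.5,
configurable), planted dispersed-repeat families at explicit loci with
per-copy identity, head-to-tail tandem rDNA arrays (edge units optionally
truncated to a fraction of their 18S), centromere positions, seeded
SNP/inversion/translocation mutants, and k-mer tables with
Poisson(multiplicity × depth) counts standing in for Illumina read depth.
Coordinates are 0-based half-open throughout. Every generator output is a
pure function of (config, seed) and byte-reproducible.

What this does *not* model: real repeat landscapes (nested TEs, satellite
arrays, low-complexity tracts), GC heterogeneity, sequencing error models
and mapping bias in depth tables, structural-variant complexity beyond
clean inversions/translocations, or assembly artifacts. Passing tests
therefore demonstrate algorithmic correctness against known truth at desk
scale — filters remove exactly the planted repeats, pairing is optimal,
copy counts are exact — not that default thresholds are optimal for any
particular real genome.

## Problem sizes and numerics

Test and reproduction runs use scaled-down inputs chosen once as the
package's study conditions: a 2 × 600 kb two-chromosome pipeline genome
with a 3-copy near-exact repeat family (candidates every 100 bp); twenty
200-kb genomes with planted exact and 76 %/74 %-identity duplications for
homology-oracle comparisons (candidates every 2 kb plus candidates at all
planted loci); 200–600 kb chromosomes carrying rDNA arrays of 1–30 units;
and 10 cells × 15 chromosomes for karyotype statistics. Quantile
computations use numpy's default linear interpolation; quantile-band
bounds are inclusive; density thinning and pairing are fully deterministic
tie-broken by position; all randomness flows from explicit integer seeds
through `numpy.random.default_rng`.

## Known limitations

- No thermodynamic probe scoring (per-oligo Tm/ΔG) and no BLAST screening
  against external databases; the homology screen is identity-based.
- Ungapped alignment throughout; indel-containing off-targets or
  placements are outside the model.
- Barcode region placement is user-specified (validated, not optimized);
  the bundled generator exists for synthetic designs.
- In-silico PCR checks primer-site matching, not amplification efficiency
  or cycle kinetics.
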