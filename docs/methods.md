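# Methods

`mdmscan` triages *microbial dark matter sequences* (MDMS): 16S rRNA
amplicon OTUs that no reference lineage explains but that are too abundant
to discard. The pipeline runs six stages in order — classify → select →
chimera → verify → magmatch → place — each encoding one published decision
rule. This note documents the models behind each stage, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices a maintainer would want to know.

## Pairwise alignment and percent identity

Every threshold in the pipeline is a statement about percent identity, so
the aligner is the foundation. It is a Gotoh affine-gap dynamic program
(match +1, mismatch −1, gap open −2, gap extend −1; configurable) with two
modes:

* **semiglobal** — global alignment with free terminal gaps on both
  sequences. Identity is `100·matches/aligned_columns` over the aligned
  core, internal gap columns included (BLAST-like denominator). Query
  coverage is the fraction of the query inside the core.
* **local** — Smith–Waterman, used where BLAST semantics are quoted
  (amplicon comparison, contig screening).

Scores are integers, so traceback decisions are exact equalities with a
fixed preference order (diagonal > gap-in-subject > gap-in-query). In
semiglobal mode the optimum is additionally canonicalized by maximizing the
triple (raw score, −columns, matches) lexicographically, implemented with
composite integer weights. Two consequences matter:

1. identity is *unique* — of all co-optimal alignments, the shortest, then
   the most-matching one defines it — and therefore exactly symmetric under
   query/subject swap;
2. zero-score balanced match/mismatch runs cannot pad the alignment ends,
   so coverage is not inflated by chance.

Ambiguity codes (N, R, Y, …) never match anything, including themselves:
identity can only be deflated by uncertain bases, never inflated.

One caveat, verified by a property test: mutating the subject by one
substitution can *raise* identity by a fraction of a point, because the
changed base may pair with a different query position under a shifted
co-optimal alignment, changing both numerator and denominator. The effect
is bounded (<2 points per step in testing) and the trajectory over many
mutations is strictly decreasing; exact per-step monotonicity holds only in
the ungapped (Hamming) regime.

Database search uses an 8-mer prefilter (candidates must share ≥1 k-mer with
the query; both configurable). The prefilter is recall-oriented; the
correctness surface is defined with it off, where the search provably ranks
every subject. Ties in identity break by subject id.

**Credible hits.** With free end gaps, an unrelated query can align a
few-base perfect core at near-zero coverage and report identity 100. Such
hits carry no taxonomic signal, so every consumer of "best hit" — the
classifier, chimera parent selection, fragment placement — requires the
alignment to span ≥50% of the query (`classify_min_coverage`). The same
idea caps contig screening: local hits spanning <100 bp of subject
(`mag_min_overlap`) are chance matches at 16S scale and are not reported.

## Unassigned detection and novelty ranks (classify)

An OTU is **unassigned** when its best credible database identity falls
below `assign_min_identity` (default 90%). The two alignment thresholds of
the source protocol, 75% and 90%, are reported as separate flags
(`unassigned_75`, `unassigned_90`); the dark fraction characteristically
sits between them.

The **novelty rank** maps best-hit identity to the taxonomic level at which
the query is likely new, using the canonical 16S identity floors:

| best identity *d* | call |
|---|---|
| *d* > 94.5 | known genus (NONE) |
| 86.5 < *d* ≤ 94.5 | new GENUS |
| 82.0 < *d* ≤ 86.5 | new FAMILY |
| 78.5 < *d* ≤ 82.0 | new ORDER |
| 75.0 < *d* ≤ 78.5 | new CLASS |
| 60.0 ≤ *d* ≤ 75.0 | new PHYLUM candidate |
| *d* < 60.0 | BEYOND_PHYLUM (likely artifact) |

Boundaries are inclusive on the novel side: identity exactly 94.5 already
means a distinct genus. The 60% artifact floor is this package's own
addition — at that divergence a short amplicon is more plausibly a
processing artifact than biology. The best hit's lineage is transferred
truncated at the novelty rank (a GENUS-level novelty keeps domain…family).

## MDMS candidate selection (select)

Two literal gates: an OTU needs ≥50 total reads across samples, and its
**abundance summary** must be strictly greater than 0.5%. The summary is
the *sum* over samples of per-sample relative abundances, in percent; the
protocol wording is ambiguous between sum, mean and max, so the reducer is
configurable (`--summary`, default `sum`) and recorded in the output. Only
unassigned OTUs are eligible. Selection is invariant under rescaling any
single sample (relative abundances), and the candidate count is monotone
non-increasing in the cutoff.

## Bimera detection (chimera)

A PCR bimera is a prefix of one template joined to a suffix of another. The
scan aligns the query to its top-k credible parents (k=8), projects each
alignment into a per-query-position match indicator (insertions and
unaligned positions count 0), and maximizes over ordered parent pairs
(A, B) and breakpoints c:

    chimeric_matches(A,B,c) = matches_A[0,c) + matches_B[c,L)

Since c=0 and c=L reproduce the single parents, the two-parent optimum
dominates the one-parent optimum and `delta = chimeric − best_single ≥ 0`
identically. A query is CHIMERIC when delta ≥ 2.0 percentage points
(`chimera_min_delta`) and both segments are ≥50 bases; queries shorter than
two segments or with <2 credible parents are UNDECIDED. The reported
breakpoint is the midpoint of the argmax plateau — the junction is only
identifiable up to the parents' local agreement run around it. Flagged
candidates are annotated, never removed: a chimeric call invalidates the
taxonomy of that sequence, not its existence in the data.

Operating characteristics on synthetic bimeras (parents ≥10% divergent,
breakpoints in the middle third) are measured by the acceptance script.

## Existence verification (verify)

Primer QC computes GC content, nearest-neighbor melting temperature,
longest self-complementary run, and 3′ GC clamp. The Tm model is the
unified NN parameter set (Allawi & SantaLucia 1997 ΔH/ΔS table) with duplex
initiation terms and the entropic salt correction 0.368·(N−1)·ln[Na⁺]
(SantaLucia 1998):

    Tm = 1000·ΔH / (ΔS + ΔS_salt + R·ln(C_T/x)) − 273.15

with R = 1.987 cal mol⁻¹ K⁻¹, 50 mM monovalent salt and 0.5 µM total oligo
by default; x = 4 for non-self-complementary duplexes, x = 1 plus a −1.4
entropy unit symmetry term for self-complementary ones. The implementation
is validated against an independently coded NN implementation to 0.1 °C.
Acceptance windows (GC 40–60%, Tm 57–63 °C, pair ΔTm ≤ 3 °C, self-dimer run
≤ 8) are package defaults, configurable; the source protocol does not state
its values.

In-silico PCR binds the forward primer on the plus strand and the reverse
primer's reverse complement downstream, each tolerating ≤2 mismatches but
with the 3′-terminal 3 bases exact (extension starts there). Exactly one
product is required; multiple products mean non-specific amplification and
the result is discarded (`MULTIPLE_PRODUCTS`).

The re-sequencing comparison aligns the amplicon (query) to the original
representative in local mode — query cover is local-HSP based, as BLAST
reports it — and passes at identity **strictly above 95%** with **100%
query cover**. Identities in (94.5, 95] with full cover are flagged REVIEW
rather than passed: within a 97%-identity OTU, a genuine re-observation of
the same genus can fall just under the line.

## MAG cross-validation (magmatch)

Candidates are screened against metagenome contigs by local alignment
(full DP for contigs ≤20 kb, k-mer-window seeding beyond). One best hit per
(MDMS, contig) pair is reported with identity, overlap length (aligned
residue pairs — never exceeding either sequence), both lengths, and the
owning bin's completeness/contamination/size. A hit **passes** when
identity is strictly above 96% *and* the contig's bin meets the
draft-genome bar: completeness ≥50%, contamination ≤10%. Hits to unbinned
contigs are kept as assembly-only evidence (UNBINNED); hits in failing bins
carry BIN_QC; hits covering <50% of the MDMS length are flagged LOW_COVER
for human review instead of being auto-rejected, preserving the manual
"overlap locations" review step as an annotation.

## Phylogenetic placement (place)

The reference multiple alignment is masked by per-column gap frequency:
columns with gap fraction > 0.70 are dropped (deterministic, idempotent).
Posterior-probability masking of covariance-model aligners is out of scope
— there are no posteriors in a pairwise projection.

Each fragment is aligned semiglobally to its best credible reference and
projected through that reference's gap pattern into alignment columns;
fragment insertions relative to the reference are discarded, uncovered
columns stay gaps. Distances are Jukes–Cantor over shared non-gap columns;
pairs with <50 shared columns or saturated divergence (p ≥ 0.75) get 1.1×
the largest finite distance and are flagged, because neighbor joining needs
a complete matrix.

The tree is canonical Saitou–Nei neighbor joining with the Q-criterion,
deterministic via first-minimum scanning in taxon order, negative branch
lengths clamped to zero. NJ replaces approximate-ML tree building
deliberately: the artifact needs placement adequate for taxonomic
attribution, not publication-grade tree inference. Each fragment is
reported with the reference leaf minimizing path distance, that leaf's
lineage, an AMBIGUOUS flag on exact ties (lexicographic winner reported),
and a phylum-level caveat flag when the runner-up leaf disagrees at phylum
rank — the analog of "situated near phylum X" with an explicit uncertainty
marker.

## Synthetic data (synthdata)

The generator emulates a multi-environment 16S study at desk scale:

* **Reference database** — a rank-structured hierarchy (default 4 phyla ×
  2 classes × 2 orders × 2 families × 2 genera = 64 references, 450 bp, the
  V3–V4 amplicon scale), built by recursive substitution-only evolution
  with per-rank divergence steps. Because reference evolution is
  substitution-only, the true MSA is column-exact by construction;
  per-phylum deletion windows then create gapped columns, one window shared
  by half the phyla (survives masking) and one private to a single phylum
  (exceeds the 0.70 gap fraction and is masked).
* **Identity bands** are enforced by *measurement*, not mutation count:
  `evolve` mutates until the package's own aligner reports the target ±1
  point, and `plant_novel` rejection-samples until the best credible
  database identity sits ≥1 point inside the requested novelty band. Band
  guarantees are therefore definitionally true.
* **OTU table** — log-normal background counts (μ=6, σ=1.2 per cell,
  ≈10⁴ reads/sample over 8 samples); planted rows are solved against the
  background column sums so their abundance summaries land on target
  (5.0/3.0/2.5/2.0/1.6/1.2% for the six planted MDMS, 0.1% for the
  below-cutoff control, 30 total reads for the below-floor control).
* **Chimeric MDMS** — bimeras of two genus-band plants rooted in different
  phyla: each half echoes a different reference at ~90%, the whole matches
  nothing above the unassigned line.
* **Contigs and bins** — planted MDMS embedded between 300 bp random flanks
  at 0.5–5% mutation; bins follow a fixed quality spectrum that straddles
  the 50%/10% boundaries (including observed draft-genome values 83.51/0.959
  and 54.38/0).
* **Primers** — perfect-match pairs excised from each clean MDMS's ends.

Every generator writes truth TSVs; tests read truth, never regenerate it.

What the generator does **not** emulate: rRNA secondary structure and
conserved/variable region architecture, sequencing error profiles and
quality scores, PCR amplification bias, copy-number variation, real
database taxonomic imbalance, and genuinely partial-length references.
Passing tests therefore demonstrate that the decision rules are implemented
exactly and behave correctly under controlled divergence — not that the
thresholds themselves are well-calibrated for any particular real
environment.

## Problem sizes and determinism

Default test and acceptance problem sizes are chosen for seconds-to-minutes
turnaround on one core: 64-reference database, 30 OTUs, 200 oracle
alignment pairs of length ≤40, 100+100 chimera queries against a
16-reference parent pool, 50 five-taxon NJ cases. Every random draw flows
from an explicit seed; the full pipeline run is byte-deterministic given
config and inputs (verified by running it twice and comparing outputs).

## Known limitations

* Identity is pairwise, not profile- or secondary-structure-aware; on real
  16S data a covariance-model aligner would mask and align more accurately.
* The bimera model considers exactly two parents and one breakpoint;
  multi-parent chimeras and short conversion tracts are out of scope.
* NJ topology is a distance method; for deep or rate-heterogeneous
  divergence an ML tree would place fragments better.
* The E-value machinery of BLAST is replaced by hard floors (coverage,
  overlap length); these are blunt but deterministic.
* Thermodynamic hairpin/heterodimer ΔG, degenerate primers and multiplex
  interactions are not modeled in primer QC.
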