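# Methods

This note documents the models and procedures implemented in `mirkit`, the
parameters that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Coordinates, alphabets, and reporting

All coordinates are 1-based inclusive; the span of an interval
`start..end` is `end − start + 1` (so a cluster printed as `200-591`
measures 392 nt). GFF3 output uses the same convention natively; a
0-based half-open view is available and round-trips exactly. Sequences are
normalized to the RNA alphabet (T→U) at the I/O boundary, with the source
alphabet remembered for write-back, so all internal logic sees RNA only.
Percentages in reports are rounded half-up at two decimals
(`Decimal`-based, so 0.125 → "0.13"), and the targets-per-miRNA average is
rounded half-up at one decimal. Read accounting maintains the identity
`remaining = cleaned − Σ contaminants` as a structural property of the
accounting type, not a convention.

## The folding engine

Every object this package scores energetically is a single hairpin (a
precursor candidate or one arm's duplex), so the secondary-structure
engine is deliberately restricted: it searches all pseudoknot-free
structures with **exactly one hairpin loop and no multiloops** — a single
helix chain interrupted by bulges and internal loops. Within that space it
is exact: a dynamic program over closing pairs `(i, j)` with interior
extensions to an inner pair `(k, l)`, where the total unpaired length of
an interior excursion is capped at `max_interior = 30` nt. Allowed pairs
are AU, UA, GC, CG, GU, UG. If no structure scores below zero the open
structure with ΔG = 0 is returned.

The energy model is additive nearest-neighbor:

- **Stacks.** A 6×6 table of stack free energies (kcal/mol) over the six
  pair types, with Turner-like magnitudes (−0.3 to −3.4), constrained to
  be strictly stabilizing for every combination (including G:U over G:U,
  which tabulated parameters put near or above zero) and to the
  thermodynamic symmetry E[p/q] = E[rev(q)/rev(p)].
- **Loops.** Size-only penalties, never sequence-dependent:
  hairpin(n) = 5.40 + 1.08·ln(n/3); bulge(n) = 3.80 + 1.08·ln(n);
  internal(n) = 4.10 + 1.08·ln(n/2); bulges and internal loops
  additionally pay 0.45 kcal/mol per unpaired nucleotide beyond 6. The
  logarithmic term is the Jacobson–Stockmayer form at 37 °C; the linear
  term keeps wide interior excursions realistically expensive — in a
  single-hairpin-only search space, distant spurious complementarity in
  flanking sequence would otherwise chain into the main helix through
  large cheap loops, which a multiloop-capable folder would instead place
  in separate helices. All penalties are non-negative and non-decreasing
  in size. A direct consequence of the size-only design: substituting an
  unpaired loop base while the structure is held fixed leaves the energy
  unchanged, so a loop SNP whose MFE structure is allele-invariant has
  ΔΔG exactly 0.
- **Duplexes.** Bimolecular sites (miRNA:UTR) are scored as +4.1 kcal/mol
  initiation plus the same stack table, no loop terms (the duplex helix is
  contiguous by construction).

Energies are handled internally as integer centi-kcal/mol so that
equal-energy ties are exact; among ties the 5'-most, then longest, closing
helix is chosen, and the traceback re-applies the same ordering at every
step, making the fold fully deterministic. Minimum hairpin loop is 3 nt;
minimum foldable sequence is 10 nt.

Two independent reference implementations ship with the engine for
validation: `enumerate_hairpin_chains` literally generates every
single-hairpin structure with its energy (practical to ~20 nt), and
`exhaustive_fold` takes the minimum over that enumeration with no
interior-size cap. The test suite and the acceptance script verify the DP
against this enumeration on hundreds of random sequences of length 10–20.
Reproducing any specific published ΔG value from a Turner-parameter folder
is explicitly not a goal; the engine adapter (`sequence → (dot-bracket,
ΔG)`, e.g. `viennarna_engine`) exists for users who need parity with
RNAfold/UNAfold numbers. Signs and structure-invariance properties — not
magnitudes — are what the downstream SNP analysis relies on.

Complexity is O(n²·w²) with small constants (the inner minimization is a
vectorized block lookup); a 150-nt precursor candidate folds in ~30 ms.

## Region annotation

For a single-hairpin structure the terminal loop is the unpaired interval
enclosed by the innermost pair; everything 5' of it is the 5' arm
(`stem5`) and everything 3' the 3' arm (`stem3`). Bulge and internal-loop
nucleotides are labeled by their arm, not as loop. Given a mature span the
opposite arm is the anti-stem; a mature that straddles the loop (rejected
by discovery, but allowed in annotation) is assigned the arm holding the
majority of its positions, ties to the 5' arm.

## Discovery

**Homology arm.** Known matures are first deduplicated by exact sequence
(first-seen name kept, aliases recorded). Each query is scanned gap-free
against both strands of every reference, identity = matching positions /
query length, threshold 0.90; the scan is a vectorized sliding-window
comparison rather than a gapped aligner because the identity measure is
anchored to the full query and the 90% threshold tolerates at most 2–3
substitutions in a ~22-mer, where indels essentially never help.
Overlapping placements are reduced greedily best-first. Matched regions
are excised with 60-nt bilateral flanks (truncated silently at contig
ends; minus-strand hits are excised as reverse complements with the mature
offset recomputed on the excised strand), folded, and validated.

**Hairpin criteria.** Six independent flags with boundary semantics
exactly at the stated values: ΔG ≤ −15 kcal/mol; fraction of mature
positions base-paired ≥ 0.80; largest single bulge/internal loop (total
unpaired nt across both sides) ≤ 18; hairpin length > 53 nt (53 fails);
terminal loop < 22 nt (22 fails); number of unpaired mature positions
("mismatches" against the anti-stem) ≤ 6. Stem coverage is defined as the
*paired* fraction of the mature, which is the strictest reading; the
looser alternative (mature positions merely lying within the arm) passes
candidates whose mature is partly melted. A candidate whose fold is open
fails all structural flags.

**Read arm.** Cleaning: reads containing the 5' adapter are discarded;
the 3' adapter is trimmed at its leftmost match with minimum overlap 6 nt
and ≤ 1 mismatch per 10 aligned nt; after trimming, poly(A) reads (≥ 8
consecutive A or > 80% A), mean-Phred < 20 reads, and reads < 18 nt are
discarded; identical survivors are collapsed with counts. The adapter,
poly(A) and quality parameter values are this package's defaults, chosen
to match common small-RNA practice, and are all configurable. Contaminant
annotation replaces a database e-value search with deterministic
full-length matching at ≤ 1 mismatch (either strand) against user-supplied
rRNA/tRNA/snRNA/repeat FASTA sets, with that priority order. Discovery
maps reads exact-match to both strands of the references, chains stacks
within 30 nt into loci (so mature- and star-arm stacks separated by the
terminal loop form one locus), excises each locus with 60-nt flanks,
folds, and keeps loci where (a) the dominant (most abundant, ties to the
leftmost then lexicographically smallest) read lies entirely within one
arm, (b) the six criteria pass with the dominant read as the mature, and
(c) the locus holds ≥ 2 reads (the default mirrors the lowest read count
at which star sequences were retained; configurable). Reads on the
opposite arm define the star span. Because both strands are scanned, each
hairpin is typically discovered twice (once as its own reverse
complement); the catalog merge collapses these.

**Merging.** Entries merge when mature sequences are identical, or one is
a subsequence of the other at an overlapping precursor locus on the same
strand. Homology-found entries are conserved; sequencing-only entries are
conserved when homologous (≥ 0.90) to a supplied known-miRNA set, else
specific. Expression counts merge by maximum, which counts multi-mapping
loci once. Genuinely conflicting matures at one locus are kept separate
and flagged for review rather than silently resolved.

**isomiRs and moRNAs.** An isomiR is a read matching the precursor whose
span overlaps the mature span with both ends within 3 nt of the mature
ends, excluding the reference-identical read. A moRNA candidate matches
the precursor at 100% identity entirely outside the mature and star spans,
beginning or ending within 2 nt of a mature/star boundary.

## Characterization

Clusters are single-linkage chains of same-reference, same-strand
precursors with inter-member gaps ≤ `max_gap`; the default of 10,000 nt is
deliberately permissive (published fish miRNA clusters are all < 1 kb) and
configurable; singletons are excluded and the cluster span is the
min-start..max-end inclusive interval. Phylogenetic grouping of a family's
species-presence row: *shared* if present in ≥ 1 protostome and ≥ 1
deuterostome, *fish-only* if present only in fish, *vertebrate-only*
otherwise within vertebrates; the built-in species→clade map covers the
common miRBase species codes and can be overridden.

The conserved-vs-specific expression comparison uses a two-sided
Mann–Whitney U: full enumeration of label arrangements (midrank ties, the
"at least as extreme deviation of U from nm/2" definition) for combined
n ≤ 12, the tie-corrected normal approximation above. 2^−ΔΔCt profiling
computes ΔCt = Ct_gene − Ct_reference per sample, ΔΔCt against a
calibrator sample (whose relative expression is therefore exactly 1), and
carries log2(relative) = −ΔΔCt for clustering. miRNA–target correlation is
Pearson on the log2 series with a t-distribution p; r < 0 with p ≤ 0.05
flags the reciprocal pattern expected of repression. Hierarchical
clustering is agglomerative with Euclidean distance and complete linkage —
chosen for compact, outlier-robust expression groups — with deterministic
leaf order.

## Target prediction

Predictor A reports canonical seed sites by type: 6mer (Watson–Crick match
to miRNA positions 2–7), 7mer-m8 (2–8), 7mer-A1 (2–7 plus an adenosine on
the UTR opposite position 1), 8mer (both); no wobbles, no mismatches; each
match is reported once at its strongest type (8mer > 7mer-m8 > 7mer-A1 >
6mer). Predictor B accepts 6–8-nt seed duplexes anchored at miRNA
position 2 with zero mismatches and at most one G:U (none in 6mers), then
extends the helix outward in both directions while complementarity (WC or
G:U) continues and keeps the site iff the duplex energy (initiation +
stacks) is ≤ −9 kcal/mol; per seed anchor the longest qualifying seed is
reported. No accessibility/opening-energy term is modeled. The UTR is
scanned sense-strand only, with the miRNA antiparallel.

A miRNA–mRNA pair is a **consensus** target when both predictors report
sites sharing at least one UTR position (a config flag relaxes this to
pair-level identity); the consensus site inherits the A-site interval.
False-positive rate on a labeled set is the fraction of negative pairs
with ≥ 1 predicted site; because consensus pairs are a subset of each
predictor's pairs, FPR(consensus) ≤ min(FPR(A), FPR(B)) on any set — the
intersection-monotonicity property the suite asserts instead of any
data-dependent published rate.

## SNP effects

Precursor SNPs are classified on the wild-type structure: *mature* if
inside the mature span (overriding all), *loop* if in the terminal loop,
*anti-stem* on the arm opposite the mature, *stem* otherwise. These four
regions partition every precursor position. ΔΔG = ΔG(mutant) − ΔG(wild),
both alleles folded independently by the same engine. The sign convention
(mutant minus wild) is stated in every output. |ΔΔG| < 0.3 kcal/mol is
interpreted as negligible for biogenesis; at or beyond the threshold the
published direction rule is applied literally — energy decrease → reduced
mature production, increase → increased production. Because that mapping
is thermodynamically counterintuitive, `rule="inverted"`
(`--biogenesis-rule inverted` on the CLI) provides the opposite mapping;
the default preserves the published behavior.

For a 3'UTR SNP, both predictors run on both alleles, restricted to sites
overlapping the SNP position ± 7 nt (one maximal site length minus one).
Per miRNA with any site in that window: **loss** iff the wild allele has a
consensus site and neither predictor fires on the mutant; **gain** iff the
mutant has a consensus site and neither predictor fires on the wild
allele; every other firing pattern — including consensus surviving as a
single-predictor site — is **unchanged**. Over the 16 possible
(A_wild, B_wild, A_mut, B_mut) patterns exactly one is loss and one is
gain. The "neither predictor" reading of the loss definition was chosen
for symmetry with the gain definition.

## Synthetic data

Generators are deterministic under their seed (identical bytes for
identical config) and every emitted object carries a ground-truth entry.
Background sequence is i.i.d. uniform over {A, C, G, U}. Hairpins are
built as a random 5' arm, a loop with non-pairing G/A termini (so the
fold cannot creep into the loop), and a reverse-complement 3' arm degraded
by the requested mismatches (1×1 internal loops) and single-base bulges;
clean constructs with stem ≥ 8 refold to the planted structure exactly.
The mature is the loop-proximal ≤ 22 nt of the 5' arm. Reference contigs
plant tens of precursors (default 30; stems 25–35 nt, loops 4–8 nt) with
configurable clustered pairs at a stated gap and a 25% minus-strand
fraction. The read simulator draws mature (85%), star (10%) and templated
isomiR (5%) inserts per precursor at depths of 50–500 (defaults),
appends the 3' adapter, clips to 36 nt, injects substitution errors at a
configurable rate, and mixes in contaminant substrings, poly(A) junk,
adapter-only and short-insert reads; the defaults emit on the order of
10⁴ reads so a full pipeline run takes seconds, and production-scale read
counts are a config choice, not a test requirement. UTR fixtures embed
exactly one site of the requested type (with full 3'-supplementary
complementarity over six further miRNA bases, so 7mer-m8/8mer plants clear
the energy cutoff), screened against incidental sites by bounded retries;
SNP plans mutate a mid-seed pairing position ("destroy") or plant the
near-site one substitution away ("create"), verifying that the broken
allele is silent for both predictors.

What the generators do **not** emulate: realistic base-quality error
profiles, ligation bias, tissue-specific expression structure, genomic
repeat families, or paralogous precursor families. Passing the recovery
tests therefore demonstrates the pipeline's correctness on unambiguous
signals — planted hairpins recovered at 100%, shuffled decoys rejected at
100% — not its sensitivity/specificity trade-off on real libraries, which
depends on noise sources these fixtures deliberately exclude.

## Known limitations

- The folding model excludes multiloops, dangles, coaxial stacking and
  suboptimal ensembles; its ΔG values are internally consistent but not
  comparable in magnitude to Turner-parameter folders (use the engine
  adapter when that matters).
- Homology search is substitution-only; a homolog differing by indels
  from its nearest known mature will score low identity.
- Contaminant annotation is near-exact matching, not a profile/covariance
  search; diverged contaminant fragments can escape it.
- The energy target predictor has no site-accessibility term, so its
  absolute site counts are not comparable to accessibility-aware tools;
  only the consensus logic depends on it.
- The "errors in one bulge ≤ 18 nt" hairpin criterion is implemented as
  max-single-bulge/internal-loop size, the most direct reading of an
  ambiguous phrasing.
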