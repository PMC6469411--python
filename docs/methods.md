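# Methods

## Scanner model and assumptions

The scanner treats PEVK exon discovery as a two-stage problem: *seeding* by
amino-acid composition and *boundary resolution* by splice-site geometry.

Seeding operates on the three forward-frame translations of the input
(reverse-strand scanning is deliberately out of scope; a locus on the minus
strand should be reverse-complemented first). A window of `window_len`
residues (default 10) slides one residue at a time; a window seeds when its
PEVK ratio — the fraction of residues in {P, E, V, K, A}, with `X` (from
N-containing codons) and `*` counting as non-PEVK — is **at least**
`min_ratio` (default 0.54; the comparison is inclusive so the published
optimum admits windows at exactly the threshold). Overlapping windows
(sharing ≥ 1 residue) merge into candidate regions; windows that merely
abut stay separate. `window_len` and `min_exon_len` are measured in
amino-acid residues: the scan operates on translations, and the
optimization ranges (10–30, bracketing observed minimum and mean exon
lengths) are only coherent in residue units.

Boundary resolution assumes canonical GT–AG splicing: an exon is delimited
by the acceptor AG of the upstream intron (exon start `s`, with
`genome[s-2:s] == "AG"`) and the donor GT of the downstream intron (exon
end `e`, with `genome[e:e+2] == "GT"`). Acceptor candidates are every AG
whose implied start lies within `splice_flank` nt (default 60) of the
candidate start, donors symmetrically at the end; the flank is clipped at
sequence ends. An admissible pair must span at least `3·min_exon_len` nt
and overlap the seed candidate — without these constraints the raw
minimum-distance rule would collapse onto degenerate 2-nt spans. Among
admissible pairs the shortest wins; ties break to the smaller start for
determinism. Candidates with no admissible pair are discarded, which is
what makes PEVK-rich decoys without splice sites harmless and what makes
the method fail, by design, on loci with non-canonical splice sites (a
configuration hook for extra motifs exists but ships disabled).

Exons found in more than one frame are collapsed: within a group of
transitively overlapping calls the highest PEVK ratio wins, then the longer
exon, then the lower frame index. The collapse rule matters less than it
appears — overlapping calls from different frames almost always carry
identical boundaries (the admissible-pair set is frame-independent) and
differ only in the ratio of their shifted translations.

Region trimming locates the exons best matching the two landmark peptides
by best ungapped identity (landmark slid over the exon, partial overlaps
allowed, matches divided by landmark length) and keeps the inclusive range
when both exceed `landmark_min_identity` (default 0.8, generous enough for
the "nearly identical" landmark variants seen across mammals); otherwise
the set is returned untrimmed with a warning, never silently truncated.

## Benchmark

The match-score machinery replaces an external local-alignment search with
an exact-matching engine: since only 100%-identity hits are ever retained,
a hit is equivalent to a shared exact substring, and the hit score
(bit-score surrogate) is the shared-stretch length. The minimum qualifying
stretch is 12 nt (configurable; the analogue of a seed/word size). Per
annotated exon the best hit is kept (ties: longer predicted exon, then
smaller start); *perfect* means the best hit's predicted sequence equals
the annotated sequence exactly, so any over- or under-estimation of length
demotes a recovery to non-perfect. The score

`total = 0.7·(recovered/annotated) + 0.1·(perfect/recovered) + 0.2·max(0, (100−matchless)/100)`

defines the perfect component as 0 when nothing is recovered, and its
extraneous component hits 0 at 100 matchless predictions. The grid search
evaluates every combination independently (no state is shared between
evaluations) and reports all rows plus the argmax region (everything within
1e−9 of the maximum), since the optimum is properly a *region* of parameter
space rather than a point. The default ratio step of 0.01 with the
published ranges yields 21·39·21 = 17,199 combinations.

Coordinate-mode validation (for comparing third-party annotation tools)
counts a tool exon as a match when it covers ≥ 50% of some reference exon;
a tool exon spanning several reference exons counts once; *missing* and
*novel* are defined by strictly zero overlap.

## Region architecture

PEVK-N/PEVK-C and PEVK-CA/PEVK-CB boundaries are properly manual calls;
`partition_regions` applies user bounds verbatim and records provenance.
The heuristic alternative maximizes `downstream density (exons/kb) ×
downstream mean ratio − local mean ratio` over a centered 7-exon window —
the quantity peaks where sparse, mixed-ratio exons give way to the dense,
high-ratio PEVK-C — and ends PEVK-CA at the last exon of the largest run of
C-region exons whose inter-exon gaps fall in the short-gap cluster of a
two-group (minimum within-group variance) split of the gaps. A plain
median threshold is *not* used: within-CA spacing varies enough that the
median splits the CA run itself. The heuristic emits a warning and is
advisory; it recovers planted synthetic boundaries to ±2 exons but is not
claimed to reproduce any particular manual call. Composition comparisons
use Welch's unequal-variance t-test per residue (and for length/ratio),
N vs C, with no multiple-testing correction by default (configurable
downstream); cross-species substitution summaries use a one-way ANOVA with
Tukey-HSD adjusted all-pairs contrasts.

## Comparative analyses

Ortholog calls use reciprocal best hits under a fixed alignment scoring
(match +1, mismatch −1, linear gap −2): the forward search is glocal (query
fully aligned, free target end gaps, the analogue of aligning a short exon
into a larger set), ties break to the longer target then smaller index, and
hits below `min_score` (default 10, i.e. ≥ ~10 matched nt net) are
rejected. Under a fixed scoring scheme the e-value/bit-score ordering of a
database search collapses to the alignment-score ordering, which is why a
dynamic-programming aligner can stand in for it exactly. Confident
ortholog groups require ≥ 11 species including the reference ("more than
10"). Substitutions per exon pair are the mismatched columns of a global
alignment with gap columns excluded; whether gaps should count is genuinely
ambiguous in the upstream tooling, and excluding them makes the statistic a
pure substitution count. Dot plots mark window pairs agreeing at
≥ `min_identity` of positions (default window 11, identity 0.8).

## Synthetic data: what it emulates and what it does not

The generator plants a three-block architecture — by default 50 PEVK-N
exons (15–40 aa, target ratio 0.75, introns 300–900 nt), 40 PEVK-CA exons
(12–28 aa, ratio 0.85, introns 100–260 nt) and 9 PEVK-CB exons (ratio
0.80, introns 600–1400 nt) — bounded by the two landmark exons, with
PEVK-rich decoys lacking splice sites and N-runs (10–150 nt) inside
introns. These defaults mirror the observed mammalian pattern of a longer,
more variable-length N block, a dense high-ratio CA block and a sparse
tail, at region sizes matching the human exon counts.

Three construction rules make planted truth *exactly* recoverable, by
design rather than by chance:

* **Exon interiors contain no AG or GT.** One codon per amino acid is used,
  none containing AG/GT and none ending in G; valine is excluded from
  sampled exon residues (every Val codon contains GT); a small adjacency
  rule (no E/A after E/K) prevents AG at codon junctions. Hence the planted
  (AG, GT) pair is the unique admissible pair for its candidate.
* **Intron interiors are sampled over {A, C, T} with AA and CC forbidden.**
  No G means no splice sites at all; the forbidden bigrams exclude every
  Lys/Pro codon, and the missing G excludes Glu/Val/Ala codons, so intron
  translations have PEVK ratio 0 in all frames and can never seed.
* **PEVK residues are evenly spaced within each exon** (identities random,
  positions deterministic), so every window's ratio tracks the exon ratio
  to within ~1/window and threshold behaviour follows the planted ratio
  rather than sampling noise.

Two deliberate deviations from an idealised contract: per-exon ratios hit
the nearest *achievable* value `round(target·len)/len` (a ±0.02 tolerance
is unattainable by pigeonhole below 25 residues), and the terminal landmark
is planted as its nearly-identical K2→P variant — any reverse translation
of the exact peptide puts an AG within 9 nt of the exon start, where a
shorter admissible pair would beat the true boundaries. Both the variant
(identity 14/15) and the exact first landmark remain recognizable to the
trimmer; the first landmark's interior Val-codon GTs and one junction AG
sit where no admissible competing pair can form.

Consequently, passing the exact-recovery tests shows the pipeline is
correct *given* canonical splice sites and compositionally clean introns.
Real genomes violate both: spurious in-flank AG/GT near true boundaries,
non-canonical splicing, and PEVK-adjacent intron composition all produce
the boundary over-/under-estimation seen in practice. The mutation model
(`mutate_species`: point substitutions sparing retained splice
dinucleotides, tandem CA-block duplication with a clean spacer, whole-exon
loss) reintroduces some of this realism for ortholog and robustness tests,
but makes no attempt at realistic splice-signal strength, isoform
structure, or selection.

## Numerical choices and degenerate inputs

Window threshold comparisons use an integer count against `min_ratio ×
window_len` with a 1e−9 guard, so equality at the boundary is stable.
Translations force any N-containing codon to `X` regardless of synonymous
ambiguity. Sequences shorter than one codon, empty FASTA files, non-IUPAC
characters (anything outside A/C/G/T/N/U) and ambiguity codes other than N
are hard errors — failing loudly beats silently translating unexpected
assemblies. Empty window lists, candidates with no admissible pair, and
landmark misses all degrade gracefully (empty outputs or warnings, never
exceptions). Grid values are rounded to 10 decimals when enumerated so
floating-point accumulation cannot change the grid size. All randomness is
seeded through `numpy.random.default_rng`; generator output is
byte-reproducible given the spec (the seed is part of the public contract
and recorded in the truth record).

Problem sizes used by the test-suite and the acceptance script — a ~53 kb
synthetic locus with 99 planted exons for end-to-end checks, sub-2 kb loci
for brute-force oracle comparison, 40-exon subsets for alignment-heavy
properties, and 500 replicates for the composition power check — were
chosen as the smallest sizes at which each property is meaningfully
exercised.

## Known limitations

No reverse strand; no splice-site strength model (position-weight matrices
would reduce the non-canonical failure mode); frame-collision tie-breaking
is a convention, not biology; the region-boundary heuristic is advisory;
the benchmark's exact-match engine cannot credit near-identical (<100%)
recoveries, exactly as intended by the scoring definition it implements;
ortholog scoring parameters are a stated convention where the upstream
search parameters are unknowable. The CLI `optimize` over the full default
grid re-scans the locus 17,199 times and is meant for real optimization
runs, not routine testing — tests use restricted grids.
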