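# Methods

## The contact coding scheme

A contact between two skull bones is coded on two independent axes.  The
**spatial relation** is nominal with six codes: `p` (the suture plane is
perpendicular to the bone surfaces), `o`/`u` (one bone broadly overlaps
the other — two codes for the two directions of the same observation),
`c`/`cb` (one bone clasps the other), and `t` (vertically transverse).
The **suture depth** is ordinal with four levels, `s < if < im < is`
(smooth to strongly interfingering), plus `?` when the spatial relation
can be determined but the suture type cannot — the normal situation in
crushed or matrix-obscured fossil material.  A contact whose character
changes along its course is stored as an ordered anterior-to-posterior
list of (relation, depth) segments; a bone pair can also be `absent`
(demonstrably no contact) or `unknown` (region not assessable), which
are deliberately distinct states.

Because `o`/`u` and `c`/`cb` are directional complements, records are
canonicalized: the lexicographically smaller bone name is stored first
and relations are expressed from its viewpoint.  Canonicalization is
idempotent and the two directed statements of one observation map to the
identical record; both properties are under test.

## The similarity statistic

For taxa A and B, every bone pair scored in both enters the comparison
unless it touches an excluded bone (default: the nasal, present in only
one study taxon).  A pair is *similar* when both contacts are present
and their segment sequences match under the segment rule — same spatial
relation, and depth difference strictly below the threshold (default 2:
adjacent depth categories are similar, a two-step difference is not).
Present-versus-absent is dissimilar; an `unknown` status removes the
pair from the denominator.  The statistic is

    S(A, B) = round_half_up(100 · n_similar / n_comparable)

Four rules the coding scheme itself does not fix are policy fields, each
with the default stated and the alternative available for sensitivity
analysis:

| field | default | rationale |
|---|---|---|
| `depth_threshold` | 2 | two ordinal categories apart = dissimilar |
| `unknown_depth` | `treat_as_similar` | the published matrix includes the fossil despite its undeterminable depths, so unknown depths cannot have voided pairs; spatial relations must still match |
| `both_absent` | `exclude` | a shared non-contact carries no information about *contacts*; `count_similar` provided |
| `multi_segment` | `sequence_exact` | the anterior-to-posterior order is part of the observation; `multiset` ignores order |

Invariants under test on 1,000 randomized tables: symmetry, values in
[0, 100], self-similarity 100 % when statuses are known, equality with
an independently written enumeration of the rule, and monotonicity
(raising the depth threshold never lowers a similarity).

## The study fixture and why its matrix differs from the published one

`src/sutura/data/study_contacts.tsv` transcribes the narrative contact
descriptions of the four study skulls into 266 schema rows.
Transcription conventions: an explicit overlap/underlie/clasp verb takes
precedence over "parallel"/"transverse" adjectives; unqualified
"interfingering" is coded `im`; "blunt"/"loose"/"smooth" is `s`; where
the two bones' own descriptions disagree, the section with the explicit
direction verb (or, failing that, the more detailed account) was
followed; midline contacts of a bone with its antimere are outside the
pair model and are not coded.

Computed on this fixture, the similarity matrix has the published shape
and machinery but lower values (9–39 % across a 16-setting policy
sweep, against published values of 33–51 %), and the published ordinal
finding — the fossil least similar to every living taxon — does not
emerge under any setting.  Two causes were identified during
transcription and are inherent to the source text rather than the
statistic.  First, the narrative is *asymmetrically detailed*: the
fossil's contacts are mostly single segments with unknown depths (which
the default policy can only count as similar or dissimilar on spatial
grounds), while the living skulls' contacts are narrated part by part,
so segment-count mismatches register as dissimilarity between living
taxa.  Second, the narrative *disagrees with itself* in places — the
same suture is not rarely given different depths, or opposite
directions, in the two bones' sections — so the study's own tabulated
codings (a supplementary data file, not shipped here) are evidently a
cleaned dataset that prose transcription cannot recover.  Users with
access to the original coding tables can convert them to the long-TSV
schema and drop them in; every downstream number then recomputes.

## Synthetic contact evolution

The generator draws a binary tree by random sequential attachment with
Gamma(2, 0.5) branch lengths (mean 1), an ancestor whose `n_pairs` bone
pairs are independently present or absent with probability ½ (present
contacts get 1 or 2 segments, relation uniform over the six codes,
depth uniform over the four levels), and evolves each pair along each
branch with three independent Poisson event counts (mean = rate ×
length): presence toggles, relation switches (uniform resample), and
±1 depth steps clipped to [0, 3].  Depth moves of two categories — the
similarity rule's trigger — therefore require at least two events.
Defaults (rates 0.3 / 0.3 / 0.1, 50 pairs) give mid-range similarities
on unit-depth trees.  What the simulator does *not* emulate: anatomical
correlation between neighbouring pairs, directional trends, taxon-biased
missingness, or observer error; passing tests therefore demonstrate the
statistic's behaviour under the stated model, not the realism of any
particular empirical table.

Validated properties: byte-identical reruns under a fixed seed; all
100 % similarity at zero rates; with events enabled, negative Spearman
correlation between tip-pair similarity and tree path length in ≥ 95 %
of 200 replicates.

## Character-matrix assembly

Cells are frozensets of integer states, `?` (missing) or `-` (gap, kept
on round trips but counted as missing — the standard morphology
convention).  NEXUS reading goes through DendroPy; NEXUS writing and the
TNT `xread` dialect are implemented here (ordered flags travel in an
ASSUMPTIONS `TYPESET … ord:` line, or a TNT `ccode` line).

**Insertion positions.**  The seven new characters carry positions 32,
33, 62, 64, 87, 88 and 92.  These are interpreted as slots in the *base*
matrix's numbering (each new character is placed immediately before that
base column), because this interpretation reproduces every one of the
published old→new renumbering pairs — 74→78, 80→84, 86→90, 90→96,
98→105, 100→107, 102→109 — whereas reading them as final-numbering
positions contradicts 86→90.  The insertion routine returns the full
old→new index map and refuses re-insertion.

**The recoding patch.**  The ten *D. lowii* re-scorings are stored with
their expected previous states and applied atomically: if any cell does
not hold its expected value (already-patched or renumbered matrix), the
whole patch is refused with a per-cell report.  New state `?` means
missing.  The 37-entry ordered list uses final numbering.

The published base matrix is a supplementary file not shipped here;
`synthetic_base_matrix()` is a clearly labelled synthetic stand-in with
the published dimensions (154 × 256), realistic missingness (~30 %),
occasional gaps and polymorphisms, and the fossil's previous codings
pre-set so the guarded patch demonstrably applies exactly once.

## Parsimony

Tree length is the minimum number of state changes.  Unordered
characters use Fitch set operations (exact also with polymorphic and
missing leaves for unit costs); ordered characters use a Sankoff pass
with linear costs `|i − j|` over the observed state range.  Missing and
gap cells are free; polymorphic cells are ambiguity sets costing nothing
at the leaf.  Per character, `m` is the smallest length any tree allows
(unordered: minimum number of states hitting every scored cell, minus
one; ordered: the narrowest state window meeting every cell) and `g` the
star-tree length (best single ancestral state).  `CI = Σm/L`,
`RI = (Σg − L)/(Σg − Σm)`; both are reported as undefined when their
denominators vanish, and a flag excludes parsimony-uninformative
characters from the sums (off by default — the plain formulas).

Exhaustive search enumerates all unrooted binary topologies (guarded at
nine taxa).  The heuristic runs replicates of random-addition greedy
starts followed by TBR branch swapping, accepting strictly shorter
neighbours until a local optimum, then pooling that optimum and its
equal-length TBR neighbours across replicates (deduplicated by
bipartition set).  A backbone constraint — a tree over a taxon subset
whose bipartitions every accepted tree must display, other taxa floating
freely — is enforced by rejecting violating placements and
rearrangements; an addition step with no compatible placement raises an
explicit infeasibility error rather than degrading silently.  Ties are
broken by the replicate's seeded generator, so a fixed seed reproduces
the tree set byte for byte.  Strict consensus intersects bipartition
sets and rebuilds the (possibly multifurcating) tree by clade nesting;
pruning removes named leaves and suppresses degree-2 nodes.

Correctness anchors: equality with a brute-force enumeration of all
internal-node assignments on random ≤ 6-leaf instances (both cost
regimes, with missing and polymorphic cells); agreement with DendroPy's
independent Fitch pass for unordered data; `m ≤ s ≤ g` on random
columns; recovery of a generating tree, at length Σm, from its own
split characters; and ≥ 95 % agreement between heuristic and exhaustive
optima on simulated 8-taxon matrices.

## Problem sizes

The test and acceptance runs use the sizes at which the oracles are
exact and enumeration is feasible: brute-force length checks at ≤ 6
leaves, heuristic-vs-exhaustive benchmarking on 8-taxon matrices
(10,395 topologies each, 50 simulated matrices), the constrained
"full" pipeline demonstration at 12 taxa × 40 characters, and 200
replicates for the distance-decay Monte Carlo.  The assembly stage runs
at the full published shape (154 × 263) throughout.  A search over the
published matrix's 73 active taxa is supported by the same code path
(`heuristic_search` with the backbone constraint) once that matrix is
supplied in NEXUS or TNT form.

## Known limitations

* The fixture inherits every ambiguity of the prose it transcribes (see
  above); it is a fallback for the study's own coding tables, not a
  substitute of equal quality.
* The heuristic's TBR neighbourhood enumeration is exact but not
  engineered for large trees; at many tens of taxa, replicate counts in
  the thousands will be slow in pure Python.
* Branch lengths play no role in scoring (parsimony only); the
  simulator's clock is not intended for likelihood work.
* `segments_similar` treats an unknown depth as compatible with any
  depth; there is no intermediate "penalize unknowns" mode.
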