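# Methods

## Data model

A developmental timeline gives, per species, the ordinal stage at which
each of E events first appears; equal stages mean simultaneity.  Cells
are a positive integer, unknown (`?`) or inapplicable (`-`; limb events
in limbless taxa).  All downstream analyses treat `?` and `-`
identically as full ambiguity when computing tree lengths — the
convention of the standard parsimony toolchain for non-molecular
matrices — but the two markers are preserved through every I/O round
trip.

## Character construction

*Continuous scaling.*  Within a species, recorded events are collapsed
to dense ranks 1..P (ties share a rank) and mapped to (rank−1)/(P−1).
Scaling uses distinct ranks rather than raw stage numbers, so the
encoding is invariant under any strictly monotone relabelling of
stages; unknown events do not shift their neighbours' ranks.  Species
with fewer than two distinct recorded positions have undefined values
(warned, set unknown).

*Decile binning.*  State = ⌊10·v⌋ with v = 1.0 clamped to state 9.  The
interval [0.09, 0.10) is assigned to bin 0 — the simplest rule
consistent with bins described as "0–0.09" and "0.1–0.19".  Binned
characters are flagged orderable; analyses may still treat them
unordered.

*Event pairing.*  One three-state character per pair i<j, oriented by
ascending event index: 0 = i earlier, 1 = simultaneous, 2 = i later.
If either member is unknown the cell is `?`; if either is inapplicable,
`-` (inapplicability dominates when both would apply).

## Parsimony

Unordered lengths use Fitch state sets (bit masks, vectorised across
characters); ordered lengths use Sankoff dynamic programming with
|a−b| costs over the global 0–9 alphabet, which for linear costs equals
the Farris interval method used inside the search.  Polytomous trees
always go through Sankoff (Fitch's two-state-set rule is exact only on
binary trees); the two routes are cross-checked by property test.
Character bounds: mᵢ = distinct observed states − 1 (unordered) or
observed range (ordered); gᵢ = star-tree steps with the best single
root state (frequency rule unordered, median rule ordered).  When
Σsᵢ = 0 the ensemble CI is defined as 1.

*MPR sets and branch changes.*  A down/up Sankoff pass yields, per node
and character, the exact set of states attained in at least one
most-parsimonious reconstruction, restricted to the character's
admissible alphabet.  When the designated outgroup is available and its
state is among the equally parsimonious root states, the root is
conditioned on it (outgroup rooting); this never changes tree length.
A change is recorded on a branch only when the parent and child MPR
sets are disjoint, i.e. every most-parsimonious reconstruction implies
a change there — the conservative intersection of ACCTRAN and DELTRAN
placements.  Counts of most parsimonious trees depend on search
implementation internals and are reported, never asserted.

*Search.*  Per replicate: a seeded random taxon addition order, greedy
Wagner stepwise insertion (ties broken by the first minimal edge in a
deterministic enumeration), then TBR to a local optimum — every
bisection of every edge, reattachment across all edge pairs of the two
fragments, first-improvement restarts — holding up to `hold` equal-best
topologies.  Unique topologies at the global best length are pooled
across replicates (default 10 replicates, hold 10).  An exhaustive
enumerator over all unrooted topologies (≤10 taxa) serves as the oracle.

*Consensus.*  Clade-frequency counting over rooted trees; strict keeps
clades present in all inputs, majority-rule those in >50% (such clades
are pairwise compatible by construction, so the tree assembles by
nesting).

*Topology test.*  Per-character length differences between two trees;
zeros dropped; average ranks for ties; two-tailed p from the exact null
(dynamic programming over doubled ranks, n ≤ 25) or a normal
approximation with continuity and tie correction.  All differences zero
returns p = 1 with a degenerate flag.

## Continuous ancestral reconstruction

Internal values minimise Σ branches (x_parent − x_child)²/ℓ, the
branch-length-weighted squared-change criterion (with unit lengths this
is plain squared-change parsimony).  The minimiser solves the tree's
weighted-Laplacian linear system exactly; the minimised sum is the
character's "mapping score", and both unit-length and calibrated scores
are reported since the criterion is length-weighted whenever lengths
are supplied.  Note the weighting pulls estimates toward
short-branch tips (weight 1/ℓ): two tips with values 0, 1 on branches
1 and 3 give root 0.25.

Root uncertainty comes from independent contrasts: σ̂² is the mean
squared standardised contrast (df = n−1 contrasts; an n−2 convention is
selectable), v_root the root variance from the pruning recursion,
SE = √(σ̂²·v_root), and the CI uses Student t.  Polytomies are combined
pairwise in child order.  A taxon with a recorded value outside the CI
is flagged ("earlier"/"later"); with the reference set to the ancestral
ingroup member, the outgroup is pruned before reconstruction but still
compared against the interval.  Zero-length branches are rejected with
a pointer to calibration or unit lengths.

## Mk maximum likelihood

Per character, a one-rate symmetric Mk model on the observed alphabet
(k states; constant characters are skipped — a global 0–9 space would
create absorbing zero-probability states).  Transition probabilities
use the closed k-state form P_same = 1/k + (k−1)/k·e^{−krt}.  The rate
is fitted by bounded scalar maximisation of the pruning-algorithm
likelihood **in log₁₀(rate) space** over [10⁻⁸, 10²]: the likelihood
basin is typically narrow near zero on the raw scale and golden-section
search can miss it entirely (observed in practice; the log
parameterisation is well conditioned).  Convergence tolerance 1e−10;
fits at a bound are warned.  Marginal node probabilities come from the
standard down/up passes with a flat root prior and are normalised to
sum to 1.  For cracking, a branch change is recorded when the
highest-marginal-probability state sets of parent and child are
disjoint.

## Event-pair cracking

Changes on the branch into a node are converted to signed magnitudes
(child − parent under ordered state semantics; + = first event of the
pair shifts later).  Set-valued endpoints average over consistent
differences (0 → {1,2} gives +1.5); endpoints straddling both
directions (1 → {0,2}) are excluded as direction-ambiguous.  A node is
crackable only if some event participates in ≥2 usable changes.
TRC_e = (Σ contributions of e)/n_e, normalised by the number of changed
pairs involving e at that node (isolated in one function; normalising
by all scorable pairs is a one-line change).  The flagging interval is
the two-tailed 95% Student-t interval of the mean over the
participating events' TRCs; flags use strict inequality; fewer than 3
participating events leave the CI undefined (node reported, no flags).

## Branch lengths from fossils

Calibration rows carry total-group ages, which date the split of a
lineage from its sister; a row therefore resolves to the **parent** of
the MRCA of its tip set (stem semantics; rows resolving to the root
date the root).  Uncalibrated nodes age bottom-up as oldest descendant
age + 3 Ma per intervening branch (the default step), tips at 0;
branch length = parent age − child age, so trees are ultrametric and
calibrated ages are used exactly.  Two safeguards handle internally
inconsistent tables: multiple rows resolving to one node keep the
oldest (warned), and a calibrated node no older than a descendant
raises by default, with an explicit `drop_younger` mode that discards
the younger conflicting row and retries (used for the packaged table on
the morphological topology, where the gekkotan and scincoid ages cannot
be reconciled with that topology's nesting).

## Synthetic data generator

Ancestral order = identity over E events; each branch applies
Poisson(swap_rate × ℓ) random adjacent transpositions, then any
injected shifts (event moved by a signed number of positions, clamped
to the sequence); ties form at tips by independently collapsing each
inter-event boundary at `tie_rate`; missingness knocks out cells
independently and limb events in limbless tips become inapplicable.
Every branch's realised net event displacements are logged for scoring.
Study-shaped defaults: 29 species × 20 events on the molecular
hypothesis, swap rate 0.5 per unit branch, tie rate 0.15, 10% missing —
chosen to resemble real organogenesis tables, which show frequent
simultaneity and patchy observation.  What the generator does *not*
model: absolute developmental time or stage durations, correlated
missingness (real tables lose whole stage ranges, not random cells),
and event-specific rate variation.  Passing tests therefore show the
pipeline recovers clean ordinal signal under neutral noise, not that
real timelines meet these assumptions.

## Recovery benchmark

A fixed 12-taxon tree, 10 events, swap rate 0.5, one injected shift on
an internal three-tip clade, 50 seeds.  The default effect is a gross
shift of 6 positions (the event crosses more than half the sequence);
4- and 5-position shifts are reported as sensitivity points.  With a
4-position shift only ~3–4 changed pairs survive the conservative
ambiguity exclusions and the df ≤ 3 t-interval is intrinsically wide,
so cracking recall falls to ~0.5 while the continuous criterion stays
saturated — a real operating characteristic of the conservative
flagging rule, not an implementation artefact.

## Known limitations

- The packaged 29-tip molecular and morphological topologies are
  assembled from published backbone hypotheses and named clades, not
  reproductions of any single published tree (see `data/README.md`);
  analyses over them demonstrate the pipeline, not published results.
- TBR re-scores each reconnection from scratch; fine to ~30 taxa,
  not tuned for hundreds.
- Cracking normalisation and its CI follow the minimal reading of the
  verbal recipe ("CI for the mean TRCs"); alternative normalisations
  are isolated but not selected by any analysis here.
- The Mk model is symmetric and single-rate per character; ordered or
  asymmetric rate matrices are out of scope.
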