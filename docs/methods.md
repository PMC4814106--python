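# Methods

`culturetree` tests whether a collection of cultural repertoires — in the
motivating application, musical patrimonies, each scored for hundreds of
repertoire, instrument, rhythmic, metric, scale, polyphony, form and vocal
characters — evolved mainly by vertical transmission (descent from ancestral
populations) or by horizontal borrowing between neighbors.  The test has two
independent arms: a cladistic arm (maximum parsimony, homoplasy indices,
Bremer decay) and a distance arm (quartet delta scores and Q-residuals), plus
a simulator that generates matrices with known amounts of borrowing so that
both arms can be validated end to end.

## Character coding

A matrix cell is a *set* of states.  For intrinsic characters (rhythmic
cells, metrics, scales) each state names the repertoire in which the trait
occurs, so `{a,b}` means "present in repertoires a and b".  Absence is coded
`0` and missing data `?`.  Two coding conventions matter downstream:

- **Multi-state cells are ambiguity sets for parsimony.**  A terminal whose
  cell is `{a,b}` can be joined to a terminal scored `{b}` at no cost.  This
  is deliberate: two patrimonies sharing a state in the same repertoire are
  evidence of relatedness, and the alternative codings (full binary
  expansion, or states detached from repertoires) are respectively too
  strict and too permissive.
- **Absence is an ordinary state.**  This is what makes the all-zero
  hypothetical ancestor a coherent rooting device: the root of the tree is
  placed on the branch leading to a fictitious taxon scored `0` everywhere,
  which encodes the assumption that states arise from absence rather than
  the reverse.

`binarize` expands each multi-state character into one presence/absence
column per state; this recoding is used only for the distance arm (split
methods need binary data), never for parsimony.

A character is *parsimony-informative* when at least two of its states are
each carried by at least two taxa (absence counts as a state; missing never
counts).  Ambiguous cells are resolved greedily toward the globally
commonest of their states before counting — a deterministic convention; the
alternative (counting set membership directly) changes the count only for
characters whose ambiguity straddles two rare states.

## Parsimony arm

Characters are unordered and unweighted.  Per-character step counts come
from Fitch state-set optimization with terminal ambiguity sets (missing =
full alphabet), implemented on bitmasks.  For each character three step
counts are kept, following the standard notation:

- `m` — minimum conceivable changes: the smallest number of distinct states
  over all resolutions of ambiguity, minus one (a minimum hitting-set
  computation; exact, since alphabets are small);
- `s` — realized steps on the tree;
- `g` — steps on the completely unresolved star tree: the best single
  ancestral state, every cell not containing it costing one.

Then CI = m/s (1 when s = 0) and RI = (g−s)/(g−m), undefined when g = m
(autapomorphic and constant characters, which is exactly the inflation CI
suffers from and RI corrects).  Ensemble values use the summed m, s, g;
both all-character and informative-only ensembles are reported, since
published ensemble values do not always say which convention their software
used.

**Search.**  Random-addition-sequence stepwise insertion followed by
branch swapping (NNI, SPR or TBR; TBR is implemented as prune + reroot +
regraft and is the fidelity default, SPR the speed default for simulation
studies).  Ties in stepwise addition are broken by the seeded RNG; equally
parsimonious trees are deduplicated by a canonical form of the unrooted
topology and collected up to a cap, with extra "plateau" sweeps that branch-
swap on saved ties to harvest equally parsimonious rearrangements.  Hitting
the cap flags the result (and every downstream support value) as a lower
bound.  An exhaustive enumerator over all (2n−5)!! topologies serves small
problems and is the oracle the heuristic is tested against.

**Consensus.**  Strict and majority-rule consensus are computed by clade
counting over trees rooted via the all-zero ancestor (which is pruned from
reported trees).  The majority rule is strictly-greater-than (a clade in
exactly half the trees is excluded); frequencies are annotated as integer
percents.

**ACCTRAN.**  Ancestral states for a character are assigned by unit-cost
dynamic programming; walking down from the root, ties between keeping the
parent's state and changing are broken in favor of changing.  This places
changes as close to the root as possible, so homoplasy is expressed as a
reversal rather than a parallel gain, and the implied change count always
equals the Fitch step count.

**Bremer decay.**  For each clade of a reference consensus, the support is
the smallest k such that the strict consensus of all trees within k steps
of the optimum lacks the clade.  Tree sets come from exhaustive enumeration
up to 8 taxa and otherwise from the heuristic search run with a retention
slack of k_max; clades surviving at k_max are reported as lower bounds.

## Distance arm

Distances on the binarized matrix are mean character differences with
pairwise deletion of missing data (the proportion of jointly scored columns
that differ).  The distance transform used by the original split-network
software is not documented in our source; mean character difference is the
conventional default for binary data, and because the Q-residual is
normalized by the mean distance the choice mostly cancels there.

For every quartet {i,j,k,l} the three pairing sums d(i,j)+d(k,l),
d(i,k)+d(j,l), d(i,l)+d(j,k) are ordered m1 ≥ m2 ≥ m3:

- delta = (m1−m2)/(m1−m3), defined as 0 when m1 = m3.  Additive (tree-like)
  distances satisfy the four-point condition m1 = m2, so delta is 0 on
  perfectly vertical signal and grows toward 1 under conflict.
- Q-residual = ((m1−m2)/2)² on distances pre-scaled so the mean
  off-diagonal entry is 1.

Quartets are enumerated exhaustively up to a 500 000-quartet budget (the
58-taxon case, C(58,4) ≈ 425 000, is still exhaustive); beyond that a seeded
random sample is used.  Patristic distances from a tree with branch lengths
are provided as the delta = 0 / Q-residual = 0 oracle.

## Transmission simulator

The generator is the package's study design, not a fixture: it emulates the
shape of the motivating dataset and provides complete ground truth.

- **Genealogy**: pure-birth (Yule, rate 1) rooted binary tree.  Lineages
  still open at the n-th speciation receive one final exponential hanging
  time so every branch length is positive.
- **Vertical phase**: every character starts absent at the root and accrues
  Poisson(mu x branch length) state changes.  Under the infinite-allele
  model each innovation mints a previously unused state — homoplasy is
  impossible by construction, so parsimony must score CI = RI = 1 and the
  true genealogy is always among the most parsimonious trees.  Under the
  finite-allele model states are redrawn uniformly from a bounded alphabet
  (absence included), allowing convergence and reversal.  Missing cells are
  injected at the leaf-scoring step, mimicking unscored fieldwork.
- **Horizontal phase**: a single contact epoch after the vertical phase.
  Each (taxon, character) cell is independently replaced with probability h
  by the corresponding cell of a donor drawn from the pre-contact matrix,
  either uniformly or weighted toward phylogenetically close taxa
  (weights ∝ 1/patristic distance).  Continuous-in-time borrowing would be
  the natural extension; a single epoch already spans the vertical-to-
  horizontal contrast the statistics must detect.

Defaults: 58 taxa, 322 characters split across categories in the published
proportions 161/63/64/14/13/3/2/2, mu = 0.3 per unit branch length,
finite alphabet of 8 states for all categories except repertoire (which is
infinite-allele: new repertoires are de novo namings), missing fraction
0.02.  These were chosen once as a realistic regime — multi-state cells,
a few percent missing data, roughly half to two-thirds of characters
informative — and are not fitted to any test outcome.

What the simulator does *not* emulate: geographic structure, population
sizes, repertoire-level correlation between characters (characters evolve
independently), polymorphic (multi-state) cells at the leaves, and
time-extended contact.  Passing simulation tests therefore shows that the
statistics respond correctly to the vertical/horizontal mixing rate under
independent-character evolution, not that they are robust to correlated
borrowing of whole repertoires.

A practical consequence of finite-allele homoplasy worth noting: even at
h = 0 the generating tree is occasionally *not* most parsimonious (homoplasy
can make a slightly different topology shorter), so exact-recovery
experiments are run under the infinite-allele model, where recovery is a
theorem rather than a tendency; the finite-allele regime is instead used
for the retention-index threshold and degradation studies.

## Simulation studies wired into the test suite

- **RI threshold**: 20 replicates (20 taxa, 150 finite-allele characters,
  mu = 0.3, h = 0, seeds 1–20) give a median ensemble RI well above 0.60,
  the level treated in the comparative-culture literature as indicating
  predominantly vertical transmission.  `scripts/acceptance.py` recomputes
  exactly this number.
- **Degradation**: mean RI decreases and the Robinson-Foulds distance of
  the inferred trees to the truth increases monotonically through
  h ∈ {0, 0.25, 0.5}.
- **Recovery**: under infinite alleles and h = 0 the true genealogy is
  recovered exactly (RF = 0) in ≥95% of replicates.

Problem sizes in the suite (20 taxa, 100–200 characters, 2 addition
sequences with SPR swapping, tree caps of a few hundred) were chosen as the
smallest at which these effects are unambiguous; the heuristic-vs-exhaustive
oracle tests justify trusting the downscaled search.

## Numerical and degenerate-case conventions

- CI of a constant character (s = 0) is 1 by convention; characters with
  g = m are excluded from every RI average.
- delta of an equidistant quartet (m1 = m3) is 0.
- All-missing characters score m = 0 with a warning.
- A taxon pair with no jointly scored binary columns is an error, not a
  silent NaN.
- Every stochastic component (search tie-breaks, quartet sampling, all
  simulator draws) consumes an explicit seed; reruns are byte-identical.
- State alphabets are capped at 64 states per character by the bitmask
  encoding (the data model's 2–22 plus the absence state fits comfortably).

## Known limitations

- TBR on large matrices is O(n³) tree evaluations per sweep in a pure-
  Python implementation; the 58-taxon published matrix is tractable but
  takes minutes-to-hours at the published search effort (1000 addition
  sequences), which is why the simulation studies default to SPR.
- The number of equally parsimonious trees is cap- and search-effort-
  dependent and is not a reproducible quantity; supports computed from a
  capped tree set are flagged as lower bounds.
- NEXUS serialization requires single-character state symbols; matrices
  whose infinite-allele runs minted more than 26 states per character
  round-trip through CSV instead.
- The greedy informativeness convention and the distance transform are
  package choices where the original analyses leave the convention
  unstated; both are isolated behind single functions.
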