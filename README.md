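# culturetree

Phylogenetic tooling for testing **vertical versus horizontal transmission of
cultural repertoires** — built for multi-state cultural character matrices
such as collections of musical patrimonies scored for repertoires,
instruments, rhythmic cells, metrics, scales, polyphonic processes, vocal
forms and vocal techniques.

The question the package answers: when dozens of populations share hundreds
of cultural traits, is the sharing structured like descent down a genealogy
(vertical transmission), or like borrowing between neighbors (horizontal
transmission)?  Two independent statistical arms address it:

- **Cladistic arm.**  Maximum parsimony over unordered multi-state
  characters (Fitch optimization, with multi-state cells treated as
  ambiguity sets and absence `0` as an ordinary state), rooted on an
  all-zero hypothetical ancestor.  Per-character homoplasy is profiled with
  the consistency index **CI = M/S** and retention index
  **RI = (G−S)/(G−M)**, where M is the minimum conceivable number of
  changes, S the realized steps on the tree, and G the steps on a star
  tree.  High ensemble CI/RI (RI ≳ 0.60 in the comparative-culture
  literature) indicates predominantly vertical transmission.  Branch
  robustness uses Bremer decay supports (the extra tree length at which a
  clade collapses out of the strict consensus of near-optimal trees), a
  non-resampling method that preserves the internal structure of the data.
- **Distance arm.**  Quartet treeness statistics on the binarized matrix:
  the **delta score** (m1−m2)/(m1−m3) over the ordered pairing sums of each
  quartet, and the **Q-residual** ((m1−m2)/2)² on mean-normalized
  distances.  Both are 0 for perfectly tree-like (additive) distances and
  grow under reticulate, borrowing-driven signal.

A third component, the **transmission simulator**, generates matrices under
a Yule genealogy with Poisson innovation and a tunable horizontal borrowing
rate h, with full ground truth (genealogy + event log), so every statistic
can be validated against data whose mixing rate is known.

## Worked example

Simulate a purely vertical dataset (12 taxa, 120 characters in the standard
category proportions), then run the full analysis:

```
culturetree simulate --n-taxa 12 --n-characters 120 --h 0.0 --seed 42 \
    --out patrimonies.csv --categories patrimonies.categories
culturetree run --config analysis.yaml
```

with `analysis.yaml`:

```yaml
matrix: patrimonies.csv
categories: patrimonies.categories
outdir: analysis
seed: 42
n_addition_sequences: 4
swap: spr
bremer_kmax: 3
```

This prints:

```
culturetree analysis report
===========================
tree length          : 358
most-parsimonious trees kept : 1
ensemble CI / RI     : 0.955 / 0.944
  informative only   : 0.952 / 0.944
informative characters : 101
treeness             : delta = 0.080, Q-residual = 0.0003 (495 quartets)

CI distribution by category (informative characters, bins of 0.1)
category               n    mean_ci  0.0 0.1 0.2 0.3 0.4 0.5 0.6 0.7 0.8 0.9
instrument             21   0.902      0   0   0   0   0   2   3   0   0  16
metric                 4    0.938      0   0   0   0   0   0   0   1   0   3
repertoire             55   1.000      0   0   0   0   0   0   0   0   0  55
rhythmic_cell          15   0.904      0   0   0   0   0   0   2   0   4   9
scale                  5    1.000      0   0   0   0   0   0   0   0   0   5
vocal_form             1    0.750      0   0   0   0   0   0   0   1   0   0
vocal_technique        1    0.667      0   0   0   0   0   0   1   0   0   0

Bremer supports (clade size, decay):
  |  9| >= 3
  |  7| >= 3
  |  5| = 3
  ...
```

How to read it: the single most-parsimonious tree needs 358 steps; ensemble
CI 0.955 / RI 0.944 mean almost no homoplasy, and the delta score of 0.08
with a Q-residual of 0.0003 means the distances are nearly perfectly
tree-like — exactly what purely vertical transmission should produce (this
dataset was simulated with borrowing rate h = 0; rerunning with `--h 0.5`
collapses the RI and inflates delta).  The per-category table shows which
kinds of characters carry the hierarchical signal, and the Bremer column
gives, per clade, how many extra steps are needed before the clade is lost
(`>= 3` means it survived the deepest relaxation explored).

All intermediates (most-parsimonious trees, consensus newicks, per-character
fit table, treeness table, search log) are plain files in `analysis/`, and a
rerun with the same seed is byte-identical.

The same pipeline runs on real data: `culturetree convert` reads the
XLSX/CSV matrix dialect (cells `0`, `?`, `a`, `{a,b}`) and NEXUS with
per-category CHARSETs, and `PipelineConfig.categories` accepts a sidecar
category map for matrices whose format carries no category block.

## Library surface

```python
from culturetree import (
    read_matrix, binarize, informative_mask,      # character matrices
    add_zero_ancestor, heuristic_search,          # parsimony search
    ensemble_fit, bremer_supports,                # homoplasy + supports
    mean_character_distance, treeness_report,     # delta / Q-residual
    SimParams, simulate,                          # transmission simulator
)
```

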