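# Methods

## The model

`cmkg` treats drug prioritization as two coupled problems over a typed,
gene-bridged knowledge graph: *which* candidates associate with a disease
(link prediction in embedding space) and *why* (explicit mechanistic paths
scored by a unified semantic score). The graph is a deduplicated triple
store (head, relation, tail) over a closed vocabulary of fifteen entity
types; genes act as the bridge between the traditional-medicine side
(herb, ingredient, TCM symptom, syndrome) and the modern-medicine side
(compound, disease, modern symptom, anatomy, pathway, GO terms).

### Relation fusion

Sources describe overlapping semantics under different relation names. Two
relations with intersecting (head-type, tail-type) signatures are compared
by the (head, tail) pair sets they cover: merge when Jaccard ≥ `j_hi`
(default 0.8), or when Jaccard ≤ `j_lo` (0.2) while Overlap ≥ `o_hi`
(0.6) — the case of a small relation nested inside a large one. The larger
relation survives, ties broken lexicographically (the survivor rule is a
package choice; only one worked merge direction is fixed by convention).
Merging is a union-find over pairwise decisions, so chains of merges
resolve consistently or fail loudly.

### Embedding-based link prediction

Four scoring functions are implemented exactly as usually defined: TransE
f = −‖h + r − t‖ (L2 by default, L1 selectable), DistMult f = Σ hᵢrᵢtᵢ,
ComplEx f = Re⟨h, r, t̄⟩, RotatE f = −‖h ∘ r − t‖ with unit-modulus
relation coordinates. DistMult is computed with the product grouped as
(h·t)·r so that its defining symmetry f(h,r,t) = f(t,r,h) holds *bitwise*,
not merely approximately. RotatE relations are stored as phase vectors, so
the |rᵢ| = 1 constraint holds by parametrisation; phases are re-wrapped to
(−π, π] after every update.

Training minimises the pairwise margin ranking loss
mean over pairs of max(0, γ − f(pos) + f(neg)) with uniform corruption of
head or tail (negatives are not filtered during training, which is
standard; filtering applies only to evaluation). Optimisation is plain SGD
with analytic gradients and L2 weight decay (default 1e-9); embeddings are
initialised uniformly in [−6/√d, 6/√d] per channel, RotatE phases
uniformly in [−π, π]. The margin defaults to γ = 6 and is configurable;
the reference protocol's published settings (d = 400, batch 1024,
200 negatives per positive) are kept as the documented defaults, while
tests and the acceptance script run desk-scale settings (d = 32,
batch 128, 16 negatives, 60–200 epochs) chosen so the whole suite runs in
about a minute on one CPU. Learning rates are per-model (1.0 for the
product models, 2.0 for RotatE), mirroring the common practice of tuning
the step size per scoring geometry; with a shared rate the distance models
converge far more slowly than the bilinear ones.

Evaluation follows the filtered protocol: for each test triple the true
head (and tail) is ranked against all entities after removing candidates
that form *other* known-true triples anywhere in the store. Ranks use the
average tie policy — a model that scores many candidates identically is
credited with the mean rank of the tied block, not the optimistic minimum.
This matters for DistMult, whose symmetry produces systematic ties.

### Candidate ranking

A disease's bridge set is every gene adjacent to it in either direction.
Each candidate herb or compound receives the score grid
f(candidate, r, gene) over the bridge genes and a fixed set of drug-gene
meta-path relations (gene-headed relations place the candidate in the tail
slot). The grid is collapsed to a scalar as the mean of its top-m cells
(default m = 5): how a practitioner should collapse a 709-gene × 6-relation
grid is genuinely open, and the top-m mean rewards multi-target support
while resisting single-cell outliers; plain mean and max are available,
and m = ∞ reduces to the plain mean. Known triples can optionally be
masked out (`exclude_known`).

### Horn rules

Chain rules head(X,Y) ⇐ b₁(X,A₁), …, b_L(A_{L−1},Y) are mined by the
random-path-sampling recipe: draw a known-true triple, probe for a random
simple path of a sampled length (≤ 4) between its endpoints over forward
and inverse edges, generalise the path to a variable chain, then compute
support and body count *exactly* by brute-force grounding — confidence is
support / body-count in integer arithmetic, with body count defined over
distinct (X, Y) endpoint pairs. The mining budget is expressed in samples
rather than wall-clock seconds so runs are reproducible; inverse-direction
atoms carry a `^-1` relation suffix in the rule dialect. Only chain-shaped
rules with both endpoints variable are mined or grounded; constant-bound
rules parse but are ignored with a count. Grounding a rule between a
source and target enumerates every body instantiation as a relational
join; groundings are not required to be simple paths (a join may revisit a
node), matching rule semantics rather than search semantics.

### Unified path scoring

Every explanation path P = (e₀, r₁, e₁, …, r_L, e_L) scores

    Score(P) = BaseScore × Decay(L) × C_effective × Bonus.

*BaseScore* is the geometric mean (∏_{i=1..L} w_{rᵢ} · w_{eᵢ})^{1/L}; the
head entity e₀ is excluded, as the index range of the product dictates.
Relation weights: 1.0 for gene-gene edges in the evidence set
(`experiments`, `experiments_transferred`), 0.9 for other gene-gene edges,
0.7 baseline otherwise. Entity weights: 1.0 for mechanism types (Herb,
Ingredient, Gene, Compound), 0.7 otherwise. Ingredient weights are scaled
by the **ISI** factor max(floor, ln(N/(df+1))/ln N) with floor 0.01 — an
inverse-document-frequency transplant that sends an ingredient found in
nearly every herb (df = N−1) to the floor and leaves a unique ingredient
(df = 0) untouched. The formula is applied to the ingredient's mechanism
weight 1.0; the alternative reading (scaling the 0.7 baseline instead) is
one argument away in `isi_weight`.

*Decay* is 1.0 for L ≤ 2 and 0.9^{L−2} for 2 < L ≤ 4; paths longer than
four hops are never enumerated. *C_effective* puts both path origins on one
confidence scale: min(1, C_rule) for rule groundings, min(1, BaseScore ·
λ_DFS) for search paths, with λ_DFS = 0.2 by default — without the factor,
search paths (whose geometric means are systematically higher than rule
confidences) drown out the rules. *Bonus* has two tiers: a structural tier
(1.2) for paths containing a gene or a *specific* ingredient (ISI factor at
least 0.5 of its pre-ISI weight), and an evidence tier (1.5) for paths
using an evidence relation or the herb-composition relation `includes`;
tiers multiply and cap at 1.8. How multiple triggers combine within the
published [1.2, 1.8] band is not fixed by the band itself; the two-tier
product with a cap is this package's choice and every tier is configurable.

DFS enumeration yields all simple paths up to four hops, traversing edges
head-to-tail, plus tail-to-head for relations declared symmetric
(gene-gene interaction relations by default — without inverse traversal,
most gene-chain paths are unreachable because interaction edges are stored
in one canonical direction). Hybrid ranking deduplicates identical
node/relation sequences keeping rule provenance, sorts by score, breaks
ties toward shorter paths then lexicographic node ids, and reports a
four-component breakdown per path (rounded to 4 decimals for display, full
precision internally).

### Sensitivity and ablation harnesses

The λ sweep re-ranks a fixed hybrid pool over a grid (default
{0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0}) and reports the rule share and mean
score of the top-k list; the rule share is provably non-increasing in λ.
Robustness re-ranks a drug panel under named configuration variants
(weights flattened to 1.0 or sharpened to 0.2; decay off or 0.5; bonus off
or cap 5.0; ISI floor 1.0 = ISI off) and reports mean IoU of top-k lists
against the baseline, plus three ablation metrics: average ISI over
ingredient node occurrences (0 when no path carries an ingredient — paths
without ingredients simply do not contribute), evidence ratio over *edges*
(not paths), and rule contribution. Drugs with no path to the target are
skipped and counted.

## Synthetic data: what it does and does not emulate

The generator reproduces the schema's shape, not its scale: tens of herbs,
ingredients, compounds, genes and diseases instead of hundreds of
thousands; herb→ingredient composition edges with *exact*, controllable
document frequencies (a configurable fraction of ingredients is planted as
near-ubiquitous, df = N−1, the rest rare with df ≤ 3); a gene-gene
interaction layer of which ~30% carries evidence labels; gene-disease,
compound-gene and symptom layers; planted mechanistic chains of 2–4 hops;
and planted Horn rules whose support/body-count pairs are constructed
exactly (each grounding uses a dedicated bridge gene, and the rule
relations come from a reserved name pool that noise generation never
touches). Passing tests therefore demonstrate the *machinery* — exact
statistics, closure of mining and search over planted structure,
qualitative orderings — not real-data recall: the generator has no degree
heterogeneity, no name noise requiring fuzzy alignment, and no correlated
multi-source redundancy.

The antisymmetric benchmark graph (cyclic offsets: relation `plus_k` links
i to i+k mod n) is the cleanest construction on which symmetric scorers
provably cannot rank directionally: every relation is an antisymmetric
bijection exactly representable by rotations, so ComplEx and RotatE
separate sharply from DistMult under filtered Hits@10 while the
construction stays deterministic.

## Numerical choices and degenerate inputs

- Jaccard of two empty sets, Overlap with an empty side, IoU of two empty
  lists, rule ratio of an empty list: undefined-input errors, not 0.
- ISI requires N ≥ 2 herbs (ln N > 0); df of an unseen ingredient is 0.
- TransE/RotatE norms add 1e-12 inside the root to keep gradients finite
  at exact zeros; scores themselves are exact for the published examples.
- Percentages are rounded to two decimals for source-contribution tables
  and one decimal for shared-target statistics, matching the conventions
  of the published tables they mirror.
- Determinism: every stochastic routine takes a seed and uses an isolated
  `numpy` generator; training twice with one config yields identical loss
  traces, and the synthesizer yields byte-identical fixtures per seed.

## Known limitations

- Full-scale benchmark numbers (MRR/Hits on a 7-million-triple graph) are
  out of reach at desk scale by design; the embedding claims verified here
  are qualitative orderings and protocol properties.
- The miner's sample budget trades completeness for time; rare rules with
  few support triples need proportionally more samples to be drawn.
- Candidate ranking scores every candidate against every bridge gene
  densely; at hundreds of thousands of candidates this loop would need
  batching over the candidate axis.
- Entity alignment is exact-normalized-name only; no synonym dictionaries
  or embedding-based matching.
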