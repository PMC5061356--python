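# Methods

## Scope and model

The package operationalises the CBC species criterion on ITS1/ITS2 secondary
structure. Its inputs are (a) an aligned set of ITS sequences over
{A,C,G,U,N,-}; (b) one curated secondary-structure template per region in
Vienna dot-bracket notation, anchored to one alignment row; and (c)
optionally a rooted tree whose tips match the alignment. The analysis makes
three structural assumptions: the template structure is pseudoknot-free;
homology of paired sites across taxa follows from the alignment columns that
hold the template's residues; and the ITS fold is organised as stem-loop
arms ("helices", numbered I, II, … 5'→3') emanating from one exterior loop,
with internal loops, bulges and multiway junctions contained *inside* a
named helix. A helix's `n_nt` is its full span, end − start + 1, hairpin
loop included; this convention is a deliberate choice where either reading
(span vs. paired nucleotides only) would be defensible, and it is what the
reference models are built to.

Coordinates are 1-based and inclusive in every interface and file. DNA input
is normalised to RNA (T→U, logged once per file); `-` is the only gap
character and `.` is rejected in alignments because it is reserved for
dot-bracket strings.

## Substitution taxonomy

Pair states: canonical = {AU, UA, GC, CG}; wobble = {GU, UG}; incomplete =
any state containing `-` or N; noncanonical otherwise. Transitions between
two distinct gap-free states are classified symmetrically:

| condition | category |
|---|---|
| both states canonical (two distinct canonical pairs always differ on both strands) | CBC |
| exactly one noncanonical, the other canonical or wobble | nonCBC |
| canonical ↔ wobble with exactly one strand changed | hCBC |
| canonical ↔ wobble with both strands changed; wobble ↔ wobble; noncanonical ↔ noncanonical | other_paired (subtype-tagged) |

`other_paired` exists because the three-way CBC/hCBC/nonCBC taxonomy does
not cover every changed pair state; collapsing those cases into one of the
three would silently redefine them. Classification is unordered: the
polarity of a change (which state is ancestral) requires a rooted tree and
is assigned only by the tree-mapping step, from the state reconstructed at
the parent node. Any state containing a gap yields an `indel` event, never a
substitution category, so missing data cannot manufacture CBCs; sites where
any taxon shows N are excluded from classification and reported.

At a site showing *s* distinct complete states, one event is emitted per
unordered state pair — s(s−1)/2 events — each carrying the taxon sets on its
two sides. When more than two states co-occur this counts an hCBC once per
state pair rather than once per site; the alternative (per-site counting) is
not distinguishable from published totals in the two-state situations that
dominate real data, and the per-pair rule keeps the event ↔ state-pair
correspondence exact.

The pairwise CBC matrix sums CBC events over all paired sites of all
regions. CBC clades are **maximal cliques** of the zero-CBC graph, not
connected components: a clique guarantees "no CBC between any pair of
members" for every pair. With a single CBC site the two notions coincide;
when the zero-CBC relation is not transitive, the overlapping cliques are
returned with a warning instead of being merged.

## Subclades

Within each CBC clade, taxa are grouped by their profile over all paired
sites carrying hCBC / nonCBC / other_paired / indel events; two taxa fall in
the same subclade iff their states agree at every such site. Unpaired-column
variation (`single` events) never splits a subclade — loop sequence
variation is recorded but treated as below the structural signal. Structural
deletions enter the profile through their paired-site indel states. Each
subclade is reported with the events diagnostic for it (events whose taxon
side, restricted to the clade, is exactly the subclade); a residual group
may have none. Subclades are numbered I, II, … following tree tip order when
a tree is given, sorted taxon ids otherwise.

## Tree mapping

Each paired site defines a character whose alphabet is the set of observed
gap-free pair states; taxa with incomplete states are treated as missing
data. The character is optimised on the rooted input tree by uniform-cost
Sankoff dynamic programming (identical change counts to Fitch parsimony). A
canonical most-parsimonious reconstruction is reported — root state chosen
by minimum cost then lexicographic order, children following the parent's
state whenever cost-optimal — so that per site the number of change edges
equals the parsimony length. For every edge the implementation also computes
the minimum tree length with and without a change forced on that edge;
placements achievable but not forced are flagged `ambiguous`, and edges that
carry the change only in alternative reconstructions are listed per site. No
ACCTRAN/DELTRAN resolution is imposed.

Monophyly of a taxon set on the rooted tree: monophyletic iff it equals some
node's tip set; paraphyletic iff it equals a node's tip set minus the tip
set of one node nested inside it; polyphyletic otherwise.

## Consensus folding

`consensus_fold` is a covariation-scored Nussinov dynamic programme, a
deliberately simple consensus folder: column pair (i, j) is allowed if the
fraction of rows forming canonical or wobble pairs is ≥ `pair_threshold`
(default 0.5; rows with gaps count against the fraction), and scores
fraction + `covariation_bonus` × (number of distinct compatible pair types −
1) (default bonus 1.0). The DP maximises the score sum over pseudoknot-free
structures with a minimum hairpin loop of 3 nt. Ties are broken
deterministically toward the structure whose 5'-most differing position is
paired, with the smaller partner preferred — implemented as a greedy
interval traceback and specified precisely so an exhaustive enumeration
reproduces the same structure. The folder models conservation and
compensatory covariation only, not thermodynamics or an explicit
evolutionary model; supplying a curated dot-bracket template remains the
recommended path for publication analyses, and the pipeline treats the two
sources identically.

## Deletion detection

A template pair is *lost* in a taxon when at least one of its two projected
columns is a gap in that taxon's row; losses are grouped and counted per
helix. The definition is deliberately one-sided-sensitive: a single gapped
strand already breaks the pair.

## Simulator

The generator emulates the statistical structure of a small ITS dataset from
a closely related species complex: a rooted tree (balanced, caterpillar, or
random Yule-like, or an explicit newick), one structured template per region
(all template pairs canonical) joined by an unpaired spacer, and planted
events applied on single edges — each target taxon set must be the tip set
of one tree node, so every planted event has parsimony length 1 and clean
polarity. Derived states are constructed per category (CBC: another
canonical pair, both strands changed; hCBC: the unique one-sided
canonical→wobble neighbour; nonCBC: a one-sided change to a noncanonical
state). A deletion gaps the top `n_pairs` pairs of a named helix — walking
outward from its 3'-most hairpin — plus the hairpin loop, in the target
clade. Background substitutions are confined to unpaired sites so planted
paired-site counts stay exact; the truth log records every change and can
replay the alignment from the template, and a fixed seed makes all outputs
byte-identical.

The study-scale preset (`study_scale_config`) is a 19-taxon configuration:
one ITS2 CBC at pair 9 of helix II separating a 4-taxon clade from the
remaining 15; three ITS1 hCBCs (two on helix III — one private to a 3-taxon
group, one to a singleton — and one on helix IV), two ITS1 non-CBCs
(helices II, IV) and two ITS2 hCBCs (helix III) shared by a 13-taxon clade;
and a 6-pair helix III deletion confined to an 8-taxon lineage. The tree
places the larger CBC clade paraphyletically. Background loop substitution
probability is 0.02 per site per taxon — enough to produce the loop
"sequence variation" real ITS data show without touching any paired site.
Region templates are the synthetic reference models below.

### Synthetic reference models

`refmodels.py` provides synthetic stand-ins for curated ITS 2D models (no
real sequence data ship with the package): ITS1 (143 nt) with five
exterior-loop helices, helix III the longest (55 nt) with a three-way
junction whose right subhelix carries the deletable 6-pair upper stem; ITS2
(171 nt) with the eukaryote common-core geometry — four main helices plus a
short fifth near the 3' end, helix II spanning exactly 32 nt and helix III
67 nt. Sequences are generated deterministically with all pairs canonical.

## What the synthetic data do and do not show

Passing the recovery tests demonstrates that classification, clique
delimitation, subclade profiling, parsimony mapping and deletion detection
are exact on data whose ground truth is known and whose events sit on single
edges without homoplasy, alignment error, or rate variation. Real ITS data
add risks the simulator deliberately omits: alignment ambiguity around
indels, homoplasy (which the ambiguity flags surface but cannot remove),
template misfit when the 2D model is wrong, and base composition /
length variation between taxa. Results on real data therefore inherit the
quality of the curated alignment and template.

## Numerical and implementation choices

* Minimum hairpin loop: 3 nt, enforced at parse time and in the folder.
* Site-pattern counting treats the gap as a fifth character state and
  applies no ambiguity collapsing; tools that collapse undetermined columns
  can report slightly different counts on the same alignment.
* Event tables order the two states of an unordered event lexicographically;
  all outputs are deterministic for fixed inputs (reports carry an input
  hash in their provenance block).
* Simulation problem sizes used in the shipped tests and the acceptance
  script (19 taxa × ~330 columns, ~100 randomized 4–8-taxon configurations,
  folding oracles at sequence length ≤ 12, parsimony oracles at ≤ 6 tips)
  were chosen so exhaustive oracles stay exact and the whole suite runs in
  seconds.

## Known limitations

* No pseudoknots, suboptimal ensembles, or free-energy model in the folder.
* The zero-CBC clique definition can return overlapping clades on
  non-transitive data; downstream interpretation is then up to the user.
* The ~0.76 conspecificity probability is a literature constant echoed in
  summaries, not an estimate this package can produce.
* Tree inference, support values, and alignment construction are inputs,
  never outputs.
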