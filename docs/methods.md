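# Methods

`qsevo` reconstructs how enzyme quaternary structure (QS) evolves: it calls
protein–protein interfaces from buried solvent-accessible surface area,
groups homologous interfaces across orthologs, maps discrete QS states onto
phylogenies, reconstructs ancestral states, and summarises the dynamics with
ratchet statistics. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## Solvent-accessible surface area

SASA is computed with a Shrake–Rupley quadrature. Each atom is inflated by
the probe radius (default 1.4 Å, water) and sampled with a deterministic
golden-section spiral of `n_points` directions (default 960); a direction is
buried if the sample point lies inside any neighbouring inflated atom.
Per-atom area is `accessible/n_points × 4π(r+probe)²`; residue areas are
sums over atoms. Design choices:

* **Radii.** A NACCESS/Chothia-style element table (C 1.87, N 1.65, O 1.40,
  S 1.85 Å; fallback 1.80), configurable per call. Hydrogens and waters are
  excluded; hetero records are excluded unless ligands are requested.
* **Determinism.** The spiral point set involves no random numbers, so SASA
  is bit-reproducible. Rotating a structure changes areas only through
  quadrature noise (measured < 0.2% on toy complexes; single-sphere error
  < 0.1% at 960 points).
* **Degenerate input.** Atoms with exactly coincident centres are treated as
  mutually occluding (both report zero area) with a warning; this keeps the
  handling symmetric and deterministic.
* **Altlocs.** Only the highest-occupancy conformer is kept at parse time.

Relative solvent accessibility (RSA) divides residue SASA by the Miller et
al. tripeptide reference areas (shipped as a CSV fixture). RSA above 1
(extended termini) is not clipped. Pseudo-atom synthetic structures use the
isolated-sphere area as their reference instead, since Miller values assume
full side chains.

## Interface calling and interface descriptors

A residue is **interface** when assembly buries more than 10% of its
isolated-subunit SASA *and* its subunit RSA exceeds 20%; non-interface
residues with RSA above 20% are **surface**; the remainder is **core**.
Both inequalities are strict, matching the "larger than"/"higher than"
wording of the thresholds; residues with zero subunit SASA cannot satisfy
the relative-burial rule and fall to core. Both thresholds are config
parameters (`delta_frac`, `rsa_min`).

Per-complex quantities use totals, not the per-residue called set:

* interface area = (Σ subunit SASA − complex SASA) / n_subunits (Å²);
* relative buried surface = (Σ subunit SASA − complex SASA) / Σ subunit SASA.

Hydrophobicity of a region is the fraction of C, F, I, L, M, V, W residues.
Where a per-chain region is needed (hydrophobicity, interface overlap) the
first subunit is used by default, configurable. Molecular weight sums
water-subtracted residue masses over the sequence (minus signal/transit
ranges) times the subunit count.

## Structural comparison

Orthogroup members are homologous, so residue correspondence comes from a
global affine-gap sequence alignment (BLOSUM62, gap open 11, extend 1);
an externally computed correspondence (e.g. from a structural aligner) can
be injected for exact parity with other tools. Superposition alternates a
least-squares rigid fit (SVD Kabsch, reflections excluded) with rejection
of pairs beyond 5 Å. Rejection is monotone — a rejected pair never
re-enters — so the retained set shrinks, the retained-pair RMSD does not
increase, and the loop terminates. TM-score is computed over *all*
corresponded pairs with `d0 = 1.24(L−15)^⅓ − 1.8` (floored at 0.5 Å),
normalised by the smaller chain length, which makes the score symmetric.
Exact parity with TM-align is not claimed; the downstream quantities
(aligned pairs, smaller-structure normalisation) are preserved.

## Interface homology and QS states

Interface overlap between two complexes is the number of corresponded
residue pairs that are interface on both sides, divided by the smaller
interface; it is symmetric by construction, undefined (and excluded from
averages, not imputed as zero) when either interface is empty. Homology
groups are connected components of the graph with an edge at overlap ≥ 0.5.

QS states are binary (monomer vs homomer) or multi-state: the pair
(subunit count, homology group), so equal stoichiometry with independent
interfaces yields distinct states, and "similar number of subunits" is read
strictly as equality. All monomers share one state. Homomers with interface
area below 1000 Å² are reclassified as monomers (probable crystallographic
interfaces); the threshold is a config parameter, and the synthetic bundle
scales it to 50 Å² because pseudo-atom toy dimers bury ~30–160 Å² per
subunit — the threshold sits below typical genuine toy interfaces just as
1000 Å² sits below typical genuine ones.

## Ancestral reconstruction

States evolve under the equal-rates (ER) continuous-time Markov model with
closed-form transition probabilities
`P(stay,t) = 1/k + (1−1/k)e^{−kqt}`, `P(switch,t) = (1 − e^{−kqt})/k`.
The likelihood uses Felsenstein pruning with per-node rescaling and a flat
root prior 1/k; missing tips contribute all-ones partials. The single rate
is fitted on [1e-8, 100] by a coarse log-grid scan followed by bounded
Brent refinement (xatol 1e-8); with fewer than two observed states the
likelihood is monotone decreasing in q and the rate pins to the lower
bound. Marginal posteriors combine downward partials with upward messages
(the ER matrix is symmetric, which simplifies the outside recursion); both
match exhaustive enumeration over internal-node assignments to < 1e-8 on
all 3–5-leaf topologies.

Maximum parsimony uses a unit-cost Sankoff pass (valid for
multifurcations), giving the exact minimum change count. Ambiguity is
resolved in preorder: among equal-cost candidate states, a change on the
current edge is preferred (accelerated transformation — the change is
placed as close to the root as possible), then the lowest state index;
root ties take the lowest index. The minimum score is invariant to these
tie-breaks.

Trees are midpoint-rooted when no rooted input is supplied: the input is
treated as unrooted (a leftover degree-2 junction is contracted), the
longest leaf-to-leaf path is found exactly, and the root is placed at its
midpoint — on a node when the midpoint coincides with one. Midpoint
rooting stands in for model-based rooting methods; downstream statistics
require only a rooted topology, and externally rooted Newick trees are
accepted as-is.

Only trees whose most likely root state reaches 51% posterior probability
are kept ("at least", so exactly 0.51 passes). Internal nodes are
"determined" when their maximal marginal strictly exceeds 0.5 and is
unique — the same convention extended from the root rule; the threshold is
configurable and this extension is this package's documented choice.

## Ratchet statistics

Change frequency = (determined parent–child pairs with different states) /
(determined pairs); edges with an undetermined endpoint leave the
denominator. Gains and losses compare subunit counts along determined
edges; a homology-group switch at constant stoichiometry is a change but
neither a gain nor a loss, and a multi-step jump (monomer → tetramer on
one edge) is one event, since node pairs, not subunits, are counted.
Trees with a single observed state are retained with change frequency 0.
Per-orthogroup summaries add mean root-to-leaf distance, mean pairwise
leaf distance, the extracellular fraction (requiring ≥ 5 leaves with known
location), the modal extracellular QS (ties → missing), and its agreement
with the root state.

## Annotation scores

* **Conservation.** Normalised per-residue conservation scores (lower =
  more conserved, the ConSurf convention; the sign is configurable) are
  compared between interface and surface by difference of means with a
  two-sided Wilcoxon rank-sum test; the "significantly more conserved
  interface" flag requires both the conserved direction and p < α (0.05).
  The choice of test is this package's assumption, consistent with the
  rank-sum tests used throughout the analysis; each region needs ≥ 3
  residues.
* **Synthesis cost.** Mean high-energy phosphate bonds per residue, from a
  fixture of per-amino-acid costs in whole phosphate bonds spanning 11
  (Ala/Gly/Ser) to 74 (Trp); the anchors are asserted at load time.
* **Scaled abundance.** Abundance (ppm) divided by subunit count
  approximates particle concentration; a homomer of unknown stoichiometry
  is assumed dimeric when the flag is set.

## Synthetic data

The generators produce every pipeline input with known ground truth; all
are pure functions of their seed.

* **Toy complexes.** One 1.9 Å sphere per residue on a jittered 3.8 Å
  cubic lattice, folded by a seeded self-avoiding walk with backtracking
  inside a box with ~50% slack (distinct seeds give genuinely different
  folds; unrelated folds score TM < 0.3). Cn symmetry is imposed by
  rotation about z, with the radial offset bisected so adjacent subunits'
  nearest atoms sit 4.0 Å apart; residues with a neighbouring-subunit atom
  within 5.0 Å (a heavy-atom contact distance) form the ground-truth
  buried set. Interface calling recovers 100% of buried residues with
  subunit RSA > 0.2 across 100 seeded C2 dimers.
* **Trees.** Pure-birth (Yule) simulation, unit birth rate, stopping either
  at a tip count (then extending all tips by one further waiting time) or
  at a fixed height; the mean tip count at fixed height matches e^{λT}.
* **Trait histories.** Exact Gillespie simulation of an arbitrary generator
  matrix along each branch with a full event log; replaying the log
  reproduces all node states. The ratchet scenario uses the
  monomer–dimer–tetramer ladder with gains at 0.3 and losses at 0.1 per
  unit branch length — a 3:1 bias at a scale where true histories show more
  gains than losses in ~97% of 200 20-leaf trees, i.e. the forward process
  genuinely ratchets upward.
* **Conservation and abundance tables.** Interface scores are shifted down
  by a configurable amount against unit-variance noise (default shift 1.0);
  abundances are lognormal (ln-mean 3, ln-sd 1 — spanning the orders of
  magnitude typical of proteome ppm tables) with homomers shifted up by
  ln 2 and subunit counts drawn from {2: 0.6, 4: 0.3, 8: 0.1}, the dominant
  homomer stoichiometries. With the ln 2 shift and all-dimer homomers, the
  raw difference is significant and the scaled difference is not in ~94% of
  replicates at n = 300 per group — scaling removes the shift by
  construction.

What the toy data do **not** emulate: real fold geometry, secondary
structure, side chains, sequence evolution, heteromers, or crystallographic
artefacts. Passing tests therefore establish the correctness of the
*computations* (thresholds applied as stated, statistics equal to their
oracles, generators matched to their closed forms), not the biological
accuracy of interface calls on real structures.

## Known limitations

* **Directional bias is compressed by symmetric-model reconstruction.**
  On histories simulated with a 3:1 gain:loss bias, gains exceed losses on
  ML-reconstructed states in only ~70–80% of trees (vs ~97% on the true
  histories): the flat-prior equal-rates model places the root at the
  majority tip state, and once the ratchet has driven most tips to homomer
  states the monomer root is misinferred, converting true gains into
  apparent losses. The marginals themselves are exact (they match
  exhaustive enumeration), so this is a property of symmetric-model
  reconstruction applied to an asymmetric process — worth keeping in mind
  when interpreting per-tree gain/loss tallies; under symmetric rates no
  spurious direction appears (both directions win in ~40% of trees).
* The toy bundle's structures are reduced representations; metadata fields
  (resolution, coverage, UniProt length) are simulated independently of the
  pseudo-atom geometry and exercise only the filtering logic.
* Sequence-guided correspondence degrades with very low sequence identity,
  where a structural aligner should be injected instead.
* Problem sizes in tests and the acceptance script (24–30-residue toys,
  20-leaf trees, 200–1000 replicates) were chosen to exercise every code
  path at desk scale; corpus-scale constants (e.g. the 1000 Å² QS-error
  threshold) keep their published defaults.
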