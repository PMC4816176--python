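# Methods

This note documents the model, the algorithmic conventions, and the design
choices behind `diffgrn`, in the order the pipeline runs. Nothing here
reports an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Boolean network model

A gene regulatory network is a directed graph over gene symbols with
per-edge sign (activation or inhibition). States are binary vectors
(gene expressed / not expressed); dynamics are fully synchronous.

**Majority rule.** At each step every gene is updated simultaneously:

* ON iff the number of ON activators strictly exceeds the number of ON
  inhibitors,
* equal counts (including zero–zero) give OFF,
* a gene with no incoming edges at all is constitutively ON.

Only ON regulators count; OFF regulators are invisible to the update (a
property the suite tests directly). The unregulated-ON exception is
structural (in-degree zero), not state-dependent: a gene whose regulators
happen to be all OFF follows the tie rule and goes OFF. A consequence
worth stating explicitly: a lone self-inhibiting gene has **no** 2-cycle —
from ON it steps to OFF, and OFF (0 activators = 0 inhibitors) is a fixed
point. Sustained oscillation requires wider negative feedback.

Attractors are found by iterating updates and hashing exact states; the
first revisited state closes the cycle (length 1 = fixed point). The step
budget defaults to 2ⁿ + 1, which makes non-termination impossible; in
practice transients are a handful of steps. Both the attractor search and
the clamped perturbation dynamics are verified exactly against a full
2⁸-state transition-graph tabulation on 100 random 8-gene networks.

## Differential expression and binarization

* **Test**: Welch (unequal-variance) two-sample *t*-test per gene; the
  variant is a deliberate choice — small microarray-style replicate groups
  rarely justify pooled variance. Genes with zero variance in both groups
  get an ε-guard (distinct means ⇒ p≈0, equal means ⇒ p=1) rather than a
  crash.
* **Selection**: raw p < `p_cutoff` AND linear fold change >
  `fc_cutoff` (defaults 0.05 / 2.0; both case-specific in practice and
  fully configurable). No multiple-testing correction by default, because
  the selection contract is defined on raw p-values; a Benjamini–Hochberg
  switch exists (`bh_fdr`) but defaults off. If inputs are log-scale, set
  `log_scale` so the fold change is exponentiated from the mean
  difference.
* **Binarization rule** (an interpretation, stated prominently: the
  selection procedure implies differential ON/OFF states but no explicit
  rule): the phenotype with the higher group mean is ON, the other OFF.
  Exact ties binarize OFF/OFF and are logged as ambiguous. For any gene
  passing a fold-change filter > 1 the two patterns are complementary.

## GA contextualization

Genome = three bit subarrays over one master edge list: presence bits for
network 1, presence bits for network 2, and one sign bit per
originally-unknown edge (1 = activation). Sign bits apply identically to
both networks, so the two contextualized GRNs can never disagree on a
shared edge's mode of action.

**Objectives (all minimized).** The published description names only
"attractors and stability", so the decomposition is this package's own:

* o1 — Hamming mismatch between network 1's attractor (started *from*
  phenotype A's pattern — the question being whether the data pattern is
  (near) an attractor) and that pattern, plus (cycle length − 1) as an
  instability penalty;
* o2 — the same for network 2 / phenotype B;
* o3 — total pruned edges over both networks. Parsimony of *pruning*
  (trust the curated map unless the data demand otherwise), not of edges.

**Loop.** NSGA-II-style: nondominated sorting + crowding-distance
truncation for survival (elitist); the population's best o1+o2 is
additionally guarded so it can never regress. Mating deliberately replaces
binary tournament with *cooperative selection* over a scalarized rank
(front, then o1+o2, ties by index): the best individual is returned, its
working fitness is overwritten by the mean of the 2nd and 3rd best, and
the next pick therefore selects a different individual. The overwrite
lives on a per-generation working copy — stored objective vectors are
never corrupted. Variation: three-point crossover (probability 0.9; one
independent cut per subarray, child 1 = parent 1 prefix + parent 2 suffix
per subarray) and independent per-bit mutation at 0.01 per subarray.
Reference configuration: population 700, 250 generations; the validation
experiments run population 100 / 60 generations on 15-gene instances,
where the same qualitative behavior is reached in seconds.

**Initialization** (unspecified upstream): one tenth of the population
starts with all edges present (random sign bits) — encoding trust in the
map — and the rest at 50 % presence for diversity.

**Consensus.** Populations retain variability, so the output is a
majority vote over the top `consensus_fraction` (default 0.1) of solutions
ranked by (front, o1+o2): an edge enters consensus network *k* iff present
in strictly more than `consensus_threshold` (default 0.5) of them; each
unknown edge takes its majority sign, ties resolved to activation and
logged. The two networks vote independently. With a fixed seed the entire
run is bit-reproducible.

## Circuits and candidate genes

Elementary circuits (every directed cycle visiting intermediate nodes
once, self-loops included) are enumerated with Johnson's algorithm via
`networkx.simple_cycles`, canonicalized to start at the lexicographically
smallest gene, and verified exactly against a brute-force permutation
enumerator on 200 random digraphs. Circuit sign = parity of its inhibition
count (even = positive, odd = negative). Enumeration is uncapped by
default; `max_circuit_length` bounds it on large dense networks (logged
when active).

Circuit identity for the two-network intersection requires equal node
sequence **and** equal edge signs: a sign flip changes the circuit's
stability role, so a path-only match is not the same circuit (cases where
the looser rule would differ are logged). Candidate genes are the union of
genes on common circuits; genes under differential regulation — different
sets of *expressed* regulators between the two networks, where
"expressed" means ON in that phenotype's pattern — are solo candidates
unless already on a common circuit. "Regulators" means in-network
regulators; no external transcription-factor annotation is consulted.

## Perturbation scan

A perturbation clamps genes to fixed values after every update (and in the
initial state) — a sustained intervention with dominant effect. Clamp
values are the gene's state in the *reference* (opposite) phenotype, the
only reading that makes "reversion" well-defined; the simulation runs on
the network of the phenotype being perturbed (the disease network when
reverting disease; configurable). Change is counted relative to the
initial pattern; for limit cycles, mean occupancy > 0.5 counts ON, < 0.5
OFF, exactly 0.5 counts unchanged.

`gec = #changed − #clamped` never exceeds n − |combination| and discounts
the trivial "change" of the clamped genes themselves. Scans enumerate all
circuit-gene subsets per size when C(m,k) ≤ `max_per_size` (then the scan
is deterministic regardless of seed) and otherwise sample that many
distinct subsets uniformly; solo candidates contribute size-1 combinations
only and never mix into larger ones. Results sort by gec desc, then
smaller size, then gene order.

## Drug enrichment

Weights w_g = single-target gec rescaled to [0,1] over the candidates
(all-equal ⇒ all 1). Raw enrichment of drug d in combination i sums w_g
over d's targets in the combination, **restricted to targets that are
candidates**; normalization divides by d's maximum attainable score (sum
of its candidate-target weights), which makes drugs with different target
counts comparable — the stated requirement is only that scores lie in
[0,1]. Drugs without candidate targets, or with zero total mass, are
excluded with a warning.

The PMF lays the normalized mass over the grid of distinct observed gec
values (shared across drugs of one run, so the uniform comparison is
like-for-like); the CDF is its running sum; AUC sums the CDF with unit
step per grid value, excluding the top value — the only convention under
which a point mass at the best observed gec yields exactly 0. The uniform
baseline is then (g−1)/2 on a g-point grid and rankings report
100 × (AUC_uniform − AUC_d)/AUC_uniform. Absolute AUC magnitudes are
grid-size dependent and therefore only meaningful within one run. The
whole-drug assay clamps all candidate targets simultaneously
(increases → ON, decreases → OFF, unspecified → reference state) and
reports the changed fraction.

## Synthetic planted instances

The generator fabricates all three external inputs with known truth:

* master map: random signed digraph (defaults: 15 genes, edge density
  0.15 ≈ 34 candidate edges, 25 % inhibition), with 30 % of edge signs
  hidden as unknown (true sign recorded);
* true network pair: two independent 10 % prunings of the master;
* patterns: the fixed-point pair of the two pruned networks (exhaustive
  2ⁿ enumeration, n ≤ 20) with maximal Hamming separation, rejected unless
  they differ in ≥ 25 % of genes;
* expression: replicates (default 4 per phenotype) at ON level 10 / OFF
  level 2 with Gaussian noise (default SD 1 — essentially saturated t-test
  power, degradable via `noise_sd`);
* drugs: one planted drug whose targets are the exactly-optimal
  combination from an exhaustive scan up to size 3, plus 10 decoys with
  1–3 uniform random targets over the network genes.

Instances failing any rejection rule are reseeded deterministically
(attempt index mixed into the seed); the same seed reproduces the same
files byte for byte.

What the generator does **not** emulate: realistic microarray noise
(heteroscedasticity, probe effects), map incompleteness beyond random
pruning, hub-dominated degree distributions, or network scale beyond ~20
genes — so green tests certify algorithmic correctness and small-scale
recovery, not performance on genome-scale data.

## Known limitations

* **Sign identifiability.** The only evidence about an unknown edge sign
  is whether flipping it disturbs the two planted fixed points. On
  15-gene instances 20–60 % of unknown signs are dynamically free
  (verified by direct single-flip enumeration), so consensus sign
  recovery is capped well below 100 % regardless of optimizer quality;
  the recovery experiment reports what the data permit.
* **Drug recovery at small scale.** With 15 genes the candidate set can
  cover most of the network, single-gene perturbations often attain the
  maximal gec (degenerating several weights to 1.0), and a solo candidate
  appears in exactly one scanned combination — so a random decoy hitting
  one strong solo gene achieves a point-mass enrichment at the grid
  maximum (AUC 0) and can legitimately out-rank the planted multi-target
  drug. At realistic scale (hundreds of genes, candidates a small
  fraction) these degeneracies vanish.
* Asynchronous updating, multi-valued logic, dose effects and
  pharmacokinetic drug–drug interaction are out of scope; combination
  drugs are handled only insofar as their target sets are disjoint.
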