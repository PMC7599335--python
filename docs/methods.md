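# Methods

## The reconciliation post-processing model

The package consumes branch-wise summaries of sampled gene tree / species
tree reconciliations. A reconciliation embeds a gene tree into a rooted
binary species tree and explains their discordance by duplication (D),
transfer (T) and loss (L) events plus an origination (O) — the appearance
of the family's first copy, either a de novo birth or a transfer from
outside the sampled taxa. Averaging over a sample of reconciliations
(100 by default) yields, per family and per branch, real-valued event
frequencies and expected copy numbers; these are support values, not
counts.

A *branch* is identified by its child node, matching ALE's branch tables;
the root's branch row is legal and used only for originations. Branch
identifiers come either from internal node labels of the input newick or,
when unlabelled, from ALE-style postorder numbering (leaves `0..n-1` in
postorder appearance, then internal nodes `n..2n-2` in postorder).

### Discretization rules

* **Event calls.** A frequency `f` on a branch yields
  `⌊f⌋ + [frac(f) ≥ t]` calls at threshold `t` (default 0.3). For `f ≤ 1`
  this is exactly the "called iff `f ≥ t`" rule; the whole-unit extension
  handles branches hosting multiple events of one type. A float guard of
  1e-9 makes the ≥ comparisons robust to representation noise. Raising
  `t` can only decrease call counts (a tested invariant).
* **Extinction adjustment.** Reconstructed copy numbers are corrected
  upward for gene lineages that went extinct without sampled descendants:
  `n̂ = n / (1 − P_ext)` with the per-family extinction probability
  `P_ext`. Values of `P_ext ≥ 0.99` are rejected as numerically unstable
  rather than silently amplifying noise ~100×. Presence is evaluated on
  adjusted copies; event calls use raw frequencies (the adjustment is a
  copy-number correction, not an event-rate correction).
* **Support categories.** absent `< 0.3`, weak `[0.3, 0.65)`, moderate
  `[0.65, 1.0)`, strong `≥ 1.0`. The half-open intervals make the mapping
  total; the source convention leaves the exact boundary points
  unassigned, and assigning a boundary upward is the deterministic choice.
* **Complex presence.** A complex of `n` subunits is present when
  `2·k ≥ n`, where `k` counts subunits with copy number ≥ 0.3 ("at least
  half of the subunits").
* **Singletons.** Families with one member sequence are never reconciled;
  each adds one origination call and one strong presence at its genome's
  leaf.
* **Genome size** is the count of present (non-absent) families per node,
  not the sum of copy numbers.
* **Transfer matrices.** Donor→recipient pairs are thresholded
  independently, which need not agree with calls made on the recipient's
  marginal frequency; both tables are emitted and the disagreement is
  flagged per branch (`transfer_marginal_consistency`).

## Origination sources

For a family whose reconciliation shows an origination, placements of its
sequences on a pruned tree-of-life reference tree are summarized: each
sequence's likelihood-weight ratios are renormalized to 1, mapped to the
placement edges' taxonomic label paths, summed per label and averaged
over sequences, so weights sum to 1 per family. The argmax label is the
inferred donor; ties resolve to the tied labels' least-specific common
ancestor (a Terrabacteria/Proteobacteria tie reports Bacteria).
Families with no reference homologs are de novo. With fewer than four
reference taxa the placement algorithm cannot run and the family is
assigned to the last common ancestor of the remaining taxa; that LCA
label is taken from an explicit argument, or computed as the longest
common prefix of the reference edge labels when a profile is available.
The per-sequence-then-per-family averaging is one defensible reading of
"highest relative likelihood weight"; it is invariant under per-sequence
weight rescaling, which is the property the tests pin down.

The robustness check compares each comparable sequence's best-placement
edge label with the label of its true sister branch in the raw reference
tree, and classifies families as all / some / none identically placed.

## Compositional-bias treatments

Per-taxon heterogeneity is
`χ²_t = Σ_a (n_{t,a} − N_t·f̄_a)² / (N_t·f̄_a)` over amino acids `a` with
global mean frequency `f̄_a > 0`; gaps and `X` are excluded from all
denominators and contribute nothing to site scores. Two site rankings are
offered:

* `greedy` (reference semantics): repeatedly remove the column whose
  removal most decreases `H = Σ_t χ²_t`, recomputing `f̄` after every
  removal; quadratic in columns, testable against a brute-force oracle.
* `single_pass` (default): score each column once from full-alignment
  statistics, `score(s) = Σ_t (f_{t,a(t,s)} − f̄_{a(t,s)}) / f̄_{a(t,s)}`;
  linear and the one used at scale.

Trimming removes `⌊fraction·n⌋` columns (the study used 0.5 for a broad
taxon sample and 0.3 for the focused one); ties break toward lower column
indices for determinism; partitions are re-indexed over surviving columns
and empty partitions dropped, with a column-provenance map returned.
SR4 recoding maps AGNPST→A, CHWY→C, DEKQR→G, FILMV→T (nucleotide-letter
stand-ins for the four groups), passing gaps and `X` through. N-ARSC is
the mean count of side-chain nitrogen atoms per residue
(R:3, H:2, K/N/Q/W:1, others 0).

## Family construction

Single-linkage clustering takes pairwise hits with `identity ≥ 0.6` and
`overlap ≥ 0.9` (both inclusive; overlap is aligned length over the
shorter sequence — the common convention, since the upstream tool's exact
semantics are not restated) and returns connected components; proteins
appearing only in sub-threshold hits become singletons.

Fusion splitting: families with a member annotated with ≥ 2 distinct
COG/NOG ids are screened with per-COG profile hits. Hits on one protein
are resolved in descending score (ties: longer region, then lower start);
each accepted region claims its interval, later regions keep only their
longest contiguous remaining flank, and a region retaining < 30% of its
original length is discarded — so a fully contained lower-scoring region
always drops. The family then splits into one `<family>_<COG>` component
per distinct COG, each resolved region becoming its own member record;
members with no resolved region are preserved in `<family>_rest`
(flagged residual) rather than dropped, since preservation is reversible
and dropping is not. Profile scores come from HMMER domtblout (per-domain
bit score, ali coordinates) or from a built-in ungapped sliding-window
log-odds scanner intended for tests and small examples only.

## The synthetic-data generator

The simulator is a discrete, branch-wise DTL process: a family originates
at the root (probability `p_orig_root`, default 0.5) or a uniform other
node; every gene copy entering a branch independently suffers at most one
event — loss `p_loss` (default 0.15), duplication `p_dup` (0.05), or
transfer `p_trans` (0.05) to a uniformly chosen non-descendant branch
(a time-consistency surrogate in an undated setting; the root branch
receives no transfers). Transferred copies propagate onward from their
landing node. Copy-number conservation
`copies(child) = copies(parent) + D + T + O − L` holds exactly on every
branch of every history, which is what makes downstream recovery testable
exactly. Default probabilities are subcritical so transfer cascades stay
finite; a hard guard aborts pathological parameterizations.

Frequency tables average `r = 100` pseudo-reconciliations per family.
Each sample equals the truth with probability `1 − perturb`; otherwise
one uniformly chosen true event is deleted or one spurious event is added
on a random branch (50/50), so the frequency noise is symmetric around
truth. A perturbed sample's copy numbers follow the event edit (±1 over
the subtree below the edited branch, clamped at zero — a deleted
origination cannot drive copies negative). Deleting a transfer removes
its donor→recipient pair together with the recipient's marginal, so the
pair-sum/marginal invariant survives perturbation.

Biased alignments draw unbiased sites from one Dirichlet-sampled global
composition and biased sites per taxon from that composition shifted
toward a taxon-specific preferred residue with weight `bias_strength − 1`
(strength 1 = no bias). Fusion proteins concatenate one sequence from
each of two pools and emit region hits whose inner boundaries are
jittered by ±`jitter` residues. Placement scenarios put `1 − noise`
weight on an edge under the true donor label and spread `noise` uniformly
over the other edges; `None` donors yield de novo families with no
profile.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlated reconciliation errors (real
rootings and gene-tree artifacts bias events systematically, not
symmetrically), rate heterogeneity across branches and families, dated
constraints on transfers, sequence evolution itself (the biased-site
model plants composition, not phylogenetic signal), and profile-search
score noise beyond coordinate jitter. Recovery results certify the
post-processing logic, not the upstream inference.

## Problem sizes and numerical choices

The validation suite and the acceptance script use a 16-leaf tree with
200 families and 100 samples for DTL recovery (noise-free and at
`perturb = 0.2`), 6×20 alignments for the greedy-vs-oracle check and
8×200 for planted-site recovery (bias strength 8, fraction 0.2), 100
random hit graphs for the clustering oracle, 50 fusions with ±5 jitter,
and 100 noiseless placement scenarios — sizes at which exact oracles are
feasible and the whole suite runs in seconds. Comparisons at category and
threshold boundaries carry a 1e-9 guard; all randomness flows through
`numpy.random.default_rng` seeded per call, so every generator is
bit-reproducible and file-emitting generators write a parameter manifest.

## Known limitations

* The extinction correction `n/(1 − P_ext)` is the package's documented
  interpretation of "adjusting copy numbers by the extinction
  probability"; the upstream patch it mirrors does not print a formula.
* Whether the original χ² trimmer ranked sites once or greedily
  re-evaluated is unknown; both are provided and the choice is recorded
  in output metadata.
* `_rest` residual families and one-flank trimming are conservative
  choices where the source procedure is silent; both are flagged in
  output so downstream users can filter.
* The full reconciliation-string syntax of `uml_rec` files is out of
  scope; only branch-wise frequency tables (plus transfer pairs and the
  extinction line) are parsed.
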