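# Methods

## Model

The unit of analysis is the *perturbed functional sub-network*: a connected
component of `M(t) ∪ A(t)`, where `M(t)` is the set of interactome proteins
annotated with biological-process term `t` (after ancestor propagation) and
`A(t)` is the set of profiled drug targets attached to `M(t)`. A target is
attached when some path links it to a member with every interior node
itself a profiled target; operationally, `A(t)` is the set of targets
reachable from `M(t)` inside the subgraph induced on members ∪ targets.
Direct targets (annotated members) belong to both sets. Because attachment
is computed before taking components, one target adjacent to two of a
term's components fuses them into a single network.

Each component is scored

    s_net = (n_annot,net / n_net) · (n_drug,net / n_net) · (T_drug,net / T_drug)

with `n_net` the component size, `n_annot,net` its annotated members,
`n_drug,net` its profiled targets, `T_drug,net` the sum of their affinity
scores and `T_drug` the affinity sum over the *entire* profile. Each factor
lies in [0, 1]; `s_net = 0` iff the component contains no target or no
affinity. Targets absent from the interactome still count in `T_drug` but
can never enter any `T_drug,net` — a conservative convention that penalizes
profiles whose binding mass falls outside the network. The first factor
penalizes dilution by unannotated peripherals, the second penalizes generic
terms whose huge components a handful of targets cannot meaningfully
perturb, and the third concentrates the ranking on where the drug actually
binds. A direct consequence worth knowing: uniform scaling of all
affinities cancels, so the logarithm base in the affinity score and any
global potency rescaling do not move ranks.

## Affinity scores

Competition mode (the default): `a_t = (1 − p_comp/p_t) · log10(p_t)` from
peptide counts without (`p_t ≥ 1`) and with (`p_comp ≥ 0`) soluble-drug
competition. `p_comp ≥ p_t` is read as "not competed" and scores exactly 0;
so does a single-peptide protein (`log10(1) = 0`), a documented consequence
of log damping. `a_t` is non-increasing in `p_comp` at fixed `p_t` and
non-decreasing in `p_t` at a fixed competition ratio. Missing `p_comp`
cells are treated as not competed (logged).

External-weight mode accepts measured potencies with a transform:
`log10` (default — weights in the direction the nM magnitude suggests),
`neglog10` (emphasizes potent, low-IC50 inhibitors; offered because the
appropriate direction depends on what the potency represents) or
`identity`. Negative transformed values are clamped to 0 with a warning.

## Ancestor propagation

Annotations are restricted to interactome nodes and propagated to all
ancestors over `is_a` and `part_of` within biological_process (true-path
rule); `regulates`-type relations do not imply annotation transfer and are
ignored. `part_of` can be excluded (`include_part_of=False` /
`--no-part-of`). Propagation is idempotent and closure-monotone (a parent's
set contains each child's); cycles in the parent relation are an error.
The root term is retained and scored like any other — its sub-network is
enormous and the two size factors crush it, so no special-casing is needed.

## Randomization null

Each of N instances (default N = 500; the benchmark suite uses N = 100)
rewires the interactome and then reassigns annotations:

* **Rewiring**: 10·|E| attempted double-edge swaps, rejecting any swap that
  would create a self-loop or parallel edge. Per-node degrees are preserved
  exactly. The swap budget is configurable (`--swaps-per-edge`).
* **Annotation shuffle**: each term is reassigned to the same number of
  nodes, drawn uniformly without replacement, independently across terms.
  The draw pool is the *annotated* node set by default. The alternative
  pool of all nodes (`--shuffle-candidates all`) is provided but not the
  default for a structural reason: proteins carrying no annotation at all —
  unannotated drug targets above all — would then receive process
  annotations in the null, and any term landing on a high-affinity target
  creates a singleton "network" scoring `a_t/T_drug` regardless of
  topology. With a profile whose affinity sits on a few targets this
  artifact dominates every instance and the null degenerates to a property
  of the profile rather than of the term–topology association under test.
  Sampling within the annotated pool preserves per-term counts *and* the
  annotated fraction. Ancestor closure is deliberately not re-imposed after
  shuffling — the null randomizes the term-node association as such.

The observed score's p-value is `|{i : max_i ≥ s}| / N`, where `max_i` is
instance i's best sub-network score; ties count as exceedances, p is a
non-increasing step function of s, and zero exceedances are reported as
the bound `<1/N` (e.g. `<0.002` at N = 500). Using the per-instance maximum
makes the test family-wise across terms by construction, so no further
multiple-testing correction is applied. Instances are pure functions of
(inputs, instance seed); instance seeds derive from the master seed by
index, so results are identical under any evaluation order or parallel
schedule.

## Robustness analyses

*Leave-one-out* re-scores the full table with each target removed in turn
(`T_drug` recomputed) and tracks selected terms' ranks; columns are ordered
by descending affinity. Removing a zero-affinity target that belongs to no
network is provably a no-op (it contributes nothing to either side of the
affinity ratio and no membership count).

*Hub weighting* multiplies (`up`) or divides (`down`) each target's
affinity by log10 of its interactome degree — degree on the original
interactome, not the sub-network — then re-scores. Degree-1 targets get
`a_t = 0` in up mode (log10(1) = 0); in down mode, where the same factor
would divide by zero, their affinity is left unchanged with a warning.
Uniform degree makes either mode a global rescaling, which cancels — a
useful exactness check.

## Synthetic benchmarks

The generator emulates the statistical structure of the real inputs without
any download: an Erdős–Rényi background (default 500 proteins at edge
probability 0.01, mean degree ≈ 5 — the order of curated interactomes; a
configuration-model alternative accepts a degree sequence), one planted
40-protein module wired to connectivity at internal density 0.3 and
annotated with its own term, a depth-3 ontology (leaves under branch terms
under the root, one `part_of` link), 10 decoy terms annotated to random
background nodes at counts matched to the module (so rank-1 recovery
discriminates mechanism, not term size), and a 10-target profile: 5
high-affinity attached targets (3 peripheral plus a chain of 2; peptide
counts ≈ 100, near-fully competed) and 5 zero-affinity decoy targets
(`p_comp ≥ p_t`) placed at random.

Two generator conventions matter for interpretation. Attached targets keep
*only* their role-defining edges, so the truth record's roles are exact — a
"chained" target genuinely reaches the module only through its predecessor.
Decoy targets keep their natural background edges: unspecific binders are
dispersed over the interactome, and when one happens to touch the planted
module it joins that network with zero affinity (visible as `n_drug` above
5 in the worked example). Nodes left without any interaction are dropped —
they could never join a connected sub-network.

What the benchmarks do not model: scale (three orders of magnitude fewer
proteins, terms and annotations than a real analysis), heavy-tailed degree
distributions beyond the configuration-model option, correlated annotation
structure of real GO beyond a 3-level hierarchy, and realistic peptide
count distributions. Passing tests therefore demonstrate the algorithmic
contracts (extraction, scoring, null conservation laws, recovery and
calibration at benchmark scale), not field performance on a curated human
interactome.

The generator's inverse, `counts_from_affinity`, produces integer
`(p_t, p_comp)` whose affinity round-trips within `log10(p_t)/p_t`.

## Numerical and procedural choices

* Logarithms are base 10 throughout (affinity, IC50 transform, hub
  weighting); the base cancels in the affinity ratio within one profile.
* Components of a term are indexed in order of their lexicographically
  smallest member; results sort by descending score with ties broken by
  term accession, then component index — fully deterministic output.
* Scored components with `s_net = 0` are suppressed from tables by default
  (`--include-zero` restores them); `--collapse` keeps only each term's
  best component; a minimum uniform-component size is available
  (`--min-size`, default 1: a single annotated protein plus its attached
  targets is a meaningful perturbed unit).
* Self-interactions are dropped at parse time (they can never attach a
  target and would break rewiring invariants); duplicate edges collapse at
  interactome assembly.
* Degenerate inputs fail loudly: empty merged interactome, cyclic
  ontology, mixed-mode or duplicate-protein profiles, zero-peptide
  targets, leave-one-out on a single-target profile.
* Randomness: numpy `SeedSequence` with explicit spawn keys everywhere; a
  single master seed determines fixture generation, rewiring and shuffling
  bit-for-bit.

## Known limitations

Edges are unweighted and undirected; no activation/inhibition signs, no
evidence-code or interaction-type filtering (readers accept everything;
filter upstream if needed), no identifier mapping across namespaces, and no
statement about whether a perturbation enhances or suppresses the process —
the score measures impact, not direction. The empirical p-value resolution
is 1/N; claims below that resolution are reported as bounds, never as
estimates.
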