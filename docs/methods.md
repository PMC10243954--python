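# Methods

Precise definitions of every computation in `netpharm`, the parameter
defaults and their rationale, and what the synthetic generator does and does
not model.

## ADMET screening (`netpharm.screen`)

A compound passes iff all of the following hold (all inequalities strict):

1. **Oral potential** — oral bioavailability OB > 30 %, **or** Lipinski
   rule-of-five compliance with at most one violation among
   {MW > 500, AlogP > 5, H-bond donors > 5, H-bond acceptors > 10};
2. **Caco-2 permeability** > 0.4;
3. **drug-likeness** DL > 0.18;
4. **half-life** > 3 h.

These are the customary cut-offs of TCMSP-style herbal compound screens.
`screen_compounds` additionally returns a per-criterion failure counter
(`oral_potential`, `caco2`, `dl`, `half_life`); a compound can contribute to
several counters. Predicted-toxicity endpoints are carried as annotations
and summarized, never used to reject.

## Target assembly (`netpharm.targets`)

- **Drug targets**: genes whose compound–gene association probability is
  strictly > 0.8 (default `min_probability`).
- **Disease targets**: the top `ceil(fraction · N)` score-ranked genes from
  the GeneCards-like source (ties broken alphabetically for determinism),
  unioned with every gene from the curated DisGeNET-like source. Default
  `genecards_top_fraction = 0.5`.
- **Compound aliases**: compounds found in ≥ 2 herbs get letters A, B, …
  ordered by (herb count descending, compound id); compounds unique to one
  herb get `<herb code><index>`. Labels are checked for global uniqueness.

## Network construction and topology (`netpharm.netcore`)

Edges are kept when confidence is strictly > 0.4 (the usual
medium-confidence STRING cut-off, here on a 0–1 scale; the edge reader
accepts 0–1000 scores and rescales). Average degree is 2E/V; clustering is
the mean local clustering coefficient including zeros.

**Key targets** are nodes whose degree *and* unnormalized betweenness are
both strictly greater than twice the respective network-wide median — the
common "hub by two centralities" rule. Betweenness is computed on the
unweighted graph.

## MCODE (`netpharm.mcode`)

Defaults mirror the Cytoscape plugin: `degree_cutoff = 2`,
`node_score_cutoff = 0.2`, `k_core = 2`, haircut on, fluff off.

- **Node score** = density of the highest k-core of the node's closed
  neighborhood × that core's k (0 if degree < `degree_cutoff`).
- **Growth**: seeds are unvisited nodes in decreasing score order; a
  breadth-first expansion adds neighbors whose score exceeds
  `seed_score × (1 − node_score_cutoff)`.
- **Haircut**: iterated removal of nodes with < 2 neighbors inside the
  complex (a 2-core trim).
- **Complex score** = density of the induced subgraph × its size; complexes
  are reported in decreasing score order.

An isolated K4 therefore scores exactly 4, and a planted 5-clique in a
sparse background is recovered as the top complex.

## Random walk with restart (`netpharm.diffusion`)

Iterates `p ← (1−r)·W·p + r·e` where W is the column-normalized adjacency
matrix, e is uniform over the seed genes, and `r = 0.7` by default. Mass at
dangling (degree-zero) nodes is redirected to the restart vector, so scores
always sum to 1. Convergence at L1 residual `1e-10` (max 1000 iterations;
non-convergence raises). On the path A–B–C with seed {A} and r = 1/2 the
fixed point is exactly (7/12, 1/3, 1/12), which the tests verify along with
agreement with a dense linear solve.

## Network proximity (`netpharm.proximity`)

Closest-distance convention (Menche et al.): d_AB is the mean over all
(a, b) pairs' contributions via each node's closest partner in the other
set; d_AA and d_BB the within-set analogues (self excluded). The separation
index is

    s_AB = d_AB − (d_AA + d_BB) / 2,

negative when the sets overlap topologically. The **random control** draws
50 groups (default) of fixed size uniformly from the network nodes outside
set A and reports the mean ± sd of their s to set A; group size in the
pipeline is matched to the drug target set.

## Enrichment and clustering (`netpharm.enrichment`)

Over-representation p-value is the hypergeometric upper tail
`P(X ≥ k)` via `scipy.stats.hypergeom.sf(k−1, N, K, n)`; multiple testing by
Benjamini–Hochberg (`statsmodels`). Default significance cut-off
`p < 0.005`; terms with zero overlap are omitted; results sort by
(p, term id). Correlation clustering is average-linkage hierarchical
clustering of the 1 − correlation distance (`scipy.cluster.hierarchy`),
label-permutation equivariant by construction.

## Docking post-processing (`netpharm.docking`)

Inhibition constants from binding free energies at T = 298.15 K with
R = 1.98720 cal·mol⁻¹·K⁻¹:

    Ki (µmol/L) = 10⁶ · exp(ΔG · 1000 / (R · T)),   ΔG in kcal/mol.

A complex is called stable when ΔG < −5 kcal/mol. The bundled 14-pair table
(`netpharm.datasets`) stores only the energies; Ki is always recomputed and
matches the published constants to printed precision.

## Synthetic data model (`netpharm.synth`)

All draws go through `numpy.random.SeedSequence([seed, stream_tag])`, one
independent stream per generator, so outputs are reproducible and adding a
generator never perturbs the others.

- **Compounds** (`n_compounds = 100`): each property is drawn on the passing
  or failing side of its threshold according to `pass_fraction = 0.67`;
  each compound belongs to 1–3 of `n_herbs = 15` herbs.
- **PPI network** (`n_genes = 150`): Barabási–Albert graph (`m = 2`) with a
  planted 5-clique on low-degree periphery nodes, a 4-gene set A on
  non-clique periphery, a nearby set (1 hop from A) and a distant set
  (≥ 3 hops, resampled up to 200 times). Edge confidences ~ U(0.41, 1) so
  the default filter keeps everything.
- **Gene sets** (`n_terms = 20`, sizes 10–30): one planted term samples
  query genes with weight `enrichment_strength = 30`. The default of 30 was
  set by measuring planted-term rank-1 recovery across 300 seeds (≈ 99.7 %);
  at weight 10 recovery was ≈ 93 %, below the intended ≥ 95 % design
  guarantee of the default configuration.
- **Correlation matrix**: one latent factor per block
  (`correlation_blocks = 4`), within-block correlation ≈ 0.8.
- **Association / disease tables**: association probabilities uniform with
  genes drawn from the lower 40 % of the universe ("druggable space");
  disease scores Pareto(1.5) on the upper 80 % — so drug and disease target
  sets overlap partially, as in a real screen.

**What the generator does not model**: real protein identifiers or
annotation biases, degree-correlated confidence scores, literature-derived
term overlap structure, or any chemistry — compound properties are
statistically, not physically, plausible. It exists to make every pipeline
stage exercisable and falsifiable offline, not to imitate any particular
organism or database release.

## Pipeline reproducibility (`netpharm.pipeline`)

Stages run in a fixed order (screen → targets → network → mcode → rwr →
proximity → enrichment → optional clustering → optional docking); each
artifact is recorded in `manifest.json` with its sha256 and the parameters
that produced it. A failing stage raises `RuntimeError` naming the stage.
Reruns with the same config and seed are byte-identical.

## Numerical choices

- Strict inequalities everywhere a threshold is specified, so boundary
  values are excluded deterministically.
- Ties are always broken lexicographically (gene name, term id, compound
  id) to keep outputs stable across platforms.
- Sample standard deviations use ddof = 1 and are NaN for a single draw.
- Derived seeds stay below 2³¹ for portability.

## Limitations

- Betweenness is exact, not sampled; very large networks (> ~10⁴ nodes)
  will be slow in `key_targets` and `proximity`.
- The RWR solver is dense-vector iterative; it is intended for networks up
  to ~10⁵ edges, not genome-scale multiplex graphs.
- The proximity null matches group size only, not degree distribution; a
  degree-preserving null would be stricter on hub-heavy target sets.
- MCODE's optional fluff step is implemented but off by default, matching
  the plugin defaults rather than exploring parameter space.
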