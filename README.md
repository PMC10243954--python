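# netpharm

A network-pharmacology toolkit for multi-herb formulas. It models the common
workflow used to study how a traditional herbal decoction (e.g. Duhuo Jisheng
Decoction, DJD) acts on a disease (e.g. intervertebral disc degeneration,
IDD): screen compounds by ADMET properties, assemble drug and disease target
sets, build a confidence-filtered protein–protein interaction (PPI) network,
find key targets and dense modules, rank candidate genes by network
diffusion, quantify drug–disease proximity against a random control, test
pathway enrichment, and post-process molecular-docking energies.

Every step is an importable, separately testable function; a thin `netpharm`
command-line interface chains them into a reproducible pipeline. A synthetic
data generator with planted ground truth (a hidden clique, a deliberately
proximal gene set, an inflated pathway term, a block-structured correlation
matrix) makes the whole pipeline runnable and verifiable offline.

## What's inside

| Module | Purpose |
|---|---|
| `netpharm.io` | TSV tables with schemas, weighted edge lists, GMT gene sets, graph round-trips |
| `netpharm.screen` | ADMET screening: OB/RO5, Caco-2, drug-likeness, half-life; toxicity summary |
| `netpharm.targets` | Drug targets (association probability > 0.8), disease targets (top-scored ∪ curated), compound aliases |
| `netpharm.netcore` | Confidence-filtered network build, degree/betweenness, key-target rule, TF subnetwork |
| `netpharm.mcode` | MCODE dense-module detection (k-core node scores, greedy growth, haircut) |
| `netpharm.diffusion` | Random walk with restart (RWR) gene prioritization |
| `netpharm.proximity` | s_AB network proximity index with a matched random control |
| `netpharm.enrichment` | Hypergeometric over-representation with BH adjustment; correlation clustering |
| `netpharm.docking` | Binding energy → inhibition constant (Ki) conversion, docking summaries |
| `netpharm.datasets` | Bundled receptor–ligand binding energies (14 DJD-related pairs) |
| `netpharm.synth` | Seeded synthetic data with planted ground truth |
| `netpharm.pipeline` | YAML-configured end-to-end runs with a hashed artifact manifest |

## Worked example

```python
from netpharm.synth import SyntheticConfig, gen_ppi
from netpharm.mcode import mcode_find_complexes
from netpharm.proximity import proximity_index, null_control

planted = gen_ppi(SyntheticConfig(seed=11))
top = mcode_find_complexes(planted.network)[0]
print(sorted(top.members))     # recovers the planted 5-clique

s = proximity_index(planted.network, set(planted.set_a),
                    set(planted.set_b_near)).s_ab
mean, sd, _ = null_control(planted.network, set(planted.set_a),
                           group_size=4, n_groups=50, seed=11)
print(f"s_AB = {s:.3f} vs random control {mean:.3f} ± {sd:.3f}")
# s_AB = -1.375 vs random control -0.320 ± 0.435  (lower = closer)
```

And the docking conversion, Ki(µmol/L) = 10⁶·exp(ΔG/RT) at 298.15 K:

```python
from netpharm.docking import ki_from_energy
ki_from_energy(-8.26)   # 0.88 µmol/L
ki_from_energy(-12.61)  # 5.7e-04 µmol/L — the strongest bundled complex
```

From the shell, a complete simulated study:

```sh
netpharm simulate --seed 21 --out simdir
netpharm run simdir/config.yaml
cat simdir/results/manifest.json     # every artifact with its sha256
```

See `examples/` for one narrative script per capability.

## Design notes

- All thresholds are strict inequalities and are exposed as parameters with
  the conventional defaults (confidence > 0.4, association probability > 0.8,
  key-target rule "both centralities > 2× median", ΔG < −5 for stability).
- Randomness flows exclusively through `numpy.random.SeedSequence`; the same
  seed gives byte-identical pipeline artifacts.
- See `docs/methods.md` for the precise definitions, parameter rationale and
  limitations of the synthetic model.
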