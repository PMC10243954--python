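"""ADMET screening of a herbal compound library.

Generates a synthetic compound table (each compound annotated with oral
bioavailability, Caco-2 permeability, drug-likeness, half-life and Lipinski
properties), applies the screening rule, and reports why compounds failed.
"""

from netpharm.screen import ScreenThresholds, screen_compounds, summarize_toxicity
from netpharm.synth import SyntheticConfig, gen_compound_table

compounds = gen_compound_table(SyntheticConfig(seed=42))
kept, failures = screen_compounds(compounds, ScreenThresholds())

print(f"screened {len(compounds)} compounds, kept {len(kept)}")
print("failure reasons (a compound may fail several):")
for criterion, count in sorted(failures.items()):
    print(f"  {criterion:15s} {count}")

print("\nfirst five passing compounds:")
for c in kept[:5]:
    herbs = ",".join(sorted(c.herb_ids))
    print(f"  {c.compound_id}  OB={c.ob:5.1f}  DL={c.dl:.2f}  herbs={herbs}")

active = summarize_toxicity(kept)
print("\npredicted-toxicity endpoints flagged among kept compounds:")
for endpoint, count in sorted(active.items()):
    print(f"  {endpoint:25s} {count}")
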