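"""Binding energies to inhibition constants for the bundled docking table.

Converts each receptor-ligand binding free energy (kcal/mol) to an
inhibition constant Ki (umol/L) at 298.15 K and summarizes the table.
"""

from netpharm.datasets import djd_docking_table
from netpharm.docking import summarize_docking

records = djd_docking_table()
print(f"{'receptor':8s} {'ligand':14s} {'dG kcal/mol':>12s} {'Ki umol/L':>12s}")
for r in sorted(records, key=lambda r: r.delta_g):
    print(f"{r.receptor:8s} {r.ligand:14s} {r.delta_g:12.2f} {r.ki:12.4g}")

summary = summarize_docking(records)
print(f"\nstable complexes (dG < -5): {summary.n_stable}/{summary.n_records}")
print(f"strongest binding: {summary.min_delta_g} kcal/mol")
for receptor, ligand in sorted(summary.best_ligand_per_receptor.items()):
    print(f"  best ligand for {receptor}: {ligand}")
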