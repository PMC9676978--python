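"""Ranking a molecular-docking affinity table.

Loads the packaged target-compound affinity table (binding free energies in
kcal/mol from a docking run; more negative = more stable complex), ranks it,
and reports each target's best-binding compound.
"""

from herbnet import load_packaged_docking, rank_docking

records = load_packaged_docking()
ranked, best = rank_docking(records, per_target=True)

print(f"{len(ranked)} docking records; global best {ranked[0].affinity} kcal/mol")
print("top of the ranking:")
for r in ranked[:3]:
    print(f"  {r.target:6s} {r.compound:12s} {r.affinity:5.1f} kcal/mol (PDB {r.pdb_id})")
print("per-target best compound:")
for target, r in sorted(best.items()):
    print(f"  {target:6s} -> {r.compound} ({r.affinity} kcal/mol)")
# Three pairs tie at the strongest affinity; ties resolve lexicographically
# so the ranking is deterministic.
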