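"""ADME screening of the packaged herb compound tables.

Loads the two herb ingredient tables shipped with the package and applies
the conventional oral-bioavailability / drug-likeness filter (OB >= 30%,
DL >= 0.18).  The retained rows are the "active components" that move on to
target mapping; a compound listed under both herbs counts once per herb.
"""

from herbnet import AdmeThresholds, filter_compounds, load_packaged_herb

kushen = load_packaged_herb("kushen")
baituling = load_packaged_herb("baituling")
active = filter_compounds(kushen + baituling, AdmeThresholds(ob_min=30, dl_min=0.18))

print(f"kushen rows:    {len(kushen)}")
print(f"baituling rows: {len(baituling)}")
print(f"active components (OB>=30, DL>=0.18): {len(active)}")
boundary = [c for c in active if c.dl == 0.18]
print(f"boundary case kept (DL exactly 0.18): {boundary[0].mol_id} {boundary[0].name}")
# All 58 rows pass because the packaged tables list pre-screened core
# components; the boundary row shows the inclusive comparison at work.
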