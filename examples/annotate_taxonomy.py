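"""Assign taxonomy to metagenome-derived mOTUs by weighted LCA consensus.

Simulates a protein-hit table (query gene, subject lineage, bitscore),
annotates every marker gene with a bitscore-weighted LCA (keep hits at
>=90% of the best bitscore, report the deepest taxon covering >=75% of
the retained bitscore), transfers the best member annotation to each
MGC and forms a per-rank consensus for the mOTU (>=3 annotated MGCs per
rank, consistent if at least half agree).
"""

import tempfile
from pathlib import Path

import motulite as ml
from motulite.simulate import simulate_hit_table
from motulite.taxonomy import annotate_database_motu, read_hit_table

workdir = Path(tempfile.mkdtemp())

simdb = ml.simulate_database(ml.SimConfig(seed=3, n_known=2, n_unknown=3))
hit_path = workdir / "hits.tsv"
simulate_hit_table(simdb, hit_path, seed=3)
hits = read_hit_table(hit_path)

motu_mgcs = {m.id: sorted(m.mgcs.values()) for m in simdb.db.motus.values()}
mgc_members = {m.id: sorted(m.members) for m in simdb.db.mgcs.values()}
annotations = annotate_database_motu(motu_mgcs, mgc_members, hits)

print(f"{'mOTU':>16} {'consistent':>10}  lineage")
for motu_id in sorted(annotations):
    lineage, consistent = annotations[motu_id]
    print(f"{motu_id:>16} {str(consistent):>10}  {lineage}")
print()
print("Each mOTU's lineage is the rank-by-rank plurality of its ten MGC")
print("annotations; 'consistent' means at least half of the annotated MGCs")
print("agreed at every annotated rank. The planted species name reappears")
print("at the species rank because the top protein hit dominates the LCA.")
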