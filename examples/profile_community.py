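"""Profile a simulated metagenomic sample into mOTU relative abundances.

Builds a 20-species marker-gene database (half the species without
reference representation), simulates one error-free sample of 50k paired
inserts, runs the profiling workflow at the default parameters
(-l 100, -g 3) and compares the estimate against the planted truth.
"""

import tempfile
from pathlib import Path

import motulite as ml

workdir = Path(tempfile.mkdtemp())

simdb = ml.simulate_database(ml.SimConfig(seed=42, n_known=10, n_unknown=10))
truth = ml.random_abundances(simdb, seed=42)
sam = workdir / "sample.sam"
motu_truth = ml.simulate_sample(simdb, truth, 50_000, sam, seed=42)

profile = ml.profile_sample(sam, simdb.db, unit="insert.scaled_counts",
                            min_length=100, min_mgcs=3)
predicted = ml.relative_abundance(profile, include_unbinned=True)

pair = ml.BenchmarkPair(truth=motu_truth, predicted=predicted)
precision, recall = ml.precision_recall(pair)

print(f"{'mOTU':>16} {'truth':>8} {'estimate':>9}")
for motu in sorted(motu_truth, key=motu_truth.get, reverse=True):
    print(f"{motu:>16} {motu_truth[motu]:8.4f} {predicted.get(motu, 0.0):9.4f}")
print()
print(f"aligned inserts : {profile.total_aligned_inserts}")
print(f"precision/recall: {precision:.2f} / {recall:.2f}")
print(f"MAE             : {ml.mae(pair):.5f}")
print()
print("Each row is one species-level mOTU; the estimate is the scaled-count")
print("relative abundance recovered from read alignments alone. A MAE of a")
print("few 1e-4 means the profile matches the planted composition almost")
print("exactly; '-1' would collect any marker genes not binned into a mOTU.")
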