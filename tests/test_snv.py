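"""Pileups, the SNV filter cascade and strain-population distances."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from motulite import (
    AlleleFrequencyTable,
    SnvFilterParams,
    call_and_filter,
    centroid_database,
    coverage_summary,
    pileup,
    simulate_strains,
    snv_distances,
)
from motulite.snv import run_snv_workflow


@pytest.fixture(scope="module")
def cdb(toy_db):
    return centroid_database(toy_db)


def perfect_read(db, mg_id, name, pos=0, length=100, flag=0, subst=None):
    mg = db.marker_genes[mg_id]
    seq = list(mg.sequence[pos : pos + length])
    nm = 0
    if subst:
        for offset, base in subst.items():
            if seq[offset] != base:
                nm += 1
            seq[offset] = base
    return (name, flag, mg_id, pos, f"{length}M", "".join(seq), nm, length - 2 * nm)


class TestPileup:
    def test_perfect_reads_count_reference_base(self, cdb, write_sam):
        mg = "m2.COG0012.g"
        sam = write_sam(cdb, [perfect_read(cdb, mg, f"r{i}") for i in range(5)])
        pu = pileup(sam, cdb)
        ref = cdb.marker_genes[mg].coding_sequence
        for pos in range(100):
            assert pu[mg][pos] == {ref[pos]: 5}

    def test_substitution_counted_as_alt(self, cdb, write_sam):
        mg = "m2.COG0012.g"
        ref = cdb.marker_genes[mg].coding_sequence
        alt = "A" if ref[10] != "A" else "C"
        rows = [perfect_read(cdb, mg, f"r{i}") for i in range(4)]
        rows.append(perfect_read(cdb, mg, "r4", subst={10: alt}))
        pu = pileup(write_sam(cdb, rows), cdb)
        assert pu[mg][10] == {ref[10]: 4, alt: 1}

    def test_multiple_flagged_inserts_contribute_nothing(self, cdb, write_sam):
        rows = [
            perfect_read(cdb, "m1.COG0012.g", "multi"),
            perfect_read(cdb, "m2.COG0012.g", "multi"),
        ]
        pu = pileup(write_sam(cdb, rows), cdb)
        assert pu == {}

    def test_padded_positions_excluded(self, cdb, write_sam):
        # m1.COG0012.g has 20 nt padding; align a read across the left edge
        mg = "m1.COG0012.g"
        row = perfect_read(cdb, mg, "edge", pos=0, length=100)
        pu = pileup(write_sam(cdb, [row]), cdb)
        # padded ref positions 0..19 map to no coding position
        assert min(pu[mg]) == 0
        assert max(pu[mg]) == 79  # 100 ref positions - 20 padding


class TestCoverageSummary:
    def test_horizontal_and_vertical(self, cdb, write_sam):
        mg = "m2.COG0012.g"
        rows = [perfect_read(cdb, mg, f"r{i}") for i in range(10)]  # 100/1000 pos
        pileups = {"s1": pileup(write_sam(cdb, rows), cdb)}
        summary = coverage_summary(pileups, cdb)
        # the mOTU pools ten 1000 nt centroids: 100 of 10000 positions covered
        assert summary.horizontal[("s1", "m2")] == pytest.approx(1.0)
        assert summary.vertical[("s1", "m2")] == pytest.approx(10 * 100 / 10_000)

    def test_empty_pileup_is_zero(self, cdb):
        summary = coverage_summary({"s1": {}}, cdb)
        assert summary.horizontal[("s1", "m1")] == 0.0
        assert summary.vertical[("s1", "m1")] == 0.0


def make_pileups(cdb, depths_by_sample, alt_at=None, alt_count=0):
    """Uniform-depth pileups over every centroid of mOTU m2.

    ``alt_at`` plants an alternative allele at one coding position of the
    first centroid with ``alt_count`` of the reads.
    """
    motu = cdb.motus["m2"]
    centroids = sorted(cdb.mgcs[m].centroid for m in motu.mgcs.values())
    pileups = {}
    for sample, depth in depths_by_sample.items():
        pu = {}
        for c in centroids:
            ref = cdb.marker_genes[c].coding_sequence
            per_pos = {}
            for pos in range(len(ref)):
                counts = {ref[pos]: depth}
                if alt_at is not None and c == centroids[0] and pos == alt_at:
                    alt = "A" if ref[pos] != "A" else "C"
                    counts = {ref[pos]: depth - alt_count, alt: alt_count}
                per_pos[pos] = counts
            pu[c] = per_pos
        pileups[sample] = pu
    return pileups


class TestFilterCascade:
    def test_low_horizontal_coverage_drops_sample(self, cdb):
        pileups = make_pileups(cdb, {"good1": 10, "good2": 10}, alt_at=5, alt_count=4)
        # remove 21% of positions from one sample: horizontal 79% < fb=80
        low = make_pileups(cdb, {"low": 10}, alt_at=5, alt_count=4)["low"]
        for c in low:
            n = len(low[c])
            for pos in range(int(0.79 * n), n):
                del low[c][pos]
        pileups["low"] = low
        tables = call_and_filter(pileups, cdb, SnvFilterParams())
        assert "low" not in tables["m2"].frequencies.columns
        assert {"good1", "good2"} <= set(tables["m2"].frequencies.columns)

    def test_min_samples_gate_drops_motu(self, cdb):
        pileups = make_pileups(cdb, {"only": 10}, alt_at=5, alt_count=4)
        tables = call_and_filter(pileups, cdb, SnvFilterParams(fm=2))
        assert "m2" not in tables

    def test_position_prevalence_boundary(self, cdb):
        # depth >= fc in 9 of 10 samples at one position: 0.9 >= fp -> kept
        depths = {f"s{i}": 10 for i in range(10)}
        pileups = make_pileups(cdb, depths, alt_at=7, alt_count=4)
        motu = cdb.motus["m2"]
        first = sorted(cdb.mgcs[m].centroid for m in motu.mgcs.values())[0]
        ref = cdb.marker_genes[first].coding_sequence
        pileups["s9"][first][7] = {ref[7]: 4}  # depth 4 < fc=5 in one sample
        tables = call_and_filter(pileups, cdb, SnvFilterParams())
        assert (first, 7) in {
            (c, p) for c, p, _r, _a in tables["m2"].frequencies.index
        }
        # drop a second sample below fc: 8/10 = 0.8 < 0.9 -> position gone
        pileups["s8"][first][7] = {ref[7]: 4}
        tables = call_and_filter(pileups, cdb, SnvFilterParams())
        assert "m2" not in tables or (first, 7) not in {
            (c, p) for c, p, _r, _a in tables["m2"].frequencies.index
        }

    def test_tightening_filters_never_adds_rows(self, cdb):
        depths = {f"s{i}": 8 for i in range(6)}
        pileups = make_pileups(cdb, depths, alt_at=3, alt_count=3)
        base = call_and_filter(pileups, cdb, SnvFilterParams())
        n_base = sum(len(t.frequencies) for t in base.values())
        for tighter in (
            SnvFilterParams(fb=90), SnvFilterParams(fd=9), SnvFilterParams(fm=7),
            SnvFilterParams(fc=9), SnvFilterParams(fp=1.0),
        ):
            tightened = call_and_filter(pileups, cdb, tighter)
            assert sum(len(t.frequencies) for t in tightened.values()) <= n_base


class TestDistances:
    def make_table(self, values, samples=("a", "b")):
        index = pd.MultiIndex.from_tuples(
            [("c", i, "A", "C") for i in range(len(values))],
            names=["centroid", "pos", "ref", "alt"],
        )
        return AlleleFrequencyTable(
            motu="m", frequencies=pd.DataFrame(values, index=index, columns=samples)
        )

    def test_identical_vectors(self):
        t = self.make_table([[0.2, 0.2], [0.8, 0.8]])
        mann, major = snv_distances(t)
        assert mann.loc["a", "b"] == 0.0
        assert major.loc["a", "b"] == 0.0

    def test_two_position_worked_example(self):
        t = self.make_table([[0.9, 0.2], [0.3, 0.2]])  # diffs 0.7 and 0.1
        mann, major = snv_distances(t)
        assert mann.loc["a", "b"] == pytest.approx(0.8)
        assert major.loc["a", "b"] == pytest.approx(0.5)

    def test_opposite_vectors_maximal(self):
        t = self.make_table([[0.0, 1.0], [1.0, 0.0]])
        mann, major = snv_distances(t)
        assert mann.loc["a", "b"] == pytest.approx(2.0)
        assert major.loc["a", "b"] == pytest.approx(1.0)

    def test_missing_cells_excluded_pairwise(self):
        t = self.make_table([[0.9, np.nan], [0.3, 0.2]])
        mann, _ = snv_distances(t)
        assert mann.loc["a", "b"] == pytest.approx(0.1)

    def test_no_shared_positions_is_nan(self):
        t = self.make_table([[0.9, np.nan], [np.nan, 0.2]])
        mann, major = snv_distances(t)
        assert np.isnan(mann.loc["a", "b"]) and np.isnan(major.loc["a", "b"])

    def test_manhattan_triangle_inequality(self):
        rng = np.random.default_rng(2)
        t = self.make_table(rng.random((20, 3)), samples=("a", "b", "c"))
        mann, _ = snv_distances(t)
        for x, y, z in itertools.permutations(("a", "b", "c")):
            assert mann.loc[x, z] <= mann.loc[x, y] + mann.loc[y, z] + 1e-12


class TestStrainConcordance:
    def test_mg_distances_track_whole_genome_truth(self, simdb, tmp_path):
        """Marker-gene SNV distances correlate with genome-wide distances."""
        cdb = centroid_database(simdb.db)
        sim = simulate_strains(
            simdb, simdb.species[0], tmp_path, n_samples=10, n_inserts=2000, seed=8
        )
        _, _tables, distances = run_snv_workflow(
            {s: p for s, p in sim.sam_paths.items()}, cdb, out_dir=tmp_path / "out"
        )
        motu = simdb.species_motu[simdb.species[0]]
        mann, _major = distances[motu]
        est, true = [], []
        for a, b in itertools.combinations(mann.index, 2):
            est.append(mann.loc[a, b])
            true.append(sim.true_manhattan.loc[a, b])
        r = np.corrcoef(est, true)[0, 1]
        assert r > 0.9

    def test_pure_strain_self_distance_zero(self, simdb, tmp_path):
        sim = simulate_strains(
            simdb, simdb.species[0], tmp_path, n_samples=2,
            proportions=[0.0, 0.0], n_inserts=1500, seed=9,
        )
        assert sim.true_manhattan.values.max() == 0.0

    def test_output_layout(self, simdb, tmp_path):
        cdb = centroid_database(simdb.db)
        sim = simulate_strains(
            simdb, simdb.species[1], tmp_path, n_samples=3, n_inserts=1500, seed=10
        )
        out = tmp_path / "layout"
        run_snv_workflow({s: p for s, p in sim.sam_paths.items()}, cdb, out_dir=out)
        assert (out / "snv.cov.tab").exists()
        assert (out / "snv.perc.tab").exists()
        assert (out / "snv.log").exists()
        assert (out / "filtered-snv").is_dir()
        assert (out / "distances-snv").is_dir()
        mann_files = list((out / "distances-snv").glob("*.mann.dist"))
        allele_files = list((out / "distances-snv").glob("*.allele.dist"))
        assert len(mann_files) == len(allele_files) >= 1
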