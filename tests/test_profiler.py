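"""Alignment filtering, insert assignment and abundance computation."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motulite import (
    assign_inserts,
    mgc_base_coverage,
    mgc_insert_counts,
    motu_profile,
    parse_and_filter,
    profile_sample,
    relative_abundance,
    scale_counts,
)
from motulite.datamodel import UNBINNED
from motulite.profiler import InsertAssignment, SamFormatError

SEQ100 = "A" * 100


def _row(qname, flag, rname, cigar="100M", nm=0, score=None, pos0=0, seq=SEQ100):
    if score is None:
        score = sum(
            int(n) for n, op in _cigar_items(cigar) if op in "M=X"
        ) - 2 * nm
    return (qname, flag, rname, pos0, cigar, seq, nm, score)


def _cigar_items(cigar):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield num, c
            num = ""


class TestParseAndFilter:
    def test_identity_boundary(self, toy_db, write_sam):
        mg = "m1.COG0016.g"
        sam = write_sam(toy_db, [
            _row("r1", 0, mg, nm=3),   # 97/100 = 0.97: retained
            _row("r2", 0, mg, nm=4),   # 0.96: discarded
        ])
        records = parse_and_filter(sam)
        assert [r.insert_id for r in records] == ["r1"]
        assert records[0].identity == pytest.approx(0.97)

    def test_length_boundary(self, toy_db, write_sam):
        mg = "m1.COG0016.g"
        sam = write_sam(toy_db, [
            _row("short", 0, mg, cigar="74M", seq="A" * 74),  # perfect but 74 nt
            _row("ok", 0, mg, cigar="75M", seq="A" * 75),
        ])
        assert [r.insert_id for r in parse_and_filter(sam)] == ["ok"]

    def test_soft_clips_excluded_from_aligned_length(self, toy_db, write_sam):
        mg = "m1.COG0016.g"
        sam = write_sam(toy_db, [_row("r", 0, mg, cigar="10S80M10S")])
        (rec,) = parse_and_filter(sam)
        assert rec.aligned_length == 80

    def test_missing_nm_and_md_is_hard_error(self, toy_db, write_sam, tmp_path):
        mg = "m1.COG0016.g"
        path = write_sam(toy_db, [])
        bad = path.read_text() + f"noNM\t0\t{mg}\t1\t60\t100M\t*\t0\t0\t{SEQ100}\t*\n"
        (tmp_path / "bad.sam").write_text(bad)
        with pytest.raises(SamFormatError, match="noNM"):
            parse_and_filter(tmp_path / "bad.sam")

    def test_md_fallback(self, toy_db, write_sam, tmp_path):
        mg = "m1.COG0016.g"
        path = write_sam(toy_db, [])
        text = path.read_text() + (
            f"mdread\t0\t{mg}\t1\t60\t100M\t*\t0\t0\t{SEQ100}\t*\tMD:Z:50A24C24\n"
        )
        (tmp_path / "md.sam").write_text(text)
        (rec,) = parse_and_filter(tmp_path / "md.sam")
        assert rec.identity == pytest.approx(0.98)

    @pytest.mark.parametrize("param,tighter", [("min_identity", 0.99), ("min_length", 120)])
    def test_tightening_filters_is_monotone(self, simdb, tmp_path, param, tighter):
        """Raising a filter threshold only removes alignments, so the unique
        alignment profile and the total assigned inserts never increase.
        (A redistributed count of an individual MGC may rise when a tied
        insert loses one of its targets and becomes unique.)"""
        from motulite import simulate_sample, random_abundances

        truth = random_abundances(simdb, seed=3)
        sam = tmp_path / "mono.sam"
        simulate_sample(simdb, truth, 2000, sam, seed=3, error_rate=0.005)
        loose_records = parse_and_filter(sam)
        tight_records = parse_and_filter(sam, **{param: tighter})
        key = lambda r: (r.insert_id, r.mate, r.target_mg, r.aligned_ref_span)
        assert {key(r) for r in tight_records} <= {key(r) for r in loose_records}

        loose_assign = assign_inserts(loose_records, simdb.db)
        tight_assign = assign_inserts(tight_records, simdb.db)
        assert len(tight_assign) <= len(loose_assign)

        def unique_counts(assignments):
            out = {}
            for a in assignments:
                if a.flag == "unique":
                    (t,) = a.best_targets
                    out[t] = out.get(t, 0) + 1
            return out

        loose_u, tight_u = unique_counts(loose_assign), unique_counts(tight_assign)
        # with error-free simulated reads the best target never changes, so
        # uniques can only disappear, never move between MGCs
        clean = tmp_path / "clean.sam"
        simulate_sample(simdb, truth, 2000, clean, seed=3, error_rate=0.0)
        c_loose = mgc_insert_counts(assign_inserts(parse_and_filter(clean), simdb.db))
        c_tight = mgc_insert_counts(
            assign_inserts(parse_and_filter(clean, **{param: tighter}), simdb.db)
        )
        for mgc, v in c_tight.items():
            assert v <= c_loose.get(mgc, 0.0) + 1e-9


class TestAssignInserts:
    def test_pair_summed_scores_pick_unique_best(self, toy_db, write_sam):
        sam = write_sam(toy_db, [
            _row("ins", 0x1 | 0x40, "m1.COG0016.g", score=60),
            _row("ins", 0x1 | 0x80, "m1.COG0016.g", score=60),
            _row("ins", 0x1 | 0x40, "m2.COG0016.g", score=50),
        ])
        (a,) = assign_inserts(parse_and_filter(sam), toy_db)
        assert a.best_targets == frozenset({"m1.COG0016"})
        assert a.flag == "unique"
        assert a.insert_score == 120

    def test_equal_best_score_flags_multiple(self, toy_db, write_sam):
        sam = write_sam(toy_db, [
            _row("ins", 0x1 | 0x40, "m1.COG0016.g", score=60),
            _row("ins", 0x1 | 0x40, "m2.COG0016.g", score=60),
        ])
        (a,) = assign_inserts(parse_and_filter(sam), toy_db)
        assert a.flag == "multiple"
        assert len(a.best_targets) == 2

    def test_single_end_single_hit_is_unique(self, toy_db, write_sam):
        sam = write_sam(toy_db, [_row("se", 0, "m2.COG0012.g")])
        (a,) = assign_inserts(parse_and_filter(sam), toy_db)
        assert a.flag == "unique"

    def test_mates_on_different_members_count_as_one_target(self, simdb, write_sam):
        # pick an MGC with >= 2 members
        mgc = next(m for m in simdb.db.mgcs.values() if len(m.members) >= 2)
        m1, m2 = sorted(mgc.members)[:2]
        seq = "A" * 100
        sam = write_sam(simdb.db, [
            ("ins", 0x1 | 0x40, m1, 0, "100M", seq, 0, 100),
            ("ins", 0x1 | 0x80, m2, 0, "100M", seq, 0, 100),
        ])
        (a,) = assign_inserts(parse_and_filter(sam), simdb.db)
        assert a.best_targets == frozenset({mgc.id})
        assert a.flag == "unique"
        assert a.insert_score == 200


def brute_force_counts(assignments: list[InsertAssignment]) -> dict[str, float]:
    """Oracle: materialise every insert's fractional share explicitly."""
    unique: dict[str, float] = {}
    for a in assignments:
        if a.flag == "unique":
            (t,) = a.best_targets
            unique[t] = unique.get(t, 0) + 1
    totals: dict[str, float] = {}
    for a in assignments:
        targets = sorted(a.best_targets)
        if a.flag == "unique":
            shares = {targets[0]: 1.0}
        else:
            denom = sum(unique.get(t, 0) for t in targets)
            if denom == 0:
                shares = {t: 1 / len(targets) for t in targets}
            else:
                shares = {t: unique.get(t, 0) / denom for t in targets}
        for t, s in shares.items():
            totals[t] = totals.get(t, 0.0) + s
    return totals


def random_assignments(rng: random.Random, n_mgcs: int = 6) -> list[InsertAssignment]:
    mgcs = [f"M{i}" for i in range(n_mgcs)]
    out = []
    for i in range(rng.randint(1, 20)):
        k = rng.choice([1, 1, 1, 2, 2, 3])
        targets = frozenset(rng.sample(mgcs, k))
        out.append(InsertAssignment(
            insert_id=f"i{i}", best_targets=targets,
            flag="unique" if k == 1 else "multiple", insert_score=100,
        ))
    return out


class TestRedistribution:
    def test_worked_example(self):
        """unique A=3, B=1 plus 4 inserts tied A/B: A gets 3+3, B gets 1+1."""
        assignments = (
            [InsertAssignment(f"u{i}", frozenset({"A"}), "unique", 1) for i in range(3)]
            + [InsertAssignment("u3", frozenset({"B"}), "unique", 1)]
            + [InsertAssignment(f"m{i}", frozenset({"A", "B"}), "multiple", 1)
               for i in range(4)]
        )
        counts = mgc_insert_counts(assignments)
        assert counts == pytest.approx({"A": 6.0, "B": 2.0})

    def test_all_zero_uniques_split_uniformly(self):
        (a,) = [InsertAssignment("m", frozenset({"A", "B"}), "multiple", 1)]
        assert mgc_insert_counts([a]) == pytest.approx({"A": 0.5, "B": 0.5})

    def test_no_multiples_equals_unique_profile(self):
        assignments = [
            InsertAssignment(f"u{i}", frozenset({"A"}), "unique", 1) for i in range(5)
        ]
        assert mgc_insert_counts(assignments) == {"A": 5.0}

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        assignments = random_assignments(rng)
        got = mgc_insert_counts(assignments)
        want = brute_force_counts(assignments)
        assert set(got) == set(want)
        for k in got:
            assert got[k] == pytest.approx(want[k])

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, seed):
        """Counts always sum exactly to the number of assigned inserts."""
        assignments = random_assignments(random.Random(seed))
        assert sum(mgc_insert_counts(assignments).values()) == pytest.approx(
            len(assignments)
        )


class TestAbundanceUnits:
    def test_base_coverage_arithmetic(self, toy_db, write_sam):
        # 10 single-end perfect reads x 200 aligned bases on a 1000 nt gene
        rows = [
            (f"r{i}", 0, "m1.COG0012.g", 0, "200M", "A" * 200, 0, 200)
            for i in range(10)
        ]
        sam = write_sam(toy_db, rows)
        cov = mgc_base_coverage(assign_inserts(parse_and_filter(sam), toy_db), toy_db)
        assert cov["m1.COG0012"] == pytest.approx(2.0)

    def test_coverage_linear_in_depth(self, toy_db, write_sam):
        def rows(n):
            return [(f"r{i}", 0, "m1.COG0012.g", 0, "200M", "A" * 200, 0, 200)
                    for i in range(n)]

        cov1 = mgc_base_coverage(
            assign_inserts(parse_and_filter(write_sam(toy_db, rows(4), "a.sam")), toy_db),
            toy_db,
        )
        cov2 = mgc_base_coverage(
            assign_inserts(parse_and_filter(write_sam(toy_db, rows(8), "b.sam")), toy_db),
            toy_db,
        )
        assert cov2["m1.COG0012"] == pytest.approx(2 * cov1["m1.COG0012"])

    def test_motu_median_of_detected(self, toy_db):
        mgc_values = {f"m1.{c}": v for c, v in zip(
            ["COG0012", "COG0016", "COG0018"], [2.0, 4.0, 6.0])}
        prof = motu_profile(mgc_values, toy_db, "base.coverage", 0, min_mgcs=3)
        assert prof.motu_values["m1"] == pytest.approx(4.0)
        assert prof.motu_values["m2"] == 0.0

    def test_min_mgcs_gate(self, toy_db):
        mgc_values = {"m1.COG0012": 2.0, "m1.COG0016": 4.0}
        prof = motu_profile(mgc_values, toy_db, "base.coverage", 0, min_mgcs=3)
        assert prof.motu_values["m1"] == 0.0

    def test_unbinned_median_of_cog_sums(self, simdb):
        # two unbinned MGCs of different COGs at 5.0 -> 8 zero sums, median 0;
        # all ten COGs at 5.0 -> median 5.0
        unbinned = sorted(simdb.db.unbinned_mgcs)
        values = {m: 5.0 for m in unbinned}
        prof = motu_profile(values, simdb.db, "base.coverage", 0)
        assert prof.motu_values[UNBINNED] == pytest.approx(5.0)
        two = {m: 5.0 for m in unbinned[:2]}
        prof2 = motu_profile(two, simdb.db, "base.coverage", 0)
        assert prof2.motu_values[UNBINNED] == 0.0

    def test_scale_counts_proportional(self, toy_db):
        prof = motu_profile({"m1.COG0012": 1.0}, toy_db, "base.coverage", 40)
        prof.motu_values = {"m1": 2.0, "m2": 6.0, UNBINNED: 0.0}
        scaled = scale_counts(prof, 40)
        assert scaled.motu_values["m1"] == pytest.approx(10.0)
        assert scaled.motu_values["m2"] == pytest.approx(30.0)
        assert sum(scaled.motu_values.values()) == pytest.approx(40.0)

    def test_scale_counts_inconsistent_inputs(self, toy_db):
        prof = motu_profile({}, toy_db, "base.coverage", 10)
        with pytest.raises(ValueError, match="zero total coverage"):
            scale_counts(prof, 10)

    def test_relative_abundance_renormalization(self, toy_db):
        prof = motu_profile({}, toy_db, "base.coverage", 100)
        prof.unit = "insert.scaled_counts"
        prof.motu_values = {"m1": 30.0, "m2": 10.0, UNBINNED: 60.0}
        incl = relative_abundance(prof, include_unbinned=True)
        assert incl == pytest.approx({"m1": 0.3, "m2": 0.1, UNBINNED: 0.6})
        excl = relative_abundance(prof, include_unbinned=False)
        assert excl == pytest.approx({"m1": 0.75, "m2": 0.25})

    def test_exclude_equals_include_when_unbinned_zero(self, toy_db):
        prof = motu_profile({}, toy_db, "base.coverage", 100)
        prof.unit = "insert.scaled_counts"
        prof.motu_values = {"m1": 30.0, "m2": 10.0, UNBINNED: 0.0}
        incl = relative_abundance(prof, include_unbinned=True)
        excl = relative_abundance(prof, include_unbinned=False)
        assert excl == pytest.approx({k: v for k, v in incl.items() if k != UNBINNED})


class TestEndToEnd:
    def test_raw_counts_are_integers(self, simdb, tmp_path):
        from motulite import simulate_sample, random_abundances

        truth = random_abundances(simdb, seed=5)
        sam = tmp_path / "s.sam"
        simulate_sample(simdb, truth, 3000, sam, seed=5)
        prof = profile_sample(sam, simdb.db, unit="insert.raw_counts")
        assert all(v == int(v) for v in prof.motu_values.values())

    def test_scaled_counts_conservation(self, simdb, tmp_path):
        from motulite import simulate_sample, random_abundances

        truth = random_abundances(simdb, seed=6)
        sam = tmp_path / "s.sam"
        simulate_sample(simdb, truth, 3000, sam, seed=6)
        prof = profile_sample(sam, simdb.db, unit="insert.scaled_counts")
        assert sum(prof.motu_values.values()) == pytest.approx(
            prof.total_aligned_inserts, abs=1e-6
        )
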