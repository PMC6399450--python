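"""Shared fixtures: a small planted database and hand-written SAM helpers."""

from __future__ import annotations

from pathlib import Path

import pytest

from motulite import SimConfig, simulate_database
from motulite.datamodel import (
    MGC,
    MOTU,
    MarkerGene,
    ProfileDatabase,
    TaxonLineage,
)


@pytest.fixture(scope="session")
def simdb():
    """Planted database: 3 ref + 2 meta species, 1 unbinned species."""
    return simulate_database(SimConfig(seed=11, n_known=3, n_unknown=2, n_unbinned=1))


@pytest.fixture(scope="session")
def toy_db():
    """Hand-built 2-species database with single-member MGCs.

    Each species has 10 MGCs (one per COG); gene A of species 1 carries
    20 nt of padding on each side so padding handling is exercised.
    """
    from motulite.datamodel import COG_TYPES

    rng_seq = "ACGT" * 300  # deterministic filler
    marker_genes, mgcs, motu_mgcs = {}, {}, {"m1": {}, "m2": {}}
    for si, motu in enumerate(("m1", "m2")):
        for ci, cog in enumerate(COG_TYPES):
            mg_id = f"{motu}.{cog}.g"
            pad = 20 if (si == 0 and ci == 0) else 0
            seq = rng_seq[: 1000 + 2 * pad]
            marker_genes[mg_id] = MarkerGene(
                id=mg_id, cog_type=cog, source="reference",
                sequence=seq, coding_span=(pad, pad + 1000),
            )
            mgc_id = f"{motu}.{cog}"
            mgcs[mgc_id] = MGC(
                id=mgc_id, cog_type=cog, members={mg_id},
                centroid=mg_id, kind="ref", motu=motu,
            )
            motu_mgcs[motu][cog] = mgc_id
    motus = {
        m: MOTU(id=m, kind="ref", mgcs=motu_mgcs[m],
                taxonomy=TaxonLineage(("Bacteria",)))
        for m in ("m1", "m2")
    }
    return ProfileDatabase(marker_genes, mgcs, motus, set())


def sam_text(db: ProfileDatabase, rows: list[tuple]) -> str:
    """Render SAM text for ``(qname, flag, rname, pos0, cigar, seq, nm, as)`` rows."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for mg in sorted(db.marker_genes.values(), key=lambda m: m.id):
        lines.append(f"@SQ\tSN:{mg.id}\tLN:{len(mg.sequence)}")
    for qname, flag, rname, pos0, cigar, seq, nm, score in rows:
        lines.append(
            f"{qname}\t{flag}\t{rname}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0"
            f"\t{seq}\t*\tNM:i:{nm}\tAS:i:{score}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_sam(tmp_path: Path):
    """Factory writing hand-crafted SAM rows for a database to a temp file."""

    def _write(db: ProfileDatabase, rows: list[tuple], name: str = "test.sam") -> Path:
        path = tmp_path / name
        path.write_text(sam_text(db, rows))
        return path

    return _write
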