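"""Core domain types and database I/O for marker-gene OTU profiling.

The database is a three-level hierarchy:

* **Marker gene (MG)** — a nucleotide sequence of one of ten universal,
  single-copy, protein-coding gene families (COGs), optionally padded with
  up to 100 nt of flanking sequence on each side to reduce mapping
  artefacts at gene boundaries.
* **Marker gene cluster (MGC)** — a species-level cluster of MG sequences
  of a single COG type, represented by a centroid (medoid) member.
* **mOTU** — a species-level operational taxonomic unit: a bin of 6–10
  MGCs, at most one per COG type.  MGCs not binned into any mOTU are
  tracked in a pooled "unbinned" group written as ``-1`` in profiles.

On disk a database is a nucleotide FASTA (the padded MG sequences) plus a
single tab-separated manifest mapping every MG to its COG type, source,
MGC, mOTU, coding-segment coordinates and taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The ten COG families usable for metagenomic marker-gene profiling.
COG_TYPES: tuple[str, ...] = (
    "COG0012", "COG0016", "COG0018", "COG0172", "COG0215",
    "COG0495", "COG0525", "COG0533", "COG0541", "COG0552",
)

#: Canonical rank order, domain-to-species.
RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)

UNBINNED = "-1"

MAX_PADDING = 100


class DatabaseError(ValueError):
    """Raised when a marker-gene database violates a structural invariant."""


@dataclass(frozen=True)
class TaxonLineage:
    """A ranked lineage from domain to species, possibly truncated.

    ``names`` holds taxon names positionally aligned with :data:`RANKS`;
    a lineage annotated down to genus has ``len(names) == 6``.
    """

    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) > len(RANKS):
            raise ValueError(f"lineage deeper than {len(RANKS)} ranks: {self.names}")
        if any(not n for n in self.names):
            raise ValueError(f"lineage has a gap: {self.names}")

    @classmethod
    def from_string(cls, text: str) -> "TaxonLineage":
        """Parse a semicolon-separated lineage, e.g. ``Bacteria;Firmicutes``."""
        text = text.strip()
        if not text or text == "NA":
            return cls(())
        return cls(tuple(part.strip() for part in text.split(";")))

    def __str__(self) -> str:
        return ";".join(self.names) if self.names else "NA"

    def __len__(self) -> int:
        return len(self.names)

    @property
    def deepest_rank(self) -> str | None:
        return RANKS[len(self.names) - 1] if self.names else None

    def at_rank(self, rank: str) -> str | None:
        """Name at ``rank``, or None if the lineage stops above it."""
        i = RANKS.index(rank)
        return self.names[i] if i < len(self.names) else None

    def truncated(self, depth: int) -> "TaxonLineage":
        return TaxonLineage(self.names[:depth])

    def is_ancestor_of(self, other: "TaxonLineage") -> bool:
        return other.names[: len(self.names)] == self.names


@dataclass
class MarkerGene:
    id: str
    cog_type: str
    source: str  # "reference" | "metagenome"
    sequence: str
    coding_span: tuple[int, int]  # 0-based half-open, within the padded sequence

    def __post_init__(self) -> None:
        if self.cog_type not in COG_TYPES:
            raise DatabaseError(f"MG {self.id}: unknown COG type {self.cog_type!r}")
        if self.source not in ("reference", "metagenome"):
            raise DatabaseError(f"MG {self.id}: bad source {self.source!r}")
        start, end = self.coding_span
        if not (0 <= start < end <= len(self.sequence)):
            raise DatabaseError(f"MG {self.id}: coding span {self.coding_span} outside sequence")
        if start > MAX_PADDING or len(self.sequence) - end > MAX_PADDING:
            raise DatabaseError(f"MG {self.id}: padding exceeds {MAX_PADDING} nt per side")

    @property
    def length(self) -> int:
        """Length of the coding region in nt (padding excluded)."""
        return self.coding_span[1] - self.coding_span[0]

    @property
    def coding_sequence(self) -> str:
        return self.sequence[self.coding_span[0] : self.coding_span[1]]


@dataclass
class MGC:
    id: str
    cog_type: str
    members: set[str]
    centroid: str
    kind: str  # "ref" | "meta"
    motu: str  # mOTU id, or UNBINNED

    def __post_init__(self) -> None:
        if not self.members:
            raise DatabaseError(f"MGC {self.id}: empty")
        if self.centroid not in self.members:
            raise DatabaseError(f"MGC {self.id}: centroid {self.centroid} not a member")
        if self.kind not in ("ref", "meta"):
            raise DatabaseError(f"MGC {self.id}: bad kind {self.kind!r}")


@dataclass
class MOTU:
    id: str
    kind: str  # "ref" | "meta"
    mgcs: dict[str, str]  # cog_type -> MGC id
    taxonomy: TaxonLineage = field(default_factory=TaxonLineage)

    def __post_init__(self) -> None:
        if not 6 <= len(self.mgcs) <= 10:
            raise DatabaseError(
                f"mOTU {self.id}: has {len(self.mgcs)} MGCs, need 6-10"
            )
        if self.kind not in ("ref", "meta"):
            raise DatabaseError(f"mOTU {self.id}: bad kind {self.kind!r}")


@dataclass
class ProfileDatabase:
    """Keyed collections of marker genes, MGCs and mOTUs plus the unbinned set."""

    marker_genes: dict[str, MarkerGene]
    mgcs: dict[str, MGC]
    motus: dict[str, MOTU]
    unbinned_mgcs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errors: list[str] = []
        for mgc in self.mgcs.values():
            for mg_id in mgc.members:
                mg = self.marker_genes.get(mg_id)
                if mg is None:
                    errors.append(f"MGC {mgc.id}: dangling member {mg_id}")
                elif mg.cog_type != mgc.cog_type:
                    errors.append(
                        f"MGC {mgc.id}: member {mg_id} has COG {mg.cog_type}, "
                        f"cluster is {mgc.cog_type}"
                    )
            if mgc.motu == UNBINNED:
                if mgc.id not in self.unbinned_mgcs:
                    errors.append(f"MGC {mgc.id}: unbinned but not in unbinned set")
            elif mgc.motu not in self.motus:
                errors.append(f"MGC {mgc.id}: dangling mOTU pointer {mgc.motu}")
            elif self.motus[mgc.motu].mgcs.get(mgc.cog_type) != mgc.id:
                errors.append(f"MGC {mgc.id}: mOTU {mgc.motu} does not list it")
        for motu in self.motus.values():
            for cog, mgc_id in motu.mgcs.items():
                mgc = self.mgcs.get(mgc_id)
                if mgc is None:
                    errors.append(f"mOTU {motu.id}: dangling MGC {mgc_id}")
                elif mgc.cog_type != cog:
                    errors.append(f"mOTU {motu.id}: MGC {mgc_id} listed under wrong COG")
                elif mgc.motu != motu.id:
                    errors.append(f"mOTU {motu.id}: MGC {mgc_id} points elsewhere")
            if motu.kind == "ref" and not any(
                self.mgcs[m].kind == "ref" for m in motu.mgcs.values() if m in self.mgcs
            ):
                errors.append(f"mOTU {motu.id}: ref-mOTU without a ref MGC")
        for mgc_id in self.unbinned_mgcs:
            if mgc_id not in self.mgcs:
                errors.append(f"unbinned set: dangling MGC {mgc_id}")
            elif self.mgcs[mgc_id].motu != UNBINNED:
                errors.append(f"unbinned set: MGC {mgc_id} is binned")
        if errors:
            raise DatabaseError("; ".join(errors))

    def mgc_of_mg(self) -> dict[str, str]:
        """Map every marker-gene id to its MGC id."""
        out: dict[str, str] = {}
        for mgc in self.mgcs.values():
            for mg_id in mgc.members:
                out[mg_id] = mgc.id
        return out

    def centroid_length(self, mgc_id: str) -> int:
        """Coding length (nt) of an MGC's centroid sequence."""
        return self.marker_genes[self.mgcs[mgc_id].centroid].length


# ---------------------------------------------------------------------------
# database I/O

MANIFEST_COLUMNS = (
    "mg_id", "cog", "source", "mgc_id", "motu_id",
    "coding_start", "coding_end", "taxonomy",
)


def read_database(fasta_path: str | Path, manifest_path: str | Path) -> ProfileDatabase:
    """Load a marker-gene database from a FASTA + TSV manifest pair.

    The manifest is tab-separated with a ``#``-prefixed header line naming
    the columns in :data:`MANIFEST_COLUMNS`; mOTU column ``-1`` marks an
    unbinned MGC.  All structural invariants (unique ids, one COG per MGC,
    6-10 MGCs per mOTU, referential closure) are checked on load.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise DatabaseError(f"duplicated FASTA id {rec.id}")
        sequences[rec.id] = str(rec.seq).upper()

    rows: list[dict[str, str]] = []
    with open(manifest_path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip().split("\t")
                continue
            if header is None:
                raise DatabaseError("manifest lacks a '#'-prefixed header line")
            rows.append(dict(zip(header, line.split("\t"), strict=True)))
    missing = set(MANIFEST_COLUMNS) - (set(rows[0]) if rows else set(MANIFEST_COLUMNS))
    if missing:
        raise DatabaseError(f"manifest missing columns: {sorted(missing)}")

    marker_genes: dict[str, MarkerGene] = {}
    mgc_rows: dict[str, list[dict[str, str]]] = {}
    for row in rows:
        mg_id = row["mg_id"]
        if mg_id in marker_genes:
            raise DatabaseError(f"duplicated MG id {mg_id} in manifest")
        if mg_id not in sequences:
            raise DatabaseError(f"MG {mg_id} missing from FASTA")
        marker_genes[mg_id] = MarkerGene(
            id=mg_id,
            cog_type=row["cog"],
            source=row["source"],
            sequence=sequences[mg_id],
            coding_span=(int(row["coding_start"]), int(row["coding_end"])),
        )
        mgc_rows.setdefault(row["mgc_id"], []).append(row)
    extra = set(sequences) - set(marker_genes)
    if extra:
        raise DatabaseError(f"FASTA ids absent from manifest: {sorted(extra)[:5]}")

    mgcs: dict[str, MGC] = {}
    motu_mgcs: dict[str, dict[str, str]] = {}
    motu_taxonomy: dict[str, TaxonLineage] = {}
    unbinned: set[str] = set()
    for mgc_id, members in mgc_rows.items():
        cogs = {r["cog"] for r in members}
        if len(cogs) > 1:
            raise DatabaseError(f"MGC {mgc_id} spans COG types {sorted(cogs)}")
        motus_here = {r["motu_id"] for r in members}
        if len(motus_here) > 1:
            raise DatabaseError(f"MGC {mgc_id} listed under several mOTUs {sorted(motus_here)}")
        motu_id = motus_here.pop()
        kind = "ref" if any(r["source"] == "reference" for r in members) else "meta"
        member_ids = {r["mg_id"] for r in members}
        centroid = pick_manifest_centroid(member_ids)
        mgcs[mgc_id] = MGC(
            id=mgc_id, cog_type=cogs.pop(), members=member_ids,
            centroid=centroid, kind=kind, motu=motu_id,
        )
        if motu_id == UNBINNED:
            unbinned.add(mgc_id)
        else:
            motu_mgcs.setdefault(motu_id, {})[mgcs[mgc_id].cog_type] = mgc_id
            motu_taxonomy.setdefault(
                motu_id, TaxonLineage.from_string(members[0]["taxonomy"])
            )

    motus = {
        motu_id: MOTU(
            id=motu_id,
            kind="ref" if any(mgcs[m].kind == "ref" for m in cog_map.values()) else "meta",
            mgcs=cog_map,
            taxonomy=motu_taxonomy[motu_id],
        )
        for motu_id, cog_map in motu_mgcs.items()
    }
    return ProfileDatabase(marker_genes, mgcs, motus, unbinned)


def pick_manifest_centroid(member_ids: Iterable[str]) -> str:
    """Centroid convention for manifests: lexicographically smallest member.

    Databases built by the clusterer store a medoid picked by mean identity
    (see :func:`motulite.clusterer.pick_centroid`); manifests written by
    :func:`write_database` list members in sorted order with the centroid
    first, so the two conventions round-trip.
    """
    return min(member_ids)


def write_database(db: ProfileDatabase, fasta_path: str | Path, manifest_path: str | Path) -> None:
    """Write the FASTA + manifest pair in canonical (sorted-by-id) order."""
    mgc_of = db.mgc_of_mg()
    records = [
        SeqRecord(Seq(mg.sequence), id=mg.id, description="")
        for mg in sorted(db.marker_genes.values(), key=lambda m: m.id)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(manifest_path, "w") as fh:
        fh.write("#" + "\t".join(MANIFEST_COLUMNS) + "\n")
        for mg in sorted(db.marker_genes.values(), key=lambda m: m.id):
            mgc = db.mgcs[mgc_of[mg.id]]
            taxonomy = (
                db.motus[mgc.motu].taxonomy if mgc.motu != UNBINNED else TaxonLineage(())
            )
            fh.write(
                "\t".join(
                    [
                        mg.id, mg.cog_type, mg.source, mgc.id, mgc.motu,
                        str(mg.coding_span[0]), str(mg.coding_span[1]), str(taxonomy),
                    ]
                )
                + "\n"
            )


def centroid_database(db: ProfileDatabase) -> ProfileDatabase:
    """Reduce the database to one (centroid) sequence per MGC.

    The MGC/mOTU structure is unchanged; this is the reference set used
    for SNV calling, where variants are identified against a single
    representative sequence per cluster.
    """
    marker_genes = {}
    mgcs = {}
    for mgc in db.mgcs.values():
        marker_genes[mgc.centroid] = db.marker_genes[mgc.centroid]
        mgcs[mgc.id] = replace(mgc, members={mgc.centroid})
    return ProfileDatabase(
        marker_genes, mgcs, {m.id: replace(m) for m in db.motus.values()},
        set(db.unbinned_mgcs),
    )
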