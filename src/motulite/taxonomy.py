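"""Taxonomic annotation of marker genes, MGCs and metagenomic mOTUs.

A marker gene is annotated from its protein-database hits by a
bitscore-weighted lowest-common-ancestor (LCA) rule: hits within 90% of
the top bitscore are retained, and walking from species upward the
deepest taxon whose retained hits cover at least 75% of the summed
bitscore is reported.  MGCs inherit the lineage of their best-scoring
member.  A metagenomic mOTU is annotated per rank by the plurality name
of its MGC lineages, requiring at least three MGCs annotated at the rank,
and is flagged consistent when at least half of the annotated MGCs agree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .datamodel import RANKS, TaxonLineage


@dataclass(frozen=True)
class ProteinHit:
    query_mg: str
    subject_lineage: TaxonLineage
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore <= 0:
            raise ValueError(f"hit for {self.query_mg}: bitscore must be positive")


def weighted_lca(
    hits: Sequence[ProteinHit], keep_frac: float = 0.90, cover_frac: float = 0.75
) -> TaxonLineage:
    """Bitscore-weighted LCA of a marker gene's protein hits.

    Hits scoring at least ``keep_frac`` of the best bitscore are retained.
    Walking from the species rank upward, the deepest taxon whose summed
    retained bitscore reaches ``cover_frac`` of the retained total is
    returned; hits whose lineage stops above a rank do not contribute at
    that rank (but still count toward the total, excluding outliers).
    """
    if not hits:
        return TaxonLineage(())
    best = max(h.bitscore for h in hits)
    retained = [h for h in hits if h.bitscore >= keep_frac * best]
    total = sum(h.bitscore for h in retained)
    for depth in range(len(RANKS), 0, -1):
        coverage: dict[tuple[str, ...], float] = {}
        for h in retained:
            if len(h.subject_lineage) >= depth:
                prefix = h.subject_lineage.names[:depth]
                coverage[prefix] = coverage.get(prefix, 0.0) + h.bitscore
        if not coverage:
            continue
        prefix, score = min(coverage.items(), key=lambda kv: (-kv[1], kv[0]))
        if score >= cover_frac * total:
            return TaxonLineage(prefix)
    return TaxonLineage(())


def annotate_mgc(
    member_annotations: Mapping[str, tuple[TaxonLineage, float]]
) -> TaxonLineage:
    """Transfer the lineage of the best-scoring annotated member to the MGC.

    ``member_annotations`` maps member id to (lineage, top retained
    bitscore); unannotated members carry an empty lineage.  Ties break on
    lexicographically smallest member id.
    """
    annotated = {
        m: (lin, score)
        for m, (lin, score) in member_annotations.items()
        if len(lin) > 0
    }
    if not annotated:
        return TaxonLineage(())
    best = min(annotated, key=lambda m: (-annotated[m][1], m))
    return annotated[best][0]


def annotate_meta_motu(
    mgc_lineages: Sequence[TaxonLineage],
    min_annotated: int = 3,
    consensus_frac: float = 0.5,
) -> tuple[TaxonLineage, bool]:
    """Consensus lineage of a metagenomic mOTU from its MGC lineages.

    Per rank (domain downward) the mOTU is annotated with the plurality
    name among MGCs annotated at that rank, provided at least
    ``min_annotated`` MGCs carry a name there; ties break
    lexicographically.  A rank is blanked (truncating the lineage) when
    its chosen name's parent disagrees with the rank above, keeping the
    lineage gap-free.  The mOTU is consistent iff at every annotated rank
    the plurality count reaches ``consensus_frac`` of the annotated MGCs.
    """
    names: list[str] = []
    consistent = True
    for depth in range(1, len(RANKS) + 1):
        at_rank = [lin for lin in mgc_lineages if len(lin) >= depth]
        if len(at_rank) < min_annotated:
            break
        counts = Counter(lin.names[depth - 1] for lin in at_rank)
        top_count = max(counts.values())
        name = min(n for n, c in counts.items() if c == top_count)
        # gap-freeness: the chosen name must extend the chosen parent
        supporting = [
            lin for lin in at_rank if lin.names[depth - 1] == name
        ]
        if names and not any(
            lin.names[: depth - 1] == tuple(names) for lin in supporting
        ):
            break
        names.append(name)
        if top_count < consensus_frac * len(at_rank):
            consistent = False
    return TaxonLineage(tuple(names)), consistent


def read_hit_table(path: str | Path) -> dict[str, list[ProteinHit]]:
    """Protein hit tables as TSV: query, semicolon-ranked lineage, bitscore."""
    hits: dict[str, list[ProteinHit]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            query, lineage, bitscore = line.split("\t")
            hits.setdefault(query, []).append(
                ProteinHit(query, TaxonLineage.from_string(lineage), float(bitscore))
            )
    return hits


def annotate_database_motu(
    motu_mgcs: Mapping[str, Iterable[str]],
    mgc_members: Mapping[str, Iterable[str]],
    hits_by_mg: Mapping[str, Sequence[ProteinHit]],
    keep_frac: float = 0.90,
    cover_frac: float = 0.75,
    min_annotated: int = 3,
    consensus_frac: float = 0.5,
) -> dict[str, tuple[TaxonLineage, bool]]:
    """Annotate each mOTU end-to-end from per-MG protein hits.

    ``motu_mgcs`` maps mOTU id to its MGC ids, ``mgc_members`` maps MGC id
    to member MG ids.
    """
    mg_lineage: dict[str, tuple[TaxonLineage, float]] = {}
    for mg, hits in hits_by_mg.items():
        lineage = weighted_lca(hits, keep_frac, cover_frac)
        best = max(h.bitscore for h in hits) if hits else 0.0
        mg_lineage[mg] = (lineage, best)
    out: dict[str, tuple[TaxonLineage, bool]] = {}
    for motu, mgcs in motu_mgcs.items():
        mgc_lineages = []
        for mgc in mgcs:
            members = {
                m: mg_lineage.get(m, (TaxonLineage(()), 0.0))
                for m in mgc_members[mgc]
            }
            mgc_lineages.append(annotate_mgc(members))
        out[motu] = annotate_meta_motu(
            mgc_lineages, min_annotated=min_annotated, consensus_frac=consensus_frac
        )
    return out
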