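"""Species-level clustering of marker genes and genomes.

Reference genomes are grouped into species clusters by average-linkage
hierarchical clustering of gene-length-weighted marker-gene distances at
a 96.5% nucleotide-identity cutoff (distance 0.035).  Marker genes
recovered from metagenome assemblies are then attached to the existing
reference clusters by open-reference clustering — a metagenomic gene
whose average distance to a cluster is within the cutoff joins it — and
the remainder are clustered de novo into metagenome-only clusters.

Global identities use Needleman-Wunsch alignment with a fixed scoring
scheme (match +1, mismatch -1, gap -2, end gaps penalised); identity is
matching columns over all alignment columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import Align

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class PairwiseIdentity:
    a_id: str
    b_id: str
    identity: float
    aligned_bases: int


@dataclass
class ClusterSet:
    """A partition of items produced at a given distance cutoff."""

    clusters: list[frozenset[str]]
    cutoff: float

    def labels(self) -> dict[str, int]:
        return {m: i for i, c in enumerate(self.clusters) for m in c}


def _aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )


def global_identity(
    seq_a: str, seq_b: str, a_id: str = "a", b_id: str = "b"
) -> PairwiseIdentity:
    """Global (Needleman-Wunsch) nucleotide identity between two sequences.

    Identity is matches over alignment columns (gap columns included);
    ``aligned_bases`` counts the non-gap (match + mismatch) columns.
    """
    for name, seq in ((a_id, seq_a), (b_id, seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq.upper()) - _VALID_BASES
        if bad:
            raise ValueError(f"sequence {name} has non-ACGTN characters: {sorted(bad)}")
    # align the lexicographically smaller sequence first so that tie-broken
    # optimal alignments do not depend on argument order (identity symmetry)
    x, y = sorted((seq_a.upper(), seq_b.upper()))
    aln = _aligner().align(x, y)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return PairwiseIdentity(
        a_id=a_id,
        b_id=b_id,
        identity=counts.identities / columns,
        aligned_bases=counts.identities + counts.mismatches,
    )


def genome_distance(per_mg: Sequence[tuple[float, float]]) -> float:
    """Gene-length-weighted mean distance between two genomes.

    ``per_mg`` holds one ``(length, identity)`` pair per shared marker
    gene; the distance is ``1 - sum(length * identity) / sum(length)``.
    """
    if not per_mg:
        raise ValueError("no shared marker genes")
    total = sum(length for length, _ in per_mg)
    weighted = sum(length * identity for length, identity in per_mg)
    return 1.0 - weighted / total


def average_linkage(
    dist_matrix: np.ndarray,
    labels: Sequence[str],
    cutoff: float = 0.035,
) -> ClusterSet:
    """Average-linkage agglomerative clustering halted at a distance cutoff.

    Clusters are merged while the minimum average inter-cluster distance
    is at most ``cutoff`` (the 96.5% identity threshold corresponds to
    0.035).  Ties are broken by the lexicographically smallest pair of
    cluster representatives, making the result deterministic.
    """
    d = np.asarray(dist_matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix / labels shape mismatch")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    # representative (smallest member label) per cluster, for tie-breaking
    rep: dict[int, str] = {i: labels[i] for i in range(n)}
    while len(clusters) > 1:
        best: tuple[float, str, str, int, int] | None = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            avg = float(
                np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
            )
            key_pair = tuple(sorted((rep[i], rep[j])))
            cand = (avg, key_pair[0], key_pair[1], i, j)
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is None or best[0] > cutoff:
            break
        _, _, _, i, j = best
        clusters[i] |= clusters[j]
        rep[i] = min(rep[i], rep[j])
        del clusters[j], rep[j]
    return ClusterSet(
        clusters=sorted(
            (frozenset(labels[m] for m in members) for members in clusters.values()),
            key=lambda c: min(c),
        ),
        cutoff=cutoff,
    )


def open_reference_cluster(
    ref_mgcs: Mapping[str, Sequence[str]],
    meta_mgs: Sequence[str],
    sequences: Mapping[str, str],
    identity_cutoff: float = 0.965,
    min_aligned: int = 20,
) -> tuple[dict[str, list[str]], list[frozenset[str]]]:
    """Attach metagenomic MGs to reference MGCs, cluster the rest de novo.

    ``ref_mgcs`` maps cluster id to member MG ids; all sequences live in
    ``sequences``.  Pairwise alignments spanning fewer than ``min_aligned``
    bases are treated as identity 0.  Metagenomic MGs are assigned
    greedily in order of decreasing best identity: one joins a reference
    cluster if its average-linkage distance to the (current) members is at
    most ``1 - identity_cutoff``.  Unassigned MGs are clustered among
    themselves by average linkage at the same cutoff.

    Returns the augmented reference clusters and the list of new
    metagenome-only clusters.
    """
    cutoff = 1.0 - identity_cutoff
    cache: dict[tuple[str, str], float] = {}

    def ident(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            pid = global_identity(sequences[a], sequences[b], a, b)
            cache[key] = pid.identity if pid.aligned_bases >= min_aligned else 0.0
        return cache[key]

    augmented = {cid: list(members) for cid, members in ref_mgcs.items()}
    # best achievable identity per meta-MG, for greedy ordering
    order = sorted(
        meta_mgs,
        key=lambda mg: (
            -max(
                (ident(mg, m) for members in augmented.values() for m in members),
                default=0.0,
            ),
            mg,
        ),
    )
    leftover: list[str] = []
    for mg in order:
        best_cid, best_dist = None, None
        for cid in sorted(augmented):
            avg = float(np.mean([1.0 - ident(mg, m) for m in augmented[cid]]))
            if best_dist is None or avg < best_dist:
                best_cid, best_dist = cid, avg
        if best_dist is not None and best_dist <= cutoff:
            augmented[best_cid].append(mg)
        else:
            leftover.append(mg)

    new_clusters: list[frozenset[str]] = []
    if leftover:
        labels = sorted(leftover)
        d = np.zeros((len(labels), len(labels)))
        for i, j in itertools.combinations(range(len(labels)), 2):
            d[i, j] = d[j, i] = 1.0 - ident(labels[i], labels[j])
        new_clusters = average_linkage(d, labels, cutoff=cutoff).clusters
    return augmented, new_clusters


def pick_centroid(
    members: Sequence[str],
    identity: Callable[[str, str], float] | Mapping[tuple[str, str], float],
) -> str:
    """Medoid of an MGC: the member with maximal mean identity to the others.

    Ties are broken by lexicographically smallest id; a singleton is its
    own centroid.
    """
    members = sorted(members)
    if len(members) == 1:
        return members[0]
    if not callable(identity):
        table = identity

        def lookup(a: str, b: str) -> float:
            return table[(a, b)] if (a, b) in table else table[(b, a)]

    else:
        lookup = identity
    best_id, best_mean = None, -1.0
    for m in members:
        mean = float(np.mean([lookup(m, o) for o in members if o != m]))
        if mean > best_mean:
            best_id, best_mean = m, mean
    return best_id


def write_distance_matrix(d: np.ndarray, labels: Sequence[str], path) -> None:
    """Square distance matrix as TSV with row/column labels."""
    with open(path, "w") as fh:
        fh.write("#id\t" + "\t".join(labels) + "\n")
        for i, lab in enumerate(labels):
            fh.write(lab + "\t" + "\t".join(f"{x:.6g}" for x in d[i]) + "\n")


def read_distance_matrix(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    labels = [r[0] for r in rows]
    if labels != header:
        raise ValueError("distance matrix rows/columns disagree")
    return np.array([[float(x) for x in r[1:]] for r in rows]), labels


def write_cluster_set(cs: ClusterSet, path) -> None:
    """Two-column TSV: member, cluster index."""
    with open(path, "w") as fh:
        fh.write("#member\tcluster\n")
        for i, cluster in enumerate(cs.clusters):
            for m in sorted(cluster):
                fh.write(f"{m}\t{i}\n")
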