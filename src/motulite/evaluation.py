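"""Benchmarking and community-ecology metrics for taxonomic profiles.

Covers the standard profiler evaluation suite — presence/absence
precision and recall, mean absolute error (L1) of relative abundances
with and without re-normalisation over detected taxa, Shannon diversity
— plus beta-diversity distances (log-Euclidean, Bray-Curtis, Canberra),
nearest-neighbour self-matching between paired profile sets,
intra-vs-inter individuality AU-ROC with bootstrap confidence intervals,
and correspondence of metagenome-assembled genomes (MAGs) with mOTUs
including the completeness/contamination quality score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import braycurtis, canberra, euclidean
from sklearn.metrics import roc_auc_score

from .datamodel import UNBINNED, ProfileDatabase


@dataclass
class BenchmarkPair:
    """Truth and predicted relative abundances over a taxon namespace."""

    truth: dict[str, float]
    predicted: dict[str, float]
    rank: str = "species"


@dataclass
class MagRecord:
    """A metagenome-assembled genome and its marker-gene hits.

    ``mg_hits`` holds (cog_type, matched MGC id, identity) triples already
    thresholded upstream (identity >= 0.96, query coverage >= 0.7).
    """

    id: str
    completeness: float
    contamination: float
    mg_hits: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for v in (self.completeness, self.contamination):
            if not 0 <= v <= 100:
                raise ValueError(f"MAG {self.id}: percentages must be in [0, 100]")


def precision_recall(
    pair: BenchmarkPair, presence_threshold: float = 0.0
) -> tuple[float, float]:
    """Presence/absence precision TP/(TP+FP) and recall TP/(TP+FN).

    A taxon is present when its abundance exceeds ``presence_threshold``.
    An empty prediction has precision 1 by convention (no false
    positives); an empty truth gives recall 1.
    """
    truth = {t for t, v in pair.truth.items() if v > presence_threshold}
    pred = {t for t, v in pair.predicted.items() if v > presence_threshold}
    tp = len(truth & pred)
    fp = len(pred - truth)
    fn = len(truth - pred)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall


def _renormalize(values: Mapping[str, float]) -> dict[str, float]:
    total = sum(values.values())
    if total == 0:
        return dict(values)
    return {k: v / total for k, v in values.items()}


def mae(pair: BenchmarkPair, renormalize: bool = False) -> float:
    """Mean absolute error (L1) of relative abundances.

    Averaged over the union of taxa present in truth or prediction.  With
    ``renormalize`` both vectors are first rescaled to sum to 1 over
    their detected taxa — the convention of common benchmark evaluations,
    which penalises profilers that report an unassigned fraction.
    """
    truth, pred = dict(pair.truth), dict(pair.predicted)
    if renormalize:
        truth, pred = _renormalize(truth), _renormalize(pred)
    taxa = set(truth) | set(pred)
    if not taxa:
        return 0.0
    return sum(abs(pred.get(t, 0.0) - truth.get(t, 0.0)) for t in taxa) / len(taxa)


def shannon(profile: Mapping[str, float], renormalize: bool = True) -> float:
    """Shannon diversity H' = -sum p ln p over nonzero relative abundances."""
    values = np.array([v for v in profile.values() if v > 0], dtype=float)
    if values.size == 0:
        raise ValueError("Shannon index undefined for an all-zero profile")
    if renormalize:
        values = values / values.sum()
    return float(-(values * np.log(values)).sum())


def profile_distance(
    a: Mapping[str, float], b: Mapping[str, float], metric: str = "log-euclidean"
) -> float:
    """Distance between two profiles sharing a taxon space.

    ``log-euclidean`` is the Euclidean distance of log-transformed
    relative abundances after adding a pseudocount of half the smallest
    nonzero value across both profiles; ``bray-curtis`` and ``canberra``
    follow their usual definitions.
    """
    taxa = sorted(set(a) | set(b))
    va = np.array([a.get(t, 0.0) for t in taxa], dtype=float)
    vb = np.array([b.get(t, 0.0) for t in taxa], dtype=float)
    if metric == "log-euclidean":
        nonzero = np.concatenate([va[va > 0], vb[vb > 0]])
        pseudo = 0.5 * nonzero.min() if nonzero.size else 1.0
        return float(euclidean(np.log(va + pseudo), np.log(vb + pseudo)))
    if metric == "bray-curtis":
        return float(braycurtis(va, vb))
    if metric == "canberra":
        with np.errstate(invalid="ignore", divide="ignore"):
            return float(canberra(va, vb))
    raise ValueError(f"unknown metric {metric!r}")


def best_match_rate(
    set_a: Mapping[str, Mapping[str, float]],
    set_b: Mapping[str, Mapping[str, float]],
    pairing: Mapping[str, str],
    metric: str = "log-euclidean",
) -> float:
    """Fraction of profiles in A whose nearest profile in B is their pair.

    ``pairing`` maps each A key to its intended B key (e.g. the
    metatranscriptome sequenced from the same sample as a metagenome).
    Distance ties count as failures.
    """
    hits = 0
    for a_key, a_profile in set_a.items():
        dists = {
            b_key: profile_distance(a_profile, b_profile, metric)
            for b_key, b_profile in set_b.items()
        }
        best = min(dists.values())
        winners = [k for k, d in dists.items() if d == best]
        if winners == [pairing[a_key]]:
            hits += 1
    return hits / len(set_a)


def individuality_auroc(
    distances: Sequence[float],
    same_individual: Sequence[bool],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AU-ROC of "small distance predicts same individual", with bootstrap CI.

    Values near 1 indicate that intra-individual strain-population
    distances are clearly smaller than inter-individual ones.  The 95%
    confidence interval resamples pairs with replacement.
    """
    y = np.asarray(same_individual, dtype=int)
    d = np.asarray(distances, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("need both intra- and inter-individual pairs")
    auroc = float(roc_auc_score(y, -d))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(y), len(y))
        if len(set(y[idx])) < 2:
            continue
        boots.append(roc_auc_score(y[idx], -d[idx]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (math.nan, math.nan))
    return auroc, (float(lo), float(hi))


def mag_quality(completeness: float, contamination: float) -> tuple[float, bool]:
    """Quality score QS = completeness - 5 x contamination; keep iff QS > 50."""
    qs = completeness - 5.0 * contamination
    return qs, qs > 50.0


def assign_mag(mag: MagRecord, db: ProfileDatabase) -> str:
    """Match a MAG to a mOTU through its marker-gene hits.

    Hits to unbinned MGCs are discarded; fewer than three mOTU-assigned
    hits yields ``UNASSIGNED``; a strict majority (>50%) of the remaining
    hits pointing at one mOTU yields that mOTU, otherwise
    ``INCONSISTENT``.
    """
    motu_hits = [
        db.mgcs[mgc_id].motu
        for (_cog, mgc_id, _ident) in mag.mg_hits
        if mgc_id in db.mgcs and db.mgcs[mgc_id].motu != UNBINNED
    ]
    if len(motu_hits) < 3:
        return "UNASSIGNED"
    counts: dict[str, int] = {}
    for m in motu_hits:
        counts[m] = counts.get(m, 0) + 1
    best = max(counts, key=lambda m: counts[m])
    if counts[best] * 2 > len(motu_hits):
        return best
    return "INCONSISTENT"
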