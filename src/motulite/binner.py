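"""Co-abundance binning of marker-gene clusters (MGCs) into mOTUs.

Genes from the same genome co-vary in abundance across metagenomic
samples, so MGCs belonging to one species can be recognised by
correlating their abundance trajectories.  Per biome, correlations are
computed on (optionally log-transformed) relative abundances after a
prevalence filter that suppresses spurious correlations between rarely
observed MGCs.  Raw correlations are not comparable across biomes, so
each biome's values are transformed into an FDR-calibrated association:
two correlations are mapped to the same association value whenever they
imply the same empirical false-discovery rate among reference MGC pairs
of known species membership.  A pair's final association is the maximum
calibrated value over the biomes in which it survived filtering.

Binning is greedy: starting from reference seed groups (MGCs of one
species cluster), pairs are processed in decreasing association down to
a cutoff of 0.8, merging groups only when the union keeps at most one
MGC per COG type.  Groups with at least six MGCs become mOTUs; the rest
stay unbinned.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Pair = tuple[str, str]


@dataclass
class BiomeConfig:
    """Per-biome correlation settings.

    ``prevalence_min`` is the minimum number of samples in which an MGC
    must be detected (abundance > 0) for its pairs to be scored.
    """

    name: str
    prevalence_min: int = 5
    transform: str = "log"  # "raw" | "log"
    correlation: str = "pearson"  # "pearson" | "spearman"

    def __post_init__(self) -> None:
        if self.prevalence_min < 1:
            raise ValueError("prevalence_min must be >= 1")
        if self.transform not in ("raw", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation {self.correlation!r}")


#: Biome presets: prevalence filter, transform and correlation measure.
DEFAULT_BIOME_CONFIGS: dict[str, BiomeConfig] = {
    "gut": BiomeConfig("gut", 5, "log", "pearson"),
    "ocean": BiomeConfig("ocean", 5, "raw", "pearson"),
    "oral": BiomeConfig("oral", 50, "raw", "pearson"),
    "vaginal": BiomeConfig("vaginal", 5, "log", "pearson"),
    "skin": BiomeConfig("skin", 10, "log", "spearman"),
}


@dataclass
class AssociationScore:
    pair: Pair
    per_biome_corr: dict[str, float] = field(default_factory=dict)
    calibrated: float = 0.0


def _ordered(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def biome_correlations(
    matrix: pd.DataFrame, config: BiomeConfig
) -> dict[Pair, float]:
    """All-pairs MGC correlations within one biome's samples.

    ``matrix`` is MGC x sample (non-negative) with the columns already
    restricted to the biome.  Abundances are column-normalised to
    relative abundances; the log transform adds a pseudocount of half the
    smallest nonzero relative abundance.  Pairs involving an MGC detected
    in fewer than ``config.prevalence_min`` samples are omitted.
    """
    if (matrix.values < 0).any():
        raise ValueError("abundance matrix has negative entries")
    if matrix.shape[1] < 3:
        warnings.warn(
            f"biome {config.name}: fewer than 3 samples, no correlations computed"
        )
        return {}
    prevalence = (matrix.values > 0).sum(axis=1)
    keep = matrix.index[prevalence >= config.prevalence_min]
    if len(keep) < 2:
        return {}
    col_sums = matrix.sum(axis=0).replace(0, np.nan)
    rel = matrix.div(col_sums, axis=1).fillna(0.0)
    data = rel.loc[keep].values
    if config.transform == "log":
        nonzero = rel.values[rel.values > 0]
        pseudo = 0.5 * nonzero.min() if nonzero.size else 1e-9
        data = np.log(data + pseudo)
    if config.correlation == "spearman":
        data = stats.rankdata(data, axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(data)
    out: dict[Pair, float] = {}
    ids = list(keep)
    for i, j in itertools.combinations(range(len(ids)), 2):
        c = corr[i, j]
        if np.isnan(c):  # constant row: undefined correlation, treat as 0
            c = 0.0
        out[_ordered(ids[i], ids[j])] = float(c)
    return out


class FdrCalibration:
    """Monotone map from correlation to an FDR-calibrated association.

    Built from reference MGC pairs labelled same-species (true) or
    different-species (false).  For a threshold ``t`` the empirical FDR is
    the false fraction among labelled pairs with correlation >= t,
    monotonised (non-increasing in ``t``) as in q-value estimation; the
    calibrated association of a correlation ``c`` is ``1 - FDR(c)``.
    """

    def __init__(self, labelled: Mapping[Pair, bool], correlations: Mapping[Pair, float]):
        scored = [(correlations[p], is_true) for p, is_true in labelled.items() if p in correlations]
        if not scored:
            raise ValueError("no labelled pairs with correlations: calibration impossible")
        scored.sort(key=lambda x: -x[0])
        thresholds: list[float] = []
        fdr: list[float] = []
        n_false = 0
        for rank, (c, is_true) in enumerate(scored, start=1):
            if not is_true:
                n_false += 1
            if rank < len(scored) and scored[rank][0] == c:
                continue  # emit one step per distinct threshold
            thresholds.append(c)
            fdr.append(n_false / rank)
        # monotonise: FDR non-increasing in the threshold
        for i in range(len(fdr) - 2, -1, -1):
            fdr[i] = min(fdr[i], fdr[i + 1])
        # thresholds descending -> store ascending for searchsorted
        self._thresholds = np.array(thresholds[::-1])
        self._calibrated = 1.0 - np.array(fdr[::-1])

    def __call__(self, correlation: float) -> float:
        """Calibrated association for a correlation value."""
        # rightmost stored threshold <= correlation; below all thresholds,
        # fall back to the most permissive (lowest) one.
        idx = int(np.searchsorted(self._thresholds, correlation, side="right")) - 1
        idx = max(idx, 0)
        return float(self._calibrated[idx])


def fdr_calibrate(
    correlations: Mapping[Pair, float], labelled_pairs: Mapping[Pair, bool]
) -> dict[Pair, float]:
    """Map every pair's correlation to its FDR-calibrated association."""
    cal = FdrCalibration(labelled_pairs, correlations)
    return {p: cal(c) for p, c in correlations.items()}


def combine_biomes(
    per_biome_calibrated: Mapping[str, Mapping[Pair, float]]
) -> list[AssociationScore]:
    """Combine per-biome calibrated associations by taking the maximum.

    A pair appears in the output iff it survived prevalence filtering in
    at least one biome.
    """
    merged: dict[Pair, AssociationScore] = {}
    for biome, values in per_biome_calibrated.items():
        for pair, v in values.items():
            score = merged.setdefault(pair, AssociationScore(pair=pair))
            score.per_biome_corr[biome] = v
            score.calibrated = max(score.calibrated, v)
    return sorted(merged.values(), key=lambda s: s.pair)


def greedy_bin(
    associations: Sequence[AssociationScore],
    seed_groups: Sequence[Iterable[str]],
    mgc_cogs: Mapping[str, str],
    cutoff: float = 0.8,
    min_size: int = 6,
) -> tuple[list[frozenset[str]], set[str]]:
    """Greedy co-abundance binning of MGCs into candidate mOTUs.

    Seed groups (reference MGCs grouped by species cluster) are fixed
    starting bins and are never split.  Associations are processed in
    decreasing calibrated order (ties by pair id) down to ``cutoff``; the
    two groups touched by a pair are merged only if the union contains at
    most one MGC per COG type.  Groups reaching ``min_size`` MGCs are
    returned as mOTUs; every other MGC is returned as unbinned.
    """
    group_of: dict[str, int] = {}
    groups: dict[int, set[str]] = {}
    cogs_of_group: dict[int, set[str]] = {}
    next_id = 0

    def ensure(mgc: str) -> int:
        nonlocal next_id
        if mgc not in group_of:
            group_of[mgc] = next_id
            groups[next_id] = {mgc}
            cogs_of_group[next_id] = {mgc_cogs[mgc]}
            next_id += 1
        return group_of[mgc]

    for seed in seed_groups:
        seed = list(seed)
        cogs = [mgc_cogs[m] for m in seed]
        if len(set(cogs)) != len(cogs):
            raise ValueError("seed group has two MGCs of one COG type")
        gid = next_id
        next_id += 1
        groups[gid] = set(seed)
        cogs_of_group[gid] = set(cogs)
        for m in seed:
            group_of[m] = gid

    for score in sorted(associations, key=lambda s: (-s.calibrated, s.pair)):
        if score.calibrated < cutoff:
            break
        a, b = score.pair
        ga, gb = ensure(a), ensure(b)
        if ga == gb:
            continue
        if cogs_of_group[ga] & cogs_of_group[gb]:
            continue  # a COG slot already occupied: do not merge
        groups[ga] |= groups[gb]
        cogs_of_group[ga] |= cogs_of_group[gb]
        for m in groups[gb]:
            group_of[m] = ga
        del groups[gb], cogs_of_group[gb]

    motus: list[frozenset[str]] = []
    unbinned: set[str] = set()
    for members in groups.values():
        if len(members) >= min_size:
            motus.append(frozenset(members))
        else:
            unbinned |= members
    motus.sort(key=lambda g: min(g))
    return motus, unbinned


def bin_matrix(
    matrix: pd.DataFrame,
    sample_biomes: Mapping[str, str],
    seed_groups: Sequence[Iterable[str]],
    mgc_cogs: Mapping[str, str],
    biome_configs: Mapping[str, BiomeConfig] | None = None,
    cutoff: float = 0.8,
    min_size: int = 6,
) -> tuple[list[frozenset[str]], set[str]]:
    """Full binning pipeline from an MGC x sample abundance matrix.

    Labelled pairs for FDR calibration are derived from the seed groups:
    pairs within one seed group are true, pairs across seed groups false.
    """
    configs = dict(DEFAULT_BIOME_CONFIGS)
    if biome_configs:
        configs.update(biome_configs)
    labelled = _labelled_pairs(seed_groups)
    per_biome: dict[str, dict[Pair, float]] = {}
    for biome in sorted(set(sample_biomes.values())):
        cols = [s for s in matrix.columns if sample_biomes[s] == biome]
        config = configs.get(biome, BiomeConfig(biome))
        corr = biome_correlations(matrix[cols], config)
        if corr:
            per_biome[biome] = fdr_calibrate(corr, labelled)
    associations = combine_biomes(per_biome)
    return greedy_bin(associations, seed_groups, mgc_cogs, cutoff, min_size)


def _labelled_pairs(seed_groups: Sequence[Iterable[str]]) -> dict[Pair, bool]:
    groups = [sorted(g) for g in seed_groups]
    labelled: dict[Pair, bool] = {}
    for g in groups:
        for a, b in itertools.combinations(g, 2):
            labelled[_ordered(a, b)] = True
    for g1, g2 in itertools.combinations(groups, 2):
        for a in g1:
            for b in g2:
                labelled[_ordered(a, b)] = False
    return labelled


def binning_cross_validation(
    matrix: pd.DataFrame,
    sample_biomes: Mapping[str, str],
    seed_groups: Sequence[Iterable[str]],
    biome_configs: Mapping[str, BiomeConfig] | None = None,
    folds: int = 5,
    resamples: int = 100,
    seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Cross-validated quality check of the co-abundance association signal.

    In each of ``resamples`` shuffles, reference MGCs are split into
    ``folds`` folds; per fold, the held-out MGCs are stripped of their
    species labels, associations are calibrated on the remaining labelled
    pairs, and held-out pairs are scored against the same-group ground
    truth with a ROC over the association threshold.  Returns the mean
    AUROC, its standard deviation, and all per-fold values.
    """
    from sklearn.metrics import roc_auc_score

    configs = dict(DEFAULT_BIOME_CONFIGS)
    if biome_configs:
        configs.update(biome_configs)
    if len(seed_groups) < 2:
        raise ValueError("need at least 2 seed groups")
    member_group = {
        m: gi for gi, g in enumerate(seed_groups) for m in g
    }
    members = sorted(member_group)
    per_biome_corr: dict[str, dict[Pair, float]] = {}
    for biome in sorted(set(sample_biomes.values())):
        cols = [s for s in matrix.columns if sample_biomes[s] == biome]
        config = configs.get(biome, BiomeConfig(biome))
        corr = biome_correlations(matrix[cols], config)
        if corr:
            per_biome_corr[biome] = corr
    if not per_biome_corr:
        raise ValueError("no biome produced correlations")

    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    for _ in range(resamples):
        order = list(members)
        rng.shuffle(order)
        fold_of = {m: i % folds for i, m in enumerate(order)}
        for fold in range(folds):
            held = {m for m in members if fold_of[m] == fold}
            train = [m for m in members if m not in held]
            train_groups: dict[int, list[str]] = {}
            for m in train:
                train_groups.setdefault(member_group[m], []).append(m)
            labelled = _labelled_pairs(list(train_groups.values()))
            per_biome_cal = {}
            for biome, corr in per_biome_corr.items():
                try:
                    per_biome_cal[biome] = fdr_calibrate(corr, labelled)
                except ValueError:
                    continue
            if not per_biome_cal:
                continue
            combined = {s.pair: s.calibrated for s in combine_biomes(per_biome_cal)}
            y_true, y_score = [], []
            for a, b in itertools.combinations(sorted(held), 2):
                pair = _ordered(a, b)
                if pair not in combined:
                    continue
                y_true.append(int(member_group[a] == member_group[b]))
                y_score.append(combined[pair])
            if len(set(y_true)) == 2:
                aucs.append(float(roc_auc_score(y_true, y_score)))
    if not aucs:
        raise ValueError("no fold produced a scorable pair set")
    return float(np.mean(aucs)), float(np.std(aucs)), aucs


def read_abundance_matrix(path) -> pd.DataFrame:
    """MGC x sample abundance matrix from TSV (first column: MGC id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "mgc_id"
    return df


def write_motu_membership(motus: Sequence[frozenset[str]], unbinned: set[str], path) -> None:
    """mOTU membership as TSV: mgc_id, motu index or -1."""
    with open(path, "w") as fh:
        fh.write("#mgc_id\tmotu\n")
        for i, group in enumerate(motus):
            for m in sorted(group):
                fh.write(f"{m}\t{i}\n")
        for m in sorted(unbinned):
            fh.write(f"{m}\t-1\n")
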