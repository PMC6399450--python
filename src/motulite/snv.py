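"""Single-nucleotide variant profiling on marker-gene centroids.

Reads are aligned against the centroid database (one representative
sequence per MGC) and only inserts flagged as unique alignments feed the
pileup; padded (non-coding) positions are excluded.  Per sample and mOTU
two coverage summaries are computed: horizontal (percentage of pooled
centroid positions covered at least once) and vertical (mean reads per
position).  A five-parameter filter cascade then decides which samples,
mOTUs and positions enter the allele-frequency table:

* ``fb`` — minimum horizontal coverage per sample and mOTU (%, default 80)
* ``fd`` — minimum vertical coverage per sample and mOTU (default 5)
* ``fm`` — minimum number of retained samples per mOTU (default 2)
* ``fc`` — minimum depth per SNV position and sample (default 5)
* ``fp`` — minimum proportion of retained samples meeting ``fc`` at a
  position (default 0.9)

Distances between the strain populations of two samples are the
Manhattan distance of their allele-frequency vectors over shared
positions, and the major-allele distance: the fraction of shared
positions whose allele frequency differs by more than 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ProfileDatabase
from .profiler import assign_inserts, parse_and_filter

#: pileup: centroid MG id -> {coding position -> {base -> read count}}
Pileup = dict[str, dict[int, dict[str, int]]]


@dataclass
class SnvFilterParams:
    fb: float = 80.0  # min horizontal coverage, percent
    fd: float = 5.0  # min vertical coverage, x
    fm: int = 2  # min retained samples per mOTU
    fc: int = 5  # min depth per SNV position
    fp: float = 0.9  # min proportion of samples meeting fc
    min_alt: int = 2  # min alt count in >=1 retained sample to call a SNV

    def __post_init__(self) -> None:
        if not 0 <= self.fb <= 100:
            raise ValueError("fb must be a percentage in [0, 100]")
        if not 0 <= self.fp <= 1:
            raise ValueError("fp must be a proportion in [0, 1]")
        if min(self.fd, self.fm, self.fc, self.min_alt) < 0:
            raise ValueError("filter parameters must be non-negative")


@dataclass
class CoverageSummary:
    """Per (sample, mOTU) horizontal (%) and vertical (x) coverage."""

    horizontal: dict[tuple[str, str], float] = field(default_factory=dict)
    vertical: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class AlleleFrequencyTable:
    """Filtered SNV positions x samples for one mOTU.

    ``frequencies`` is indexed by (centroid MG, coding position, ref base,
    alt base) with one column per retained sample; cells are the
    alt-allele frequency (alt count over depth) or NaN where the sample's
    depth at the position is below ``fc``.
    """

    motu: str
    frequencies: pd.DataFrame


def pileup(
    sam_path: str | Path,
    centroid_db: ProfileDatabase,
    min_identity: float = 0.97,
    min_length: int = 75,
) -> Pileup:
    """Base counts per coding position from unique-insert alignments.

    Alignments pass the profiler's identity/length filters first; inserts
    with multiple best-scoring MGCs contribute nothing.  Reference
    positions are converted to coding coordinates and padded positions
    are dropped.
    """
    records = parse_and_filter(
        sam_path, min_identity=min_identity, min_length=min_length, keep_columns=True
    )
    assignments = assign_inserts(records, centroid_db)
    counts: Pileup = {}
    for a in assignments:
        if a.flag != "unique":
            continue
        (mgc_id,) = a.best_targets
        for rec in a.alignments[mgc_id]:
            mg = centroid_db.marker_genes[rec.target_mg]
            start, end = mg.coding_span
            if rec.aligned_ref_span[1] > len(mg.sequence):
                raise ValueError(
                    f"read {rec.insert_id}: alignment beyond {mg.id} bounds"
                )
            per_pos = counts.setdefault(mg.id, {})
            for _q, ref_pos, base in rec.aligned_columns or ():
                if not start <= ref_pos < end:
                    continue  # padded region
                col = per_pos.setdefault(ref_pos - start, {})
                col[base] = col.get(base, 0) + 1
    return counts


def coverage_summary(
    pileups: Mapping[str, Pileup], db: ProfileDatabase
) -> CoverageSummary:
    """Pool each mOTU's centroid positions and summarise coverage per sample.

    Horizontal coverage is the percentage of pooled coding positions with
    depth >= 1; vertical coverage is total reads over total positions.
    """
    summary = CoverageSummary()
    motu_centroids = {
        motu.id: [db.mgcs[m].centroid for m in motu.mgcs.values()]
        for motu in db.motus.values()
    }
    for sample, pu in pileups.items():
        for motu_id, centroids in motu_centroids.items():
            total_pos = sum(db.marker_genes[c].length for c in centroids)
            covered = 0
            reads = 0
            for c in centroids:
                for col in pu.get(c, {}).values():
                    covered += 1
                    reads += sum(col.values())
            summary.horizontal[(sample, motu_id)] = 100.0 * covered / total_pos
            summary.vertical[(sample, motu_id)] = reads / total_pos
    return summary


def call_and_filter(
    pileups: Mapping[str, Pileup],
    db: ProfileDatabase,
    params: SnvFilterParams | None = None,
) -> dict[str, AlleleFrequencyTable]:
    """Apply the filter cascade and build per-mOTU allele-frequency tables.

    A sample is retained for a mOTU iff horizontal >= fb and vertical >=
    fd; a mOTU is retained iff >= fm samples survive; a position is
    retained iff its depth reaches fc in >= fp of the retained samples;
    a retained position becomes a SNV row iff at least one retained
    sample shows the alternative allele at count >= ``min_alt``.
    """
    params = params or SnvFilterParams()
    summary = coverage_summary(pileups, db)
    samples = sorted(pileups)
    tables: dict[str, AlleleFrequencyTable] = {}
    for motu in sorted(db.motus.values(), key=lambda m: m.id):
        retained = [
            s
            for s in samples
            if summary.horizontal[(s, motu.id)] >= params.fb
            and summary.vertical[(s, motu.id)] >= params.fd
        ]
        if len(retained) < params.fm:
            continue
        rows: list[tuple[str, int, str, str]] = []
        cells: list[list[float]] = []
        for mgc_id in sorted(motu.mgcs.values()):
            centroid = db.mgcs[mgc_id].centroid
            mg = db.marker_genes[centroid]
            positions = sorted(
                {p for s in retained for p in pileups[s].get(centroid, {})}
            )
            for pos in positions:
                depths = [
                    sum(pileups[s].get(centroid, {}).get(pos, {}).values())
                    for s in retained
                ]
                n_deep = sum(d >= params.fc for d in depths)
                if n_deep < params.fp * len(retained):
                    continue
                ref = mg.coding_sequence[pos]
                # most frequent alternative allele across retained samples
                alt_totals: dict[str, int] = {}
                for s in retained:
                    for base, c in pileups[s].get(centroid, {}).get(pos, {}).items():
                        if base != ref:
                            alt_totals[base] = alt_totals.get(base, 0) + c
                if not alt_totals:
                    continue
                alt = min(alt_totals, key=lambda b: (-alt_totals[b], b))
                has_call = any(
                    pileups[s].get(centroid, {}).get(pos, {}).get(alt, 0)
                    >= params.min_alt
                    for s in retained
                )
                if not has_call:
                    continue
                freqs: list[float] = []
                for s, depth in zip(retained, depths):
                    if depth < params.fc:
                        freqs.append(np.nan)
                    else:
                        alt_count = pileups[s].get(centroid, {}).get(pos, {}).get(alt, 0)
                        freqs.append(alt_count / depth)
                rows.append((centroid, pos, ref, alt))
                cells.append(freqs)
        if rows:
            index = pd.MultiIndex.from_tuples(
                rows, names=["centroid", "pos", "ref", "alt"]
            )
            tables[motu.id] = AlleleFrequencyTable(
                motu=motu.id,
                frequencies=pd.DataFrame(cells, index=index, columns=retained),
            )
    return tables


def snv_distances(
    table: AlleleFrequencyTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Manhattan and major-allele distance matrices between samples.

    Both run over positions non-missing in the two samples compared:
    Manhattan is the summed absolute frequency difference; the
    major-allele distance is the fraction of shared positions whose
    frequencies differ by more than 0.5.  Pairs without shared positions
    get NaN.
    """
    samples = list(table.frequencies.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for distances")
    values = table.frequencies.values
    n = len(samples)
    mann = np.zeros((n, n))
    major = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
            if not shared.any():
                mann[i, j] = mann[j, i] = np.nan
                major[i, j] = major[j, i] = np.nan
                continue
            diff = np.abs(values[shared, i] - values[shared, j])
            mann[i, j] = mann[j, i] = diff.sum()
            major[i, j] = major[j, i] = (diff > 0.5).mean()
    return (
        pd.DataFrame(mann, index=samples, columns=samples),
        pd.DataFrame(major, index=samples, columns=samples),
    )


def run_snv_workflow(
    sam_paths: Mapping[str, str | Path],
    centroid_db: ProfileDatabase,
    out_dir: str | Path | None = None,
    params: SnvFilterParams | None = None,
    min_identity: float = 0.97,
    min_length: int = 75,
) -> tuple[CoverageSummary, dict[str, AlleleFrequencyTable], dict[str, tuple[pd.DataFrame, pd.DataFrame]]]:
    """Pileup, filter and distance computation over a set of samples.

    ``sam_paths`` maps sample name to its SAM alignment file.  When
    ``out_dir`` is given the output layout is written there: a horizontal
    coverage table (``snv.cov.tab``), a vertical one (``snv.perc.tab``),
    a log file, per-mOTU allele-frequency tables under ``filtered-snv/``
    and per-mOTU distance matrices (``*.mann.dist``, ``*.allele.dist``)
    under ``distances-snv/``.
    """
    params = params or SnvFilterParams()
    pileups = {
        sample: pileup(path, centroid_db, min_identity, min_length)
        for sample, path in sam_paths.items()
    }
    summary = coverage_summary(pileups, centroid_db)
    tables = call_and_filter(pileups, centroid_db, params)
    distances = {
        motu_id: snv_distances(t)
        for motu_id, t in tables.items()
        if t.frequencies.shape[1] >= 2
    }
    if out_dir is not None:
        _write_outputs(Path(out_dir), summary, tables, distances, params, sorted(sam_paths))
    return summary, tables, distances


def _write_outputs(
    out_dir: Path,
    summary: CoverageSummary,
    tables: dict[str, AlleleFrequencyTable],
    distances: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    params: SnvFilterParams,
    samples: Sequence[str],
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    motus = sorted({m for (_s, m) in summary.horizontal})
    for name, data in (("snv.cov.tab", summary.horizontal), ("snv.perc.tab", summary.vertical)):
        df = pd.DataFrame(
            [[data[(s, m)] for s in samples] for m in motus],
            index=motus,
            columns=samples,
        )
        df.to_csv(out_dir / name, sep="\t", index_label="#motu")
    (out_dir / "snv.log").write_text(
        f"filters: fb={params.fb} fd={params.fd} fm={params.fm} "
        f"fc={params.fc} fp={params.fp} min_alt={params.min_alt}\n"
        f"samples: {len(samples)}\nmOTUs in table: {len(tables)}\n"
    )
    filt = out_dir / "filtered-snv"
    filt.mkdir(exist_ok=True)
    for motu_id, table in tables.items():
        table.frequencies.to_csv(filt / f"{motu_id}.freq.tab", sep="\t")
    dist = out_dir / "distances-snv"
    dist.mkdir(exist_ok=True)
    for motu_id, (mann, major) in distances.items():
        mann.to_csv(dist / f"{motu_id}.mann.dist", sep="\t", index_label="#sample")
        major.to_csv(dist / f"{motu_id}.allele.dist", sep="\t", index_label="#sample")
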