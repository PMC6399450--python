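"""Synthetic marker-gene databases, metagenomes and strain mixtures.

Every generator is a pure function of its configuration and seed, and
emits the same on-disk formats the analysis modules consume (FASTA +
manifest, SAM, abundance-matrix TSV, hit-table TSV), so the whole stack
can be exercised end-to-end with known ground truth and no downloads.

The default scale is a desk-scale stand-in for a production profiling
study: 20 species, each carrying the ten single-copy marker genes
embedded in a small synthetic genome, profiled at tens of thousands of
inserts per sample (production databases hold thousands of species and
samples run to 10^8 inserts).  Species are planted well apart
(inter-species marker identity far below the 96.5% species boundary,
intra-species members at >=99%), paired 150 nt reads are drawn with a
350 +/- 30 nt insert size, and sequencing errors are uniform
substitutions only, which keeps identity arithmetic exact.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .datamodel import (
    COG_TYPES,
    UNBINNED,
    MGC,
    MOTU,
    MarkerGene,
    ProfileDatabase,
    TaxonLineage,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic community.

    ``n_known`` species get reference-derived mOTUs, ``n_unknown`` get
    metagenome-derived (meta-)mOTUs, and ``n_unbinned`` species exist in
    the database only as unbinned MGCs (their reads land in the pooled
    "-1" group).  Lengths are in nt; the error rate is a per-base
    substitution probability.
    """

    seed: int = 0
    n_known: int = 10
    n_unknown: int = 10
    n_unbinned: int = 0
    mg_length: tuple[int, int] = (600, 900)
    spacer_length: tuple[int, int] = (350, 450)
    max_members: int = 3
    padding: int = 100
    error_rate: float = 0.0
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 30.0
    abundance_sigma: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_known, self.n_unknown, self.n_unbinned) < 0:
            raise ValueError("species counts must be non-negative")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be a probability")

    @property
    def n_species(self) -> int:
        return self.n_known + self.n_unknown + self.n_unbinned


@dataclass
class Locus:
    """Placement of one marker gene's coding region in its genome."""

    mg_id: str
    mgc_id: str
    start: int  # coding start on the genome
    end: int  # coding end on the genome
    window: tuple[int, int]  # padded window on the genome matching the DB record


@dataclass
class SimulatedDatabase:
    db: ProfileDatabase
    genomes: dict[str, str]
    loci: dict[str, list[Locus]]
    species_motu: dict[str, str]  # species -> mOTU id, or "-1"
    config: SimConfig

    @property
    def species(self) -> list[str]:
        return sorted(self.genomes)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions."""
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _lineage(index: int, species: str) -> TaxonLineage:
    return TaxonLineage(
        (
            "Bacteria",
            f"Phylum{index % 4}",
            f"Class{index % 4}",
            f"Order{index}",
            f"Family{index}",
            f"Genus{index}",
            f"Species {species}",
        )
    )


def simulate_database(config: SimConfig) -> SimulatedDatabase:
    """Build a planted database: 10 MGCs per species, one genome each.

    Intra-species MGC members differ by at most 1% (>=99% identity);
    different species carry independent random sequences, far below the
    96.5% clustering boundary.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    marker_genes: dict[str, MarkerGene] = {}
    mgcs: dict[str, MGC] = {}
    motus: dict[str, MOTU] = {}
    unbinned: set[str] = set()
    genomes: dict[str, str] = {}
    loci: dict[str, list[Locus]] = {}
    species_motu: dict[str, str] = {}

    for k in range(config.n_species):
        sp = f"s{k:02d}"
        if k < config.n_known:
            kind, source, motu_id = "ref", "reference", f"ref_motu_{sp}"
        elif k < config.n_known + config.n_unknown:
            kind, source, motu_id = "meta", "metagenome", f"meta_motu_{sp}"
        else:
            kind, source, motu_id = "meta", "metagenome", UNBINNED
        species_motu[sp] = motu_id

        genome_parts: list[str] = [
            _random_seq(rng, int(rng.integers(*config.spacer_length)))
        ]
        genome_pos = len(genome_parts[0])
        sp_loci: list[Locus] = []
        motu_mgcs: dict[str, str] = {}
        for cog in COG_TYPES:
            length = int(rng.integers(*config.mg_length))
            coding = _random_seq(rng, length)
            mgc_id = f"{sp}.{cog}"
            centroid_id = f"{sp}.{cog}.m0"
            sp_loci.append(
                Locus(
                    mg_id=centroid_id,
                    mgc_id=mgc_id,
                    start=genome_pos,
                    end=genome_pos + length,
                    window=(genome_pos - config.padding, genome_pos + length + config.padding),
                )
            )
            genome_parts.append(coding)
            spacer = _random_seq(rng, int(rng.integers(*config.spacer_length)))
            genome_parts.append(spacer)
            genome_pos += length + len(spacer)

        genome = "".join(genome_parts)
        genomes[sp] = genome
        loci[sp] = sp_loci

        for locus, cog in zip(sp_loci, COG_TYPES):
            w0, w1 = locus.window
            padded = genome[w0:w1]
            span = (locus.start - w0, locus.end - w0)
            members = {locus.mg_id}
            marker_genes[locus.mg_id] = MarkerGene(
                id=locus.mg_id, cog_type=cog, source=source,
                sequence=padded, coding_span=span,
            )
            for j in range(1, int(rng.integers(1, config.max_members + 1))):
                mid = f"{sp}.{cog}.m{j}"
                n_subs = int(rng.integers(1, max(2, len(padded) // 100)))
                marker_genes[mid] = MarkerGene(
                    id=mid, cog_type=cog, source=source,
                    sequence=_mutate(rng, padded, n_subs), coding_span=span,
                )
                members.add(mid)
            mgcs[locus.mgc_id] = MGC(
                id=locus.mgc_id, cog_type=cog, members=members,
                centroid=locus.mg_id, kind=kind, motu=species_motu[sp],
            )
            if species_motu[sp] == UNBINNED:
                unbinned.add(locus.mgc_id)
            else:
                motu_mgcs[cog] = locus.mgc_id

        if species_motu[sp] != UNBINNED:
            motus[species_motu[sp]] = MOTU(
                id=species_motu[sp], kind=kind, mgcs=motu_mgcs,
                taxonomy=_lineage(k, sp),
            )

    db = ProfileDatabase(marker_genes, mgcs, motus, unbinned)
    return SimulatedDatabase(db, genomes, loci, species_motu, config)


# ---------------------------------------------------------------------------
# read simulation

def _sam_header(db: ProfileDatabase) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": mg.id, "LN": len(mg.sequence)}
                for mg in sorted(db.marker_genes.values(), key=lambda m: m.id)
            ],
        }
    )


def _emit_read(
    writer: pysam.AlignmentFile,
    header: pysam.AlignmentHeader,
    name: str,
    flag: int,
    read_seq: str,
    read_start: int,
    ref_genome: str,
    sp_loci: Sequence[Locus],
    window_starts: Sequence[int],
    min_overlap: int = 20,
) -> None:
    """Write alignments of one read against the marker-gene windows it spans.

    ``ref_genome`` is the genome the database records were cut from, so
    NM counts every mismatch (sequencing error or strain variant) of the
    read against the reference in the aligned window.
    """
    r0, r1 = read_start, read_start + len(read_seq)
    j = bisect_right(window_starts, r0)
    for locus in sp_loci[max(0, j - 1) : j + 1]:
        w0, w1 = locus.window
        o0, o1 = max(r0, w0), min(r1, w1)
        if o1 - o0 < min_overlap:
            continue
        nm = sum(
            1
            for q, p in zip(read_seq[o0 - r0 : o1 - r0], ref_genome[o0:o1])
            if q != p
        )
        seg = pysam.AlignedSegment(header)
        seg.query_name = name
        seg.flag = flag
        seg.reference_name = locus.mg_id
        seg.reference_start = o0 - w0
        seg.mapping_quality = 60
        left, mlen, right = o0 - r0, o1 - o0, r1 - o1
        seg.cigarstring = (
            (f"{left}S" if left else "") + f"{mlen}M" + (f"{right}S" if right else "")
        )
        seg.query_sequence = read_seq
        seg.set_tags([("NM", nm), ("AS", mlen - 2 * nm)])
        writer.write(seg)


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    """Substitute bases uniformly at ``error_rate``."""
    if error_rate == 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    arr = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_sample(
    simdb: SimulatedDatabase,
    truth_abundances: Mapping[str, float],
    n_inserts: int,
    sam_path: str | Path,
    seed: int = 0,
    error_rate: float | None = None,
) -> dict[str, float]:
    """Draw paired reads from the community and write their SAM alignments.

    ``truth_abundances`` maps species to relative (cell) abundance and
    must sum to 1.  Inserts are drawn proportional to abundance times
    genome length, so per-base depth — and hence marker-gene coverage —
    is proportional to abundance.  Returns the ground-truth mOTU profile
    (named mOTUs plus the pooled "-1" fraction).
    """
    config = simdb.config
    if error_rate is None:
        error_rate = config.error_rate
    species = sorted(truth_abundances)
    probs = np.array([truth_abundances[s] for s in species], dtype=float)
    if probs.min() < 0 or not math.isclose(probs.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("truth abundances must be non-negative and sum to 1")
    lengths = np.array([len(simdb.genomes[s]) for s in species], dtype=float)
    weights = probs * lengths
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    rl = config.read_length
    header = _sam_header(simdb.db)
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as writer:
        if n_inserts > 0:
            sp_idx = rng.choice(len(species), size=n_inserts, p=weights)
            ilens = np.clip(
                rng.normal(config.insert_mean, config.insert_sd, size=n_inserts),
                2 * rl,
                None,
            ).astype(int)
            for i in range(n_inserts):
                sp = species[int(sp_idx[i])]
                genome = simdb.genomes[sp]
                ilen = min(int(ilens[i]), len(genome))
                start = int(rng.integers(0, len(genome) - ilen + 1))
                sp_loci = simdb.loci[sp]
                window_starts = [loc.window[0] for loc in sp_loci]
                name = f"insert_{i:07d}"
                for mate_flag, r0 in (
                    (0x1 | 0x40, start),
                    (0x1 | 0x80, start + ilen - rl),
                ):
                    seq = _apply_errors(rng, genome[r0 : r0 + rl], error_rate)
                    _emit_read(
                        writer, header, name, mate_flag, seq, r0, genome,
                        sp_loci, window_starts,
                    )
    return truth_motu_profile(simdb, truth_abundances)


def truth_motu_profile(
    simdb: SimulatedDatabase, truth_abundances: Mapping[str, float]
) -> dict[str, float]:
    """Aggregate species abundances to mOTU ids (unbinned species pool in "-1")."""
    out: dict[str, float] = {UNBINNED: 0.0}
    for sp, value in truth_abundances.items():
        motu = simdb.species_motu[sp]
        out[motu] = out.get(motu, 0.0) + value
    return out


def random_abundances(
    simdb: SimulatedDatabase, seed: int = 0
) -> dict[str, float]:
    """Log-normal community composition over the database's species."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(0.0, simdb.config.abundance_sigma, size=len(simdb.species))
    values /= values.sum()
    return dict(zip(simdb.species, values))


# ---------------------------------------------------------------------------
# co-abundance matrices (binner fixtures)

def simulate_coabundance(
    simdb: SimulatedDatabase,
    n_samples: int = 30,
    noise_sd: float = 0.1,
    biome: str = "gut",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """MGC x sample abundance matrix with planted species structure.

    Each species follows a log-normal abundance trajectory across
    samples; its ten MGC rows share the trajectory plus iid Gaussian
    noise (sd ``noise_sd``) on the natural-log scale.  Returns the
    matrix, a sample -> biome map and an MGC -> species label map.
    """
    rng = np.random.default_rng(seed)
    samples = [f"{biome}_{j:03d}" for j in range(n_samples)]
    rows: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for sp in simdb.species:
        trajectory = rng.normal(0.0, 1.0, size=n_samples)
        for locus in simdb.loci[sp]:
            noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
            rows[locus.mgc_id] = np.exp(trajectory + noise)
            labels[locus.mgc_id] = sp
    matrix = pd.DataFrame(rows).T
    matrix.columns = samples
    matrix.index.name = "mgc_id"
    return matrix.sort_index(), {s: biome for s in samples}, labels


# ---------------------------------------------------------------------------
# strain mixtures (SNV fixtures)

@dataclass
class StrainSimulation:
    species: str
    sam_paths: dict[str, Path]
    proportions: dict[str, float]  # sample -> fraction of haplotype B
    variant_positions: list[int]  # genome coordinates
    mg_variant_count: int  # variants inside marker-gene coding regions
    true_manhattan: pd.DataFrame = field(repr=False)


def simulate_strains(
    simdb: SimulatedDatabase,
    species: str,
    out_dir: str | Path,
    n_samples: int = 10,
    proportions: Sequence[float] | None = None,
    n_inserts: int = 2000,
    snv_rate: float = 0.01,
    seed: int = 0,
) -> StrainSimulation:
    """Two strain haplotypes of one species mixed at varying proportions.

    Haplotype B differs from the genome at ``snv_rate`` of its positions
    (some inside marker-gene loci).  Per sample, inserts are drawn from
    haplotype B with the sample's mixture proportion.  The returned
    ground truth holds every variant position and the exact whole-genome
    Manhattan distances ``n_variants * |p_i - p_j|`` implied by the
    mixture proportions.
    """
    config = simdb.config
    rng = np.random.default_rng(seed)
    genome = simdb.genomes[species]
    sp_loci = simdb.loci[species]
    window_starts = [loc.window[0] for loc in sp_loci]

    n_var = max(1, int(len(genome) * snv_rate))
    variant_positions = sorted(int(p) for p in rng.choice(len(genome), n_var, replace=False))
    hap_b = _mutate_at(rng, genome, variant_positions)
    mg_variant_count = sum(
        1 for p in variant_positions
        if any(loc.start <= p < loc.end for loc in sp_loci)
    )

    if proportions is None:
        proportions = np.linspace(0.0, 1.0, n_samples)
    samples = [f"strain_{j:02d}" for j in range(len(proportions))]
    props = dict(zip(samples, (float(p) for p in proportions)))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = _sam_header(simdb.db)
    rl = config.read_length
    sam_paths: dict[str, Path] = {}
    for sample in samples:
        p_b = props[sample]
        path = out_dir / f"{sample}.sam"
        sam_paths[sample] = path
        with pysam.AlignmentFile(str(path), "wh", header=header) as writer:
            ilens = np.clip(
                rng.normal(config.insert_mean, config.insert_sd, size=n_inserts),
                2 * rl,
                None,
            ).astype(int)
            from_b = rng.random(n_inserts) < p_b
            for i in range(n_inserts):
                src = hap_b if from_b[i] else genome
                ilen = min(int(ilens[i]), len(src))
                start = int(rng.integers(0, len(src) - ilen + 1))
                name = f"{sample}_insert_{i:06d}"
                for mate_flag, r0 in (
                    (0x1 | 0x40, start),
                    (0x1 | 0x80, start + ilen - rl),
                ):
                    seq = _apply_errors(rng, src[r0 : r0 + rl], config.error_rate)
                    _emit_read(
                        writer, header, name, mate_flag, seq, r0, genome,
                        sp_loci, window_starts,
                    )

    pvals = np.array([props[s] for s in samples])
    true_d = n_var * np.abs(pvals[:, None] - pvals[None, :])
    return StrainSimulation(
        species=species,
        sam_paths=sam_paths,
        proportions=props,
        variant_positions=variant_positions,
        mg_variant_count=mg_variant_count,
        true_manhattan=pd.DataFrame(true_d, index=samples, columns=samples),
    )


def _mutate_at(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    arr = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# protein hit tables (taxonomy fixtures)

def simulate_hit_table(
    simdb: SimulatedDatabase,
    path: str | Path,
    n_hits: tuple[int, int] = (2, 5),
    seed: int = 0,
) -> None:
    """Per-MG protein hits whose weighted LCA recovers the planted lineage.

    Each marker gene receives a top hit with its species' full lineage
    plus lower-scoring hits from sister species of the same genus-level
    neighbourhood, mimicking a homology search against a protein
    reference.
    """
    rng = np.random.default_rng(seed)
    db = simdb.db
    lineage_of = {
        sp: _lineage(i, sp) for i, sp in enumerate(simdb.species)
    }
    with open(path, "w") as fh:
        fh.write("#query\tlineage\tbitscore\n")
        for sp in simdb.species:
            for locus in simdb.loci[sp]:
                for mg_id in sorted(db.mgcs[locus.mgc_id].members):
                    top = float(rng.integers(300, 500))
                    fh.write(f"{mg_id}\t{lineage_of[sp]}\t{top:.1f}\n")
                    for _ in range(int(rng.integers(*n_hits))):
                        other = simdb.species[int(rng.integers(len(simdb.species)))]
                        score = top * rng.uniform(0.5, 0.89)
                        fh.write(f"{mg_id}\t{lineage_of[other]}\t{score:.1f}\n")
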