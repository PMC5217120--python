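"""Synthetic study generator: pedigree, genotypes, counts, alignments, reads.

Emulates the design of a paired cell/exosome small-RNA study on a
three-generation family (four grandparents, two parents, 11 children;
34 libraries = 17 individuals x 2 compartments), with

* biallelic autosomal markers segregating through two meioses with
  Poisson-distributed crossovers,
* negative-binomial read counts with compartment log2 fold changes, one
  massively exosome-exported genomic miRNA cluster, higher dispersion on
  the exosome side, and haplotype-driven cis effects in a subset of miRNAs,
* hairpin-local alignments carrying nontemplated 3'/5' tails encoded as
  CIGAR soft clips, and unmapped reads with planted 10-mers.

Every quantity the downstream stages are meant to recover is recorded in a
:class:`TruthSet` so the whole pipeline is testable without any download.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._data import (
    CELL,
    COMPARTMENTS,
    EXOSOME,
    CountMatrix,
    GenotypeTable,
    Individual,
    MirnaAnnotation,
    Pedigree,
)

DNA = np.array(list("ACGT"))

# Compartment log2-FC class shifts (exosome relative to cell) giving the
# qualitative composition contrast: exosomes richer in piRNA and rRNA,
# cells richer in miRNA and snoRNA.
BIOTYPE_LFC_SHIFT = {
    "miRNA": -0.6,
    "snoRNA": -1.2,
    "piRNA": 1.0,
    "rRNA": 1.0,
    "lincRNA": 0.0,
    "misc": 0.0,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real design: 11 children (17 individuals total),
    paired cell and exosome libraries, one strongly exported miRNA cluster,
    more dispersion on the exosome side, and a few cis-acting haplotype
    effects. ``nta_rates`` maps tail labels to per-read probabilities;
    a leading "-" marks a 3' tail ("-A"), a trailing "-" a 5' tail ("A-").
    """

    n_children: int = 11
    n_markers_per_chrom: int = 300
    n_chromosomes: int = 2
    chrom_length: int = 100_000_000
    recomb_rate: float = 1.0
    n_mirnas: int = 60
    n_pirnas: int = 40
    exported_cluster_size: int = 5
    exported_cluster_lfc: float = 10.0
    n_eqtl_mirnas: int = 3
    eqtl_beta: float = 1.5
    nb_dispersion_cell: float = 0.1
    nb_dispersion_exosome: float = 0.3
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    nta_rates: dict[str, float] = field(
        default_factory=lambda: {"-A": 0.08, "-T": 0.04, "-TT": 0.02, "A-": 0.01}
    )
    planted_kmer: str = "GATTACAGAT"
    planted_kmer_rate: float = 0.05
    lfc_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_children <= 0:
            raise ConfigurationError("n_children must be positive")
        if self.n_markers_per_chrom <= 0:
            raise ConfigurationError("n_markers_per_chrom must be positive")
        if self.n_chromosomes <= 0:
            raise ConfigurationError("n_chromosomes must be positive")
        if self.recomb_rate < 0:
            raise ConfigurationError("recomb_rate must be non-negative")
        if self.exported_cluster_size < 2:
            raise ConfigurationError("exported_cluster_size must be >= 2")
        if self.nb_dispersion_cell <= 0 or self.nb_dispersion_exosome <= 0:
            raise ConfigurationError("NB dispersions must be positive")
        for tail, rate in self.nta_rates.items():
            core = tail.strip("-")
            if not (tail.startswith("-") ^ tail.endswith("-")) or not core:
                raise ConfigurationError(f"bad NTA label {tail!r}; use '-XY' (3') or 'XY-' (5')")
            if len(core) > 2:
                raise ConfigurationError(f"NTA tail {tail!r} longer than 2 nt")
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"NTA rate for {tail!r} outside [0, 1]")
        if sum(self.nta_rates.values()) > 1:
            raise ConfigurationError("NTA rates sum to more than 1")

    def rng(self, stream: str) -> np.random.Generator:
        """One independent RNG stream per output artifact, derived from seed."""
        key = zlib.crc32(stream.encode())  # stable across processes
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class TruthSet:
    """Ground truth recorded during simulation.

    ``origins[(child, side)][chrom]`` is the per-marker grandparental-origin
    vector (0 grandpaternal, 1 grandmaternal); ``breakpoints`` are the true
    crossover positions of each gamete.  eQTL and exported-cluster truth is
    filled in by :func:`simulate_counts`.
    """

    origins: dict[tuple[str, str], dict[str, np.ndarray]] = field(default_factory=dict)
    breakpoints: dict[tuple[str, str], dict[str, list[float]]] = field(default_factory=dict)
    marker_positions: dict[str, np.ndarray] = field(default_factory=dict)
    eqtl_transcripts: dict[str, tuple[float, float]] = field(default_factory=dict)
    exported_cluster_matures: list[str] = field(default_factory=list)
    exported_cluster_lfc: float = 0.0
    transcript_lfc: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "origins": {
                f"{c}|{s}": {ch: v.tolist() for ch, v in d.items()}
                for (c, s), d in self.origins.items()
            },
            "breakpoints": {
                f"{c}|{s}": {ch: list(map(float, v)) for ch, v in d.items()}
                for (c, s), d in self.breakpoints.items()
            },
            "eqtl_transcripts": {k: list(v) for k, v in self.eqtl_transcripts.items()},
            "exported_cluster_matures": self.exported_cluster_matures,
            "exported_cluster_lfc": self.exported_cluster_lfc,
            "transcript_lfc": self.transcript_lfc,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


# ---------------------------------------------------------------------------
# pedigree + genotypes
# ---------------------------------------------------------------------------

def make_pedigree(n_children: int = 11) -> Pedigree:
    """Four grandparents, two parents, ``n_children`` children."""
    members = [
        Individual("GF1", None, None, "M", 0),
        Individual("GM1", None, None, "F", 0),
        Individual("GF2", None, None, "M", 0),
        Individual("GM2", None, None, "F", 0),
        Individual("FAT", "GF1", "GM1", "M", 1),
        Individual("MOT", "GF2", "GM2", "F", 1),
    ]
    for i in range(n_children):
        sex = "M" if i % 2 == 0 else "F"
        members.append(Individual(f"C{i + 1:02d}", "FAT", "MOT", sex, 2))
    return Pedigree(members)


def _meiosis(hap0, hap1, positions, chrom_length, recomb_rate, rng):
    """One gamete from two parental haplotypes with Poisson crossovers.

    Returns (gamete alleles, per-marker origin vector, crossover positions).
    Origin 0 means the allele came from ``hap0``.
    """
    n_cx = rng.poisson(recomb_rate)
    cx = np.sort(rng.uniform(0, chrom_length, size=n_cx))
    start = int(rng.integers(0, 2))
    # origin flips parity at every crossover
    origin = (start + np.searchsorted(cx, positions, side="right")) % 2
    gamete = np.where(origin == 0, hap0, hap1)
    return gamete, origin, list(cx)


def simulate_pedigree_genotypes(
    config: SimulationConfig,
) -> tuple[Pedigree, GenotypeTable, TruthSet]:
    """Drop biallelic markers through two meioses of a three-generation family.

    Grandparent haplotypes are i.i.d. Bernoulli draws at each marker with
    minor-allele frequency ~ Uniform(0.2, 0.5); each parent is formed from
    one gamete per grandparent, and each child from one paternal and one
    maternal gamete, all with Poisson(``recomb_rate``) crossovers placed
    uniformly along the chromosome.  Genotypes are unphased dosages.
    """
    rng = config.rng("genotypes")
    ped = make_pedigree(config.n_children)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    marker_rows = []
    dosage_cols: dict[str, list[np.ndarray]] = {iid: [] for iid in ped.individuals}
    truth = TruthSet()
    for child in ped.children:
        for side in ("paternal", "maternal"):
            truth.origins[(child, side)] = {}
            truth.breakpoints[(child, side)] = {}

    for chrom in chroms:
        n = config.n_markers_per_chrom
        draw = np.unique(rng.integers(1, config.chrom_length, size=4 * n))
        while len(draw) < n:  # pragma: no cover - astronomically unlikely
            draw = np.unique(
                np.concatenate([draw, rng.integers(1, config.chrom_length, size=n)])
            )
        positions = np.sort(rng.choice(draw, size=n, replace=False))
        maf = rng.uniform(0.2, 0.5, size=n)

        # two haplotypes per grandparent
        gp_haps = {
            gp: [rng.binomial(1, maf), rng.binomial(1, maf)] for gp in ped.grandparents
        }
        # parental haplotypes: hap0 from the grandfather (origin code 0),
        # hap1 from the grandmother (origin code 1)
        parent_haps = {}
        for parent, (gf, gm) in (("FAT", ("GF1", "GM1")), ("MOT", ("GF2", "GM2"))):
            h_pat, _, _ = _meiosis(
                *gp_haps[gf], positions, config.chrom_length, config.recomb_rate, rng
            )
            h_mat, _, _ = _meiosis(
                *gp_haps[gm], positions, config.chrom_length, config.recomb_rate, rng
            )
            parent_haps[parent] = [h_pat, h_mat]

        child_haps = {}
        for child in ped.children:
            gp_gamete, gp_origin, gp_cx = _meiosis(
                *parent_haps["FAT"], positions, config.chrom_length, config.recomb_rate, rng
            )
            gm_gamete, gm_origin, gm_cx = _meiosis(
                *parent_haps["MOT"], positions, config.chrom_length, config.recomb_rate, rng
            )
            child_haps[child] = [gp_gamete, gm_gamete]
            truth.origins[(child, "paternal")][chrom] = gp_origin
            truth.breakpoints[(child, "paternal")][chrom] = gp_cx
            truth.origins[(child, "maternal")][chrom] = gm_origin
            truth.breakpoints[(child, "maternal")][chrom] = gm_cx

        truth.marker_positions[chrom] = positions
        for i, pos in enumerate(positions):
            marker_rows.append((f"{chrom}_{pos}", chrom, int(pos), "A", "G"))
        for gp in ped.grandparents:
            dosage_cols[gp].append(gp_haps[gp][0] + gp_haps[gp][1])
        for parent in ped.parents:
            dosage_cols[parent].append(parent_haps[parent][0] + parent_haps[parent][1])
        for child in ped.children:
            dosage_cols[child].append(child_haps[child][0] + child_haps[child][1])

    markers = pd.DataFrame(
        marker_rows, columns=["marker", "chrom", "pos", "ref", "alt"]
    ).set_index("marker")
    dosages = pd.DataFrame(
        {iid: np.concatenate(cols) for iid, cols in dosage_cols.items()},
        index=markers.index,
        dtype=np.int64,
    )
    return ped, GenotypeTable(markers, dosages), truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig) -> MirnaAnnotation:
    """Toy small-RNA annotation on the simulated chromosomes.

    Lays out one dense miRNA cluster of ``exported_cluster_size`` hairpins
    (2 kb apart, each yielding a 5p and a 3p mature), isolated singleton
    hairpins elsewhere, one mature shared by two distant hairpins (a
    multi-locus case), piRNAs, and a few rRNA/snoRNA/lincRNA/misc
    transcripts for the composition analysis.
    """
    rng = config.rng("annotation")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    hp_rows, mat_rows = [], []
    biotypes: dict[str, str] = {}

    def add_hairpin(name, chrom, start, strand="+"):
        hp_rows.append((name, chrom, start, start + 80, strand))

    def add_mature(name, chrom, start, parents, strand="+"):
        mat_rows.append((name, chrom, start, start + 22, strand, tuple(parents)))
        biotypes[name] = "miRNA"

    # exported cluster on chr1 at 5 Mb: hairpins 2 kb apart, 2 matures each
    cluster_start = 5_000_000
    for i in range(config.exported_cluster_size):
        hp = f"sim-mir-C{i + 1}"
        s = cluster_start + i * 2_000
        add_hairpin(hp, "chr1", s)
        add_mature(f"sim-miR-C{i + 1}-5p", "chr1", s + 5, [hp])
        add_mature(f"sim-miR-C{i + 1}-3p", "chr1", s + 50, [hp])

    # singleton hairpins spread over the chromosomes, >10 kb apart
    n_single = config.n_mirnas - config.exported_cluster_size
    for i in range(n_single):
        chrom = chroms[i % len(chroms)]
        s = 10_000_000 + (i // len(chroms)) * 1_500_000 + int(rng.integers(0, 500_000))
        hp = f"sim-mir-{i + 1}"
        add_hairpin(hp, chrom, s)
        add_mature(f"sim-miR-{i + 1}-5p", chrom, s + 5, [hp])
        if rng.random() < 0.5:
            add_mature(f"sim-miR-{i + 1}-3p", chrom, s + 50, [hp])

    # one mature produced by two hairpins at distant loci (multi-locus case)
    add_hairpin("sim-mir-dupA", chroms[-1], 90_000_000)
    add_hairpin("sim-mir-dupB", chroms[-1], 95_000_000)
    add_mature("sim-miR-dup-5p", chroms[-1], 90_000_005, ["sim-mir-dupA", "sim-mir-dupB"])

    hairpins = pd.DataFrame(
        hp_rows, columns=["name", "chrom", "start", "end", "strand"]
    ).set_index("name")
    matures = pd.DataFrame(
        mat_rows, columns=["name", "chrom", "start", "end", "strand", "parents"]
    ).set_index("name")

    for i in range(config.n_pirnas):
        biotypes[f"sim-piR-{i + 1}"] = "piRNA"
    for cls, n in (("rRNA", 2), ("snoRNA", 3), ("lincRNA", 3), ("misc", 3)):
        for i in range(n):
            biotypes[f"sim-{cls}-{i + 1}"] = cls

    return MirnaAnnotation(hairpins, matures, biotypes)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _origin_from_breakpoints(
    truth: TruthSet, child: str, side: str, chrom: str, pos: float
) -> int:
    """True grandparental origin of a gamete at an arbitrary position.

    The per-marker origin vector and the crossover list jointly determine
    the origin anywhere: parity differences equal crossover counts between
    positions, anchored at the first marker.
    """
    origins = truth.origins[(child, side)][chrom]
    cx = np.asarray(truth.breakpoints[(child, side)][chrom])
    positions = truth.marker_positions[chrom]
    k_pos = int(np.searchsorted(cx, pos))
    k_first = int(np.searchsorted(cx, positions[0]))
    return int((origins[0] + k_pos - k_first) % 2)


def simulate_counts(
    pedigree: Pedigree,
    annotation: MirnaAnnotation,
    config: SimulationConfig,
    truth: TruthSet | None = None,
    genotypes: GenotypeTable | None = None,
) -> tuple[CountMatrix, TruthSet]:
    """Negative-binomial counts for 2 x n_individuals paired libraries.

    Mean model per transcript t and sample s (individual i, compartment c):

        mu_ts = L_s * q_t * 2^(LFC_t * I[c = exosome]) * exp(bp*p_i + bm*m_i)

    with baseline relative abundances q_t (log-normal, normalised to sum 1),
    per-transcript compartment LFCs drawn around biotype-specific shifts,
    LFC = ``exported_cluster_lfc`` for exported-cluster matures, and the
    haplotype factor applied only to children at eQTL transcripts (p_i, m_i
    are the true parental-side origin codes at the transcript's locus).
    Var = mu + alpha_c * mu^2 via a gamma-Poisson mixture, with
    compartment-specific dispersion alpha_c.
    """
    if truth is None:
        truth = TruthSet()
    rng = config.rng("counts")

    cluster_matures = [
        m for m in annotation.matures.index if m.startswith("sim-miR-C")
    ]
    if config.exported_cluster_size >= 2 and len(cluster_matures) < 2:
        raise ConfigurationError(
            "annotation lacks a qualifying exported cluster "
            f"(need >= {config.exported_cluster_size} clustered hairpins)"
        )

    transcripts = list(annotation.matures.index) + [
        t for t, b in annotation.biotypes.items() if b != "miRNA"
    ]
    biot = {t: annotation.biotypes.get(t, "miRNA") for t in transcripts}
    n_t = len(transcripts)

    # baseline relative abundance: log-normal; exported cluster held low in
    # cells (nearly undetectable there, massive in exosomes)
    log_q = rng.normal(0.0, 1.2, size=n_t)
    q = np.exp(log_q)
    q /= q.sum()
    q = dict(zip(transcripts, q))
    cluster_cell_abundance = 2e-5  # ~20 reads/Mread in cells
    for m in cluster_matures:
        q[m] = cluster_cell_abundance

    # compartment LFCs
    lfc = {}
    for t in transcripts:
        lfc[t] = rng.normal(BIOTYPE_LFC_SHIFT[biot[t]], config.lfc_sd)
    for m in cluster_matures:
        lfc[m] = config.exported_cluster_lfc
    truth.transcript_lfc = dict(lfc)
    truth.exported_cluster_matures = list(cluster_matures)
    truth.exported_cluster_lfc = config.exported_cluster_lfc

    # eQTL truth: single-parent, non-cluster matures with a recorded locus
    truth.eqtl_transcripts = {}
    eqtl_codes: dict[str, tuple[dict[str, int], dict[str, int]]] = {}
    if config.n_eqtl_mirnas > 0:
        if not truth.origins:
            raise ConfigurationError(
                "planting eQTL effects requires the genotype TruthSet "
                "(run simulate_pedigree_genotypes first)"
            )
        candidates = [
            m
            for m, row in annotation.matures.iterrows()
            if len(row["parents"]) == 1 and m not in cluster_matures
        ]
        chosen = list(rng.choice(candidates, size=config.n_eqtl_mirnas, replace=False))
        for m in chosen:
            truth.eqtl_transcripts[m] = (config.eqtl_beta, 0.0)
            hp = annotation.matures.at[m, "parents"][0]
            chrom = annotation.hairpins.at[hp, "chrom"]
            mid = (annotation.hairpins.at[hp, "start"] + annotation.hairpins.at[hp, "end"]) / 2
            p_codes, m_codes = {}, {}
            for child in pedigree.children:
                p_codes[child] = _origin_from_breakpoints(truth, child, "paternal", chrom, mid)
                m_codes[child] = _origin_from_breakpoints(truth, child, "maternal", chrom, mid)
            eqtl_codes[m] = (p_codes, m_codes)

    individuals = pedigree.individuals
    sample_rows, sample_ids = [], []
    for comp in COMPARTMENTS:
        for iid in individuals:
            sid = f"{iid}_{comp}"
            sample_ids.append(sid)
            sample_rows.append((sid, iid, comp))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "individual", "compartment"]
    ).set_index("sample")

    lo, hi = config.library_size_range
    lib_sizes = rng.integers(lo, hi + 1, size=len(sample_ids))
    children = set(pedigree.children)

    counts = np.zeros((n_t, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        iid = samples.at[sid, "individual"]
        comp = samples.at[sid, "compartment"]
        alpha = config.nb_dispersion_exosome if comp == EXOSOME else config.nb_dispersion_cell
        mu = np.empty(n_t)
        for k, t in enumerate(transcripts):
            m_ts = lib_sizes[j] * q[t]
            if comp == EXOSOME:
                m_ts *= 2.0 ** lfc[t]
            if t in eqtl_codes and iid in children:
                bp, bm = truth.eqtl_transcripts[t]
                p_codes, m_codes = eqtl_codes[t]
                m_ts *= np.exp(bp * p_codes[iid] + bm * m_codes[iid])
            mu[k] = m_ts
        # gamma-Poisson: Var = mu + alpha mu^2
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
        counts[:, j] = rng.poisson(lam)

    cm = CountMatrix(pd.DataFrame(counts, index=transcripts, columns=sample_ids), samples)
    return cm, truth


# ---------------------------------------------------------------------------
# hairpin-local alignments + unmapped reads
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAlignments:
    """SAM text, unmapped FASTQ text, and the planted NTA truth."""

    sam_lines: list[str]
    fastq_lines: list[str]
    hairpin_seqs: dict[str, str]
    #: (hairpin, nta_label) -> read count; label "" means tail-free
    nta_truth: dict[tuple[str, str], int]
    n_aligned: int

    def write_sam(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.sam_lines) + "\n")

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.fastq_lines) + "\n")


def simulate_hairpin_alignments(
    config: SimulationConfig,
    n_reads: int = 2000,
    n_hairpins: int = 5,
    n_unmapped: int = 500,
    nta_rates: dict[str, float] | None = None,
    kmer_rate: float | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedAlignments:
    """Hairpin-local SAM alignments with soft-clipped nontemplated tails.

    Each read is a 22 nt substring of a random 70 nt hairpin; with the
    per-read probabilities in ``nta_rates`` a nontemplated 1-2 nt tail is
    appended (3', label "-XY") or prepended (5', label "XY-") and encoded
    as a CIGAR soft clip (e.g. ``22M2S``).  The unmapped FASTQ carries
    36 nt reads with the configured 10-mer planted at rate ``kmer_rate``
    for the k-mer mapping-bias QC stage.
    """
    if nta_rates is None:
        nta_rates = config.nta_rates
    for tail in nta_rates:
        if len(tail.strip("-")) > 2:
            raise ConfigurationError(f"NTA tail {tail!r} longer than 2 nt")
    if kmer_rate is None:
        kmer_rate = config.planted_kmer_rate
    if rng is None:
        rng = config.rng("alignments")

    hp_names = [f"sim-mir-{i + 1}" for i in range(n_hairpins)]
    hairpin_seqs = {
        name: "".join(rng.choice(DNA, size=70)) for name in hp_names
    }

    labels = list(nta_rates)
    probs = np.array([nta_rates[l] for l in labels])
    none_p = 1.0 - probs.sum()
    events = rng.choice(len(labels) + 1, size=n_reads, p=np.append(probs, none_p))

    sam_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in hp_names:
        sam_lines.append(f"@SQ\tSN:{name}\tLN:70")
    nta_truth: dict[tuple[str, str], int] = {}
    read_len = 22
    for i in range(n_reads):
        hp = hp_names[int(rng.integers(0, n_hairpins))]
        start = int(rng.integers(0, 70 - read_len + 1))
        core = hairpin_seqs[hp][start : start + read_len]
        ev = events[i]
        if ev < len(labels):
            label = labels[ev]
            tail = label.strip("-")
            if label.startswith("-"):  # 3' tail
                seq = core + tail
                cigar = f"{read_len}M{len(tail)}S"
            else:  # 5' tail
                seq = tail + core
                cigar = f"{len(tail)}S{read_len}M"
        else:
            label = ""
            seq = core
            cigar = f"{read_len}M"
        nta_truth[(hp, label)] = nta_truth.get((hp, label), 0) + 1
        sam_lines.append(
            "\t".join(
                [
                    f"read{i}",
                    "0",
                    hp,
                    str(start + 1),
                    "255",
                    cigar,
                    "*",
                    "0",
                    "0",
                    seq,
                    "I" * len(seq),
                ]
            )
        )

    fastq_lines = []
    kmer = config.planted_kmer
    for i in range(n_unmapped):
        seq = "".join(rng.choice(DNA, size=36))
        if rng.random() < kmer_rate:
            off = int(rng.integers(0, 36 - len(kmer) + 1))
            seq = seq[:off] + kmer + seq[off + len(kmer):]
        fastq_lines += [f"@unmapped{i}", seq, "+", "I" * 36]

    return SimulatedAlignments(sam_lines, fastq_lines, hairpin_seqs, nta_truth, n_reads)


# ---------------------------------------------------------------------------
# file writers (VCF / GFF3 / TSV)
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeTable, path) -> None:
    """Unphased biallelic genotypes as minimal VCF v4.2 (GT field only)."""
    individuals = list(genotypes.dosages.columns)
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in genotypes.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individuals)
            + "\n"
        )
        for mid, row in genotypes.markers.iterrows():
            gts = "\t".join(gt_code[int(genotypes.dosages.at[mid, i])] for i in individuals)
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{mid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_genotypes_tsv(genotypes: GenotypeTable, path) -> None:
    table = genotypes.markers.join(genotypes.dosages)
    table.rename_axis("marker").to_csv(path, sep="\t")


def write_pedigree_tsv(pedigree: Pedigree, path) -> None:
    rows = [
        (m.iid, m.father or ".", m.mother or ".", m.sex, m.generation)
        for m in pedigree.members.values()
    ]
    pd.DataFrame(rows, columns=["iid", "father", "mother", "sex", "generation"]).to_csv(
        path, sep="\t", index=False
    )


def write_gff3(annotation: MirnaAnnotation, path) -> None:
    """miRBase-dialect GFF3: hairpins as ``miRNA_primary_transcript``,
    matures as ``miRNA`` with ``Derives_from``; 1-based inclusive output.

    A mature with several parent hairpins is written once per parent with a
    distinct ID but a shared Name, as miRBase does for multi-locus matures.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, row in annotation.hairpins.iterrows():
            fh.write(
                f"{row['chrom']}\t.\tmiRNA_primary_transcript\t{row['start'] + 1}"
                f"\t{row['end']}\t.\t{row['strand']}\t.\tID={name};Name={name}\n"
            )
        for name, row in annotation.matures.iterrows():
            for k, parent in enumerate(row["parents"]):
                uid = name if len(row["parents"]) == 1 else f"{name}_{k + 1}"
                fh.write(
                    f"{row['chrom']}\t.\tmiRNA\t{row['start'] + 1}\t{row['end']}"
                    f"\t.\t{row['strand']}\t.\tID={uid};Name={name};Derives_from={parent}\n"
                )


def write_biotypes_tsv(annotation: MirnaAnnotation, path) -> None:
    pd.Series(annotation.biotypes, name="biotype").rename_axis("transcript").to_csv(
        path, sep="\t"
    )


def simulate_study(config: SimulationConfig):
    """Convenience: full synthetic study in one call.

    Returns (pedigree, genotypes, annotation, counts, truth).
    """
    pedigree, genotypes, truth = simulate_pedigree_genotypes(config)
    annotation = simulate_annotation(config)
    counts, truth = simulate_counts(pedigree, annotation, config, truth)
    return pedigree, genotypes, annotation, counts, truth
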