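"""Shared in-memory containers for the cell/exosome small-RNA pipeline.

All genomic coordinates are internal 0-based half-open; GFF3 I/O converts
from 1-based inclusive at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL = "cell"
EXOSOME = "exosome"
COMPARTMENTS = (CELL, EXOSOME)

#: Sentinel cluster assignment for matures whose parent hairpins span
#: more than one genomic cluster.
EXCLUDED_MULTI_CLUSTER = "EXCLUDED_MULTI_CLUSTER"

#: The six small-RNA classes entering the composition analysis.
BIOTYPE_CLASSES = ("lincRNA", "miRNA", "misc", "piRNA", "rRNA", "snoRNA")


class CountMatrix:
    """Transcripts x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with transcript names as index and sample IDs as columns.
    samples
        Sample metadata indexed by sample ID with at least the columns
        ``individual`` and ``compartment`` (one of ``cell``/``exosome``);
        an optional ``run`` column records the sequencing run.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        counts = counts.copy()
        samples = samples.copy()
        if not set(counts.columns) <= set(samples.index):
            missing = sorted(set(counts.columns) - set(samples.index))
            raise ValueError(f"samples missing metadata: {missing}")
        samples = samples.loc[list(counts.columns)]
        vals = counts.to_numpy()
        if vals.size and (np.any(vals < 0) or not np.issubdtype(vals.dtype, np.integer)):
            if np.issubdtype(vals.dtype, np.floating):
                if not np.allclose(vals, np.round(vals)) or np.any(vals < 0):
                    raise ValueError("counts must be non-negative integers")
                counts = counts.round().astype(np.int64)
            else:
                raise ValueError("counts must be non-negative integers")
        bad = samples["compartment"][~samples["compartment"].isin(COMPARTMENTS)]
        if len(bad):
            raise ValueError(f"unknown compartment labels: {sorted(set(bad))}")
        pairs = list(zip(samples["individual"], samples["compartment"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (individual, compartment) pair in metadata")
        self.counts = counts
        self.samples = samples

    @property
    def transcripts(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def compartment_samples(self, compartment: str) -> list[str]:
        mask = self.samples["compartment"] == compartment
        return list(self.samples.index[mask])

    def subset_transcripts(self, names) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(names)], self.samples)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.samples.loc[list(sample_ids)])

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("transcript").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(counts, samples)


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: str  # "M" or "F"
    generation: int  # 0 grandparents, 1 parents, 2 children


class Pedigree:
    """Three-generation nuclear family: grandparents, two parents, children."""

    def __init__(self, members: list[Individual]):
        self.members = {m.iid: m for m in members}
        if len(self.members) != len(members):
            raise ValueError("duplicate individual IDs in pedigree")

    @property
    def individuals(self) -> list[str]:
        return list(self.members)

    @property
    def grandparents(self) -> list[str]:
        return [i for i, m in self.members.items() if m.generation == 0]

    @property
    def parents(self) -> list[str]:
        return [i for i, m in self.members.items() if m.generation == 1]

    @property
    def children(self) -> list[str]:
        return [i for i, m in self.members.items() if m.generation == 2]

    @property
    def father(self) -> str:
        return next(i for i in self.parents if self.members[i].sex == "M")

    @property
    def mother(self) -> str:
        return next(i for i in self.parents if self.members[i].sex == "F")

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        m = self.members[iid]
        return m.father, m.mother

    def trios(self) -> list[tuple[str, str, str]]:
        """(child, father, mother) triples for every member with known parents."""
        out = []
        for iid, m in self.members.items():
            if m.father is not None and m.mother is not None:
                out.append((iid, m.father, m.mother))
        return out


MISSING_DOSAGE = -1


class GenotypeTable:
    """Biallelic unphased genotypes as dosages in {0, 1, 2} (-1 missing).

    ``markers`` is indexed by marker ID with columns chrom, pos, ref, alt;
    ``dosages`` shares that index and has one column per individual.
    """

    def __init__(self, markers: pd.DataFrame, dosages: pd.DataFrame):
        if not markers.index.equals(dosages.index):
            raise ValueError("markers and dosages must share an index")
        for chrom, grp in markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
        vals = dosages.to_numpy()
        if vals.size and not np.all(np.isin(vals, [0, 1, 2, MISSING_DOSAGE])):
            raise ValueError("dosages must be in {0, 1, 2} or -1 for missing")
        self.markers = markers.copy()
        self.dosages = dosages.copy()

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, marker_ids) -> "GenotypeTable":
        idx = list(marker_ids)
        return GenotypeTable(self.markers.loc[idx], self.dosages.loc[idx])

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))


@dataclass
class MirnaAnnotation:
    """Hairpin and mature miRNA records plus a transcript biotype map.

    ``hairpins``: DataFrame indexed by hairpin name with chrom, start, end,
    strand.  ``matures``: DataFrame indexed by mature name with chrom, start,
    end, strand and a ``parents`` column holding a tuple of parent hairpin
    names.  ``biotypes`` maps any transcript name to one of the six classes.
    """

    hairpins: pd.DataFrame
    matures: pd.DataFrame
    biotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.hairpins) and (self.hairpins["start"] >= self.hairpins["end"]).any():
            bad = self.hairpins.index[self.hairpins["start"] >= self.hairpins["end"]][0]
            raise ValueError(f"hairpin {bad} has start >= end")
        for name, parents in self.matures.get("parents", pd.Series(dtype=object)).items():
            if not parents:
                raise ValueError(f"mature {name} has no parent hairpin")
            for p in parents:
                if p not in self.hairpins.index:
                    raise ValueError(f"mature {name} references unknown hairpin {p}")

    def multi_locus_matures(self) -> set[str]:
        """Matures whose parent hairpins occupy more than one genomic locus."""
        out = set()
        for name, row in self.matures.iterrows():
            parents = row["parents"]
            if len(parents) > 1:
                loci = {
                    (self.hairpins.at[p, "chrom"], self.hairpins.at[p, "start"] // 1_000_000)
                    for p in parents
                }
                if len(loci) > 1 or len({self.hairpins.at[p, "start"] for p in parents}) > 1:
                    out.add(name)
        return out


@dataclass
class ClusterMap:
    """Partition of hairpins into proximity clusters plus mature assignments.

    ``clusters`` maps cluster ID to the frozenset of member hairpin names;
    ``mature_cluster`` maps each mature to its cluster ID or to
    :data:`EXCLUDED_MULTI_CLUSTER`.
    """

    clusters: dict[str, frozenset]
    mature_cluster: dict[str, str]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for cid, members in self.clusters.items():
            for h in members:
                if h in seen:
                    raise ValueError(f"hairpin {h} in clusters {seen[h]} and {cid}")
                seen[h] = cid
        self._hairpin_cluster = seen

    def cluster_of_hairpin(self, hairpin: str) -> str:
        return self._hairpin_cluster[hairpin]

    @property
    def n_hairpins(self) -> int:
        return len(self._hairpin_cluster)

    def excluded_matures(self) -> set[str]:
        return {m for m, c in self.mature_cluster.items() if c == EXCLUDED_MULTI_CLUSTER}


@dataclass
class HaplotypeBlock:
    """Genomic segment between recombination points in the children.

    ``paternal``/``maternal`` map child ID to the grandparental-origin code
    (0 = grandpaternal, 1 = grandmaternal) that child carries throughout the
    block on that parental side.
    """

    chrom: str
    start: int
    end: int
    paternal: dict[str, int]
    maternal: dict[str, int]
    n_informative_paternal: int = 0
    n_informative_maternal: int = 0

    @property
    def block_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end
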