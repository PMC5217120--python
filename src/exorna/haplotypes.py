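"""Pedigree phasing and haplotype blocks from unphased genotypes.

A three-generation family lets every informative marker be phased without
a population model: a heterozygous parent's alleles are assigned to the
grandpaternal (code 0) or grandmaternal (code 1) haplotype whenever the
grandparental genotypes disambiguate them, and each child's transmitted
allele then reveals which grandparental haplotype the child inherited.
Origin calls are smoothed by a sliding-window majority vote to absorb
genotyping error, and recombination breakpoints -- midpoints between the
flanking informative markers of every origin switch, pooled over all
children and both parental sides -- cut each chromosome into haplotype
blocks.  The per-child block codes (p_i, m_i) are exactly the regressors
of the downstream eQTL model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._data import MISSING_DOSAGE, GenotypeTable, HaplotypeBlock, Pedigree

UNKNOWN = -1


def _gamete_set(dosage: int) -> set:
    if dosage == MISSING_DOSAGE:
        return {0, 1}
    return {0: {0}, 1: {0, 1}, 2: {1}}[dosage]


def mendelian_filter(
    genotypes: GenotypeTable, pedigree: Pedigree
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop markers with any Mendelian-inconsistent trio.

    A trio (child, father, mother) is inconsistent when no pair of
    transmissible parental alleles sums to the child's dosage.  Missing
    genotypes are treated as unconstrained.
    """
    missing = [
        i for i in pedigree.individuals if i not in genotypes.dosages.columns
    ]
    if missing:
        raise KeyError(f"individuals missing from genotypes: {missing}")
    trios = pedigree.trios()
    bad_rows = []
    bad_markers = set()
    dos = genotypes.dosages
    for child, father, mother in trios:
        c = dos[child].to_numpy()
        f = dos[father].to_numpy()
        m = dos[mother].to_numpy()
        # possible child dosages: {a+b : a in gamete(f), b in gamete(m)}
        for idx in range(len(c)):
            if c[idx] == MISSING_DOSAGE:
                continue
            possible = {
                a + b for a in _gamete_set(int(f[idx])) for b in _gamete_set(int(m[idx]))
            }
            if int(c[idx]) not in possible:
                marker = genotypes.markers.index[idx]
                bad_markers.add(marker)
                bad_rows.append((marker, child, father, mother))
    report = pd.DataFrame(bad_rows, columns=["marker", "child", "father", "mother"])
    keep = [m for m in genotypes.markers.index if m not in bad_markers]
    return genotypes.subset_markers(keep), report


@dataclass
class PhasedParents:
    """Parental haplotypes anchored to grandparental origin.

    ``haplotypes[parent]`` is a DataFrame over markers with integer columns
    ``hap0`` (grandpaternal) and ``hap1`` (grandmaternal); -1 marks
    uninformative markers.
    """

    haplotypes: dict[str, pd.DataFrame]

    def informative_markers(self, parent: str) -> pd.Index:
        df = self.haplotypes[parent]
        return df.index[df["hap0"] != UNKNOWN]


def phase_parents(genotypes: GenotypeTable, pedigree: Pedigree) -> PhasedParents:
    """Assign each heterozygous parent's alleles to grandparental haplotypes.

    A marker is informative for a parent when the parent is heterozygous
    and the grandparental genotypes admit exactly one assignment of the
    two alleles to the grandfather- and grandmother-derived haplotypes
    (ambiguous when both grandparents are heterozygous or data is missing).
    """
    out = {}
    for parent in pedigree.parents:
        gf, gm = pedigree.parents_of(parent)
        if gf is None or gm is None:
            raise KeyError(f"parent {parent} lacks genotyped grandparents")
        p = genotypes.dosages[parent].to_numpy()
        f = genotypes.dosages[gf].to_numpy()
        m = genotypes.dosages[gm].to_numpy()
        hap0 = np.full(len(p), UNKNOWN, dtype=np.int64)
        hap1 = np.full(len(p), UNKNOWN, dtype=np.int64)
        for idx in np.nonzero(p == 1)[0]:
            fset = _gamete_set(int(f[idx]))
            mset = _gamete_set(int(m[idx]))
            config_a = 0 in fset and 1 in mset  # hap0=0, hap1=1
            config_b = 1 in fset and 0 in mset  # hap0=1, hap1=0
            if config_a and not config_b:
                hap0[idx], hap1[idx] = 0, 1
            elif config_b and not config_a:
                hap0[idx], hap1[idx] = 1, 0
        out[parent] = pd.DataFrame(
            {"hap0": hap0, "hap1": hap1}, index=genotypes.markers.index
        )
    return PhasedParents(out)


@dataclass
class TransmissionVector:
    """Per-child, per-parental-side grandparental-origin calls.

    ``calls[(child, side)][chrom]`` is a DataFrame over that child's
    deducible informative markers with columns pos, raw, origin (smoothed).
    ``side`` is "paternal" or "maternal".
    """

    calls: dict[tuple[str, str], dict[str, pd.DataFrame]]
    chrom_extent: dict[str, tuple[int, int]]
    informative_positions: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def _majority_smooth(raw: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window majority vote; ties keep the original call."""
    n = len(raw)
    half = w // 2
    out = raw.copy()
    for i in range(n):
        window = raw[max(0, i - half) : i + half + 1]
        ones = int(window.sum())
        zeros = len(window) - ones
        if ones > zeros:
            out[i] = 1
        elif zeros > ones:
            out[i] = 0
    return out


def infer_transmissions(
    genotypes: GenotypeTable,
    phased: PhasedParents,
    pedigree: Pedigree,
    smoothing_window: int = 5,
) -> TransmissionVector:
    """Determine which grandparental haplotype each child inherited.

    At a marker informative for a parent, the allele that parent
    transmitted is deduced from the child's dosage and the other parent's
    genotype (skipped when both transmissions are consistent), and mapped
    to origin 0/1 via the phased parental haplotypes.  Raw calls are then
    smoothed by a width-``smoothing_window`` majority vote.
    """
    w = smoothing_window
    if w < 3 or w % 2 == 0:
        raise ValueError("smoothing_window must be an odd integer >= 3")
    father, mother = pedigree.father, pedigree.mother
    chroms = genotypes.chromosomes()
    markers = genotypes.markers
    extent = {
        c: (int(markers.loc[markers["chrom"] == c, "pos"].min()),
            int(markers.loc[markers["chrom"] == c, "pos"].max()) + 1)
        for c in chroms
    }

    calls: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
    informative_positions: dict[tuple[str, str], np.ndarray] = {}
    for side, parent, other in (("paternal", father, mother), ("maternal", mother, father)):
        phase = phased.haplotypes[parent]
        informative = phase.index[phase["hap0"] != UNKNOWN]
        for chrom in chroms:
            chrom_markers = markers.index[markers["chrom"] == chrom]
            pos_inf = markers.loc[chrom_markers.intersection(informative), "pos"]
            informative_positions[(side, chrom)] = pos_inf.to_numpy()
        for child in pedigree.children:
            per_chrom = {}
            for chrom in chroms:
                chrom_mask = markers["chrom"] == chrom
                inf_here = [m for m in markers.index[chrom_mask] if m in set(informative)]
                rows = []
                for mk in inf_here:
                    c = int(genotypes.dosages.at[mk, child])
                    o = int(genotypes.dosages.at[mk, other])
                    if c == MISSING_DOSAGE:
                        continue
                    oset = _gamete_set(o)
                    candidates = [t for t in (0, 1) if (c - t) in oset]
                    if len(candidates) != 1:
                        continue
                    t = candidates[0]
                    origin = 0 if int(phase.at[mk, "hap0"]) == t else 1
                    rows.append((mk, int(markers.at[mk, "pos"]), origin))
                df = pd.DataFrame(rows, columns=["marker", "pos", "raw"]).set_index("marker")
                df["origin"] = _majority_smooth(df["raw"].to_numpy(), w) if len(df) else []
                per_chrom[chrom] = df
            calls[(child, side)] = per_chrom
    return TransmissionVector(calls, extent, informative_positions)


def segment_blocks(transmissions: TransmissionVector) -> list[HaplotypeBlock]:
    """Cut chromosomes into blocks at pooled recombination breakpoints.

    A breakpoint is the midpoint between the two flanking informative
    markers of any origin switch in any child on either parental side.
    Per-child codes inside a block come from that child's nearest
    smoothed call, which is constant across the block by construction.
    """
    breakpoints: dict[str, set] = {}
    for (child, side), per_chrom in transmissions.calls.items():
        for chrom, df in per_chrom.items():
            o = df["origin"].to_numpy()
            pos = df["pos"].to_numpy()
            for i in np.nonzero(np.diff(o) != 0)[0]:
                breakpoints.setdefault(chrom, set()).add((pos[i] + pos[i + 1]) / 2)

    blocks: list[HaplotypeBlock] = []
    children = sorted({c for c, _ in transmissions.calls})
    for chrom, (lo, hi) in transmissions.chrom_extent.items():
        cuts = sorted(breakpoints.get(chrom, set()))
        edges = [lo] + [int(round(c)) for c in cuts] + [hi]
        for start, end in zip(edges[:-1], edges[1:]):
            mid = (start + end) / 2
            codes = {"paternal": {}, "maternal": {}}
            ok = True
            for side in ("paternal", "maternal"):
                for child in children:
                    df = transmissions.calls[(child, side)][chrom]
                    if not len(df):
                        ok = False
                        break
                    pos = df["pos"].to_numpy()
                    inside = (pos >= start) & (pos < end)
                    if inside.any():
                        vals = df["origin"].to_numpy()[inside]
                        if len(np.unique(vals)) > 1:
                            raise RuntimeError(
                                f"{child}/{side} switches origin inside block "
                                f"{chrom}:{start}-{end} after smoothing"
                            )
                        codes[side][child] = int(vals[0])
                    else:
                        nearest = int(np.argmin(np.abs(pos - mid)))
                        codes[side][child] = int(df["origin"].to_numpy()[nearest])
                if not ok:
                    break
            if not ok:
                continue
            n_p = int(
                np.sum(
                    (transmissions.informative_positions.get(("paternal", chrom), np.array([])) >= start)
                    & (transmissions.informative_positions.get(("paternal", chrom), np.array([])) < end)
                )
            )
            n_m = int(
                np.sum(
                    (transmissions.informative_positions.get(("maternal", chrom), np.array([])) >= start)
                    & (transmissions.informative_positions.get(("maternal", chrom), np.array([])) < end)
                )
            )
            blocks.append(
                HaplotypeBlock(chrom, start, end, codes["paternal"], codes["maternal"], n_p, n_m)
            )
    return blocks


def blocks_to_bed(blocks: list[HaplotypeBlock], path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.block_id}\n")


def block_codes_table(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """Long-format per-child block codes (one row per block x child)."""
    rows = []
    for b in blocks:
        for child in b.paternal:
            rows.append(
                {
                    "block": b.block_id,
                    "chrom": b.chrom,
                    "start": b.start,
                    "end": b.end,
                    "child": child,
                    "paternal": b.paternal[child],
                    "maternal": b.maternal[child],
                }
            )
    return pd.DataFrame(rows)
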