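"""Nontemplated nucleotide addition (NTA) profiling from hairpin alignments.

Soft-clipped bases in hairpin-local alignments mark nucleotides added to
a mature miRNA's ends that the genome does not encode: a leading soft
clip is a 5' NTA, a trailing one a 3' NTA.  Labels are normalised as
"-XY" for 3' tails and "XY-" for 5' tails, uppercased.  Frequencies are
percentages of all hairpin-aligned reads; per-hairpin contribution tables
show which hairpins drive a given NTA.  The 5' and 3' streams stay
separate end-to-end; headline comparisons use the 3' stream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

BAM_CMATCH = {0, 7, 8}  # M, =, X consume both read and reference
BAM_CSOFT_CLIP = 4


@dataclass
class NtaRecord:
    hairpin: str
    side: str  # "5p" or "3p"
    clipped: str
    count: int = 1

    @property
    def label(self) -> str:
        return f"{self.clipped.upper()}-" if self.side == "5p" else f"-{self.clipped.upper()}"


@dataclass
class NtaExtraction:
    records: list[NtaRecord]
    n_aligned: int
    n_skipped_short: int = 0
    n_skipped_no_cigar: int = 0
    n_skipped_reverse: int = 0

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.label] = out.get(r.label, 0) + r.count
        return out

    def hairpin_label_counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for r in self.records:
            key = (r.hairpin, r.label)
            out[key] = out.get(key, 0) + r.count
        return out


def extract_ntas(alignment_path, min_aligned: int = 16) -> NtaExtraction:
    """Pull 5'/3' NTAs out of a SAM/BAM file via the CIGAR string.

    Reads with fewer than ``min_aligned`` matched bases are skipped;
    reverse-strand and unmapped records are excluded (hairpins are
    single-stranded references); records without a CIGAR are counted and
    skipped.  Reads with no soft clip count toward the aligned total as
    NTA-free; a read clipped on both ends contributes one record per side.
    """
    import pysam

    mode = "rb" if str(alignment_path).endswith(".bam") else "r"
    records: list[NtaRecord] = []
    n_aligned = n_short = n_nocigar = n_rev = 0
    with pysam.AlignmentFile(str(alignment_path), mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            if read.is_reverse:
                n_rev += 1
                continue
            cig = read.cigartuples
            if cig is None:
                n_nocigar += 1
                continue
            matched = sum(ln for op, ln in cig if op in BAM_CMATCH)
            if matched < min_aligned:
                n_short += 1
                continue
            n_aligned += 1
            seq = read.query_sequence or ""
            if cig[0][0] == BAM_CSOFT_CLIP:
                ln = cig[0][1]
                records.append(NtaRecord(read.reference_name, "5p", seq[:ln]))
            if len(cig) > 1 and cig[-1][0] == BAM_CSOFT_CLIP:
                ln = cig[-1][1]
                records.append(NtaRecord(read.reference_name, "3p", seq[-ln:]))
    return NtaExtraction(records, n_aligned, n_short, n_nocigar, n_rev)


@dataclass
class NtaProfile:
    """Per-sample NTA percentages of all hairpin-aligned reads."""

    percentages: dict[str, float]  # label -> % of aligned reads
    nta_free_percent: float
    other_percent: float  # clips longer than max_len
    n_aligned: int
    hairpin_counts: dict[tuple[str, str], int] = field(default_factory=dict)


def nta_frequency_table(extraction: NtaExtraction, max_len: int = 2) -> NtaProfile:
    """Percent of aligned reads carrying each 1-2 nt NTA.

    Longer clips are pooled into an "other" bucket; the NTA-free fraction
    (reads with no clip at all) completes the composition.  Because a read
    may carry both a 5' and a 3' tail, events rather than reads are
    counted; with single-ended tails the percentages, the NTA-free share
    and "other" sum to 100.
    """
    if extraction.n_aligned == 0:
        raise ValueError("no aligned reads")
    total = extraction.n_aligned
    label_counts = extraction.label_counts()
    pct: dict[str, float] = {}
    other = 0
    for label, cnt in label_counts.items():
        if len(label.strip("-")) <= max_len:
            pct[label] = 100.0 * cnt / total
        else:
            other += cnt
    # records are per clip event; with at most one clip per read this is the
    # number of clipped reads (double-clipped reads make "free" conservative)
    n_with_nta = sum(r.count for r in extraction.records)
    free = max(total - n_with_nta, 0)
    return NtaProfile(
        percentages=pct,
        nta_free_percent=100.0 * free / total,
        other_percent=100.0 * other / total,
        n_aligned=total,
        hairpin_counts=extraction.hairpin_label_counts(),
    )


def nta_hairpin_contribution(extraction: NtaExtraction, label: str) -> pd.Series:
    """Percent of all reads with ``label`` originating from each hairpin."""
    per_hp: dict[str, int] = {}
    for r in extraction.records:
        if r.label == label:
            per_hp[r.hairpin] = per_hp.get(r.hairpin, 0) + r.count
    total = sum(per_hp.values())
    if total == 0:
        raise ValueError(f"no reads carry NTA {label!r}")
    return pd.Series({h: 100.0 * c / total for h, c in per_hp.items()}, name=label).sort_values(
        ascending=False
    )


def compare_nta_between_compartments(
    cell_profiles: dict[str, NtaProfile],
    exosome_profiles: dict[str, NtaProfile],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Paired two-sided t-test per NTA label across individuals.

    Profiles are keyed by individual; each label's per-sample percentages
    in cells and exosomes are compared with a paired t-test, BH-adjusted
    over the labels.  The driver diagnostic reports the largest single-
    hairpin contribution share per compartment, exposing effects carried
    by a small number of highly abundant miRNAs.
    """
    individuals = sorted(cell_profiles)
    if set(individuals) != set(exosome_profiles):
        raise ValueError("cell and exosome profiles must cover the same individuals")
    labels = sorted(
        {l for p in cell_profiles.values() for l in p.percentages}
        | {l for p in exosome_profiles.values() for l in p.percentages}
    )
    rows = []
    for label in labels:
        x = np.array([cell_profiles[i].percentages.get(label, 0.0) for i in individuals])
        y = np.array([exosome_profiles[i].percentages.get(label, 0.0) for i in individuals])
        if np.allclose(x - y, (x - y)[0]):
            t, p = (0.0 if np.allclose(x, y) else np.nan), np.nan
        else:
            t, p = stats.ttest_rel(x, y)
        rows.append(
            {
                "nta": label,
                "mean_cell_pct": x.mean(),
                "mean_exosome_pct": y.mean(),
                "t": t,
                "pvalue": p,
                "top_hairpin_share_cell": _top_share(cell_profiles, label),
                "top_hairpin_share_exosome": _top_share(exosome_profiles, label),
            }
        )
    table = pd.DataFrame(rows).set_index("nta")
    tested = table["pvalue"].notna()
    table["padj"] = np.nan
    if tested.any():
        table.loc[tested, "padj"] = bh_adjust(table.loc[tested, "pvalue"].to_numpy())
    table["significant"] = table["padj"] < fdr
    return table


def _top_share(profiles: dict[str, NtaProfile], label: str) -> float:
    """Largest per-hairpin share of the label's reads, pooled over samples."""
    pooled: dict[str, int] = {}
    for p in profiles.values():
        for (hp, lab), cnt in p.hairpin_counts.items():
            if lab == label:
                pooled[hp] = pooled.get(hp, 0) + cnt
    total = sum(pooled.values())
    if total == 0:
        return np.nan
    return 100.0 * max(pooled.values()) / total
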