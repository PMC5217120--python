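"""Family-based haplotype eQTL mapping and its confounder checks.

For each transcript, the expression of the 11 children is regressed on
the parental haplotypes they inherited at the transcript's locus:

    log(Y_i + 1) ~ mu + beta_p * p_i + beta_m * m_i

where Y_i is the size-factor-normalized expression of child i and
p_i, m_i in {0, 1} code which paternal / maternal haplotype the child
received in the block containing the locus.  The model fit (R^2) yields
the p-value through the overall F-test; q-values control the BH FDR
within each compartment.  Sharing between cells and exosomes is assessed
by the Pearson correlation of effect sizes and by intersecting the
compartment-level hits at a 20% FDR.  Nongenetic-confounder checks rank
haplotypes by their genome-wide association counts, test unmapped-read
10-mer content against the haplotype groups, and probe sex confounding.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._data import CountMatrix, HaplotypeBlock, MirnaAnnotation, Pedigree
from .diffexp import bh_adjust, size_factors

P_FLOOR = np.finfo(float).tiny


@dataclass
class EqtlFit:
    """One haplotype-model fit: every symbol of the model equation."""

    transcript: str
    compartment: str
    n: int
    mu: float
    beta_p: float
    beta_m: float
    r2: float
    f_stat: float
    pvalue: float
    df_model: int
    df_resid: int
    qvalue: float = np.nan
    block: str = ""
    perfect_fit: bool = False
    untestable: bool = False


def fit_haplotype_model(
    y: np.ndarray,
    p: np.ndarray,
    m: np.ndarray,
    transcript: str = "",
    compartment: str = "",
    log=np.log,
) -> EqtlFit:
    """OLS of log(y + 1) on the paternal and maternal haplotype codes.

    Constant regressors are dropped (reducing model df); if both are
    constant the transcript is untestable.  The p-value is the upper tail
    of F(k, n - k - 1) at F = (R^2 / k) / ((1 - R^2) / (n - k - 1)).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    n = len(y)
    if len(p) != n or len(m) != n:
        raise ValueError("y, p, m must have equal length")
    if not np.all(np.isin(p, (0, 1))) or not np.all(np.isin(m, (0, 1))):
        raise ValueError("haplotype codes must be 0 or 1")
    ly = log(y + 1)

    cols, which = [], []
    if len(np.unique(p)) > 1:
        cols.append(p)
        which.append("p")
    if len(np.unique(m)) > 1:
        cols.append(m)
        which.append("m")
    k = len(cols)
    if k == 0:
        return EqtlFit(
            transcript, compartment, n, float(ly.mean()), np.nan, np.nan,
            np.nan, np.nan, np.nan, 0, n - 1, untestable=True,
        )
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 children (n={n}, k={k})")

    X = np.column_stack([np.ones(n)] + cols)
    coef, *_ = np.linalg.lstsq(X, ly, rcond=None)
    resid = ly - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    if ss_tot == 0:
        r2, f, pval = 0.0, 0.0, 1.0
        perfect = False
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
        df_resid = n - k - 1
        perfect = np.isclose(r2, 1.0, atol=1e-12)
        if perfect:
            f, pval = np.inf, P_FLOOR
        else:
            f = (r2 / k) / ((1.0 - r2) / df_resid)
            pval = max(float(stats.f.sf(f, k, df_resid)), P_FLOOR)
    betas = dict(zip(which, coef[1:]))
    return EqtlFit(
        transcript,
        compartment,
        n,
        float(coef[0]),
        float(betas.get("p", 0.0)),
        float(betas.get("m", 0.0)),
        float(r2),
        float(f),
        float(pval),
        k,
        n - k - 1,
        perfect_fit=bool(perfect),
    )


# ---------------------------------------------------------------------------
# transcript filtering and cis mapping
# ---------------------------------------------------------------------------

def eqtl_expression_filter(
    normalized: pd.DataFrame,
    children_samples: list[str],
    intervals: pd.DataFrame | None = None,
    multi_locus: set | None = None,
    variant_positions: pd.DataFrame | None = None,
    min_median: float = 10.0,
) -> list[str]:
    """Transcripts eligible for eQTL testing in one compartment.

    Keeps transcripts whose median normalized expression over the
    children's samples is at least ``min_median``, then drops transcripts
    flagged multi-locus and transcripts whose genomic interval overlaps a
    retained variant (mapping bias risk at short read lengths).
    """
    med = normalized[children_samples].median(axis=1)
    kept = list(normalized.index[med >= min_median])
    if multi_locus:
        kept = [t for t in kept if t not in multi_locus]
    if variant_positions is not None and len(variant_positions) and intervals is not None:
        out = []
        for t in kept:
            if t not in intervals.index:
                raise KeyError(f"no annotation interval for tested transcript {t}")
            chrom = intervals.at[t, "chrom"]
            s, e = intervals.at[t, "start"], intervals.at[t, "end"]
            hits = variant_positions[
                (variant_positions["chrom"] == chrom)
                & (variant_positions["pos"] >= s)
                & (variant_positions["pos"] < e)
            ]
            if not len(hits):
                out.append(t)
        kept = out
    return kept


def _transcript_locus(annotation: MirnaAnnotation, transcript: str) -> tuple[str, float]:
    """cis anchor: midpoint of the transcript's (single) parent hairpin."""
    if transcript in annotation.matures.index:
        parents = annotation.matures.at[transcript, "parents"]
        hp = parents[0]
        row = annotation.hairpins.loc[hp]
    elif transcript in annotation.hairpins.index:
        row = annotation.hairpins.loc[transcript]
    else:
        raise KeyError(f"transcript {transcript} has no annotated locus")
    return row["chrom"], (row["start"] + row["end"]) / 2


def _codes(block: HaplotypeBlock, children: list[str]) -> tuple[np.ndarray, np.ndarray]:
    p = np.array([block.paternal[c] for c in children], dtype=float)
    m = np.array([block.maternal[c] for c in children], dtype=float)
    return p, m


def map_eqtls(
    counts: CountMatrix,
    blocks: list[HaplotypeBlock],
    annotation: MirnaAnnotation,
    pedigree: Pedigree,
    compartment: str,
    multi_locus: set | None = None,
    variant_positions: pd.DataFrame | None = None,
    min_median: float = 10.0,
) -> pd.DataFrame:
    """Fit the haplotype model for every eligible transcript in ``compartment``.

    Size factors come from all of the compartment's samples; the children
    subset is taken afterwards.  Each transcript is assigned the block
    containing its hairpin midpoint (skipped with a note if outside every
    block); BH q-values are computed within the compartment.
    """
    comp_samples = counts.compartment_samples(compartment)
    sub = counts.subset_samples(comp_samples)
    sf = size_factors(sub)
    norm = sub.counts / sf
    child_samples = [
        s for s in comp_samples if sub.samples.at[s, "individual"] in set(pedigree.children)
    ]
    child_order = [sub.samples.at[s, "individual"] for s in child_samples]

    if multi_locus is None:
        multi_locus = annotation.multi_locus_matures()
    intervals = annotation.matures[["chrom", "start", "end"]]
    testable = [t for t in norm.index if t in annotation.matures.index]
    kept = eqtl_expression_filter(
        norm.loc[testable], child_samples, intervals, multi_locus, variant_positions, min_median
    )

    fits: list[EqtlFit] = []
    for t in kept:
        chrom, mid = _transcript_locus(annotation, t)
        block = next((b for b in blocks if b.contains(chrom, mid)), None)
        if block is None:
            continue
        y = norm.loc[t, child_samples].to_numpy()
        p, m = _codes(block, child_order)
        fit = fit_haplotype_model(y, p, m, transcript=t, compartment=compartment)
        fit.block = block.block_id
        fits.append(fit)

    table = pd.DataFrame([vars(f) for f in fits])
    if len(table):
        tested = table["pvalue"].notna()
        table.loc[tested, "qvalue"] = bh_adjust(table.loc[tested, "pvalue"].to_numpy())
        table = table.set_index("transcript")
    return table


# ---------------------------------------------------------------------------
# cross-compartment sharing
# ---------------------------------------------------------------------------

def effect_correlation(cell_fits: pd.DataFrame, exosome_fits: pd.DataFrame) -> dict:
    """Pearson correlation of haplotype effect sizes across compartments."""
    shared = cell_fits.index.intersection(exosome_fits.index)
    shared = [
        t
        for t in shared
        if np.isfinite(cell_fits.at[t, "beta_p"]) and np.isfinite(exosome_fits.at[t, "beta_p"])
    ]
    if len(shared) < 3:
        raise ValueError("need >= 3 transcripts tested in both compartments")
    out = {"n": len(shared)}
    for key in ("beta_p", "beta_m"):
        with warnings.catch_warnings():
            # a constant effect vector (e.g. every beta_m dropped to 0)
            # legitimately yields an undefined correlation
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            r, p = stats.pearsonr(
                cell_fits.loc[shared, key], exosome_fits.loc[shared, key]
            )
        out[f"r_{key}"] = float(r)
        out[f"p_{key}"] = float(p)
    return out


def shared_eqtls(
    cell_fits: pd.DataFrame, exosome_fits: pd.DataFrame, fdr: float = 0.20
) -> pd.DataFrame:
    """Transcripts significant at the given FDR in BOTH compartments."""
    if not len(cell_fits) or not len(exosome_fits):
        return pd.DataFrame()
    hits = cell_fits.index[cell_fits["qvalue"] <= fdr].intersection(
        exosome_fits.index[exosome_fits["qvalue"] <= fdr]
    )
    out = cell_fits.loc[hits].join(
        exosome_fits.loc[hits], lsuffix="_cell", rsuffix="_exosome"
    )
    return out


# ---------------------------------------------------------------------------
# nongenetic-factor checks
# ---------------------------------------------------------------------------

def rank_haplotypes_by_associations(
    counts: CountMatrix,
    blocks: list[HaplotypeBlock],
    pedigree: Pedigree,
    compartment: str,
    alpha: float = 0.05,
    min_median: float = 10.0,
) -> pd.DataFrame:
    """Genome-wide trans scan: every block against every tested transcript.

    Blocks are ranked by the number of transcripts they associate with at
    the nominal ``alpha``; an unusually high count flags a haplotype whose
    segregation pattern likely tracks a technical factor.
    """
    comp_samples = counts.compartment_samples(compartment)
    sub = counts.subset_samples(comp_samples)
    norm = sub.counts / size_factors(sub)
    child_samples = [
        s for s in comp_samples if sub.samples.at[s, "individual"] in set(pedigree.children)
    ]
    child_order = [sub.samples.at[s, "individual"] for s in child_samples]
    med = norm[child_samples].median(axis=1)
    transcripts = list(norm.index[med >= min_median])

    rows = []
    for block in blocks:
        p, m = _codes(block, child_order)
        n_sig = 0
        for t in transcripts:
            fit = fit_haplotype_model(norm.loc[t, child_samples].to_numpy(), p, m)
            if np.isfinite(fit.pvalue) and fit.pvalue <= alpha:
                n_sig += 1
        rows.append({"block": block.block_id, "n_associated": n_sig})
    table = pd.DataFrame(rows).set_index("block")
    table["rank"] = table["n_associated"].rank(ascending=False, method="min").astype(int)
    return table.sort_values("n_associated", ascending=False)


def load_reads_fastq(path) -> list[str]:
    """Read sequences (as strings) from an unmapped-reads FASTQ file."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def count_kmers(reads: list[str], k: int = 10) -> dict[str, int]:
    """All k-length windows over every read (n - k + 1 per read)."""
    counts: dict[str, int] = {}
    for seq in reads:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_bias_check(
    reads_per_child: dict[str, list[str]],
    block: HaplotypeBlock,
    beta: float,
    side: str = "paternal",
    k: int = 10,
    total_reads: dict[str, int] | None = None,
    alpha: float = 0.05,
    prevalence_floor: float = 0.5,
) -> dict:
    """Mapping-bias QC for one candidate eQTL via unmapped-read k-mers.

    A spurious eQTL driven by haplotype-dependent mapping rates would show
    an excess of some k-mer in the unmapped reads of the LOW-expression
    haplotype group.  For every k-mer present in at least
    ``prevalence_floor`` of the children, normalized counts (per total
    sequenced reads) are compared between haplotype groups with a
    one-sided Wilcoxon rank-sum test in the direction opposing the eQTL
    effect; the check passes when no k-mer reaches ``alpha``.
    """
    if any(len(r) == 0 for r in reads_per_child.values()) or not reads_per_child:
        raise ValueError("empty unmapped read set")
    codes = block.paternal if side == "paternal" else block.maternal
    children = sorted(reads_per_child)
    if total_reads is None:
        total_reads = {c: len(reads_per_child[c]) for c in children}

    norm_counts: dict[str, dict[str, float]] = {}
    for c in children:
        kc = count_kmers(reads_per_child[c], k)
        norm_counts[c] = {km: v / total_reads[c] for km, v in kc.items()}

    all_kmers: dict[str, int] = {}
    for c in children:
        for km in norm_counts[c]:
            all_kmers[km] = all_kmers.get(km, 0) + 1
    tested = [km for km, nv in all_kmers.items() if nv >= prevalence_floor * len(children)]

    # the low-expression group: code 0 when beta > 0, code 1 otherwise
    low_code = 0 if beta > 0 else 1
    low = [c for c in children if codes[c] == low_code]
    high = [c for c in children if codes[c] != low_code]
    if not low or not high:
        raise ValueError("haplotype codes are constant among these children")

    offending = []
    for km in tested:
        x = np.array([norm_counts[c].get(km, 0.0) for c in low])
        y = np.array([norm_counts[c].get(km, 0.0) for c in high])
        res = stats.mannwhitneyu(x, y, alternative="greater")
        if res.pvalue <= alpha:
            offending.append((km, float(res.pvalue)))
    return {
        "pass": not offending,
        "offending_kmers": sorted(offending, key=lambda t: t[1]),
        "n_kmers_tested": len(tested),
    }


def sex_confounding_check(
    block: HaplotypeBlock, pedigree: Pedigree, side: str = "paternal"
) -> dict:
    """Fisher's exact association between block codes and child sex."""
    codes = block.paternal if side == "paternal" else block.maternal
    table = np.zeros((2, 2), dtype=int)
    for child, code in codes.items():
        sex = pedigree.members[child].sex
        table[code, 0 if sex == "M" else 1] += 1
    odds, p = stats.fisher_exact(table)
    return {"table": table.tolist(), "odds_ratio": float(odds), "pvalue": float(p)}
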