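"""Two-step count merging, RNA-biotype composition, and compartment tests.

Per-sample proportions of reads in the six small-RNA classes (lincRNA,
miRNA, misc, piRNA, rRNA, snoRNA) form a closed composition; cells and
exosomes are compared per class with a paired two-sided t-test (paired on
individual) and Bonferroni correction over the six classes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._data import BIOTYPE_CLASSES, CELL, COMPARTMENTS, EXOSOME, CountMatrix


def merge_two_step_counts(direct: CountMatrix, genome_assigned: CountMatrix) -> CountMatrix:
    """Add direct-mapping counts to genome-mapping counts per transcript.

    The two inputs must cover the same samples; transcript name spaces are
    unioned, and a transcript present in only one input keeps that input's
    count.  Grand totals are conserved.
    """
    if set(direct.sample_ids) != set(genome_assigned.sample_ids):
        raise ValueError("sample sets of the two count inputs differ")
    g = genome_assigned.counts[list(direct.sample_ids)]
    merged = direct.counts.add(g, fill_value=0).astype(np.int64)
    return CountMatrix(merged, direct.samples)


def biotype_proportions(
    counts: CountMatrix, biotypes: dict[str, str], classes=BIOTYPE_CLASSES
) -> pd.DataFrame:
    """Per-sample proportion of mapped reads in each small-RNA class.

    Transcripts outside the six plotted classes are dropped before
    normalisation, so each sample's proportions sum to exactly 1.
    """
    unknown = [t for t in counts.transcripts if t not in biotypes]
    if unknown:
        raise KeyError(f"transcripts without a biotype: {sorted(unknown)[:5]}")
    cls = pd.Series({t: biotypes[t] for t in counts.transcripts})
    keep = cls[cls.isin(classes)]
    per_class = counts.counts.loc[keep.index].groupby(keep).sum()
    per_class = per_class.reindex(list(classes), fill_value=0)
    totals = per_class.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero mapped reads in the six classes: {bad}")
    props = (per_class / totals).T  # samples x classes
    props.index.name = "sample"
    return props


def compare_compositions(
    proportions: pd.DataFrame, samples: pd.DataFrame, bonferroni_m: int | None = None
) -> pd.DataFrame:
    """Paired two-sided t-test per class between cell and exosome proportions.

    Pairing is on individual; the Bonferroni factor defaults to the number
    of classes tested (six).  Classes whose paired differences have zero
    variance get ``p = NaN`` and ``degenerate = True`` rather than a
    fabricated zero.
    """
    meta = samples.loc[proportions.index]
    cells = meta[meta["compartment"] == CELL]
    exos = meta[meta["compartment"] == EXOSOME]
    common = sorted(set(cells["individual"]) & set(exos["individual"]))
    if set(cells["individual"]) != set(exos["individual"]):
        odd = set(cells["individual"]) ^ set(exos["individual"])
        raise ValueError(f"unpaired individuals: {sorted(odd)}")
    cell_ids = cells.reset_index().set_index("individual").loc[common].iloc[:, 0]
    exo_ids = exos.reset_index().set_index("individual").loc[common].iloc[:, 0]

    m = bonferroni_m if bonferroni_m is not None else proportions.shape[1]
    rows = []
    for cls in proportions.columns:
        x = proportions.loc[cell_ids, cls].to_numpy()
        y = proportions.loc[exo_ids, cls].to_numpy()
        diff = x - y
        degenerate = np.allclose(diff.std(ddof=1), 0.0)
        if degenerate:
            t, p = (0.0 if np.allclose(diff, 0) else np.nan), np.nan
        else:
            t, p = stats.ttest_rel(x, y)
        rows.append(
            {
                "class": cls,
                "mean_cell": x.mean(),
                "mean_exosome": y.mean(),
                "t": t,
                "p": p,
                "p_bonferroni": min(1.0, m * p) if np.isfinite(p) else np.nan,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def downsample_counts(counts: CountMatrix, fraction: float, seed: int) -> CountMatrix:
    """Binomial thinning of every count to an expected ``fraction`` of depth."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return CountMatrix(counts.counts, counts.samples)
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(counts.counts.to_numpy(), fraction)
    return CountMatrix(
        pd.DataFrame(thinned, index=counts.transcripts, columns=counts.sample_ids),
        counts.samples,
    )
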