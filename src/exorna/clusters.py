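"""miRNA genomic clusters: the 10-kb proximity rule and count aggregation.

An miRNA cluster is a set of hairpins in which every member lies within
10 kb of at least one other member, i.e. the connected components of the
proximity graph linking two hairpins on the same chromosome when the gap
between their genomic intervals is at most ``max_gap``.  Mature-level
counts are summed per cluster, excluding matures whose parent hairpins
span more than one cluster (those reads could have originated from any
of them).  Singleton hairpins form singleton clusters, so their mature
and cluster counts are identical.
"""
from __future__ import annotations

import pandas as pd

from ._data import (
    EXCLUDED_MULTI_CLUSTER,
    ClusterMap,
    CountMatrix,
    MirnaAnnotation,
)


class AnnotationError(ValueError):
    pass


def read_mirna_annotation(gff3_path, biotypes: dict[str, str] | None = None) -> MirnaAnnotation:
    """Parse a miRBase-dialect GFF3 into a :class:`MirnaAnnotation`.

    Hairpins are ``miRNA_primary_transcript`` features, matures are
    ``miRNA`` features linked by ``Derives_from``.  Matures written once
    per parent locus (shared Name, distinct IDs) are merged into a single
    record carrying every parent.  GFF3 coordinates (1-based inclusive)
    become 0-based half-open.
    """
    import gffutils

    empty_cols = ["name", "chrom", "start", "end", "strand"]
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return MirnaAnnotation(
            pd.DataFrame(columns=empty_cols).set_index("name"),
            pd.DataFrame(columns=empty_cols + ["parents"]).set_index("name"),
            dict(biotypes or {}),
        )
    hp_rows = []
    id_to_name = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = feat.attributes.get("Name", [feat.id])[0]
        if feat.end < feat.start:
            raise AnnotationError(f"hairpin {name}: end < start")
        hp_rows.append((name, feat.seqid, feat.start - 1, feat.end, feat.strand))
        id_to_name[feat.attributes.get("ID", [feat.id])[0]] = name

    mature: dict[str, dict] = {}
    for feat in db.features_of_type("miRNA"):
        name = feat.attributes.get("Name", [feat.id])[0]
        if feat.end < feat.start:
            raise AnnotationError(f"mature {name}: end < start")
        parents = feat.attributes.get("Derives_from", [])
        if not parents:
            raise AnnotationError(f"mature {name} has no Derives_from parent")
        parent_names = []
        for p in parents:
            if p not in id_to_name:
                raise AnnotationError(f"mature {name}: unresolvable parent {p!r}")
            parent_names.append(id_to_name[p])
        rec = mature.setdefault(
            name,
            {
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
                "parents": [],
            },
        )
        rec["parents"].extend(parent_names)

    hairpins = pd.DataFrame(
        hp_rows, columns=["name", "chrom", "start", "end", "strand"]
    ).set_index("name")
    matures = pd.DataFrame(
        [
            (n, r["chrom"], r["start"], r["end"], r["strand"], tuple(dict.fromkeys(r["parents"])))
            for n, r in mature.items()
        ],
        columns=["name", "chrom", "start", "end", "strand", "parents"],
    ).set_index("name")
    return MirnaAnnotation(hairpins, matures, dict(biotypes or {}))


def build_clusters(
    annotation: MirnaAnnotation, max_gap: int = 10_000, use_strand: bool = False
) -> ClusterMap:
    """Single-linkage hairpin clusters under the inter-interval gap rule.

    Two hairpins are linked iff they share a chromosome (and strand, when
    ``use_strand``) and ``max(0, later_start - earlier_end) <= max_gap``.
    Because proximity along a line is involved, a sorted sweep tracking the
    running maximum end recovers the connected components exactly.

    Matures whose parent hairpins fall into more than one cluster are
    assigned :data:`EXCLUDED_MULTI_CLUSTER`.
    """
    hp = annotation.hairpins
    keys = ["chrom", "strand"] if use_strand else ["chrom"]
    hairpin_cluster: dict[str, str] = {}
    clusters: dict[str, set] = {}
    n_cluster = 0
    if len(hp):
        for _, group in hp.groupby(keys, sort=True):
            group = group.sort_values(["start", "end"])
            current: list[str] = []
            max_end = None
            for name, row in group.iterrows():
                gap = max(0, row["start"] - max_end) if max_end is not None else None
                if max_end is None or gap > max_gap:
                    if current:
                        n_cluster += 1
                        clusters[f"cluster_{n_cluster}"] = set(current)
                    current = []
                    max_end = row["end"]
                else:
                    max_end = max(max_end, row["end"])
                current.append(name)
            if current:
                n_cluster += 1
                clusters[f"cluster_{n_cluster}"] = set(current)

    for cid, members in clusters.items():
        for h in members:
            hairpin_cluster[h] = cid

    mature_cluster: dict[str, str] = {}
    for name, row in annotation.matures.iterrows():
        cids = {hairpin_cluster[p] for p in row["parents"]}
        mature_cluster[name] = cids.pop() if len(cids) == 1 else EXCLUDED_MULTI_CLUSTER

    return ClusterMap({c: frozenset(m) for c, m in clusters.items()}, mature_cluster)


def aggregate_cluster_counts(counts: CountMatrix, cluster_map: ClusterMap) -> CountMatrix:
    """Sum mature-level counts per cluster per sample.

    Matures flagged :data:`EXCLUDED_MULTI_CLUSTER` contribute nothing;
    clusters whose matures are all excluded (or absent from the count
    matrix) appear as all-zero rows, keeping the cluster universe stable.
    """
    missing = [t for t in counts.transcripts if t not in cluster_map.mature_cluster]
    if missing:
        raise KeyError(f"matures absent from cluster map: {sorted(missing)}")
    assign = pd.Series(
        {t: cluster_map.mature_cluster[t] for t in counts.transcripts}, name="cluster"
    )
    keep = assign[assign != EXCLUDED_MULTI_CLUSTER]
    agg = counts.counts.loc[keep.index].groupby(keep).sum()
    agg = agg.reindex(list(cluster_map.clusters), fill_value=0)
    agg.index.name = "cluster"
    return CountMatrix(agg, counts.samples)


def cluster_table(annotation: MirnaAnnotation, cluster_map: ClusterMap) -> pd.DataFrame:
    """Per-cluster summary: span, member hairpins/matures, exclusions."""
    mat_by_cluster: dict[str, list[str]] = {}
    excluded: list[str] = []
    for m, c in cluster_map.mature_cluster.items():
        if c == EXCLUDED_MULTI_CLUSTER:
            excluded.append(m)
        else:
            mat_by_cluster.setdefault(c, []).append(m)
    rows = []
    for cid, members in cluster_map.clusters.items():
        sub = annotation.hairpins.loc[sorted(members)]
        rows.append(
            {
                "cluster": cid,
                "chrom": sub["chrom"].iloc[0],
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "n_hairpins": len(members),
                "hairpins": ",".join(sorted(members)),
                "matures": ",".join(sorted(mat_by_cluster.get(cid, []))),
            }
        )
    table = pd.DataFrame(rows).set_index("cluster")
    table.attrs["excluded_matures"] = sorted(excluded)
    return table
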