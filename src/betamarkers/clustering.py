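"""Tissue-tropism clustering of the curated marker panel.

Marker genes are clustered on their z-scored tissue expression profiles
(correlation distance, centroid linkage).  Cutting the dendrogram at the
silhouette-optimal number of clusters and contrasting per-cluster mean
z-scores between tissue groups assigns each gene a tropism label:

* ``B`` — near-exclusive beta-cell selectivity;
* ``A`` — shared between beta cells and neural tissues (neuroendocrine);
* ``C`` — shared with immune and gut mucosal tissues;
* ``unassigned`` — no clear group contrast.

For rows standardized to mean 0 / SD 1 (population SD over the k tissues),
the squared Euclidean distance equals 2k(1 - r) with r the Pearson
correlation, so centroid linkage on z-scored rows is a faithful
correlation/centroid clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from .io import ExpressionMatrix, OrthologMap
from .markers import tissue_means
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TissueGroups:
    """Disjoint named groups covering all atlas tissues."""

    beta: list[str]
    neural: list[str]
    immune_gut: list[str]
    other: list[str] = field(default_factory=list)

    def validate(self, tissues: list[str]) -> None:
        groups = [self.beta, self.neural, self.immune_gut, self.other]
        flat = [t for g in groups for t in g]
        if len(flat) != len(set(flat)):
            raise ValueError("tissue groups overlap")
        missing = set(tissues) - set(flat)
        if missing:
            raise ValueError(f"tissues not covered by groups: {sorted(missing)}")


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> A | B | C | unassigned
    linkage: np.ndarray
    k: int
    cluster_of: pd.Series  # gene -> cluster index at the chosen cut
    group_z: pd.DataFrame  # cluster index -> mean z per tissue group
    silhouette: float
    constant_genes: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def zscore_rows(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each gene row across tissues (population SD).

    Constant rows cannot be standardized; they are set to all-zero
    (correlation 0 to everything) and reported.
    """
    arr = profiles.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat] = 0.0
    constant = list(profiles.index[flat])
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns), constant


def hierarchical_cluster(profiles: pd.DataFrame) -> np.ndarray:
    """Centroid-linkage dendrogram on correlation distance.

    Rows are z-scored first, after which Euclidean distance is a monotone
    transform of 1 - Pearson correlation; scipy's merge order is
    deterministic with ties broken by the smallest index pair.  Centroid
    linkage can produce height inversions; heights are reported as-is and
    cuts use the cluster count, never a height.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need >=2 genes to cluster")
    z, _ = zscore_rows(profiles)
    return hierarchy.linkage(z.to_numpy(), method="centroid")


def gene_profiles(
    atlas: ExpressionMatrix,
    genes: list[str],
    omap: OrthologMap,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 tissue profiles: probe tissue-means averaged per gene."""
    means = tissue_means(atlas, floor=floor)
    log_means = np.log2(means)
    gene_lookup = omap.gene_of(atlas.species)
    rows = {}
    for gene in genes:
        probes = [p for p in gene_lookup.index[gene_lookup == gene] if p in log_means.index]
        if probes:
            rows[gene] = log_means.loc[probes].mean(axis=0)
    return pd.DataFrame(rows).T


def assign_tropism(
    profiles: pd.DataFrame,
    groups: TissueGroups,
    k_range: range = range(3, 9),
    z_threshold: float = 0.5,
) -> ClusterAssignment:
    """Cluster panel genes and label clusters by tissue-group contrast.

    The dendrogram is cut at every k in ``k_range`` and the silhouette-
    maximizing cut retained.  Each cluster's mean z-score per tissue group
    decides its label: B when beta dominates with neural and immune/gut
    means below ``z_threshold``; A when beta and neural both reach the
    threshold; C when beta and immune/gut both reach it (the larger of
    neural/immune wins when both qualify); anything else is unassigned.
    """
    if profiles.shape[0] == 0:
        raise ValueError("empty panel")
    groups.validate(list(profiles.columns))
    z, constant = zscore_rows(profiles)
    link = hierarchy.linkage(z.to_numpy(), method="centroid")
    best_k, best_sil, best_cut = None, -np.inf, None
    for k in k_range:
        if k >= profiles.shape[0]:
            break
        cut = hierarchy.fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(cut)) < 2:
            continue
        sil = silhouette_score(z.to_numpy(), cut)
        if sil > best_sil:
            best_k, best_sil, best_cut = k, float(sil), cut
    if best_cut is None:
        best_k, best_sil = 1, 0.0
        best_cut = np.ones(profiles.shape[0], dtype=int)
    cluster_of = pd.Series(best_cut, index=profiles.index)

    group_means = {}
    for name, members in (
        ("beta", groups.beta),
        ("neural", groups.neural),
        ("immune_gut", groups.immune_gut),
    ):
        group_means[name] = z[members].mean(axis=1)
    gz = pd.DataFrame(group_means)
    group_z = gz.groupby(cluster_of).mean()

    labels = {}
    for cluster, row in group_z.iterrows():
        zb, zn, zi = row["beta"], row["neural"], row["immune_gut"]
        if zb >= z_threshold and zn < z_threshold and zi < z_threshold:
            label = "B"
        elif zb >= z_threshold and zn >= z_threshold and zn >= zi:
            label = "A"
        elif zb >= z_threshold and zi >= z_threshold:
            label = "C"
        else:
            label = "unassigned"
        labels[cluster] = label
    gene_labels = cluster_of.map(labels)
    return ClusterAssignment(
        labels=gene_labels,
        linkage=link,
        k=int(best_k),
        cluster_of=cluster_of,
        group_z=group_z,
        silhouette=best_sil,
        constant_genes=constant,
    )


def annotation_enrichment(
    gene_set: list[str],
    universe: list[str],
    annotations: dict[str, list[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of annotation terms.

    For a term annotating K of the N universe genes, the p-value is the
    probability of drawing at least the observed overlap k when sampling
    |gene_set| genes without replacement.  Benjamini-Hochberg q-values are
    reported alongside the raw p.  Terms with no universe genes are
    skipped; the result is sorted by p.
    """
    gene_set = set(gene_set)
    universe_set = set(universe)
    if not gene_set <= universe_set:
        raise ValueError("gene set must be a subset of the universe")
    n_universe = len(universe_set)
    n_draw = len(gene_set)
    rows = []
    for term, members in annotations.items():
        members = set(members) & universe_set
        if not members:
            continue
        overlap = len(gene_set & members)
        p = float(_stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_draw))
        rows.append(
            {
                "term": term,
                "overlap": overlap,
                "term_size": len(members),
                "set_size": n_draw,
                "universe_size": n_universe,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
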