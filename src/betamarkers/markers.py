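"""Beta-cell selectivity scoring and cross-species candidate selection.

For every probe the pipeline computes, within one species, the ratio of
its mean beta-cell signal to its mean signal in each other tissue (the
per-tissue *fold change*), the arithmetic mean of those ratios (the
*average fold change*, avFC) and the *beta-cell rank* (1 + number of
tissues whose mean strictly exceeds the beta-cell mean; rank 1 means the
beta cell is the top tissue).  Candidates are the top ``n_top`` probes by
avFC among those at or above an avFC floor, and a gene is a conserved
candidate when at least one of its probes qualifies in every species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, OrthologMap


def tissue_means(matrix: ExpressionMatrix, floor: float = 1.0) -> pd.DataFrame:
    """Per-probe arithmetic mean over replicates per tissue, floored.

    The floor (in linear signal units) keeps subsequent ratio denominators
    away from zero; it is applied to the replicate mean, not to the raw
    values.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    groups = matrix.samples["tissue"]
    means = {}
    for tissue in matrix.tissues:
        cols = matrix.samples.index[groups == tissue]
        if len(cols) == 0:
            raise ValueError(f"tissue {tissue} has no samples")
        means[tissue] = matrix.values[cols].mean(axis=1)
    out = pd.DataFrame(means)
    return out.clip(lower=floor)


def score_probes(means: pd.DataFrame, beta_tissue: str = "beta") -> pd.DataFrame:
    """Score every probe for beta-cell selectivity.

    Parameters
    ----------
    means : DataFrame
        Probes x tissues floored replicate means (see :func:`tissue_means`).
    beta_tissue : str
        Column holding the beta-cell preparation.

    Returns
    -------
    DataFrame indexed by probe with one ``fc_<tissue>`` column per
    non-beta tissue, plus ``avfc`` and ``rank``.  Ties in the rank are
    broken conservatively: a tissue with mean exactly equal to the beta
    mean does not outrank it.
    """
    if beta_tissue not in means.columns:
        raise ValueError(f"beta tissue {beta_tissue!r} not in means")
    others = [t for t in means.columns if t != beta_tissue]
    if not others:
        raise ValueError("need at least one non-beta tissue to form ratios")
    beta = means[beta_tissue]
    fcs = means[others].rdiv(beta, axis=0)
    out = fcs.add_prefix("fc_")
    out["avfc"] = fcs.mean(axis=1)
    out["rank"] = 1 + (means[others].gt(beta, axis=0)).sum(axis=1)
    return out


@dataclass
class CandidateSet:
    """Per-species probes selected for beta-cell-abundant expression."""

    species: str
    probe_ids: list[str]
    gene_symbols: dict[str, str] = field(default_factory=dict)
    n_top: int = 0
    min_avfc: float = 1.0

    def __len__(self) -> int:
        return len(self.probe_ids)


def select_candidates(
    scores: pd.DataFrame,
    n_top: int = 2500,
    min_avfc: float = 1.2,
    species: str = "",
    gene_symbols: pd.Series | None = None,
) -> CandidateSet:
    """Top ``n_top`` probes by avFC among those with avFC >= ``min_avfc``.

    Sorting is by avFC descending, then rank ascending, then probe id, so
    the selection is fully deterministic under ties.  If fewer than
    ``n_top`` probes qualify, all qualifying probes are returned.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if min_avfc < 1:
        raise ValueError("min_avfc must be >= 1")
    qualifying = scores[scores["avfc"] >= min_avfc]
    order = sorted(
        qualifying.index,
        key=lambda p: (-qualifying.at[p, "avfc"], qualifying.at[p, "rank"], p),
    )
    chosen = order[:n_top]
    symbols = {}
    if gene_symbols is not None:
        symbols = {p: gene_symbols.get(p, "") for p in chosen}
    return CandidateSet(
        species=species, probe_ids=chosen, gene_symbols=symbols, n_top=n_top, min_avfc=min_avfc
    )


@dataclass
class IntersectionResult:
    """Cross-species conserved candidate genes with audit figures."""

    conserved_genes: list[str]
    coverage: dict[str, float]  # species -> conserved / distinct input genes
    input_genes: dict[str, int]  # species -> distinct mapped genes in candidates
    unmappable: dict[str, int]  # species -> candidate probes without a gene

    def coverage_percent(self, species: str) -> int:
        """Coverage displayed as the nearest whole percent (15.8% -> 16)."""
        return int(round(100 * self.coverage[species]))


def intersect_species(
    candidates: dict[str, CandidateSet], omap: OrthologMap
) -> IntersectionResult:
    """Genes whose probes make the candidate set in *every* species.

    A gene counts as conserved when, in each species, at least one of its
    probes (max-probe rule) belongs to that species' candidate set.  Probes
    without a gene assignment are tallied as unmappable and excluded.
    Coverage is the conserved-gene count relative to the number of
    distinct genes entering from that species' candidate set.
    """
    if len(candidates) < 2:
        raise ValueError("need candidate sets from >=2 species")
    per_species_genes: dict[str, set[str]] = {}
    input_genes: dict[str, int] = {}
    unmappable: dict[str, int] = {}
    for species, cset in candidates.items():
        gene_lookup = omap.gene_of(species)
        probes = pd.Index(cset.probe_ids)
        mapped = probes[probes.isin(gene_lookup.index)]
        unmappable[species] = len(probes) - len(mapped)
        genes = set(gene_lookup.loc[mapped])
        per_species_genes[species] = genes
        input_genes[species] = len(genes)
    conserved = set.intersection(*per_species_genes.values()) if per_species_genes else set()
    coverage = {
        sp: (len(conserved) / n if n else 0.0) for sp, n in input_genes.items()
    }
    return IntersectionResult(
        conserved_genes=sorted(conserved),
        coverage=coverage,
        input_genes=input_genes,
        unmappable=unmappable,
    )
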