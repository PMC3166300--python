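"""Contaminant curation of the conserved candidate panel.

Isolated beta-cell preparations inevitably carry islet non-beta
(mainly alpha) cells and pancreatic exocrine (acinar and duct) cells.
Genes belonging to those contaminants are purged from the conserved
candidate list in two ordered passes:

1. alpha markers — any probe at least ``contaminant_fc``-fold higher in
   FACS-purified alpha than in beta cells with Welch p < ``contaminant_p``;
2. exocrine markers — probes showing a monotone expression gradient
   total pancreas > islets > beta cells (acinar) or duct-dominated
   expression (duct) in the human data.

The two-group test operates on log2 signal: Welch's unequal-variance
t-test, a fold change of 2^(meanA - meanB) and a one-sided lower
confidence bound (LCB) of the fold change from the Welch t interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, OrthologMap
from .markers import tissue_means

P_FLOOR = 1e-300


def two_group_test(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    lcb_confidence: float = 0.90,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Per-probe Welch t-test of tissue ``group_a`` versus ``group_b``.

    Returns a DataFrame indexed by probe with columns ``fold_change``
    (2^(meanA - meanB) on floored log2 signal), ``lcb`` (lower
    ``lcb_confidence`` one-sided confidence bound of the fold change),
    ``p_value`` (two-sided) and ``direction`` ("up" when A >= B).

    Degenerate cases: identical groups with zero variance give p = 1 and
    fold 1; distinct means with zero pooled variance give p floored at
    1e-300 with lcb equal to the fold change.
    """
    cols_a = matrix.samples_for(group_a)
    cols_b = matrix.samples_for(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >=2 replicates in each group")
    log_a = np.log2(np.maximum(matrix.values[cols_a].to_numpy(float), floor))
    log_b = np.log2(np.maximum(matrix.values[cols_b].to_numpy(float), floor))
    na, nb = log_a.shape[1], log_b.shape[1]
    mean_a, mean_b = log_a.mean(axis=1), log_b.mean(axis=1)
    var_a = log_a.var(axis=1, ddof=1)
    var_b = log_b.var(axis=1, ddof=1)
    diff = mean_a - mean_b
    se2 = var_a / na + var_b / nb
    se = np.sqrt(se2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = diff / se
        df = se2**2 / ((var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1))
        p = 2 * stats.t.sf(np.abs(t_stat), df)
        t_crit = stats.t.ppf(lcb_confidence, df)
        lcb_log = diff - t_crit * se

    zero_se = se == 0
    equal = zero_se & (diff == 0)
    distinct = zero_se & (diff != 0)
    p = np.where(equal, 1.0, p)
    p = np.where(distinct, P_FLOOR, p)
    p = np.clip(p, P_FLOOR, 1.0)
    lcb_log = np.where(zero_se, diff, lcb_log)

    out = pd.DataFrame(
        {
            "fold_change": 2.0**diff,
            "lcb": 2.0**lcb_log,
            "p_value": p,
            "direction": np.where(diff >= 0, "up", "down"),
        },
        index=matrix.values.index,
    )
    return out


@dataclass
class CuratedPanel:
    """Conserved gene panel with a full removal audit.

    ``retained`` plus the three removal lists partition the input; the
    removal lists are pairwise disjoint because the alpha test is applied
    first and exocrine tests only see survivors.
    """

    retained: list[str]
    removed_alpha: list[str] = field(default_factory=list)
    removed_duct: list[str] = field(default_factory=list)
    removed_acinar: list[str] = field(default_factory=list)
    untested: list[str] = field(default_factory=list)

    @property
    def audit(self) -> dict[str, int]:
        return {
            "input": len(self.retained)
            + len(self.removed_alpha)
            + len(self.removed_duct)
            + len(self.removed_acinar),
            "removed_alpha": len(self.removed_alpha),
            "removed_duct": len(self.removed_duct),
            "removed_acinar": len(self.removed_acinar),
            "removed_exocrine": len(self.removed_duct) + len(self.removed_acinar),
            "retained": len(self.retained),
        }


def remove_alpha_markers(
    genes: list[str],
    alpha_vs_beta: pd.DataFrame,
    omap: OrthologMap,
    species: str,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> tuple[list[str], list[str], list[str]]:
    """Drop genes enriched in alpha over beta cells.

    ``alpha_vs_beta`` must come from :func:`two_group_test` with the alpha
    tissue as group A.  A gene is removed when ANY of its probes in
    ``species`` shows fold_change >= ``fc_threshold`` with
    p < ``p_threshold``.  Genes with no tested probe are retained and
    flagged untested.

    Returns (retained, removed, untested).
    """
    retained, removed, untested = [], [], []
    for gene in genes:
        probes = [p for p in omap.probes(gene, species) if p in alpha_vs_beta.index]
        if not probes:
            retained.append(gene)
            untested.append(gene)
            continue
        res = alpha_vs_beta.loc[probes]
        hit = ((res["fold_change"] >= fc_threshold) & (res["p_value"] < p_threshold)).any()
        (removed if hit else retained).append(gene)
    return retained, removed, untested


def remove_exocrine_markers(
    genes: list[str],
    human: ExpressionMatrix,
    omap: OrthologMap,
    species: str = "human",
    gradient_fc: float = 4.0,
    beta_tissue: str = "beta",
    pancreas_tissue: str = "pancreas",
    islets_tissue: str = "islets",
    duct_tissue: str = "duct",
    floor: float = 1.0,
) -> tuple[list[str], list[str], list[str], list[str]]:
    """Drop acinar- and duct-typical genes using the human tissue data.

    Acinar markers show the contamination gradient
    mean(pancreas) >= gradient_fc x mean(islets) and
    mean(islets) >= gradient_fc x mean(beta) for at least one probe.
    Duct markers have mean(duct) >= gradient_fc x mean(beta) with duct the
    top tissue for that probe.  The acinar test takes precedence.  When no
    duct tissue is present duct removal is skipped.

    Returns (retained, removed_duct, removed_acinar, warnings).
    """
    means = tissue_means(human, floor=floor)
    for t in (pancreas_tissue, islets_tissue, beta_tissue):
        if t not in means.columns:
            raise ValueError(f"human matrix lacks required tissue {t!r}")
    warnings: list[str] = []
    have_duct = duct_tissue in means.columns
    if not have_duct:
        warnings.append(f"no {duct_tissue!r} tissue: duct removal skipped")
    gene_lookup = omap.gene_of(species)
    retained, removed_duct, removed_acinar = [], [], []
    top_tissue = means.idxmax(axis=1)
    for gene in genes:
        probes = [p for p in omap.probes(gene, species) if p in means.index]
        if not probes:
            retained.append(gene)
            continue
        sub = means.loc[probes]
        acinar = (
            (sub[pancreas_tissue] >= gradient_fc * sub[islets_tissue])
            & (sub[islets_tissue] >= gradient_fc * sub[beta_tissue])
        ).any()
        if acinar:
            removed_acinar.append(gene)
            continue
        if have_duct:
            duct = (
                (sub[duct_tissue] >= gradient_fc * sub[beta_tissue])
                & (top_tissue.loc[probes] == duct_tissue)
            ).any()
            if duct:
                removed_duct.append(gene)
                continue
        retained.append(gene)
    return retained, removed_duct, removed_acinar, warnings


def curate_panel(
    genes: list[str],
    rat: ExpressionMatrix,
    human: ExpressionMatrix,
    omap: OrthologMap,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    gradient_fc: float = 4.0,
    lcb_confidence: float = 0.90,
    floor: float = 1.0,
    alpha_tissue: str = "alpha",
    beta_tissue: str = "beta",
) -> CuratedPanel:
    """Run the full two-pass contaminant curation over a conserved gene list."""
    alpha_vs_beta = two_group_test(
        rat, alpha_tissue, beta_tissue, lcb_confidence=lcb_confidence, floor=floor
    )
    survivors, removed_alpha, untested = remove_alpha_markers(
        genes, alpha_vs_beta, omap, rat.species or "rat", fc_threshold, p_threshold
    )
    retained, removed_duct, removed_acinar, _ = remove_exocrine_markers(
        survivors,
        human,
        omap,
        species=human.species or "human",
        gradient_fc=gradient_fc,
        beta_tissue=beta_tissue,
        floor=floor,
    )
    return CuratedPanel(
        retained=retained,
        removed_alpha=removed_alpha,
        removed_duct=removed_duct,
        removed_acinar=removed_acinar,
        untested=untested,
    )
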