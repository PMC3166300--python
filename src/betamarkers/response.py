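"""Condition screens: genome-wide and panel-restricted fed-vs-fasted response.

Reuses the Welch fold-change/LCB machinery from the curation stage.  A
probe counts as altered when its fold change is at least ``response_fc``
in either direction with p below ``response_p`` (raw p, matching the
published screen; BH q-values are reported alongside).  A secondary,
looser report counts probes reproducibly down-regulated at a 1.25-fold
window, requiring every fasted replicate below every fed replicate.

Counting unit is the probe: a gene with several probes contributes each
probe to the genome-wide tally, while panel summaries are per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .curation import two_group_test
from .io import ExpressionMatrix, OrthologMap, PipelineConfig


@dataclass
class ResponseSummary:
    n_assayed: int
    n_altered: int
    n_down: int
    n_up: int
    reproducible_down_125: int = 0

    @property
    def pct_altered(self) -> float:
        return 100.0 * self.n_altered / self.n_assayed if self.n_assayed else 0.0

    @property
    def pct_down(self) -> float:
        """Share of altered probes that went down, in percent."""
        return 100.0 * self.n_down / self.n_altered if self.n_altered else 0.0

    def headline(self) -> dict[str, float]:
        """Report fields rounded the way they are printed."""
        return {
            "n_assayed": self.n_assayed,
            "n_altered": self.n_altered,
            "n_down": self.n_down,
            "pct_altered": round(self.pct_altered, 1),
            "pct_down_headline": int(round(self.pct_down)),
        }


def response_table(
    fed: ExpressionMatrix,
    fast: ExpressionMatrix,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-probe fast-vs-fed Welch results with altered/direction calls."""
    cfg = config or PipelineConfig()
    if not fed.values.index.equals(fast.values.index):
        missing = fed.values.index.symmetric_difference(fast.values.index)
        raise ValueError(f"probe sets disagree between conditions: {list(missing)[:5]}")
    merged_values = pd.concat([fast.values, fed.values], axis=1)
    from .io import sample_table  # local import to avoid cycle noise

    # relabel conditions as tissues so the two-group test sees two groups
    names = [f"fast.{i + 1}" for i in range(fast.values.shape[1])] + [
        f"fed.{i + 1}" for i in range(fed.values.shape[1])
    ]
    merged_values.columns = names
    merged = ExpressionMatrix(
        values=merged_values,
        samples=sample_table(names),
        species=fed.species,
        gene_symbols=fed.gene_symbols,
    )
    res = two_group_test(
        merged, "fast", "fed", lcb_confidence=cfg.lcb_confidence, floor=cfg.expression_floor
    )
    res["altered"] = (
        (res["fold_change"] >= cfg.response_fc)
        | (res["fold_change"] <= 1.0 / cfg.response_fc)
    ) & (res["p_value"] < cfg.response_p)
    res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]

    # reproducible >=1.25-fold suppression: all fast reps below all fed reps
    fast_vals = np.maximum(fast.values.to_numpy(float), cfg.expression_floor)
    fed_vals = np.maximum(fed.values.to_numpy(float), cfg.expression_floor)
    concordant = fast_vals.max(axis=1)[:, None] < fed_vals.min(axis=1)[:, None]
    res["reproducible_down_125"] = (res["fold_change"] <= 1 / 1.25) & concordant[:, 0]
    return res


def summarize_response(results: pd.DataFrame) -> ResponseSummary:
    altered = results[results["altered"]]
    n_down = int((altered["direction"] == "down").sum())
    return ResponseSummary(
        n_assayed=len(results),
        n_altered=len(altered),
        n_down=n_down,
        n_up=len(altered) - n_down,
        reproducible_down_125=int(results["reproducible_down_125"].sum())
        if "reproducible_down_125" in results
        else 0,
    )


def genome_wide_response(
    fed: ExpressionMatrix,
    fast: ExpressionMatrix,
    config: PipelineConfig | None = None,
) -> tuple[ResponseSummary, pd.DataFrame]:
    """Screen every assayed probe for a fasting response."""
    results = response_table(fed, fast, config)
    return summarize_response(results), results


@dataclass
class PanelResponse:
    suppressed_genes: list[str]
    per_cluster: dict[str, int]
    cluster_share: dict[str, float]  # fraction of suppressed genes per label
    panel_suppressed_fraction: float

    def share_percent(self, label: str) -> int:
        return int(round(100 * self.cluster_share.get(label, 0.0)))


def panel_response(
    results: pd.DataFrame,
    panel_genes: list[str],
    cluster_labels: pd.Series,
    omap: OrthologMap,
    species: str,
    strong_fc: float = 1.5,
    p_threshold: float = 0.05,
) -> PanelResponse:
    """Per-cluster census of strongly fasting-suppressed panel genes.

    A panel gene is suppressed when any of its probes is down at least
    ``strong_fc``-fold with p < ``p_threshold``.  Shares are fractions of
    the suppressed gene set per tropism label.
    """
    gene_lookup = omap.gene_of(species)
    suppressed = []
    for gene in panel_genes:
        probes = [p for p in gene_lookup.index[gene_lookup == gene] if p in results.index]
        if not probes:
            continue
        sub = results.loc[probes]
        hit = (
            (sub["fold_change"] <= 1.0 / strong_fc) & (sub["p_value"] < p_threshold)
        ).any()
        if hit:
            suppressed.append(gene)
    labels = ["A", "B", "C", "unassigned"]
    per_cluster = {lab: 0 for lab in labels}
    for gene in suppressed:
        lab = cluster_labels.get(gene, "unassigned")
        per_cluster[lab] = per_cluster.get(lab, 0) + 1
    n_sup = len(suppressed)
    share = {lab: (c / n_sup if n_sup else 0.0) for lab, c in per_cluster.items()}
    return PanelResponse(
        suppressed_genes=sorted(suppressed),
        per_cluster=per_cluster,
        cluster_share=share,
        panel_suppressed_fraction=n_sup / len(panel_genes) if panel_genes else 0.0,
    )
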