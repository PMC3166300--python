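"""Multi-reference geometric normalization of qPCR Ct tables.

Per replicate, the target quantity is the amplification-efficiency power
of its Ct, normalized to the geometric mean of the reference-gene
quantities measured in the same (tissue, replicate):

    quantity = E^(-Ct_target) / geomean_refs(E^(-Ct_ref))
             = E^(mean_ref_Ct - Ct_target)

with the efficiency E defaulting to 2.0 (perfect doubling).  Per (gene,
tissue) the report is the geometric mean (GEO) of the replicate
quantities and their arithmetic standard deviation, matching how such
tables are conventionally printed.  "nd" (not detected) is a distinct
state that never collapses to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import floor, log10

import numpy as np
import pandas as pd

DEFAULT_REFERENCE_GENES = ("BACT", "UBC", "PPIA", "PSMC5")


@dataclass
class NormalizationResult:
    table: pd.DataFrame  # columns gene, tissue, geo, sd, n_replicates
    dropped_replicates: list[tuple[str, str, object]] = field(default_factory=list)

    def geo_matrix(self) -> pd.DataFrame:
        """Genes x tissues matrix of GEO values (NaN where not detected)."""
        return self.table.pivot(index="gene", columns="tissue", values="geo")

    def geo(self, gene: str, tissue: str) -> float:
        sel = self.table[(self.table["gene"] == gene) & (self.table["tissue"] == tissue)]
        if sel.empty:
            return float("nan")
        return float(sel["geo"].iloc[0])


def normalize(
    ct_table: pd.DataFrame,
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
    efficiency: float = 2.0,
) -> NormalizationResult:
    """Normalize a tidy Ct table (columns gene, tissue, replicate, ct).

    Replicates missing any reference Ct are dropped for every target in
    that tissue (with an audit entry); a (gene, tissue) whose replicates
    are all dropped is reported as not detected (GEO = NaN).
    """
    required = {"gene", "tissue", "replicate", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    present_refs = [g for g in reference_genes if g in set(ct_table["gene"])]
    if len(present_refs) < 2:
        raise ValueError("need Ct values for >=2 reference genes")

    refs = ct_table[ct_table["gene"].isin(present_refs)]
    ref_mean = (
        refs.pivot_table(index=["tissue", "replicate"], columns="gene", values="ct")
        .reindex(columns=present_refs)
    )
    complete = ref_mean.notna().all(axis=1)
    dropped = [
        (tissue, rep, "missing reference Ct")
        for (tissue, rep) in ref_mean.index[~complete]
    ]
    ref_mean = ref_mean[complete].mean(axis=1)  # arithmetic mean of ref Cts

    targets = ct_table[~ct_table["gene"].isin(present_refs)]
    rows = []
    for (gene, tissue), grp in targets.groupby(["gene", "tissue"], sort=True):
        quantities = []
        for _, row in grp.iterrows():
            key = (tissue, row["replicate"])
            if key not in ref_mean.index or pd.isna(row["ct"]):
                continue
            quantities.append(efficiency ** (ref_mean.loc[key] - row["ct"]))
        if quantities:
            q = np.asarray(quantities, dtype=float)
            geo = float(np.exp(np.mean(np.log(q))))
            sd = float(np.std(q, ddof=1)) if len(q) > 1 else 0.0
        else:
            geo, sd = float("nan"), float("nan")
        rows.append(
            {"gene": gene, "tissue": tissue, "geo": geo, "sd": sd, "n_replicates": len(quantities)}
        )
    return NormalizationResult(table=pd.DataFrame(rows), dropped_replicates=dropped)


def round_sig(x: float, sig_figs: int = 1) -> float:
    """Round to ``sig_figs`` significant figures by decimal mantissa rounding."""
    if x == 0 or not np.isfinite(x):
        return x
    magnitude = floor(log10(abs(x)))
    return round(x, -int(magnitude) + sig_figs - 1)


def abundance_ratio(
    geo_values: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    tissue: str,
    sig_figs: int | None = None,
) -> float:
    """Ratio of two genes' GEO abundances in one tissue.

    ``geo_values`` is a genes x tissues matrix of GEO quantities (as from
    :meth:`NormalizationResult.geo_matrix` or a printed reference table).
    Undefined ratios (denominator 0 or not detected) return NaN.
    """
    try:
        a = float(geo_values.at[gene_a, tissue])
        b = float(geo_values.at[gene_b, tissue])
    except KeyError:
        return float("nan")
    if not np.isfinite(a) or not np.isfinite(b) or b == 0:
        return float("nan")
    ratio = a / b
    if sig_figs is not None:
        ratio = round_sig(ratio, sig_figs)
    return ratio


def load_reference_table() -> pd.DataFrame:
    """Packaged rat qPCR reference table (GEO and SD per gene x tissue).

    Values are geometric means of triplicate quantities normalized to the
    four reference genes BACT, UBC, PPIA and PSMC5; "nd" cells load as
    NaN.  Returns a tidy DataFrame (gene, tissue, geo, sd).
    """
    with resources.files("betamarkers.data").joinpath("qpcr_rat_table.tsv").open() as fh:
        wide = pd.read_csv(fh, sep="\t", dtype={"gene": str})
    tissues = sorted({c[: -len("_geo")] for c in wide.columns if c.endswith("_geo")})
    rows = []
    for _, row in wide.iterrows():
        for tissue in tissues:
            geo_raw = row[f"{tissue}_geo"]
            nd = isinstance(geo_raw, str) and geo_raw.strip() == "nd"
            geo = float("nan") if nd else float(geo_raw)
            sd_raw = row.get(f"{tissue}_sd")
            sd = float("nan") if (nd or pd.isna(sd_raw)) else float(sd_raw)
            rows.append({"gene": row["gene"], "tissue": tissue, "geo": geo, "sd": sd})
    return pd.DataFrame(rows)


def reference_geo_matrix() -> pd.DataFrame:
    """Genes x tissues GEO matrix of the packaged reference table."""
    return load_reference_table().pivot(index="gene", columns="tissue", values="geo")
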