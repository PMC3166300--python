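"""Cross-tissue detection classification of marker proteins.

Label-free LC-MS molar abundances of marker proteins across four tissues
(alpha cells, beta cells, brain, liver) are classified by detection
pattern:

* ``beta_unique``      — detected only in beta cells;
* ``islet_restricted`` — detected in beta and alpha cells only;
* ``shared_with_brain_or_liver`` — detected in brain and/or liver too.

Abundances are expressed relative to the assay's lower limit of
quantification (LLQ); entries below the LLQ ("<LLQ") and absent entries
are undetected, a state distinct from 0 for reporting but treated as 0
when comparing which tissue has the highest abundance.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

TISSUES = ("alpha", "beta", "brain", "liver")
REFERENCE_LLQ = 0.00005
DETECTION_CLASSES = ("beta_unique", "islet_restricted", "shared_with_brain_or_liver")


def load_reference_proteome() -> tuple[pd.DataFrame, float]:
    """Packaged reference protein-quantification table.

    Returns (table, llq).  Undetected entries ("-" or "<LLQ") load as
    NaN; all other abundances are relative molar units >= llq.
    """
    with resources.files("betamarkers.data").joinpath("proteome_rat_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["-", "<LLQ"])
    for tissue in TISSUES:
        df[tissue] = pd.to_numeric(df[tissue], errors="raise")
    return df, REFERENCE_LLQ


def fold_of_llq(abundance: float, llq: float) -> int:
    """Abundance as a whole-number multiple of the quantification limit."""
    if llq <= 0:
        raise ValueError("llq must be > 0")
    if not np.isfinite(abundance):
        raise ValueError("fold of LLQ undefined for an undetected protein")
    if abundance < llq:
        raise ValueError("reported abundance below the quantification limit")
    return int(np.floor(abundance / llq + 0.5))


def classify_detection(quants: pd.DataFrame) -> tuple[pd.Series, dict[str, int]]:
    """Per-protein detection class and class counts.

    Proteins not detected in beta cells are excluded (they fall outside
    the classification, which partitions beta-detected proteins).
    """
    detected_beta = quants["beta"].notna()
    usable = quants[detected_beta]
    classes = []
    for _, row in usable.iterrows():
        in_alpha = pd.notna(row["alpha"])
        in_brain_or_liver = pd.notna(row["brain"]) or pd.notna(row["liver"])
        if in_brain_or_liver:
            classes.append("shared_with_brain_or_liver")
        elif in_alpha:
            classes.append("islet_restricted")
        else:
            classes.append("beta_unique")
    labels = pd.Series(classes, index=usable.index, name="detection_class")
    counts = {cls: int((labels == cls).sum()) for cls in DETECTION_CLASSES}
    counts["excluded_not_in_beta"] = int((~detected_beta).sum())
    return labels, counts


def beta_max_fraction(quants: pd.DataFrame) -> int:
    """Percent of beta-detected proteins most abundant in beta cells.

    Undetected tissues count as 0 and ties count as not beta-maximal
    (strict inequality), the conservative convention.  Rounded to the
    nearest whole percent.
    """
    usable = quants[quants["beta"].notna()]
    if usable.empty:
        return 0
    others = usable[[t for t in TISSUES if t != "beta"]].fillna(0.0)
    wins = (usable["beta"] > others.max(axis=1)).sum()
    return int(round(100.0 * wins / len(usable)))


def rank_one_fraction(quants: pd.DataFrame) -> int:
    """Percent of beta-detected proteins whose beta-cell protein rank is 1.

    The protein rank is the source study's own call of which tissue had the
    highest abundance.  In the reference table it disagrees with the
    printed triplicate-mean abundances for one protein (Stxbp1: rank 1
    despite a higher printed brain abundance), so this rank-based share
    and :func:`beta_max_fraction` (recomputed from the printed
    abundances) can differ by one protein.
    """
    if "protein_rank" not in quants.columns:
        raise ValueError("missing column protein_rank")
    usable = quants[quants["beta"].notna()]
    if usable.empty:
        return 0
    wins = (usable["protein_rank"].astype(int) == 1).sum()
    return int(round(100.0 * wins / len(usable)))


def mrna_protein_concordance(quants: pd.DataFrame) -> dict:
    """Agreement between mRNA and protein beta-cell ranks.

    Requires ``mrna_rank`` and ``protein_rank`` columns; rows missing
    either are excluded with an audit count.  Returns the agreement
    fraction and the rank cross-tabulation.
    """
    for col in ("mrna_rank", "protein_rank"):
        if col not in quants.columns:
            raise ValueError(f"missing column {col}")
    usable = quants.dropna(subset=["mrna_rank", "protein_rank"])
    excluded = len(quants) - len(usable)
    if usable.empty:
        return {"agreement": float("nan"), "crosstab": pd.DataFrame(), "excluded": excluded}
    mrna = usable["mrna_rank"].astype(int)
    prot = usable["protein_rank"].astype(int)
    agreement = float((mrna == prot).mean())
    crosstab = pd.crosstab(mrna, prot)
    return {"agreement": agreement, "crosstab": crosstab, "excluded": excluded}


def summarize(quants: pd.DataFrame, llq: float) -> dict:
    """One-stop summary: class counts, fold-of-LLQ extremes, beta-max share."""
    labels, counts = classify_detection(quants)
    usable = quants.loc[labels.index]
    folds = usable["beta"].map(lambda a: fold_of_llq(a, llq))
    beta_unique_folds = folds[labels == "beta_unique"]
    return {
        "counts": counts,
        "beta_max_percent": beta_max_fraction(quants),
        "rank_one_percent": (
            rank_one_fraction(quants) if "protein_rank" in quants.columns else None
        ),
        "fold_of_llq": folds,
        "beta_unique_fold_range": (
            (int(beta_unique_folds.min()), int(beta_unique_folds.max()))
            if not beta_unique_folds.empty
            else (None, None)
        ),
        "concordance": mrna_protein_concordance(quants),
    }
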