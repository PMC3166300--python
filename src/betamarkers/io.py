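"""Data model and file formats for the marker-discovery pipeline.

Expression values at the I/O boundary are linear-scale normalized array
signal (never log-transformed); every log2 transform in the pipeline is
internal to the operation that needs it.

Sample columns are named ``tissue.replicate`` or, when a condition is
attached, ``tissue.condition.replicate`` (e.g. ``beta.fast.1``).  Tissue,
condition and replicate tokens therefore must not contain ``.``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs


class FormatError(ValueError):
    """A file violates the expected on-disk format or an invariant."""


class ConfigError(ValueError):
    """A configuration value is out of its admissible range."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of non-negative linear expression signal.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows indexed by unique probe id, columns by sample name.
    samples : pandas.DataFrame
        One row per sample (index = sample name) with columns
        ``tissue``, ``replicate`` and ``condition`` (condition may be None).
    species : str
        Species label, e.g. ``"rat"``.
    gene_symbols : pandas.Series
        Per-probe gene symbol aligned to ``values.index``; missing symbols
        are empty strings.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    species: str = ""
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series("", index=self.values.index)
        self.gene_symbols = self.gene_symbols.reindex(self.values.index).fillna("")
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate probe ids: {list(dups)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.values.columns.equals(self.samples.index):
            raise FormatError("sample annotation does not match matrix columns")
        if self.samples["tissue"].isna().any() or (self.samples["tissue"] == "").any():
            raise FormatError("every sample needs a tissue label")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.samples["tissue"]:
            seen.setdefault(t, None)
        return list(seen)

    def samples_for(self, tissue: str, condition: str | None = None) -> list[str]:
        mask = self.samples["tissue"] == tissue
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def subset_probes(self, probes: Iterable[str]) -> "ExpressionMatrix":
        probes = [p for p in probes if p in self.values.index]
        return ExpressionMatrix(
            values=self.values.loc[probes],
            samples=self.samples,
            species=self.species,
            gene_symbols=self.gene_symbols.loc[probes],
        )


@dataclass
class OrthologMap:
    """Mapping gene symbol -> per-species probe sets.

    Stored as a long table with one row per (gene, species, probe).  The
    same probe may not be assigned to two genes within one species.
    """

    table: pd.DataFrame  # columns: gene, species, probe_id

    def __post_init__(self) -> None:
        required = {"gene", "species", "probe_id"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"ortholog map needs columns {sorted(required)}")
        dup = self.table.duplicated(["species", "probe_id"], keep=False)
        if dup.any():
            conflicting = self.table.loc[dup]
            bad = conflicting.groupby(["species", "probe_id"])["gene"].nunique()
            if (bad > 1).any():
                raise FormatError(
                    "probe assigned to multiple genes within one species: "
                    f"{bad[bad > 1].index.tolist()[:5]}"
                )
            self.table = self.table.drop_duplicates(["species", "probe_id"])
        self.table = self.table.reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def probes(self, gene: str, species: str) -> list[str]:
        sel = self.table[(self.table["gene"] == gene) & (self.table["species"] == species)]
        return sorted(sel["probe_id"])

    def genes(self, species: str | None = None) -> list[str]:
        if species is None:
            return sorted(self.table["gene"].unique())
        return sorted(self.table.loc[self.table["species"] == species, "gene"].unique())

    def gene_of(self, species: str) -> pd.Series:
        """probe_id -> gene lookup for one species."""
        sel = self.table[self.table["species"] == species]
        return pd.Series(sel["gene"].to_numpy(), index=sel["probe_id"].to_numpy())

    def conserved_genes(self, species: Iterable[str]) -> list[str]:
        """Genes present with >=1 probe in every listed species."""
        species = list(species)
        counts = (
            self.table[self.table["species"].isin(species)]
            .groupby("gene")["species"]
            .nunique()
        )
        return sorted(counts.index[counts == len(species)])


@dataclass
class PipelineConfig:
    """Thresholds shared across pipeline stages.

    Defaults mirror the published analysis: the per-species candidate sets
    keep the top 2500 probes with average fold change at least 1.2 (20%
    higher in beta cells); contaminant and condition screens call a change
    at 1.5-fold with p < 0.05 on n = 3 replicates.
    """

    n_top: int = 2500
    min_avfc: float = 1.2
    contaminant_fc: float = 1.5
    contaminant_p: float = 0.05
    response_fc: float = 1.5
    response_p: float = 0.05
    lcb_confidence: float = 0.90
    expression_floor: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_top", "min_avfc", "contaminant_fc", "response_fc", "expression_floor"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("contaminant_p", "response_p", "lcb_confidence"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_sample_name(name: str) -> tuple[str, str, str | None]:
    tokens = name.split(".")
    if len(tokens) == 2:
        tissue, replicate = tokens
        condition = None
    elif len(tokens) == 3:
        tissue, condition, replicate = tokens
    else:
        raise FormatError(
            f"sample name {name!r} is not tissue.replicate or tissue.condition.replicate"
        )
    if not tissue or not replicate:
        raise FormatError(f"sample name {name!r} has empty tokens")
    return tissue, replicate, condition


def sample_table(names: Iterable[str]) -> pd.DataFrame:
    rows = []
    for name in names:
        tissue, replicate, condition = _parse_sample_name(name)
        rows.append({"tissue": tissue, "replicate": replicate, "condition": condition})
    return pd.DataFrame(rows, index=pd.Index(list(names), name="sample"))


def read_expression_tsv(path: str | Path, species: str = "") -> ExpressionMatrix:
    """Read a tab-delimited probes x samples expression matrix.

    First column is the probe id; a second column named ``gene_symbol``
    is optional; every remaining column is a sample named per the
    tissue.replicate convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError("expression matrix needs a probe column and >=1 sample")
    probe_col = df.columns[0]
    if df[probe_col].duplicated().any():
        raise FormatError("duplicate probe_id rows")
    df = df.set_index(probe_col)
    df.index.name = "probe_id"
    if "gene_symbol" in df.columns:
        symbols = df["gene_symbol"].fillna("").astype(str)
        df = df.drop(columns=["gene_symbol"])
    else:
        symbols = pd.Series("", index=df.index)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    if (values.to_numpy() < 0).any():
        raise ValueError("negative expression value")
    samples = sample_table(values.columns)
    return ExpressionMatrix(values=values, samples=samples, species=species, gene_symbols=symbols)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    if (matrix.gene_symbols != "").any():
        out.insert(0, "gene_symbol", matrix.gene_symbols)
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a tab-delimited (gene, species, probe_id) table, one probe per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["gene", "species", "probe_id"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"ortholog map must have columns {expected}")
    return OrthologMap(table=df[expected])


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    omap.table.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name -> uppercase sequence mapping."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(f"non-ACGTN residues in {record.id}: {sorted(bad)}")
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"no sequences in {path}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_BASES = "ACGT"


def read_transfac(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read TRANSFAC-format count matrices.

    Returns a list of (matrix id, counts) where counts is a 4 x L array
    with rows in A, C, G, T order.
    """
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "TRANSFAC")
        except Exception as exc:  # biopython raises bare ValueError/KeyError
            raise FormatError(f"cannot parse TRANSFAC file: {exc}") from exc
    out = []
    for motif in records:
        if motif.counts is None or motif.length == 0:
            raise FormatError("empty TRANSFAC matrix block")
        counts = np.array([motif.counts[b] for b in _BASES], dtype=float)
        if (counts < 0).any() or not np.isfinite(counts).all():
            raise FormatError("negative or non-numeric TRANSFAC counts")
        name = motif.get("AC") or motif.get("ID") or motif.name or f"matrix_{len(out)}"
        out.append((name, counts))
    if not out:
        raise FormatError(f"no matrices in {path}")
    return out


def write_transfac(matrices: Iterable[tuple[str, np.ndarray]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, counts in matrices:
            counts = np.asarray(counts, dtype=float)
            fh.write(f"AC  {name}\nXX\nID  {name}\nXX\n")
            fh.write("P0      A      C      G      T\n")
            for i in range(counts.shape[1]):
                col = counts[:, i]
                consensus = _BASES[int(np.argmax(col))]
                fh.write(
                    f"{i + 1:02d} {col[0]:6.2f} {col[1]:6.2f} {col[2]:6.2f} {col[3]:6.2f}      {consensus}\n"
                )
            fh.write("XX\n//\n")


def write_panel_tsv(panel, path: str | Path) -> None:
    """Write a curated panel, one gene per row with its audit status."""
    rows = []
    for gene in panel.retained:
        rows.append({"gene": gene, "status": "retained"})
    for gene in panel.removed_alpha:
        rows.append({"gene": gene, "status": "removed_alpha"})
    for gene in panel.removed_duct:
        rows.append({"gene": gene, "status": "removed_duct"})
    for gene in panel.removed_acinar:
        rows.append({"gene": gene, "status": "removed_acinar"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_run_summary(path: str | Path, stage: str, **fields) -> None:
    """JSON sidecar with stage name, counts, thresholds, seed."""
    payload = {"stage": stage, **fields}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
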