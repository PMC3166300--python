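"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
multi-species, multi-tissue log-normal expression with planted gene
classes, triplicate replicates, fed/fasted condition pairs, order-1
Markov promoter backgrounds with planted motif sites, and qPCR Ct tables
with reference genes.

Expression model (per probe, per sample):

    log2(signal) = baseline_gene + probe_offset + effect(class, tissue) + N(0, noise_sd)

with multiplicative (log-normal) replicate noise, matching microarray
signal behaviour.  Planted classes and their default tissue effects:

* ``beta_selective``     — 12x in beta cells only;
* ``neuro_shared``       — 8x in beta and neural tissues;
* ``immune_gut_shared``  — 2.5x in beta, immune and gut tissues;
* ``alpha_contaminant``  — 4x in beta, 16x in alpha (rat);
* ``acinar_contaminant`` — 4x in beta, stepped up 8x per level through
  islets and total pancreas (human), i.e. the exocrine contamination
  gradient pancreas > islets > beta;
* ``background``         — no effect.

A configurable fraction of genes per class is conserved (planted in all
species under the same class); the rest are species-private.  Each gene
is represented by 1-3 probes per species to exercise probe aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigError, ExpressionMatrix, OrthologMap, sample_table
from .motifs import BASES, MarkovBackground, PSSM

GENE_CLASSES = (
    "beta_selective",
    "neuro_shared",
    "immune_gut_shared",
    "alpha_contaminant",
    "acinar_contaminant",
    "background",
)

_CLASS_PREFIX = {
    "beta_selective": "BSEL",
    "neuro_shared": "NEUR",
    "immune_gut_shared": "IMGU",
    "alpha_contaminant": "ACON",
    "acinar_contaminant": "XCON",
    "background": "BKGD",
}

_DEFAULT_TISSUES = {
    "rat": ["beta", "alpha", "brain", "pituitary", "spleen", "intestine", "liver"],
    "mouse": [
        "beta", "brain", "cortex", "cerebellum", "pituitary", "spleen", "thymus",
        "lymphnode", "intestine", "colon", "stomach", "liver", "kidney", "muscle",
        "heart",
    ],
    "human": [
        "beta", "pancreas", "islets", "duct", "brain", "cortex", "cerebellum",
        "spleen", "thymus", "pbmc", "intestine", "colon", "liver", "muscle",
    ],
}

_DEFAULT_NEURAL = {
    "rat": ["brain", "pituitary"],
    "mouse": ["brain", "cortex", "cerebellum", "pituitary"],
    "human": ["brain", "cortex", "cerebellum"],
}
_DEFAULT_IMMUNE = {
    "rat": ["spleen"],
    "mouse": ["spleen", "thymus", "lymphnode"],
    "human": ["spleen", "thymus", "pbmc"],
}
_DEFAULT_GUT = {
    "rat": ["intestine"],
    "mouse": ["intestine", "colon", "stomach"],
    "human": ["intestine", "colon"],
}


@dataclass
class SimConfig:
    """Parameters of the synthetic atlas.

    Default tissue sets are sized like the real study (rat 7, mouse 15,
    human 14 tissues); the default replicate noise of 0.35 log2 units
    corresponds to roughly 25% CV.
    """

    species: tuple[str, ...] = ("rat", "mouse", "human")
    tissues: dict[str, list[str]] = field(default_factory=lambda: dict(_DEFAULT_TISSUES))
    neural_tissues: dict[str, list[str]] = field(default_factory=lambda: dict(_DEFAULT_NEURAL))
    immune_tissues: dict[str, list[str]] = field(default_factory=lambda: dict(_DEFAULT_IMMUNE))
    gut_tissues: dict[str, list[str]] = field(default_factory=lambda: dict(_DEFAULT_GUT))
    genes_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "beta_selective": 40,
            "neuro_shared": 40,
            "immune_gut_shared": 40,
            "alpha_contaminant": 15,
            "acinar_contaminant": 12,
            "background": 250,
        }
    )
    n_replicates: int = 3
    noise_sd: float = 0.35
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    probe_offset_sd: float = 0.30
    max_probes_per_gene: int = 3
    conserved_fraction: float = 0.7
    # planted fold effects (linear scale)
    beta_selective_fc: float = 12.0
    neuro_fc: float = 8.0
    immune_gut_fc: float = 2.5
    alpha_contaminant_beta_fc: float = 4.0
    alpha_contaminant_alpha_fc: float = 16.0
    acinar_beta_fc: float = 4.0
    acinar_step_fc: float = 8.0

    def validate(self) -> None:
        for sp in self.species:
            tissues = self.tissues.get(sp)
            if not tissues:
                raise ConfigError(f"no tissues configured for {sp}")
            if "beta" not in tissues:
                raise ConfigError(f"species {sp} lacks required beta tissue")
            for group, lookup in (
                ("neural", self.neural_tissues),
                ("immune", self.immune_tissues),
                ("gut", self.gut_tissues),
            ):
                members = lookup.get(sp, [])
                missing = [t for t in members if t not in tissues]
                if not members or missing:
                    raise ConfigError(
                        f"species {sp} needs a {group} tissue group within its tissues"
                    )
        if "rat" in self.species and "alpha" not in self.tissues.get("rat", []):
            raise ConfigError("rat tissue set must include alpha")
        if "human" in self.species:
            for t in ("pancreas", "islets"):
                if t not in self.tissues.get("human", []):
                    raise ConfigError(f"human tissue set must include {t}")
        if not 0 <= self.conserved_fraction <= 1:
            raise ConfigError("conserved_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation."""

    genes: pd.DataFrame  # index gene; columns gene_class, conserved, species (comma list)
    effects: dict[tuple[str, str], dict[str, float]]  # (species, gene) -> tissue -> log2 shift
    baselines: dict[str, pd.Series]  # species -> per-gene baseline log2
    probe_offsets: dict[str, pd.Series]  # species -> per-probe log2 offset
    config: SimConfig
    probe_genes: dict[str, pd.Series] = field(default_factory=dict)  # species -> probe -> gene
    fasting_suppressed: dict[str, float] = field(default_factory=dict)  # gene -> log2 shift
    planted_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def genes_of_class(self, gene_class: str, conserved: bool | None = None) -> list[str]:
        sel = self.genes[self.genes["gene_class"] == gene_class]
        if conserved is not None:
            sel = sel[sel["conserved"] == conserved]
        return list(sel.index)

    def class_of(self, gene: str) -> str:
        return str(self.genes.at[gene, "gene_class"])


def _class_effect_log2(cfg: SimConfig, gene_class: str, species: str, tissue: str) -> float:
    neural = tissue in cfg.neural_tissues.get(species, [])
    immune = tissue in cfg.immune_tissues.get(species, [])
    gut = tissue in cfg.gut_tissues.get(species, [])
    if gene_class == "beta_selective":
        return math.log2(cfg.beta_selective_fc) if tissue == "beta" else 0.0
    if gene_class == "neuro_shared":
        return math.log2(cfg.neuro_fc) if (tissue == "beta" or neural) else 0.0
    if gene_class == "immune_gut_shared":
        return math.log2(cfg.immune_gut_fc) if (tissue == "beta" or immune or gut) else 0.0
    if gene_class == "alpha_contaminant":
        if tissue == "beta":
            return math.log2(cfg.alpha_contaminant_beta_fc)
        if tissue == "alpha":
            return math.log2(cfg.alpha_contaminant_alpha_fc)
        return 0.0
    if gene_class == "acinar_contaminant":
        base = math.log2(cfg.acinar_beta_fc)
        step = math.log2(cfg.acinar_step_fc)
        if tissue == "beta":
            return base
        if tissue == "islets":
            return base + step
        if tissue == "pancreas":
            return base + 2 * step
        return 0.0
    return 0.0


def _plan_genes(cfg: SimConfig) -> pd.DataFrame:
    """Assign every gene a class, conservation flag and species membership."""
    rows = []
    for gene_class in GENE_CLASSES:
        n = cfg.genes_per_class.get(gene_class, 0)
        n_cons = int(round(cfg.conserved_fraction * n))
        prefix = _CLASS_PREFIX[gene_class]
        for i in range(n):
            if i < n_cons:
                rows.append(
                    {
                        "gene": f"{prefix}{i:04d}",
                        "gene_class": gene_class,
                        "conserved": True,
                        "species": ",".join(cfg.species),
                    }
                )
            else:
                sp = cfg.species[(i - n_cons) % len(cfg.species)]
                rows.append(
                    {
                        "gene": f"{prefix}{i:04d}_{sp.upper()}",
                        "gene_class": gene_class,
                        "conserved": False,
                        "species": sp,
                    }
                )
    return pd.DataFrame(rows).set_index("gene")


def simulate_atlas(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[dict[str, ExpressionMatrix], OrthologMap, GroundTruth]:
    """Generate the per-species expression atlases plus ortholog map and truth."""
    cfg = config or SimConfig()
    cfg.validate()
    genes = _plan_genes(cfg)
    effects: dict[tuple[str, str], dict[str, float]] = {}
    baselines: dict[str, pd.Series] = {}
    probe_offsets: dict[str, pd.Series] = {}
    matrices: dict[str, ExpressionMatrix] = {}
    map_rows = []

    for s_idx, sp in enumerate(cfg.species):
        rng = np.random.default_rng([seed, s_idx])
        present = [g for g in genes.index if sp in genes.at[g, "species"].split(",")]
        tissues = cfg.tissues[sp]
        sample_names = [
            f"{t}.{r + 1}" for t in tissues for r in range(cfg.n_replicates)
        ]
        probe_ids: list[str] = []
        probe_gene: list[str] = []
        base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(present))
        baselines[sp] = pd.Series(base, index=present)
        for gene in present:
            n_probes = int(rng.integers(1, cfg.max_probes_per_gene + 1))
            for j in range(n_probes):
                probe_ids.append(f"{sp}_{gene}_p{j + 1}")
                probe_gene.append(gene)
                map_rows.append({"gene": gene, "species": sp, "probe_id": probe_ids[-1]})
            effects[(sp, gene)] = {
                t: _class_effect_log2(cfg, genes.at[gene, "gene_class"], sp, t)
                for t in tissues
            }
        offsets = rng.normal(0.0, cfg.probe_offset_sd, size=len(probe_ids))
        probe_offsets[sp] = pd.Series(offsets, index=probe_ids)

        log2 = np.empty((len(probe_ids), len(sample_names)))
        tissue_of_sample = [name.split(".")[0] for name in sample_names]
        eff_matrix = np.array(
            [
                [effects[(sp, g)][t] for t in tissue_of_sample]
                for g in probe_gene
            ]
        )
        gene_base = baselines[sp].loc[probe_gene].to_numpy()[:, None]
        log2 = gene_base + offsets[:, None] + eff_matrix
        if cfg.noise_sd > 0:
            log2 = log2 + rng.normal(0.0, cfg.noise_sd, size=log2.shape)
        values = pd.DataFrame(
            np.maximum(2.0**log2, 0.0), index=pd.Index(probe_ids, name="probe_id"),
            columns=sample_names,
        )
        matrices[sp] = ExpressionMatrix(
            values=values,
            samples=sample_table(sample_names),
            species=sp,
            gene_symbols=pd.Series(probe_gene, index=values.index),
        )

    omap = OrthologMap(table=pd.DataFrame(map_rows))
    probe_genes = {
        sp: matrices[sp].gene_symbols.copy() for sp in cfg.species
    }
    truth = GroundTruth(
        genes=genes,
        effects=effects,
        baselines=baselines,
        probe_offsets=probe_offsets,
        config=cfg,
        probe_genes=probe_genes,
    )
    return matrices, omap, truth


def simulate_fasting(
    truth: GroundTruth,
    species: str = "rat",
    suppressed_fraction_c: float = 0.5,
    background_fraction: float = 0.02,
    suppression_fc: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Paired fed/fasted beta-cell matrices with planted suppressions.

    A ``suppressed_fraction_c`` share of the immune/gut-shared genes and a
    ``background_fraction`` share (capped at 2%) of background genes are
    down-regulated ``suppression_fc``-fold in the fasted condition; every
    planted change is a decrease, mirroring a fasting response in which at
    least 95% of altered transcripts are down-regulated.  The suppressed
    genes (and their planted log2 shifts) are recorded on the truth object.
    """
    if not 0 <= suppressed_fraction_c <= 1:
        raise ConfigError("suppressed_fraction_c must be in [0, 1]")
    if not 0 <= background_fraction <= 0.02:
        raise ConfigError("background_fraction must be in [0, 0.02]")
    cfg = truth.config
    if species not in cfg.species:
        raise ConfigError(f"species {species} not simulated")
    rng = np.random.default_rng([seed, 982451653])
    present = list(truth.baselines[species].index)
    immune = [g for g in truth.genes_of_class("immune_gut_shared") if g in present]
    background = [g for g in truth.genes_of_class("background") if g in present]
    n_c = int(round(suppressed_fraction_c * len(immune)))
    n_bg = int(round(background_fraction * len(background)))
    suppressed = list(rng.choice(immune, size=n_c, replace=False)) if n_c else []
    suppressed += list(rng.choice(background, size=n_bg, replace=False)) if n_bg else []
    shift = -math.log2(suppression_fc)
    truth.fasting_suppressed = {g: shift for g in suppressed}

    probes = truth.probe_offsets[species]
    probe_ids = list(probes.index)
    gene_of = truth.probe_genes[species].to_dict()
    matrices = {}
    for condition in ("fed", "fast"):
        sample_names = [f"beta.{condition}.{r + 1}" for r in range(cfg.n_replicates)]
        log2 = np.empty((len(probe_ids), cfg.n_replicates))
        for i, probe in enumerate(probe_ids):
            gene = gene_of[probe]
            mu = (
                truth.baselines[species][gene]
                + probes[probe]
                + truth.effects[(species, gene)]["beta"]
            )
            if condition == "fast" and gene in truth.fasting_suppressed:
                mu += truth.fasting_suppressed[gene]
            log2[i] = mu
        if cfg.noise_sd > 0:
            log2 = log2 + rng.normal(0.0, cfg.noise_sd, size=log2.shape)
        values = pd.DataFrame(
            np.maximum(2.0**log2, 0.0),
            index=pd.Index(probe_ids, name="probe_id"),
            columns=sample_names,
        )
        matrices[condition] = ExpressionMatrix(
            values=values,
            samples=sample_table(sample_names),
            species=species,
            gene_symbols=pd.Series([gene_of[p] for p in probe_ids], index=values.index),
        )
    return matrices["fed"], matrices["fast"]


def simulate_promoters(
    n_background: int,
    n_planted: int,
    motif: PSSM | np.ndarray | None = None,
    sites_per_seq: int = 1,
    length: int = 2000,
    seed: int = 0,
    cpg_factor: float = 0.25,
    marginals: tuple[float, ...] = (0.3, 0.2, 0.2, 0.3),
) -> tuple[dict[str, str], dict[str, list[tuple[int, str]]], MarkovBackground]:
    """Markov-1 promoter set with optional planted motif sites.

    Background sequences come from an order-1 chain with the C->G
    transition down-weighted (CpG depletion).  Planted sites are sampled
    column-wise from the motif frequency matrix, inserted at uniform
    non-overlapping positions on a random strand.  Returns (sequences,
    planted sites as name -> [(start, strand), ...], background model).
    """
    if n_planted > 0:
        if motif is None:
            raise ConfigError("planting sites requires a motif")
        if not isinstance(motif, PSSM):
            motif = PSSM(np.asarray(motif), name="planted")
        if sites_per_seq * motif.length > length:
            raise ConfigError("sites_per_seq x motif length exceeds sequence length")
    background = MarkovBackground.cpg_depleted(marginals=marginals, cpg_factor=cpg_factor)
    rng = np.random.default_rng([seed, 15485863])
    n_total = n_background + n_planted
    # draw all chains at once, position by position
    seqs_idx = np.empty((n_total, length), dtype=np.int8)
    seqs_idx[:, 0] = rng.choice(4, size=n_total, p=background.stationary)
    cum = np.cumsum(background.transition, axis=1)
    u = rng.random((n_total, length - 1))
    for pos in range(1, length):
        prev = seqs_idx[:, pos - 1]
        seqs_idx[:, pos] = (u[:, pos - 1, None] > cum[prev]).sum(axis=1)
    sequences: dict[str, str] = {}
    sites: dict[str, list[tuple[int, str]]] = {}
    base_arr = np.array(list(BASES))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in range(n_total):
        name = f"promoter_{i + 1:04d}"
        seq = "".join(base_arr[seqs_idx[i]])
        planted: list[tuple[int, str]] = []
        if i >= n_background and n_planted > 0:
            freqs = motif.frequencies
            L = motif.length
            occupied: list[tuple[int, int]] = []
            while len(planted) < sites_per_seq:
                start = int(rng.integers(0, length - L + 1))
                if any(start < e and start + L > s for s, e in occupied):
                    continue
                site = "".join(
                    BASES[rng.choice(4, p=freqs[:, j])] for j in range(L)
                )
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    site = "".join(comp[b] for b in reversed(site))
                seq = seq[:start] + site + seq[start + L :]
                occupied.append((start, start + L))
                planted.append((start, strand))
            planted.sort()
        sequences[name] = seq
        sites[name] = planted
    return sequences, sites, background


def simulate_qpcr(
    abundances: pd.DataFrame,
    reference_genes: tuple[str, ...] = ("BACT", "UBC", "PPIA", "PSMC5"),
    seed: int = 0,
    noise_sd: float = 0.25,
    n_replicates: int = 3,
    ct_offset: float = 30.0,
) -> pd.DataFrame:
    """Ct table for target genes with constant-abundance reference genes.

    ``abundances`` is genes x tissues of true relative abundance; every
    reference gene has abundance 1 in every tissue.  Ct is modelled as
    ``ct_offset - log2(abundance) + N(0, noise_sd)`` so that perfect
    doubling efficiency recovers the planted quantities.
    """
    if len(reference_genes) < 2:
        raise ConfigError("need >=2 reference genes")
    if (abundances.to_numpy() <= 0).any():
        raise ConfigError("true abundances must be > 0")
    rng = np.random.default_rng([seed, 32452843])
    rows = []
    all_genes = list(abundances.index) + [g for g in reference_genes if g not in abundances.index]
    for gene in all_genes:
        for tissue in abundances.columns:
            if gene in abundances.index:
                abundance = float(abundances.at[gene, tissue])
            else:
                abundance = 1.0
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": gene,
                        "tissue": tissue,
                        "replicate": rep,
                        "ct": ct_offset - math.log2(abundance) + noise,
                    }
                )
    return pd.DataFrame(rows)
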