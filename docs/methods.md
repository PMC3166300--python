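# Methods

`betamarkers` implements a cross-species pipeline for discovering genes
with conserved, abundant and selective expression in pancreatic beta
cells, together with the downstream analyses such a panel supports:
contaminant curation, tissue-tropism clustering, a fed/fasted condition
screen, reference-gene qPCR normalization, promoter motif enrichment and
a protein-level concordance check.  This note records the models, the
parameters that matter, and the design choices made where the procedure
left room for interpretation.

## Marker scoring and cross-species selection

Within one species, expression is summarized per probe as the arithmetic
mean over replicates per tissue, floored at `expression_floor`
(default 1.0 linear signal unit) to keep ratio denominators away from
zero.  Three statistics follow:

* **fold change** per non-beta tissue *t*: `mean(beta) / mean(t)`;
* **avFC** (average fold change): the arithmetic mean of those ratios —
  arithmetic rather than geometric by definition of the statistic; a
  geometric variant would down-weight single-tissue co-expression;
* **rank**: 1 + the number of tissues whose mean strictly exceeds the
  beta-cell mean.  Ties do not outrank beta; this is the conservative,
  deterministic convention.

Candidate selection takes the top `n_top` (default 2500) probes by avFC
among those with avFC ≥ `min_avfc` (default 1.2, i.e. at least 20%
higher in beta cells), with ties broken by rank and then probe id so the
output is reproducible.  A gene is a **conserved candidate** when at
least one of its probes qualifies in every species (max-probe rule:
oligonucleotide probe sets for the same gene vary widely in sensitivity,
so demanding that all probes qualify would punish genes with one poor
probe).  Probes without a gene symbol are scored but cannot enter the
intersection; they are tallied in an `unmappable` audit.  Coverage per
species is the conserved-gene count divided by the distinct genes
entering from that species' candidate set, displayed as a whole percent.

## Contaminant curation

Beta-cell preparations carry islet non-beta (alpha) cells and exocrine
(acinar/duct) cells.  Curation runs two ordered passes:

1. **Alpha pass** — Welch's unequal-variance t-test on log2 signal,
   alpha versus beta; a gene is removed when any probe shows
   fold ≥ `contaminant_fc` (1.5) with p < `contaminant_p` (0.05).
2. **Exocrine pass** — on the human data, an *acinar* marker shows the
   contamination gradient mean(pancreas) ≥ `gradient_fc` × mean(islets)
   and mean(islets) ≥ `gradient_fc` × mean(beta); a *duct* marker has
   mean(duct) ≥ `gradient_fc` × mean(beta) with duct the top tissue.
   The gradient factor defaults to 4.  No quantitative rule for
   "typical exocrine expression" exists beyond the qualitative
   pancreas > islets > beta pattern, so the gradient rule is this
   package's explicit operationalization and is config-exposed.

A gene meeting both criteria is reported under alpha (the passes are
ordered), so the removal lists partition the input.  The fold-change
lower confidence bound (LCB) is the one-sided 90% Welch bound,
`2^(Δ − t₀.₉₀,df · SE)`; 90% one-sided is the convention associated with
LCB reporting in the dChip lineage of tools.

## Tissue-tropism clustering

Panel genes are clustered on their z-scored log2 tissue profiles
(per-gene probe means, standardized across tissues with the population
SD).  For standardized rows the squared Euclidean distance is a monotone
transform of 1 − Pearson correlation, so centroid linkage on the
z-scored rows is a faithful correlation/centroid clustering; centroid
linkage can produce height inversions, therefore dendrogram cuts use
cluster counts, never heights.  Constant rows cannot be standardized;
they are set to zero (correlation 0 to everything) and flagged.

The dendrogram is cut at every k in 3..8 and the silhouette-maximizing
cut kept.  Cluster labels come from mean z-scores per tissue group
(threshold 0.5, config-exposed): **B** when beta dominates alone,
**A** when beta and neural tissues are jointly high, **C** when beta and
immune/gut tissues are jointly high, otherwise unassigned.  The original
assignment of marker-gene clusters to tropism classes was done by visual
inspection of a heat map; the z-contrast rule is the reproducible
substitute, and genes between clusters legitimately end up unassigned.

Annotation enrichment is the hypergeometric upper tail per term, with
Benjamini–Hochberg q-values reported alongside the raw p (the raw p is
kept because per-term p<0.001 is the comparable headline threshold).

## Fed/fasted condition screen

The genome-wide screen reuses the Welch machinery with fast as group A:
a probe is altered when |fold| ≥ `response_fc` (1.5) in either direction
with raw p < `response_p` (0.05); direction follows the sign of the log
fold.  Counting is per probe (a multi-probe gene contributes each
probe), while panel summaries are per gene.  A secondary, looser report
counts probes reproducibly ≥1.25-fold down with every fasted replicate
below every fed replicate.  BH q-values are reported but not used for
the headline counts, which follow the raw-p convention of the screen
being reproduced.

## qPCR normalization

Per replicate the target quantity is normalized to the geometric mean of
the reference-gene quantities from the same (tissue, replicate):
`quantity = E^(mean(Ct_refs) − Ct_target)` with amplification efficiency
E fixed at 2.0 (perfect doubling; per-assay efficiencies are rarely
known and only rescale quantities).  Per (gene, tissue) the report is
the geometric mean of replicate quantities ± their arithmetic SD, the
form in which such tables are printed.  Replicates missing a reference
Ct are dropped with an audit entry; "not detected" propagates as a
distinct state, never as 0.  Abundance ratios between genes are
scale-free, so only ratio-based quantities are compared against the
packaged reference table; one-significant-figure rounding is explicit
decimal rounding of the mantissa.

## Promoter motif enrichment

For each 4×L count matrix, Hertz–Stormo log-ratio weights are built with
a total pseudocount of 1.0 distributed proportionally to the background
base composition: `w(b,i) = log2((f(b,i) + p(b)) / (2 p(b)))` (base 2;
the base only rescales thresholds, never P-values).  Every window of
every promoter is scored on both strands; windows containing N are
skipped.

The null distribution of the window score under an order-1 Markov
background (fitted from the input with add-one smoothing; N breaks the
chain; the given strand only) is computed **exactly** by dynamic
programming over motif positions, conditioning on the previous base,
with weights discretized to a score lattice (`resolution`, default
1e-3).  Scanning uses the same lattice, so observed scores coincide with
distribution support and tail queries are exact; with continuous
scanning scores, words whose true scores differ by less than one lattice
step would be mis-binned, which the exhaustive-enumeration tests would
catch.

Enrichment sweeps the distinct observed scores in descending order; at
threshold t, hits(t) windows score ≥ t against a single-window
background probability p(t), and over-representation is the upper tail
of Binom(n_scanned, p(t)), minimized over t and reported as
sig = −log10(P) (P floored at 1e-300).  The sweep is restricted to
*informative* thresholds with p(t) ≤ `site_p_max` (default 0.01):
overlapping windows are counted individually (no clumping correction),
and below the rare-site regime their dependence makes the binomial
systematically anticonservative — in calibration runs on pure background
an unrestricted sweep yields median control sig ≈ 2.4, the capped sweep
≈ 1.0.  For realistic transcription-factor matrices (L ≥ 8) informative
thresholds lie far below the cap, so the restriction only disciplines
degenerate short-motif sweeps.

Negative controls permute matrix columns (sampled uniformly without
replacement, identity excluded whenever possible), preserving residue
composition and information content while destroying the motif; the full
analysis is re-run per permutation and summarized by the median and
maximum control sig.  The consensus report intersects matrix sets
identified by independent search configurations; the sig cutoff for
"identified" defaults to 2 and is config-exposed.

## Proteome concordance

Marker proteins quantified by label-free LC-MS across alpha, beta, brain
and liver are classified by detection pattern (beta-unique,
islet-restricted, shared with brain/liver); "<LLQ" entries are
undetected, a state distinct from zero.  `fold_of_llq` is the abundance
divided by the lower limit of quantification (packaged reference value
5e-5 relative molar units), rounded to the nearest integer — the
rounding that reproduces every printed cell of the reference table.

Two "highest in beta" statistics are provided because the packaged
reference table is internally inconsistent for exactly one protein:
`beta_max_fraction` recomputes the share of beta-detected proteins whose
printed beta abundance strictly exceeds every other tissue (ties and
undetected-as-zero count against beta; 27/38 = 71% on the reference
table), while `rank_one_fraction` uses the table's own per-protein rank
call (28/38 = 74%; Stxbp1 carries rank 1 despite a higher printed brain
abundance, presumably reflecting information in the source quantification
beyond the printed triplicate means).  Both are reported side by side.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
it is the test bed, not a reconstruction of any real array data set.
Per probe and sample,

    log2(signal) = baseline_g + probe_offset + effect(class, tissue) + N(0, sd)

with log-normal (multiplicative) noise, matching microarray signal
behaviour.  Defaults and what they represent:

| parameter | default | meaning |
|---|---|---|
| species / tissues | rat 7, mouse 15, human 14 | study-sized tissue panels; rat carries alpha, human carries pancreas/islets/duct |
| replicates | 3 | triplicate hybridizations |
| noise_sd | 0.35 log2 units | ≈25% CV; replicate CVs for such arrays are not published, so this is a generator choice exposed in config |
| probe_offset_sd | 0.30 | per-probe affinity differences; cancels in all ratio statistics |
| probes per gene | 1–3 per species | exercises probe-set aggregation |
| conserved_fraction | 0.7 | share of each class planted in all species |
| beta_selective effect | 12× in beta | the 10–15-fold selectivity tier |
| neuro_shared effect | 8× in beta + neural tissues | |
| immune_gut_shared effect | 2.5× in beta + immune + gut | the 2–3-fold tier |
| alpha contaminant | 4× beta, 16× alpha | alpha enrichment ≥ the 1.5-fold removal threshold with headroom |
| acinar contaminant | 4× beta, 8× per step through islets and pancreas | monotone exocrine gradient; 8-fold steps keep planted gradients clear of the 4-fold detection threshold under replicate noise (a gradient planted exactly at the threshold would be detected only ~half the time) |

Fasting simulation suppresses a chosen fraction of immune/gut-shared
genes (and ≤2% of background genes) 2-fold in the fasted condition;
every planted change is a decrease.  Promoter backgrounds are order-1
Markov chains with the C→G transition down-weighted (factor 0.25) to
mimic vertebrate CpG depletion; planted sites are drawn column-wise from
the motif frequency matrix and inserted at uniform non-overlapping
positions on a Bernoulli(0.5) strand.  qPCR tables model
Ct = offset − log2(abundance) + noise with constant-abundance reference
genes.

What the generator does **not** emulate: probe-level hybridization
artifacts, batch effects, array saturation at high abundance,
inter-species probe-sensitivity biases, or correlated noise across
tissues.  Passing recovery tests therefore demonstrate that the pipeline
recovers planted structure under idealized log-normal noise — necessary,
not sufficient, evidence for behaviour on real arrays.

## Numerical choices and degenerate inputs

* Welch test with zero variance in both groups: p = 1 when means are
  equal, p floored at 1e-300 when they differ; LCB collapses to the fold
  change when SE = 0.  Direction of a zero fold difference is "up" by
  convention.
* Expression values are floored before log2 so zeros never reach the
  logarithm; the floor (1.0 signal unit) is far below any planted
  baseline (2^6).
* Candidate sorting, intersection output and curation lists are sorted
  deterministically (avFC desc, rank asc, id; lexicographic elsewhere).
* Silhouette-based k selection falls back to a single cluster when no
  cut produces two distinct groups (then every gene is unassigned).
* Problem sizes in tests and the acceptance script (≈400–600 genes per
  species across 6 planted classes, 20 recovery seeds, 100,000
  Monte-Carlo draws for the binomial oracle) were chosen so that each
  statistic's sampling error is comfortably below the tolerance being
  checked while the full analysis remains a desk-scale computation.

## Known limitations

* The binomial over-representation model ignores hit clumping; the
  informative-threshold cap controls, but does not remove, the residual
  dependence between overlapping windows.
* Centroid-linkage inversions mean reported merge heights are not
  monotone; only cluster-count cuts are meaningful.
* The exocrine gradient rule and the z-contrast tropism labels are
  reproducible substitutes for judgments that were originally made by
  inspection; their thresholds are config-exposed and results should be
  read with that in mind.
* Reference-gene stability ranking (geNorm M-values) is out of scope:
  reference genes are taken as given.
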