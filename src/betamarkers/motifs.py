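"""Promoter site-enrichment with PSSM scanning under a Markov background.

For each count matrix the scanner scores every window of every promoter
on both strands with Hertz-Stormo log-ratio weights.  The number of hits
above each possible score threshold is compared with the number expected
by chance under an order-1 Markov background (which captures, e.g., CpG
depletion in vertebrate promoters): the exact distribution of the window
score under the background is computed by dynamic programming over motif
positions, conditioning on the previous base.  Over-representation at a
threshold is a binomial upper-tail P-value; the scanner sweeps all
observed score thresholds and reports the one minimizing P, converted to
a significance sig = -log10(P).  Column-permuted matrices, which keep
residue composition and information content but destroy the motif, serve
as negative controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

BASES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])
P_FLOOR = 1e-300

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """DNA string -> int8 array with A,C,G,T = 0..3 and anything else -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class PSSM:
    """Position-specific scoring matrix built from a 4 x L count matrix.

    Weights follow the log-ratio form
    ``w(b, i) = log2((f(b, i) + pseudo * p(b)) / ((1 + pseudo) * p(b)))``
    with ``f`` the observed column frequencies, ``p`` the background base
    probabilities and a total pseudocount (default 1.0) distributed
    proportionally to the background composition.
    """

    def __init__(self, counts: np.ndarray, name: str = "", pseudocount: float = 1.0):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A, C, G, T)")
        if counts.shape[1] == 0:
            raise ValueError("empty count matrix")
        if (counts < 0).any():
            raise ValueError("negative counts")
        col_sums = counts.sum(axis=0)
        if (col_sums == 0).any():
            raise ValueError("count matrix has an all-zero column")
        self.counts = counts
        self.name = name
        self.pseudocount = float(pseudocount)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def weights(self, background_probs: np.ndarray, resolution: float | None = None) -> np.ndarray:
        """Log2 weight matrix; optionally snapped to a score lattice.

        When ``resolution`` is given every weight is rounded to the nearest
        multiple of it.  Scanning and the background score distribution use
        the same lattice so observed scores match distribution support
        exactly.
        """
        p = np.asarray(background_probs, dtype=float).reshape(4, 1)
        if (p <= 0).any():
            raise ValueError("background probabilities must be positive")
        f = self.frequencies
        w = np.log2((f + self.pseudocount * p) / ((1 + self.pseudocount) * p))
        if not np.isfinite(w).all():
            raise ValueError("non-finite weights")
        if resolution is not None:
            if resolution <= 0:
                raise ValueError("resolution must be > 0")
            w = np.rint(w / resolution) * resolution
        return w

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))

    def permuted(self, order: Sequence[int], name: str | None = None) -> "PSSM":
        order = list(order)
        if sorted(order) != list(range(self.length)):
            raise ValueError("order must be a permutation of the columns")
        return PSSM(
            self.counts[:, order],
            name=name or f"{self.name}_perm",
            pseudocount=self.pseudocount,
        )


@dataclass
class MarkovBackground:
    """Order-1 Markov sequence model: 4 x 4 transition matrix + stationary law."""

    transition: np.ndarray
    stationary: np.ndarray
    order: int = 1

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        self.stationary = np.asarray(self.stationary, dtype=float)
        if not np.allclose(self.stationary @ self.transition, self.stationary, atol=1e-8):
            raise ValueError("stationary law inconsistent with transitions")

    @classmethod
    def from_transition(cls, transition: np.ndarray) -> "MarkovBackground":
        transition = np.asarray(transition, dtype=float)
        transition = transition / transition.sum(axis=1, keepdims=True)
        # stationary distribution: left eigenvector for eigenvalue 1
        vals, vecs = np.linalg.eig(transition.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        stat = np.real(vecs[:, idx])
        stat = np.abs(stat) / np.abs(stat).sum()
        # polish with a few power iterations for numerical consistency
        for _ in range(200):
            stat = stat @ transition
        stat /= stat.sum()
        return cls(transition=transition, stationary=stat)

    @classmethod
    def uniform(cls) -> "MarkovBackground":
        return cls(transition=np.full((4, 4), 0.25), stationary=np.full(4, 0.25))

    @classmethod
    def fit(cls, sequences: Iterable[str], smoothing: float = 1.0) -> "MarkovBackground":
        """Estimate transitions from sequences with add-one smoothing.

        N residues break the chain (the pair spanning an N is skipped);
        only the strand as provided is used.
        """
        counts = np.full((4, 4), float(smoothing))
        total = 0
        for seq in sequences:
            enc = encode(seq)
            total += len(enc)
            valid = (enc[:-1] >= 0) & (enc[1:] >= 0)
            np.add.at(counts, (enc[:-1][valid], enc[1:][valid]), 1.0)
        if total < 100:
            raise ValueError("need >=100 nt of sequence to fit a background")
        return cls.from_transition(counts)

    @classmethod
    def cpg_depleted(
        cls, marginals: Sequence[float] = (0.3, 0.2, 0.2, 0.3), cpg_factor: float = 0.25
    ) -> "MarkovBackground":
        """Background whose C->G transition is down-weighted by ``cpg_factor``."""
        marg = np.asarray(marginals, dtype=float)
        marg = marg / marg.sum()
        transition = np.tile(marg, (4, 1))
        transition[1, 2] *= cpg_factor  # C followed by G
        return cls.from_transition(transition)


@dataclass
class ScanResult:
    scores: np.ndarray  # all window scores, both strands
    n_scanned: int


def _window_scores(enc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores of all valid (N-free) windows of one encoded strand."""
    L = weights.shape[1]
    n_win = len(enc) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for i in range(L):
        col = enc[i : i + n_win]
        valid &= col >= 0
        scores += weights[np.clip(col, 0, 3), i]
    return scores[valid]


def scan(
    sequences: Mapping[str, str] | Iterable[str],
    pssm: PSSM,
    background: MarkovBackground,
    both_strands: bool = True,
    resolution: float | None = 1e-3,
) -> ScanResult:
    """Score every window of every sequence, by default on both strands.

    Windows containing N are skipped and do not count toward
    ``n_scanned``.  The reverse strand is scored by scanning the forward
    sequence with the reverse-complemented weight matrix, which equals
    scoring the reverse-complement strand with the original matrix.
    Weights are snapped to the ``resolution`` lattice shared with
    :class:`ScoreDistribution`.
    """
    if isinstance(sequences, Mapping):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    w = pssm.weights(background.stationary, resolution=resolution)
    w_rc = w[_COMPLEMENT][:, ::-1]
    chunks = []
    for seq in seqs:
        enc = encode(seq)
        if len(enc) < pssm.length:
            continue
        chunks.append(_window_scores(enc, w))
        if both_strands:
            chunks.append(_window_scores(enc, w_rc))
    scores = np.concatenate(chunks) if chunks else np.empty(0)
    return ScanResult(scores=scores, n_scanned=len(scores))


class ScoreDistribution:
    """Exact window-score law under an order-1 Markov background.

    Computed by dynamic programming over motif positions with the score
    discretized to ``resolution``; the first window base follows the
    stationary law and each later base conditions on its predecessor.
    """

    def __init__(self, pssm: PSSM, background: MarkovBackground, resolution: float = 1e-3):
        if resolution <= 0:
            raise ValueError("resolution must be > 0")
        self.resolution = float(resolution)
        self.motif_length = pssm.length
        w = pssm.weights(background.stationary, resolution=resolution)
        wb = np.rint(w / resolution).astype(np.int64)
        L = pssm.length
        lo = int(wb[:, 0].min())
        hi = int(wb[:, 0].max())
        width = hi - lo + 1
        prob = np.zeros((4, width))
        for b in range(4):
            prob[b, wb[b, 0] - lo] = background.stationary[b]
        T = background.transition
        for i in range(1, L):
            new_lo = lo + int(wb[:, i].min())
            new_hi = hi + int(wb[:, i].max())
            new = np.zeros((4, new_hi - new_lo + 1))
            for c in range(4):
                mass = T[:, c] @ prob  # (width,)
                off = lo + wb[c, i] - new_lo
                new[c, off : off + width] += mass
            prob, lo, hi, width = new, new_lo, new_hi, new_hi - new_lo + 1
        pmf = prob.sum(axis=0)
        keep = pmf > 0
        self.support = (lo + np.flatnonzero(keep)) * resolution
        self.pmf = pmf[keep]
        self._sf = np.cumsum(self.pmf[::-1])[::-1]
        # scanned scores share the lattice; half a bin absorbs float fuzz
        self._slack = 0.5 * resolution

    def sf(self, threshold: float) -> float:
        """P(window score >= threshold) under the background."""
        idx = np.searchsorted(self.support, threshold - self._slack, side="left")
        if idx >= len(self.support):
            return 0.0
        return float(self._sf[idx])

    @property
    def total_mass(self) -> float:
        return float(self.pmf.sum())


def score_distribution(
    pssm: PSSM, background: MarkovBackground, resolution: float = 1e-3
) -> ScoreDistribution:
    return ScoreDistribution(pssm, background, resolution=resolution)


@dataclass
class EnrichmentResult:
    """Over-representation of one matrix at its optimal score threshold."""

    name: str
    threshold: float
    n_scanned: int
    hits: int
    expected: float
    site_probability: float
    p_value: float
    sig: float


def binomial_enrichment(
    scores: np.ndarray,
    n_scanned: int,
    distribution: ScoreDistribution,
    name: str = "",
    site_p_max: float = 0.01,
) -> EnrichmentResult:
    """Sweep observed score thresholds and keep the minimal binomial P.

    For each distinct observed score t (descending), hits(t) is the number
    of windows scoring >= t, p(t) the background probability of a single
    window reaching t, and P the upper tail of Binom(n_scanned, p(t)) at
    hits(t).  The binomial P is constant between observed scores, so the
    sweep over observed values is exhaustive.  Ties in P resolve to the
    highest (most specific) threshold; P is floored at 1e-300 before
    sig = -log10(P).

    Only informative thresholds — those with single-window background
    probability p(t) <= ``site_p_max`` — enter the sweep: overlapping
    windows are counted individually (no clumping correction), and below
    the rare-site regime their dependence would inflate the binomial
    statistic on pure background.  If no observed score is informative the
    result is sig = 0.
    """
    scores = np.sort(np.asarray(scores, dtype=float))[::-1]
    if scores.size == 0:
        return EnrichmentResult(name, float("nan"), n_scanned, 0, 0.0, 1.0, 1.0, 0.0)
    distinct = np.unique(scores)[::-1]
    best = None
    for t in distinct:
        p_site = min(max(distribution.sf(t), 0.0), 1.0)
        if p_site > site_p_max:
            break  # thresholds only get more permissive from here on
        hits = int(np.searchsorted(-scores, -t, side="right"))
        p_val = float(stats.binom.sf(hits - 1, n_scanned, p_site))
        if best is None or p_val < best[0]:
            best = (p_val, t, hits, p_site)
    if best is None:
        return EnrichmentResult(name, float("nan"), n_scanned, 0, 0.0, 1.0, 1.0, 0.0)
    p_val, threshold, hits, p_site = best
    p_val = min(max(p_val, P_FLOOR), 1.0)
    return EnrichmentResult(
        name=name,
        threshold=float(threshold),
        n_scanned=n_scanned,
        hits=hits,
        expected=n_scanned * p_site,
        site_probability=p_site,
        p_value=p_val,
        sig=float(-np.log10(p_val)),
    )


def enrich(
    sequences: Mapping[str, str] | Iterable[str],
    pssm: PSSM,
    background: MarkovBackground | None = None,
    resolution: float = 1e-3,
    both_strands: bool = True,
    site_p_max: float = 0.01,
) -> EnrichmentResult:
    """Full per-matrix analysis: fit/reuse background, scan, sweep thresholds."""
    if isinstance(sequences, Mapping):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    if background is None:
        background = MarkovBackground.fit(seqs)
    result = scan(seqs, pssm, background, both_strands=both_strands, resolution=resolution)
    dist = score_distribution(pssm, background, resolution=resolution)
    return binomial_enrichment(
        result.scores, result.n_scanned, dist, name=pssm.name, site_p_max=site_p_max
    )


@dataclass
class PermutationControl:
    results: list[EnrichmentResult]
    orders: list[list[int]]

    @property
    def sigs(self) -> np.ndarray:
        return np.array([r.sig for r in self.results])

    @property
    def median_sig(self) -> float:
        return float(np.median(self.sigs))

    @property
    def max_sig(self) -> float:
        return float(self.sigs.max())


def permutation_control(
    sequences: Mapping[str, str] | Iterable[str],
    pssm: PSSM,
    background: MarkovBackground | None = None,
    n_permutations: int = 20,
    seed: int = 0,
    resolution: float = 1e-3,
    both_strands: bool = True,
    site_p_max: float = 0.01,
) -> PermutationControl:
    """Re-run the full enrichment on column-permuted matrices.

    Permutations are sampled uniformly without replacement, excluding the
    identity whenever a non-identity permutation exists; for short motifs
    with fewer distinct non-identity orders than requested, all of them
    are used.
    """
    L = pssm.length
    if L < 2:
        raise ValueError("column permutation control undefined for a 1-column matrix")
    if isinstance(sequences, Mapping):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    if background is None:
        background = MarkovBackground.fit(seqs)
    rng = np.random.default_rng(seed)
    identity = tuple(range(L))
    orders: list[tuple[int, ...]] = []
    seen = {identity}
    max_distinct = math.factorial(L) - 1 if L <= 12 else n_permutations * 1000
    attempts = 0
    while len(orders) < n_permutations and len(orders) < max_distinct and attempts < 100000:
        perm = tuple(rng.permutation(L).tolist())
        attempts += 1
        if perm in seen:
            continue
        seen.add(perm)
        orders.append(perm)
    if not orders:  # every column identical: identity is the only order
        orders = [identity]
    results = []
    for k, order in enumerate(orders):
        permuted = pssm.permuted(order, name=f"{pssm.name}_perm{k}")
        results.append(
            enrich(
                seqs, permuted, background,
                resolution=resolution, both_strands=both_strands, site_p_max=site_p_max,
            )
        )
    return PermutationControl(results=results, orders=[list(o) for o in orders])


@dataclass
class ConsensusReport:
    intersection: list[str]
    union: list[str]
    only: dict[str, list[str]]

    @property
    def counts(self) -> dict[str, int]:
        out = {"intersection": len(self.intersection), "union": len(self.union)}
        out.update({f"only_{k}": len(v) for k, v in self.only.items()})
        return out


def consensus_report(identified: Mapping[str, Iterable[str]]) -> ConsensusReport:
    """Intersection / union / exclusive lists across >=2 search configurations."""
    sets = {k: set(v) for k, v in identified.items()}
    if len(sets) < 2:
        raise ValueError("need >=2 configurations")
    inter = set.intersection(*sets.values())
    union = set.union(*sets.values())
    only = {
        k: sorted(s - set.union(*(o for kk, o in sets.items() if kk != k)))
        for k, s in sets.items()
    }
    return ConsensusReport(intersection=sorted(inter), union=sorted(union), only=only)
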