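"""geNorm: pairwise-ratio stability (M), iterative elimination, and V(n/n+1).

A gene's stability value M is the mean standard deviation of its log2
expression ratios against every other candidate: two ideal reference genes
keep a constant ratio in every sample regardless of template loading, so M is
loading-invariant by construction. The most variable gene (highest M) is
discarded and M recomputed on the survivors until two genes remain — the
"best pair", which geNorm cannot rank internally. The pairwise variation
V(n/n+1) between normalization factors built from the n and n+1 most stable
genes indicates whether adding the (n+1)-th gene still changes normalization
appreciably; V <= 0.15-0.2 is conventionally read as "no benefit".

Conventions: ratios on log2, SD with the unbiased (n-1) denominator. The
M < 0.5 and V <= 0.2 thresholds are report annotations only, never filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RQMatrix
from .errors import DataIntegrityError, DimensionError

log = logging.getLogger(__name__)

M_THRESHOLD = 0.5  # conventional acceptability; plastic scenarios accept < 1.0
V_THRESHOLD = 0.2


@dataclass
class GeNormRound:
    genes: list[str]
    m: pd.Series
    eliminated: str | None  # None in the final (two-gene) round


@dataclass
class GeNormTrace:
    """Full elimination trace plus the derived ranking and V series.

    ``ranking`` lists genes most-stable first (best pair first, in name
    order); ``ranks`` assigns both best-pair genes rank 1.5 (they are tied by
    construction), then 3, 4, ... ``m_final`` is the M value each gene had in
    the round it was eliminated (best pair: final-round M).
    """

    rounds: list[GeNormRound]
    ranking: list[str]
    ranks: pd.Series
    best_pair: tuple[str, str]
    m_final: pd.Series
    v_series: list[tuple[int, float]] = field(default_factory=list)

    def v_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.v_series, columns=["n", "v"])


def _log2_matrix(rq: RQMatrix) -> pd.DataFrame:
    vals = rq.rq.to_numpy()
    if (vals <= 0).any() or not np.isfinite(vals).all():
        raise DataIntegrityError("RQ values must be positive and finite")
    return np.log2(rq.rq)


def pairwise_sd(rq: RQMatrix, gene_a: str, gene_b: str) -> float:
    """SD over samples of log2(RQ_a / RQ_b), unbiased denominator.

    Symmetric in its arguments; equals the SD of (Cq_b - Cq_a) differences
    when the amplification efficiency is exactly 2.
    """
    if rq.rq.shape[1] < 2:
        raise DimensionError("pairwise SD needs at least 2 samples")
    y = _log2_matrix(rq)
    ratio = y.loc[gene_a] - y.loc[gene_b]
    return float(ratio.std(ddof=1))


def m_values(rq: RQMatrix, genes: list[str] | None = None) -> pd.Series:
    """Stability value M for each gene in ``genes``: mean pairwise SD with all
    other genes of the subset (lower = more stable)."""
    genes = list(genes) if genes is not None else rq.genes
    if len(genes) < 3:
        raise DimensionError("M values need at least 3 genes")
    y = _log2_matrix(rq).loc[genes].to_numpy()
    k = len(genes)
    # sd of y_j - y_k over samples, all pairs at once
    diffs = y[:, None, :] - y[None, :, :]
    sds = diffs.std(axis=2, ddof=1)
    m = sds.sum(axis=1) / (k - 1)  # diagonal contributes 0
    return pd.Series(m, index=genes, name="M")


def genorm_rank(rq: RQMatrix) -> GeNormTrace:
    """Iteratively eliminate the highest-M gene until the best pair remains.

    Ties in the maximum M are broken by gene-name order (the lexicographically
    first tied gene is eliminated) and logged. The returned ranking is the
    reverse elimination order with the final two genes reported jointly.
    """
    surviving = list(rq.genes)
    if len(surviving) < 3:
        raise DimensionError("geNorm needs at least 3 genes")
    rounds: list[GeNormRound] = []
    m_final: dict[str, float] = {}
    eliminated_order: list[str] = []
    while len(surviving) > 2:
        m = m_values(rq, surviving)
        worst_val = m.max()
        tied = sorted(m.index[m == worst_val])
        if len(tied) > 1:
            log.warning("geNorm M tie at %.6g between %s; eliminating %s", worst_val, tied, tied[0])
        worst = tied[0]
        rounds.append(GeNormRound(genes=list(surviving), m=m, eliminated=worst))
        m_final[worst] = float(m[worst])
        eliminated_order.append(worst)
        surviving.remove(worst)

    # final two-gene round: M equals their mutual pairwise SD
    final_sd = pairwise_sd(rq, surviving[0], surviving[1])
    final_m = pd.Series(final_sd, index=sorted(surviving), name="M")
    rounds.append(GeNormRound(genes=sorted(surviving), m=final_m, eliminated=None))
    best_pair = tuple(sorted(surviving))
    for g in best_pair:
        m_final[g] = final_sd

    ranking = list(best_pair) + eliminated_order[::-1]
    ranks = pd.Series(index=ranking, dtype=float, name="rank")
    ranks.iloc[0] = ranks.iloc[1] = 1.5  # the pair is tied by construction
    ranks.iloc[2:] = np.arange(3, len(ranking) + 1)
    return GeNormTrace(
        rounds=rounds,
        ranking=ranking,
        ranks=ranks,
        best_pair=best_pair,
        m_final=pd.Series(m_final).reindex(ranking),
    )


def pairwise_variation_series(rq: RQMatrix, ranking: list[str]) -> list[tuple[int, float]]:
    """V(n/n+1) for n = 2 .. k-1 along a stability ranking.

    NF_n is the geometric mean RQ of the n most stable genes; V(n/n+1) is the
    SD over samples of log2(NF_n / NF_{n+1}). Small V means the (n+1)-th gene
    barely changes normalization.
    """
    if len(ranking) < 3:
        raise DimensionError("V series needs a ranking of at least 3 genes")
    y = _log2_matrix(rq).loc[list(ranking)].to_numpy()
    out = []
    for n in range(2, len(ranking)):
        nf_n = y[:n].mean(axis=0)       # log2 of geometric-mean NF
        nf_n1 = y[: n + 1].mean(axis=0)
        v = float(np.std(nf_n - nf_n1, ddof=1))
        out.append((n, v))
    return out


def genorm_full(rq: RQMatrix) -> GeNormTrace:
    """Elimination trace plus the V series in one call."""
    trace = genorm_rank(rq)
    trace.v_series = pairwise_variation_series(rq, trace.ranking)
    return trace
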