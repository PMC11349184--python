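"""Comparative deltaCt stability scoring on raw Cq values.

For every gene pair the per-sample Cq difference (dCt) is formed; a stable
pair keeps dCt constant across samples, so the SD of dCt measures the pair's
joint instability. Each gene is scored by the mean of its pair SDs against
all partners — identical in substance to geNorm's first-round M (exactly so
when the RQ transform uses efficiency 2, since log2 RQ differs from -Cq only
by per-gene constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CqMatrix
from .errors import DimensionError


@dataclass
class DeltaCtResult:
    """Pairwise dCt SD matrix plus per-gene mean scores.

    ``pair_sd`` is symmetric with zero diagonal (cycles); ``table`` columns:
    gene, score, rank (ascending score = more stable, ties by name).
    """

    pair_sd: pd.DataFrame
    table: pd.DataFrame
    ranks: pd.Series

    @property
    def scores(self) -> pd.Series:
        return pd.Series(self.table["score"].to_numpy(), index=self.table["gene"])

    @property
    def ranking(self) -> list[str]:
        return list(self.table["gene"])


def deltact_rank(cq: CqMatrix) -> DeltaCtResult:
    """Score genes by mean SD of per-sample Cq differences with all partners.

    The mean (rather than sum) over partners keeps scores comparable across
    panel sizes; the ranking is identical either way.
    """
    if cq.n_genes < 3:
        raise DimensionError("deltaCt needs at least 3 genes")
    if cq.n_samples < 2:
        raise DimensionError("deltaCt needs at least 2 samples")
    vals = cq.cq.to_numpy()
    k = cq.n_genes
    diffs = vals[:, None, :] - vals[None, :, :]
    sds = diffs.std(axis=2, ddof=1)
    pair_sd = pd.DataFrame(sds, index=cq.genes, columns=cq.genes)
    scores = pd.Series(sds.sum(axis=1) / (k - 1), index=cq.genes, name="score")

    table = (
        scores.rename_axis("gene")
        .reset_index()
        .sort_values(["score", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, k + 1)
    ranks = pd.Series(table["rank"].to_numpy(), index=table["gene"], name="rank", dtype=float)
    return DeltaCtResult(pair_sd=pair_sd, table=table, ranks=ranks)
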