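"""BestKeeper: consensus-index correlation ranking on raw Cq values.

The BestKeeper index is the per-sample geometric mean of all candidate genes'
Cq values — a consensus expression profile reflecting the mean behaviour of
the panel. Each gene is then scored by the Pearson correlation r of its Cq
series with that index: genes tracking the consensus (and hence, mostly, the
common template loading) score near 1. Descriptive per-gene spread statistics
(SD and CV of Cq) accompany the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CqMatrix
from .errors import DimensionError

#: Cq SD above which the original method would exclude a candidate; reported
#: as a flag only, never applied to the ranking.
SD_EXCLUSION_THRESHOLD = 1.0


@dataclass
class BestKeeperResult:
    """Consensus index plus per-gene correlation ranking.

    ``table`` columns: gene, r, cq_sd, cq_cv (percent of mean Cq), sd_flag,
    rank. ``ranks`` maps gene -> rank with 1 = most stable (highest r); genes
    with undefined r (zero Cq variance) rank last.
    """

    index: pd.Series
    table: pd.DataFrame
    ranks: pd.Series
    index_method: str

    @property
    def ranking(self) -> list[str]:
        return list(self.table["gene"])


def bestkeeper_rank(cq: CqMatrix, index_method: str = "geometric") -> BestKeeperResult:
    """Rank candidate genes by Pearson correlation with the BestKeeper index.

    Parameters
    ----------
    cq : CqMatrix
        Raw (replicate-collapsed) Cq values; needs >= 2 genes and >= 3 samples.
    index_method : {"geometric", "arithmetic"}
        How the consensus index averages Cq across genes. The original method
        uses the geometric mean; at typical Cq the two differ negligibly.

    Ties in r are broken by lower Cq SD, then gene name.
    """
    if cq.n_genes < 2:
        raise DimensionError("BestKeeper needs at least 2 genes")
    if cq.n_samples < 3:
        raise DimensionError("BestKeeper needs at least 3 samples for a meaningful r")

    vals = cq.cq.to_numpy()
    if index_method == "geometric":
        index = np.exp(np.log(vals).mean(axis=0))
    elif index_method == "arithmetic":
        index = vals.mean(axis=0)
    else:
        raise ValueError(f"unknown index_method {index_method!r}")
    index = pd.Series(index, index=cq.sample_ids, name="bestkeeper_index")

    rows = []
    idx_centered = index.to_numpy() - index.mean()
    for g in cq.genes:
        x = cq.cq.loc[g].to_numpy()
        sd = float(x.std(ddof=1))
        cv = 100.0 * sd / float(x.mean())
        if sd == 0.0 or idx_centered.std() == 0.0:
            r = np.nan  # undefined; ranked last
        else:
            r = float(np.corrcoef(x, index.to_numpy())[0, 1])
        rows.append(
            {
                "gene": g,
                "r": r,
                "cq_sd": sd,
                "cq_cv": cv,
                "sd_flag": sd > SD_EXCLUSION_THRESHOLD,
            }
        )
    table = pd.DataFrame(rows)
    # descending r, NaN last; ties -> lower SD, then name
    order = sorted(
        range(len(table)),
        key=lambda i: (
            np.isnan(table.loc[i, "r"]),
            -(table.loc[i, "r"] if not np.isnan(table.loc[i, "r"]) else 0.0),
            table.loc[i, "cq_sd"],
            table.loc[i, "gene"],
        ),
    )
    table = table.iloc[order].reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    ranks = pd.Series(table["rank"].to_numpy(), index=table["gene"], name="rank", dtype=float)
    return BestKeeperResult(index=index, table=table, ranks=ranks, index_method=index_method)
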