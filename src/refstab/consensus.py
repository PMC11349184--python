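"""Consensus ranking across the four methods, normalization factor and validation.

The four stability scores live on incommensurable scales (a correlation, two
cycle-scale SDs, a model-based log2 measure), so the integration works on the
method *ranks*: each gene's aggregate score is the geometric mean of its four
ranks (geNorm's tied best pair both enter as 1.5). The normalization factor
(NF) is the per-sample geometric mean of the chosen reference genes' RQ
values; target genes are divided by it on the linear scale. Validation
normalizes a deliberately low-ranking gene and compares within-group
coefficients of variation before and after — good normalization must shrink
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bestkeeper import BestKeeperResult
from .data import RQMatrix
from .deltact import DeltaCtResult
from .errors import DataIntegrityError, DimensionError
from .genorm import GeNormTrace
from .normfinder import NormFinderResult, factor_groups

log = logging.getLogger(__name__)

METHODS = ("bestkeeper", "genorm", "normfinder", "deltact")


@dataclass
class AggregateRanking:
    """Geometric-mean-of-ranks consensus.

    ``table`` columns: gene, one rank column per method, geomean_rank,
    final_rank (1 = most stable). The geometric mean is bounded by the min
    and max of the four method ranks; ties in the geometric mean are broken
    by arithmetic mean rank, then gene name.
    """

    table: pd.DataFrame
    ranks: pd.Series

    @property
    def ranking(self) -> list[str]:
        return list(self.table["gene"])


def aggregate_ranks(
    bk: BestKeeperResult,
    gn: GeNormTrace,
    nf: NormFinderResult,
    dc: DeltaCtResult,
) -> AggregateRanking:
    """Integrate the four methods' rankings by geometric mean of ranks."""
    rank_sets = {
        "bestkeeper": bk.ranks,
        "genorm": gn.ranks,
        "normfinder": nf.ranks,
        "deltact": dc.ranks,
    }
    gene_sets = {m: set(r.index) for m, r in rank_sets.items()}
    ref = gene_sets["bestkeeper"]
    for m, gs in gene_sets.items():
        if gs != ref:
            raise DataIntegrityError(
                f"gene sets differ between methods: {m} vs bestkeeper -> "
                f"{sorted(gs ^ ref)}"
            )
    genes = sorted(ref)
    tab = pd.DataFrame({"gene": genes})
    for m in METHODS:
        tab[f"rank_{m}"] = rank_sets[m].reindex(genes).to_numpy()
    rank_mat = tab[[f"rank_{m}" for m in METHODS]].to_numpy()
    tab["geomean_rank"] = np.exp(np.log(rank_mat).mean(axis=1))
    tab["mean_rank"] = rank_mat.mean(axis=1)
    tab = tab.sort_values(["geomean_rank", "mean_rank", "gene"], kind="stable").reset_index(drop=True)
    tab["final_rank"] = np.arange(1, len(tab) + 1)
    tab = tab.drop(columns="mean_rank")
    ranks = pd.Series(tab["final_rank"].to_numpy(), index=tab["gene"], name="rank", dtype=float)
    return AggregateRanking(table=tab, ranks=ranks)


@dataclass
class NormalizationFactor:
    """Per-sample geometric mean of the reference genes' RQ values."""

    reference_genes: list[str]
    nf: pd.Series


def normalization_factor(rq: RQMatrix, reference_genes: Sequence[str]) -> NormalizationFactor:
    """Build the NF from >= 2 reference genes.

    A single reference is refused outright: per the MIQE guidelines, use of a
    single reference gene is highly discouraged. Exactly two references draw
    a warning (the accepted minimum).
    """
    refs = list(reference_genes)
    unknown = [g for g in refs if g not in rq.genes]
    if unknown:
        raise LookupError(f"reference gene(s) not in dataset: {unknown}")
    if len(refs) < 2:
        raise DimensionError(
            "a single reference gene is highly discouraged (MIQE); provide >= 2"
        )
    if len(refs) == 2:
        log.warning("normalization factor built from only 2 reference genes (MIQE minimum)")
    vals = rq.rq.loc[refs].to_numpy()
    nf = np.exp(np.log(vals).mean(axis=0))
    return NormalizationFactor(
        reference_genes=refs, nf=pd.Series(nf, index=rq.sample_ids, name="nf")
    )


@dataclass
class ValidationReport:
    """Before/after comparison of a target gene normalized by an NF.

    ``samples`` has per-sample raw RQ, normalized RQ (= RQ/NF) and their log2
    values plus the group label; ``groups`` has per-group n, linear means and
    CoV (percent, SD/mean on the linear scale) before and after.
    """

    target: str
    reference_genes: list[str]
    samples: pd.DataFrame
    groups: pd.DataFrame

    @property
    def cov_reduced(self) -> bool:
        """True when every group's CoV shrank under normalization."""
        return bool((self.groups["cov_norm_pct"] <= self.groups["cov_raw_pct"]).all())


def validate_target(
    rq: RQMatrix,
    target: str,
    nf: NormalizationFactor,
    groups: pd.Series | Sequence[str] | str = ("limb", "treatment"),
) -> ValidationReport:
    """Normalize ``target`` by the NF and compare within-group CoV before/after.

    CoV is computed on the linear scale (SD/mean of RQ, resp. RQ/NF) as
    conventionally printed; log2 values are emitted alongside for plotting.
    """
    if target not in rq.genes:
        raise LookupError(f"target gene {target!r} not in dataset")
    if target in nf.reference_genes:
        log.warning("target %s is among the NF's own reference genes", target)
    if isinstance(groups, pd.Series):
        glabels = groups.reindex(rq.sample_ids)
    else:
        glabels = factor_groups(rq.annotations, list(groups) if not isinstance(groups, str) else groups)

    raw = rq.rq.loc[target]
    norm = raw / nf.nf
    samples = pd.DataFrame(
        {
            "sample": rq.sample_ids,
            "group": glabels.to_numpy(),
            "raw_rq": raw.to_numpy(),
            "raw_log2": np.log2(raw.to_numpy()),
            "norm_rq": norm.to_numpy(),
            "norm_log2": np.log2(norm.to_numpy()),
        }
    )
    rows = []
    for g, sub in samples.groupby("group", sort=False):
        if len(sub) == 0:
            log.warning("group %s is empty; excluded", g)
            continue
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "mean_raw": sub["raw_rq"].mean(),
                "mean_norm": sub["norm_rq"].mean(),
                "cov_raw_pct": 100.0 * sub["raw_rq"].std(ddof=1) / sub["raw_rq"].mean(),
                "cov_norm_pct": 100.0 * sub["norm_rq"].std(ddof=1) / sub["norm_rq"].mean(),
            }
        )
    return ValidationReport(
        target=target,
        reference_genes=list(nf.reference_genes),
        samples=samples,
        groups=pd.DataFrame(rows),
    )
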