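"""Model/Results facade tying the four stability methods together.

``ReferenceGeneStability`` is built from a :class:`~refstab.data.CqMatrix`
(or a file, or a pair of DataFrames); ``fit()`` runs BestKeeper, geNorm,
deltaCt and NormFinder plus the consensus aggregation and returns a
:class:`StabilityResults` carrying every method's scores, ranks and
diagnostics, with a ``summary()`` table and helpers for building the
normalization factor and validating target genes against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .bestkeeper import BestKeeperResult, bestkeeper_rank
from .consensus import (
    AggregateRanking,
    NormalizationFactor,
    ValidationReport,
    aggregate_ranks,
    normalization_factor,
    validate_target,
)
from .data import CqMatrix, RQMatrix, cq_to_rq, load_cq_table
from .deltact import DeltaCtResult, deltact_rank
from .genorm import GeNormTrace, genorm_full
from .normfinder import NormFinderResult, normfinder_best_pair, normfinder_stability

#: NormFinder groupings run by default: each single factor plus the full cross.
DEFAULT_GROUPINGS = ("limb", "treatment", "timepoint", "limb*treatment*timepoint")


class ReferenceGeneStability:
    """Reference-gene stability model for a panel of candidates.

    Parameters
    ----------
    cq : CqMatrix
        Replicate-collapsed Cq values with sample annotations.
    efficiency : float
        Run-wide amplification efficiency used for the Cq->RQ transform
        (2.0 = perfect doubling). BestKeeper and deltaCt operate on raw Cq;
        geNorm and NormFinder on the derived RQ values.
    bestkeeper_index : {"geometric", "arithmetic"}
        Averaging used for the BestKeeper consensus index.
    """

    def __init__(
        self,
        cq: CqMatrix,
        efficiency: float = 2.0,
        bestkeeper_index: str = "geometric",
    ):
        self.cq = cq
        self.efficiency = float(efficiency)
        self.bestkeeper_index = bestkeeper_index
        self.rq: RQMatrix = cq_to_rq(cq, efficiency)

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_file(cls, path, layout: str = "long", efficiency: float = 2.0, **kwargs):
        """Build the model straight from a delimited Cq table."""
        return cls(load_cq_table(path, layout=layout, **kwargs), efficiency=efficiency)

    @classmethod
    def from_frames(
        cls,
        cq: pd.DataFrame,
        annotations: pd.DataFrame,
        efficiency: float = 2.0,
        replicate_sd: pd.DataFrame | None = None,
    ):
        """Build from a genes x samples DataFrame plus an annotation frame."""
        return cls(
            CqMatrix(cq=cq, annotations=annotations, replicate_sd=replicate_sd),
            efficiency=efficiency,
        )

    # -- fitting -------------------------------------------------------------
    def fit(self, groupings: Sequence[str] = DEFAULT_GROUPINGS) -> "StabilityResults":
        """Run all four methods plus the consensus aggregation.

        The aggregate uses NormFinder's *ungrouped* stability (the whole-
        dataset view, commensurate with the other three methods); grouped
        NormFinder results (with best pairs) are fitted for each requested
        grouping and kept as diagnostics.
        """
        bk = bestkeeper_rank(self.cq, index_method=self.bestkeeper_index)
        gn = genorm_full(self.rq)
        dc = deltact_rank(self.cq)
        nf_ungrouped = normfinder_stability(self.rq, groups=None)
        grouped: dict[str, NormFinderResult] = {}
        best_pairs: dict[str, tuple[tuple[str, str], float]] = {}
        for g in groupings:
            res = normfinder_stability(self.rq, groups=g)
            grouped[g] = res
            best_pairs[g] = normfinder_best_pair(res)
        agg = aggregate_ranks(bk, gn, nf_ungrouped, dc)
        return StabilityResults(
            model=self,
            bestkeeper=bk,
            genorm=gn,
            deltact=dc,
            normfinder=nf_ungrouped,
            normfinder_grouped=grouped,
            normfinder_best_pairs=best_pairs,
            aggregate=agg,
        )


@dataclass
class StabilityResults:
    """Fitted stability results for one dataset."""

    model: ReferenceGeneStability
    bestkeeper: BestKeeperResult
    genorm: GeNormTrace
    deltact: DeltaCtResult
    normfinder: NormFinderResult
    normfinder_grouped: dict[str, NormFinderResult]
    normfinder_best_pairs: dict[str, tuple[tuple[str, str], float]]
    aggregate: AggregateRanking

    # -- views ---------------------------------------------------------------
    def per_gene_table(self) -> pd.DataFrame:
        """One row per gene: each method's score and rank plus the aggregate."""
        genes = sorted(self.model.cq.genes)
        bk = self.bestkeeper.table.set_index("gene")
        dc = self.deltact.table.set_index("gene")
        nf = self.normfinder.table.set_index("gene")
        agg = self.aggregate.table.set_index("gene")
        out = pd.DataFrame(
            {
                "bestkeeper_r": bk["r"].reindex(genes),
                "genorm_m": self.genorm.m_final.reindex(genes),
                "deltact_score": dc["score"].reindex(genes),
                "normfinder_rho": nf["rho"].reindex(genes),
                "rank_bestkeeper": agg["rank_bestkeeper"].reindex(genes),
                "rank_genorm": agg["rank_genorm"].reindex(genes),
                "rank_deltact": agg["rank_deltact"].reindex(genes),
                "rank_normfinder": agg["rank_normfinder"].reindex(genes),
                "geomean_rank": agg["geomean_rank"].reindex(genes),
                "final_rank": agg["final_rank"].reindex(genes),
            }
        )
        out.index.name = "gene"
        return out.sort_values("final_rank")

    def recommended_references(self, n: int = 3) -> list[str]:
        """The n top genes of the aggregate ranking (default 3, the panel size
        the validation uses)."""
        return self.aggregate.ranking[:n]

    def summary(self) -> str:
        """Human-readable summary table in the spirit of a fit report."""
        cq = self.model.cq
        tab = self.per_gene_table()
        lines = [
            "Reference-gene stability analysis",
            "=" * 74,
            f"Genes: {cq.n_genes}    Samples: {cq.n_samples}    "
            f"Efficiency: {self.model.efficiency:g}",
            f"geNorm best pair: {' / '.join(self.genorm.best_pair)}"
            f"  (M = {self.genorm.m_final.iloc[0]:.3f})",
        ]
        for g, (pair, score) in self.normfinder_best_pairs.items():
            lines.append(f"NormFinder best pair [{g}]: {' / '.join(pair)}  (stability {score:.3f})")
        v23 = next((v for n_, v in self.genorm.v_series if n_ == 2), None)
        if v23 is not None:
            lines.append(f"geNorm V(2/3): {v23:.3f}  (<= 0.2 suggests two genes suffice)")
        lines.append("-" * 74)
        with pd.option_context("display.width", 120, "display.float_format", "{:8.3f}".format):
            lines.append(
                tab[
                    ["bestkeeper_r", "genorm_m", "deltact_score", "normfinder_rho",
                     "geomean_rank", "final_rank"]
                ].to_string()
            )
        lines.append("-" * 74)
        lines.append(
            "Recommended references (top 3 aggregate): "
            + ", ".join(self.recommended_references(3))
        )
        return "\n".join(lines)

    # -- normalization -------------------------------------------------------
    def normalization_factor(self, reference_genes: Sequence[str] | None = None) -> NormalizationFactor:
        """NF from explicit references, or the top-3 aggregate genes."""
        refs = list(reference_genes) if reference_genes else self.recommended_references(3)
        return normalization_factor(self.model.rq, refs)

    def validate(
        self,
        target: str,
        reference_genes: Sequence[str] | None = None,
        groups: Sequence[str] | str = ("limb", "treatment"),
    ) -> ValidationReport:
        """Normalize ``target`` by the NF and compare within-group CoV."""
        nf = self.normalization_factor(reference_genes)
        return validate_target(self.model.rq, target, nf, groups=groups)
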