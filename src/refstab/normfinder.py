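"""NormFinder: model-based variance decomposition of log relative quantities.

Each gene's log2 RQ is decomposed, after per-sample centering (subtracting
the sample mean across genes, which removes the common loading term), into a
gene-by-group bias d and residual intragroup noise. The naive within-group
variance of centered values is biased by the centering itself; with k genes
it is corrected as

    sigma2_hat_ig = max{ (k/(k-2)) * (s2_ig - T_g / k^2), 0 },
    T_g = (k/(k-1)) * sum_i s2_ig,

where s2_ig is the unbiased within-(gene, group) variance of centered values.
In grouped mode the intergroup differences d_ig (weighted to zero across
groups per gene) are shrunk toward zero by an empirical-Bayes factor built
from the between-group variance gamma2 of d, and the per-group stability is

    rho_ig = |d_shrunk_ig| + sqrt( (sigma2_ig/n_g) * gamma2_i / (gamma2_i + sigma2_ig/n_g) ),

averaged over groups. Ungrouped mode treats all samples as one group, where
d is identically zero and rho reduces to sqrt(sigma2_hat). Lower rho = more
stable. Log base 2 is used throughout; the base only rescales rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data import RQMatrix
from .errors import DimensionError, GroupingError

log = logging.getLogger(__name__)


@dataclass
class NormFinderResult:
    """Per-gene stability rho plus the per-group diagnostic decomposition.

    ``table`` columns: gene, rho, rank (ascending rho, ties by name).
    ``per_group`` columns: gene, group, n, s2, sigma2 (bias-corrected,
    truncated at 0), z (group mean of centered values), d (intergroup
    difference), d_shrunk, rho_group. ``gamma2`` is the per-gene intergroup
    variance estimate (grouped mode; zero series otherwise).
    """

    mode: str
    grouping: str | None
    table: pd.DataFrame
    ranks: pd.Series
    per_group: pd.DataFrame
    gamma2: pd.Series
    group_sizes: pd.Series

    @property
    def stability(self) -> pd.Series:
        return pd.Series(self.table["rho"].to_numpy(), index=self.table["gene"])

    @property
    def ranking(self) -> list[str]:
        return list(self.table["gene"])


def factor_groups(annotations: pd.DataFrame, factors: list[str] | str) -> pd.Series:
    """Combine one or more annotation factors into a single group label series."""
    if isinstance(factors, str):
        factors = [f.strip() for f in factors.replace("*", ",").split(",") if f.strip()]
    missing = [f for f in factors if f not in annotations.columns]
    if missing:
        raise GroupingError(f"unknown grouping factor(s): {missing}")
    labels = annotations[factors[0]].astype(str)
    for f in factors[1:]:
        labels = labels + "|" + annotations[f].astype(str)
    return labels.rename("group")


def normfinder_stability(
    rq: RQMatrix,
    groups: pd.Series | list[str] | str | None = None,
    gamma_mode: str = "pooled",
) -> NormFinderResult:
    """Compute NormFinder stability rho, ungrouped or grouped.

    Parameters
    ----------
    rq : RQMatrix
        Needs k >= 3 genes (the centering bias correction divides by k-2).
    groups : optional
        Group label per sample (Series aligned to samples), or annotation
        factor name(s) such as ``"limb"`` or ``["limb", "treatment"]``.
        None = ungrouped. Every group needs n_g >= 2.
    gamma_mode : {"pooled", "per_gene"}
        How the intergroup variance gamma2 is estimated. "pooled" (default)
        treats d_ig as draws from one common N(0, gamma2) and pools over all
        genes and groups with (k-1)(G-1) degrees of freedom, as in the
        original model. "per_gene" estimates gamma2 per gene from its G
        intergroup differences; with two-level groupings that estimate has a
        single degree of freedom and truncates to zero for roughly half the
        genes (collapsing their stability to 0), so it is kept only as a
        diagnostic variant.
    """
    k = len(rq.genes)
    if k < 3:
        raise DimensionError("NormFinder needs at least 3 genes")
    y = np.log2(rq.rq.to_numpy())
    genes = rq.genes
    samples = rq.sample_ids

    if groups is None:
        glabels = pd.Series("all", index=samples)
        mode, grouping = "ungrouped", None
    else:
        if isinstance(groups, (str, list)):
            glabels = factor_groups(rq.annotations, groups)
            grouping = groups if isinstance(groups, str) else "*".join(groups)
        else:
            glabels = groups.reindex(samples)
            if glabels.isna().any():
                raise GroupingError("group labels missing for some samples")
            grouping = getattr(groups, "name", None) or "custom"
        mode = "grouped"

    group_names = list(dict.fromkeys(glabels))
    n_g = {g: int((glabels == g).sum()) for g in group_names}
    small = [g for g, n in n_g.items() if n < 2]
    if small:
        raise GroupingError(f"groups with fewer than 2 samples: {small}")

    # per-sample centering removes the common loading/abundance term
    r = y - y.mean(axis=0, keepdims=True)

    s2 = np.empty((k, len(group_names)))
    z = np.empty((k, len(group_names)))
    for j, g in enumerate(group_names):
        cols = (glabels == g).to_numpy()
        s2[:, j] = r[:, cols].var(axis=1, ddof=1)
        z[:, j] = r[:, cols].mean(axis=1)

    # centering-bias correction of the intragroup variance
    t_hat = (k / (k - 1)) * s2.sum(axis=0)  # per group
    sigma2_raw = (k / (k - 2)) * (s2 - t_hat[None, :] / k**2)
    truncated = sigma2_raw < 0
    if truncated.any():
        log.info("sigma2 truncated to 0 for %d (gene, group) cell(s)", int(truncated.sum()))
    sigma2 = np.clip(sigma2_raw, 0.0, None)

    n_vec = np.array([n_g[g] for g in group_names], dtype=float)
    n_total = n_vec.sum()

    if mode == "ungrouped" or len(group_names) == 1:
        d = np.zeros_like(z)
        d_shrunk = np.zeros_like(z)
        gamma2 = np.zeros(k)
        rho_group = np.sqrt(sigma2)
        rho = rho_group[:, 0]
    else:
        wmean = (z * n_vec[None, :]).sum(axis=1, keepdims=True) / n_total
        d = z - wmean  # sum_g n_g d_ig = 0 per gene
        var_term = sigma2 / n_vec[None, :]
        if gamma_mode == "pooled":
            G = len(group_names)
            pooled = (d**2).sum() / ((k - 1) * (G - 1)) - var_term.mean()
            gamma2 = np.full(k, max(pooled, 0.0))
        elif gamma_mode == "per_gene":
            gamma2 = np.clip(d.var(axis=1, ddof=1) - var_term.mean(axis=1), 0.0, None)
        else:
            raise ValueError(f"unknown gamma_mode {gamma_mode!r}")
        if (gamma2 == 0).any():
            log.info("gamma2 truncated to 0 for %d gene(s)", int((gamma2 == 0).sum()))
        denom = gamma2[:, None] + var_term
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(denom > 0, gamma2[:, None] / denom, 0.0)
        d_shrunk = d * shrink
        rho_group = np.abs(d_shrunk) + np.sqrt(var_term * shrink)
        rho = rho_group.mean(axis=1)

    per_group = pd.DataFrame(
        {
            "gene": np.repeat(genes, len(group_names)),
            "group": np.tile(group_names, k),
            "n": np.tile(n_vec.astype(int), k),
            "s2": s2.reshape(-1),
            "sigma2": sigma2.reshape(-1),
            "z": z.reshape(-1),
            "d": d.reshape(-1),
            "d_shrunk": d_shrunk.reshape(-1),
            "rho_group": rho_group.reshape(-1),
        }
    )
    table = (
        pd.DataFrame({"gene": genes, "rho": rho})
        .sort_values(["rho", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, k + 1)
    ranks = pd.Series(table["rank"].to_numpy(), index=table["gene"], name="rank", dtype=float)
    return NormFinderResult(
        mode=mode,
        grouping=grouping,
        table=table,
        ranks=ranks,
        per_group=per_group,
        gamma2=pd.Series(gamma2, index=genes, name="gamma2"),
        group_sizes=pd.Series(n_g, name="n"),
    )


def normfinder_best_pair(result: NormFinderResult) -> tuple[tuple[str, str], float]:
    """Best two-gene combination under the grouped model.

    For a pair, intergroup biases average (and can cancel if opposite-signed)
    while variances average with an extra factor 1/2:
    d_pair,g = (d~_a,g + d~_b,g)/2 and v_pair,g = (sigma2_a,g + sigma2_b,g)/(4 n_g).
    The pair-level shrinkage factor uses the mean of the two genes' gamma2.
    Combined stability = mean over groups of |d_pair,g| + sqrt(v_pair,g * shrink).
    Lower is better; ties broken lexicographically.
    """
    if result.mode != "grouped":
        raise GroupingError("best-pair selection requires a grouped result")
    genes = list(result.gamma2.index)
    if len(genes) < 2:
        raise DimensionError("best pair needs at least 2 genes")
    pg = result.per_group.set_index(["gene", "group"])
    groups = list(result.group_sizes.index)
    n_vec = result.group_sizes.to_numpy(dtype=float)

    best: tuple[str, str] | None = None
    best_score = np.inf
    for a, b in combinations(sorted(genes), 2):
        da = pg.loc[a]["d_shrunk"].reindex(groups).to_numpy()
        db = pg.loc[b]["d_shrunk"].reindex(groups).to_numpy()
        sa = pg.loc[a]["sigma2"].reindex(groups).to_numpy()
        sb = pg.loc[b]["sigma2"].reindex(groups).to_numpy()
        d_pair = (da + db) / 2.0
        v_pair = (sa + sb) / (4.0 * n_vec)
        g2 = (result.gamma2[a] + result.gamma2[b]) / 2.0
        denom = g2 + v_pair
        shrink = np.where(denom > 0, g2 / denom, 0.0)
        score = float(np.mean(np.abs(d_pair) + np.sqrt(v_pair * shrink)))
        if score < best_score - 1e-15:
            best, best_score = (a, b), score
    assert best is not None
    return best, best_score
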