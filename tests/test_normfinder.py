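import statistics
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from refstab import (
    Effect,
    GeneSpec,
    SimConfig,
    cq_to_rq,
    default_study_design,
    factor_groups,
    normfinder_best_pair,
    normfinder_stability,
    recovery_config,
    simulate_dataset,
)
from refstab.errors import DimensionError, GroupingError

from conftest import build_cq, make_annotations, random_cq


# -- independent oracle (plain loops; mirrors the published decomposition) ----

def brute_normfinder(rq, glabels, gamma_mode="pooled"):
    genes = list(rq.genes)
    samples = list(rq.sample_ids)
    k = len(genes)
    y = {(g, s): float(np.log2(rq.rq.loc[g, s])) for g in genes for s in samples}
    # per-sample centering
    r = {}
    for s in samples:
        mean_s = statistics.mean(y[(g, s)] for g in genes)
        for g in genes:
            r[(g, s)] = y[(g, s)] - mean_s
    groups = list(dict.fromkeys(glabels))
    members = {gr: [s for s in samples if glabels[s] == gr] for gr in groups}
    n = {gr: len(members[gr]) for gr in groups}
    s2 = {
        (g, gr): statistics.variance([r[(g, s)] for s in members[gr]])
        for g in genes
        for gr in groups
    }
    sigma2 = {}
    for gr in groups:
        t_g = (k / (k - 1)) * sum(s2[(g, gr)] for g in genes)
        for g in genes:
            sigma2[(g, gr)] = max((k / (k - 2)) * (s2[(g, gr)] - t_g / k**2), 0.0)
    z = {
        (g, gr): statistics.mean(r[(g, s)] for s in members[gr])
        for g in genes
        for gr in groups
    }
    ntot = sum(n.values())
    d = {}
    for g in genes:
        wmean = sum(n[gr] * z[(g, gr)] for gr in groups) / ntot
        for gr in groups:
            d[(g, gr)] = z[(g, gr)] - wmean
    var_term = {key: sigma2[key] / n[key[1]] for key in sigma2}
    if len(groups) < 2:
        gamma2 = {g: 0.0 for g in genes}
    elif gamma_mode == "pooled":
        pooled = sum(v**2 for v in d.values()) / ((k - 1) * (len(groups) - 1))
        pooled -= statistics.mean(var_term.values())
        gamma2 = {g: max(pooled, 0.0) for g in genes}
    else:
        gamma2 = {}
        for g in genes:
            vals = [d[(g, gr)] for gr in groups]
            gamma2[g] = max(
                statistics.variance(vals)
                - statistics.mean(var_term[(g, gr)] for gr in groups),
                0.0,
            )
    rho = {}
    d_shrunk = {}
    for g in genes:
        parts = []
        for gr in groups:
            vt = var_term[(g, gr)]
            shrink = gamma2[g] / (gamma2[g] + vt) if gamma2[g] + vt > 0 else 0.0
            d_shrunk[(g, gr)] = d[(g, gr)] * shrink
            parts.append(abs(d_shrunk[(g, gr)]) + (vt * shrink) ** 0.5)
        rho[g] = statistics.mean(parts)
    return {"rho": rho, "d": d, "d_shrunk": d_shrunk, "sigma2": sigma2, "gamma2": gamma2, "n": n}


def brute_best_pair(rq, glabels):
    res = brute_normfinder(rq, glabels)
    groups = list(res["n"])
    best, best_score = None, np.inf
    for a, b in combinations(sorted(rq.genes), 2):
        g2 = (res["gamma2"][a] + res["gamma2"][b]) / 2
        parts = []
        for gr in groups:
            dp = (res["d_shrunk"][(a, gr)] + res["d_shrunk"][(b, gr)]) / 2
            vp = (res["sigma2"][(a, gr)] + res["sigma2"][(b, gr)]) / (4 * res["n"][gr])
            shrink = g2 / (g2 + vp) if g2 + vp > 0 else 0.0
            parts.append(abs(dp) + (vp * shrink) ** 0.5)
        score = statistics.mean(parts)
        if score < best_score - 1e-15:
            best, best_score = (a, b), score
    return best, best_score


def _glabel_series(rq, factor="limb"):
    return factor_groups(rq.annotations, factor)


class TestUngrouped:
    def test_rho_is_sqrt_of_corrected_intragroup_variance(self):
        rng = np.random.default_rng(20)
        rq = cq_to_rq(random_cq(rng, 5, 12))
        res = normfinder_stability(rq)
        glabels = pd.Series("all", index=rq.sample_ids)
        brute = brute_normfinder(rq, glabels)
        for g in rq.genes:
            sigma2 = brute["sigma2"][(g, "all")]
            assert res.stability[g] == pytest.approx(np.sqrt(sigma2), abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(21)
        cq = random_cq(rng, 6, 10)
        base = normfinder_stability(cq_to_rq(cq)).stability
        shifted = cq.cq.to_numpy() + rng.normal(0, 1, 10)[None, :] + rng.normal(0, 2, 6)[:, None]
        got = normfinder_stability(cq_to_rq(build_cq(shifted, genes=cq.genes))).stability
        assert np.allclose(base.sort_index(), got.sort_index(), atol=1e-9)

    def test_zero_variance_panel_truncates_to_zero(self):
        cq = build_cq(np.tile([[20.0], [22.0], [24.0]], (1, 6)))
        res = normfinder_stability(cq_to_rq(cq))
        assert np.allclose(res.stability, 0.0)

    def test_needs_three_genes(self):
        cq = build_cq([[20.0, 21.0, 22.0, 23.0]] * 2, genes=["A", "B"])
        with pytest.raises(DimensionError):
            normfinder_stability(cq_to_rq(cq))


class TestGrouped:
    @pytest.mark.parametrize("gamma_mode", ["pooled", "per_gene"])
    def test_matches_brute_force_oracle(self, gamma_mode):
        rng = np.random.default_rng(22)
        for _ in range(10):
            rq = cq_to_rq(random_cq(rng, 5, 8))
            glabels = _glabel_series(rq)
            res = normfinder_stability(rq, groups="limb", gamma_mode=gamma_mode)
            brute = brute_normfinder(rq, glabels, gamma_mode=gamma_mode)
            for g in rq.genes:
                assert res.stability[g] == pytest.approx(brute["rho"][g], abs=1e-10)

    def test_weighted_intergroup_differences_center_to_zero(self, study_rq):
        res = normfinder_stability(study_rq, groups="limb*treatment*timepoint")
        pg = res.per_group
        for g, sub in pg.groupby("gene"):
            assert abs((sub["n"] * sub["d"]).sum()) < 1e-9

    def test_variances_never_negative(self, study_rq):
        for grouping in ("limb", "treatment", "limb*treatment*timepoint"):
            res = normfinder_stability(study_rq, groups=grouping)
            assert (res.per_group["sigma2"] >= 0).all()
            assert (res.gamma2 >= 0).all()
            assert (res.table["rho"] >= 0).all()

    def test_small_group_rejected_with_name(self):
        ann = make_annotations(8)
        ann.loc[ann.index[0], "timepoint"] = "d21"
        ann.loc[ann.index[1:], "timepoint"] = "d7"
        cq = build_cq(20 + np.random.default_rng(0).normal(0, 1, (4, 8)), annotations=ann)
        with pytest.raises(GroupingError, match="d21"):
            normfinder_stability(cq_to_rq(cq), groups="timepoint")

    def test_intergroup_difference_recovery(self):
        """A 1-cycle injury effect is a log2 effect of 1 under E=2; the raw
        intergroup contrast d_injured - d_uninjured should recover it (scaled
        by (k-1)/k from the per-sample centering) within +/-30%."""
        contrasts, per_group = [], []
        k = 11
        for seed in range(100):
            cq, _ = simulate_dataset(recovery_config(seed, effect_cycles=1.0))
            rq = cq_to_rq(cq)
            res = normfinder_stability(rq, groups="limb")
            pg = res.per_group.set_index(["gene", "group"])
            d_inj = pg.loc[("SDHA", "injured"), "d"]
            d_un = pg.loc[("SDHA", "uninjured"), "d"]
            contrasts.append(d_inj - d_un)
            per_group.append(abs(d_inj))
        mean_contrast = np.mean(contrasts)
        # injected effect on log2 scale is -1.0 (higher Cq = less template)
        assert mean_contrast == pytest.approx(-1.0, abs=0.3)
        # per-group magnitude ~ delta/2 (weighted split 16/19)
        assert np.mean(per_group) == pytest.approx(0.5, abs=0.15)

    def test_monotone_in_injected_noise(self):
        """Expected rho strictly increases with a gene's own noise SD."""
        mean_rho = []
        for sd in (0.15, 0.4, 0.8):
            rhos = []
            for seed in range(100):
                genes = tuple(
                    GeneSpec(f"G{i}", 20.0 + i, gene_noise_sd=sd if i == 0 else 0.15)
                    for i in range(6)
                )
                cfg = SimConfig(
                    genes=genes, design=default_study_design(),
                    loading_sd=0.8, replicate_sd=0.0, replicates=1, seed=seed,
                )
                cq, _ = simulate_dataset(cfg)
                rhos.append(normfinder_stability(cq_to_rq(cq)).stability["G0"])
            mean_rho.append(np.mean(rhos))
        assert mean_rho[0] < mean_rho[1] < mean_rho[2]

    def test_null_genes_have_equal_mean_rho(self):
        """Exchangeable genes: no gene systematically scores better (200 seeds)."""
        from refstab import null_config

        acc = []
        for seed in range(200):
            cq, _ = simulate_dataset(null_config(seed))
            acc.append(normfinder_stability(cq_to_rq(cq)).stability.sort_index())
        means = pd.concat(acc, axis=1).mean(axis=1)
        assert (means.max() - means.min()) / means.mean() < 0.05


class TestBestPair:
    def test_opposite_biases_cancel(self):
        """Two genes with equal and opposite group bias and low noise combine
        into a pair whose intergroup term vanishes."""
        rng = np.random.default_rng(23)
        ann = make_annotations(16)
        inj = (ann["limb"] == "injured").to_numpy()
        base = 20 + rng.normal(0, 0.05, (5, 16))
        base[0] += np.where(inj, 0.5, -0.5)   # biased up in injury
        base[1] += np.where(inj, -0.5, 0.5)   # biased down in injury
        base[2] += np.where(inj, 0.5, -0.5)   # partner for gene 0, same bias
        cq = build_cq(base, genes=["UP", "DOWN", "UP2", "N1", "N2"], annotations=ann)
        res = normfinder_stability(cq_to_rq(cq), groups="limb")
        pair, score = normfinder_best_pair(res)
        assert set(pair) == {"DOWN", "UP"} or set(pair) == {"DOWN", "UP2"}
        # cancellation: the winning pair scores far below a single biased gene
        assert score < res.stability["UP"] / 2

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(24)
        for _ in range(5):
            rq = cq_to_rq(random_cq(rng, 4, 10))
            res = normfinder_stability(rq, groups="limb")
            pair, score = normfinder_best_pair(res)
            bpair, bscore = brute_best_pair(rq, _glabel_series(rq))
            assert pair == bpair
            assert score == pytest.approx(bscore, abs=1e-10)

    def test_requires_grouped_mode(self, study_rq):
        res = normfinder_stability(study_rq)
        with pytest.raises(GroupingError):
            normfinder_best_pair(res)


class TestStudyPatterns:
    def test_condition_linked_gene_scores_better_under_matching_grouping(self, study_rq):
        """A gene whose shifts are treatment- and time-linked (but injury-blind)
        ranks better when samples are grouped by injury status."""
        by_limb = normfinder_stability(study_rq, groups="limb").ranks["B2M"]
        by_treatment = normfinder_stability(study_rq, groups="treatment").ranks["B2M"]
        by_time = normfinder_stability(study_rq, groups="timepoint").ranks["B2M"]
        assert by_limb < by_treatment
        assert by_limb < by_time

    def test_stable_panel_supplies_best_pairs(self, study_results):
        stable = {"ACTB", "CSNK2A2", "HPRT1", "PAK1IP1"}
        for grouping in ("limb", "limb*treatment*timepoint"):
            pair, _ = study_results.normfinder_best_pairs[grouping]
            assert set(pair) <= stable
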