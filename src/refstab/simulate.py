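"""Synthetic Cq data generator for the rat tendon-injury study design.

The generative model on the cycle (log-quantity) scale is

    Cq(g, s, rep) = baseline(g) + coupling(g) * L(s) + sum of group effects
                    + N(0, gene_noise_sd(g)) + N(0, replicate_sd)

with a per-sample loading offset L(s) ~ N(0, loading_sd) shared by all genes.
The loading offset models the sample-to-sample variation in RNA yield/quality
and cDNA synthesis efficiency that normalization exists to remove; a gene with
``loading_coupling < 1`` only partially reflects it (an rRNA species tracking
total RNA rather than mRNA input, say), which is exactly the kind of gene on
which correlation-based and ratio-based stability methods disagree.

Noise is Gaussian on the Cq scale, i.e. multiplicative in quantity — the
standard error model for qPCR. Group effects are additive Cq shifts keyed on
annotation factor levels; a *positive* delta means *lower* expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data import CqMatrix
from .errors import RefstabError

__all__ = [
    "Effect",
    "GeneSpec",
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "default_study_design",
    "default_study_config",
    "recovery_config",
    "null_config",
    "validation_config",
    "STUDY_GENES",
]

#: Candidate panel of the emulated study, alphabetical as in its primer table.
STUDY_GENES = (
    "18S", "ACTB", "AP3D1", "B2M", "CSNK2A2",
    "GAPDH", "HPRT1", "PAK1IP1", "RPL13a", "SDHA", "UBC",
)


@dataclass(frozen=True)
class Effect:
    """A group-linked Cq shift applied to samples matching all of ``when``.

    ``when`` maps factor name -> level, e.g. ``{"limb": "injured"}`` or a
    two-factor interaction ``{"limb": "injured", "treatment": "rapamycin"}``.
    ``delta_cq`` is in cycles (positive = lower expression).
    """

    when: Mapping[str, str]
    delta_cq: float

    def applies(self, annotation: Mapping[str, str]) -> bool:
        return all(annotation[f] == lvl for f, lvl in self.when.items())


@dataclass(frozen=True)
class GeneSpec:
    """Generative parameters of one candidate gene."""

    name: str
    baseline_cq: float
    gene_noise_sd: float = 0.15
    effects: tuple[Effect, ...] = ()
    loading_coupling: float = 1.0

    def __post_init__(self):
        if self.gene_noise_sd < 0:
            raise RefstabError(f"{self.name}: gene_noise_sd must be >= 0")
        if not 0.0 <= self.loading_coupling <= 1.0:
            raise RefstabError(f"{self.name}: loading_coupling must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated dataset.

    ``design`` maps (limb, treatment, timepoint) -> number of samples.
    """

    genes: tuple[GeneSpec, ...]
    design: Mapping[tuple[str, str, str], int]
    loading_sd: float = 0.8
    replicate_sd: float = 0.12
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.genes:
            raise RefstabError("config has an empty gene list")
        if any(n < 0 for n in self.design.values()):
            raise RefstabError("group counts must be >= 0")
        if sum(self.design.values()) < 4:
            raise RefstabError("design must contain at least 4 samples")
        if self.replicates < 1:
            raise RefstabError("replicates must be >= 1")

    @property
    def n_samples(self) -> int:
        return sum(self.design.values())


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery tests.

    ``effect_cq`` holds the deterministic group-effect shift actually applied
    to each (gene, sample); ``loading`` the per-sample offsets;
    ``replicate_table`` the well-level long table before collapsing.
    """

    loading: pd.Series
    effect_cq: pd.DataFrame
    gene_noise_sd: pd.Series
    loading_coupling: pd.Series
    replicate_table: pd.DataFrame


def _build_samples(design: Mapping[tuple[str, str, str], int]) -> pd.DataFrame:
    rows = []
    counter = 0
    for (limb, treatment, timepoint), n in design.items():
        for k in range(n):
            counter += 1
            rows.append(
                {
                    "sample": f"S{counter:02d}",
                    "limb": limb,
                    "treatment": treatment,
                    "timepoint": timepoint,
                    "animal_id": f"A_{treatment[:4]}_{timepoint}_{k + 1}",
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def simulate_dataset(config: SimConfig) -> tuple[CqMatrix, SimTruth]:
    """Draw one dataset from the generative model; reproducible for a fixed seed.

    Draw order is fixed (loading offsets, then per-gene biological noise, then
    replicate noise) so that identical configs with identical seeds produce
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    ann = _build_samples(config.design)
    n = len(ann)
    gene_names = [g.name for g in config.genes]

    loading = pd.Series(rng.normal(0.0, config.loading_sd, n), index=ann.index)

    effect = pd.DataFrame(0.0, index=gene_names, columns=ann.index)
    for g in config.genes:
        for eff in g.effects:
            mask = [eff.applies(ann.loc[s]) for s in ann.index]
            effect.loc[g.name, mask] += eff.delta_cq

    true_cq = pd.DataFrame(index=gene_names, columns=ann.index, dtype=float)
    for g in config.genes:
        bio = rng.normal(0.0, g.gene_noise_sd, n) if g.gene_noise_sd > 0 else np.zeros(n)
        true_cq.loc[g.name] = (
            g.baseline_cq + g.loading_coupling * loading.to_numpy()
            + effect.loc[g.name].to_numpy() + bio
        )

    reps = config.replicates
    well_noise = (
        rng.normal(0.0, config.replicate_sd, (len(gene_names), n, reps))
        if config.replicate_sd > 0
        else np.zeros((len(gene_names), n, reps))
    )
    wells = true_cq.to_numpy()[:, :, None] + well_noise
    mean_cq = pd.DataFrame(wells.mean(axis=2), index=gene_names, columns=ann.index)
    rep_sd = pd.DataFrame(
        wells.std(axis=2, ddof=1) if reps > 1 else np.zeros((len(gene_names), n)),
        index=gene_names,
        columns=ann.index,
    )

    replicate_table = pd.DataFrame(
        {
            "sample": np.tile(np.repeat(ann.index.to_numpy(), reps), len(gene_names)),
            "gene": np.repeat(gene_names, n * reps),
            "replicate": np.tile(np.arange(1, reps + 1), len(gene_names) * n),
            "cq": wells.reshape(-1),
        }
    ).merge(ann.reset_index(), on="sample")

    cq = CqMatrix(cq=mean_cq, annotations=ann, replicate_sd=rep_sd)
    truth = SimTruth(
        loading=loading,
        effect_cq=effect,
        gene_noise_sd=pd.Series({g.name: g.gene_noise_sd for g in config.genes}),
        loading_coupling=pd.Series({g.name: g.loading_coupling for g in config.genes}),
        replicate_table=replicate_table,
    )
    return cq, truth


# ---------------------------------------------------------------------------
# canonical configurations


def default_study_design() -> dict[tuple[str, str, str], int]:
    """2x2x2 factorial sample counts reproducing the study totals.

    35 samples: 19 uninjured / 16 injured, 18 rapamycin / 17 vehicle,
    n = 4-5 per cell (uninjured contralateral limbs outnumber injured because
    sample-level QC removed more injured samples).
    """
    return {
        ("injured", "rapamycin", "d7"): 4,
        ("injured", "rapamycin", "d21"): 4,
        ("injured", "vehicle", "d7"): 4,
        ("injured", "vehicle", "d21"): 4,
        ("uninjured", "rapamycin", "d7"): 5,
        ("uninjured", "rapamycin", "d21"): 5,
        ("uninjured", "vehicle", "d7"): 5,
        ("uninjured", "vehicle", "d21"): 4,
    }


def default_study_config(seed: int) -> SimConfig:
    """The emulated tendon-injury study: 11 genes, 35 samples, triplicate wells.

    Baselines follow the observed abundance ordering (the rRNA near Cq 8,
    ribosomal-protein/cytoskeletal genes abundant around Cq 18-20, the rest
    modest at 22-26). Designated unstable genes: SDHA carries a 1-cycle
    injury effect (expression reduced after injury), GAPDH a rapamycin-by-
    injury interaction (drug lowers it in injured tissue, raises it in
    uninjured); the rRNA and UBC are noisy, and a few abundant genes carry
    small injury-linked shifts so that whole-dataset stability is worse than
    within-subset stability, as in real injured-vs-control designs.
    """
    inj = lambda d: Effect({"limb": "injured"}, d)
    genes = (
        GeneSpec(
            "18S", 8.5, gene_noise_sd=0.8,
            effects=(
                inj(-0.5),
                # early inflammatory cellularity peak: extra rRNA at day 7
                Effect({"limb": "injured", "timepoint": "d7"}, -0.4),
            ),
        ),
        GeneSpec("ACTB", 19.0, gene_noise_sd=0.20),
        GeneSpec("AP3D1", 24.0, gene_noise_sd=0.25, effects=(inj(-0.25),)),
        GeneSpec(
            "B2M", 20.0, gene_noise_sd=0.30,
            effects=(
                Effect({"treatment": "rapamycin"}, 0.4),
                Effect({"timepoint": "d21"}, 0.5),
            ),
        ),
        GeneSpec("CSNK2A2", 23.0, gene_noise_sd=0.18),
        GeneSpec(
            "GAPDH", 20.0, gene_noise_sd=0.45,
            effects=(
                Effect({"treatment": "rapamycin", "limb": "injured"}, 0.8),
                Effect({"treatment": "rapamycin", "limb": "uninjured"}, -0.8),
            ),
        ),
        GeneSpec("HPRT1", 24.5, gene_noise_sd=0.20),
        GeneSpec("PAK1IP1", 25.5, gene_noise_sd=0.20),
        GeneSpec("RPL13a", 18.5, gene_noise_sd=0.22, effects=(inj(-0.3),)),
        GeneSpec("SDHA", 23.5, gene_noise_sd=0.18, effects=(inj(1.0),)),
        GeneSpec("UBC", 22.5, gene_noise_sd=0.60),
    )
    return SimConfig(
        genes=genes,
        design=default_study_design(),
        loading_sd=0.8,
        replicate_sd=0.12,
        replicates=3,
        seed=seed,
    )


def recovery_config(
    seed: int, effect_cycles: float = 1.0, effect_gene: str = "SDHA"
) -> SimConfig:
    """Benchmark config for effect recovery: one injury-shifted gene among
    otherwise exchangeable candidates (all gene_noise_sd 0.15, loading SD 0.8)."""
    genes = tuple(
        GeneSpec(
            name,
            baseline_cq=20.0 + 0.5 * i,
            gene_noise_sd=0.15,
            effects=(Effect({"limb": "injured"}, effect_cycles),)
            if name == effect_gene
            else (),
        )
        for i, name in enumerate(STUDY_GENES)
    )
    return SimConfig(
        genes=genes,
        design=default_study_design(),
        loading_sd=0.8,
        replicate_sd=0.0,
        replicates=1,
        seed=seed,
    )


def null_config(seed: int, gene_noise_sd: float = 0.3) -> SimConfig:
    """Fully exchangeable genes: no effects, equal noise. Used for calibration
    checks (every gene equally likely to rank first)."""
    genes = tuple(
        GeneSpec(name, baseline_cq=20.0 + 0.5 * i, gene_noise_sd=gene_noise_sd)
        for i, name in enumerate(STUDY_GENES)
    )
    return SimConfig(
        genes=genes,
        design=default_study_design(),
        loading_sd=0.8,
        replicate_sd=0.0,
        replicates=1,
        seed=seed,
    )


def validation_config(seed: int) -> SimConfig:
    """Benchmark for normalization-factor validation: a target gene whose only
    variability is the shared loading offset, plus low-noise reference genes.

    Dividing the target's RQ by a normalization factor built from the
    references should cancel the loading term almost exactly, so within-group
    CoV must drop."""
    genes = (
        GeneSpec("REF1", 20.0, gene_noise_sd=0.15),
        GeneSpec("REF2", 21.0, gene_noise_sd=0.15),
        GeneSpec("REF3", 22.0, gene_noise_sd=0.15),
        GeneSpec("TARGET", 24.0, gene_noise_sd=0.0),
    )
    return SimConfig(
        genes=genes,
        design=default_study_design(),
        loading_sd=0.8,
        replicate_sd=0.0,
        replicates=1,
        seed=seed,
    )
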