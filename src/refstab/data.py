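"""Cq data model, file I/O, replicate collapsing, Cq->RQ conversion and subsetting.

The central containers are :class:`CqMatrix` (replicate-collapsed quantification
cycles, genes x samples, with per-sample annotations) and :class:`RQMatrix`
(linear relative quantities, ``RQ = E**(calibrator - Cq)``). Annotations carry
the three experimental factors of the tendon-injury design — ``limb``
(injured/uninjured), ``treatment`` (rapamycin/vehicle) and ``timepoint``
(d7/d21) — which drive the canonical data subsets and the grouped analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, DimensionError, FormatError

log = logging.getLogger(__name__)

LIMB_LEVELS = ("injured", "uninjured")
TREATMENT_LEVELS = ("rapamycin", "vehicle")
TIMEPOINT_LEVELS = ("d7", "d21")
FACTORS: Mapping[str, tuple[str, ...]] = {
    "limb": LIMB_LEVELS,
    "treatment": TREATMENT_LEVELS,
    "timepoint": TIMEPOINT_LEVELS,
}

#: Replicate scatter (SD in cycles) above which a well triplet is flagged.
REPLICATE_SD_FLAG = 0.5

#: Admissible per-cycle amplification efficiencies (2.0 = perfect doubling).
EFFICIENCY_RANGE = (1.6, 2.2)


def _normalise_level(factor: str, value) -> str:
    """Map common spellings onto the canonical factor levels."""
    v = str(value).strip().lower()
    if factor == "timepoint":
        v = v.replace("day", "").strip()
        if v.endswith("d"):
            v = "d" + v[:-1]
        elif not v.startswith("d"):
            v = "d" + v
    levels = FACTORS[factor]
    if v not in levels:
        raise FormatError(
            f"unrecognised {factor} level {value!r}; expected one of {levels}"
        )
    return v


@dataclass(frozen=True)
class SampleAnnotation:
    """Experimental annotation of one cDNA sample."""

    sample_id: str
    limb: str
    treatment: str
    timepoint: str
    animal_id: str | None = None

    def __post_init__(self):
        for factor in FACTORS:
            object.__setattr__(self, factor, _normalise_level(factor, getattr(self, factor)))


@dataclass(frozen=True)
class SubsetSpec:
    """Declarative sample filter: keep samples whose annotation matches ``factors``.

    Applying a spec never reorders the retained samples.
    """

    name: str
    factors: Mapping[str, str]

    def mask(self, annotations: pd.DataFrame) -> pd.Series:
        keep = pd.Series(True, index=annotations.index)
        for factor, level in self.factors.items():
            keep &= annotations[factor] == _normalise_level(factor, level)
        return keep


#: Table-style canonical subsets: full data plus one subset per factor level
#: of limb and treatment.
CANONICAL_SUBSETS: tuple[SubsetSpec, ...] = (
    SubsetSpec("all_data", {}),
    SubsetSpec("all_uninjured", {"limb": "uninjured"}),
    SubsetSpec("all_injured", {"limb": "injured"}),
    SubsetSpec("all_rapamycin", {"treatment": "rapamycin"}),
    SubsetSpec("all_vehicle", {"treatment": "vehicle"}),
)


def _check_annotations(annotations: pd.DataFrame, sample_ids: Sequence[str]) -> pd.DataFrame:
    ann = annotations.copy()
    missing = [c for c in FACTORS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation columns missing: {missing}")
    if list(ann.index) != list(sample_ids):
        ann = ann.reindex(sample_ids)
        if ann[list(FACTORS)].isna().any().any():
            bad = ann.index[ann[list(FACTORS)].isna().any(axis=1)].tolist()
            raise DataIntegrityError(f"samples without complete annotations: {bad}")
    for factor in FACTORS:
        ann[factor] = [_normalise_level(factor, v) for v in ann[factor]]
    if "animal_id" not in ann.columns:
        ann["animal_id"] = None
    return ann[[*FACTORS, "animal_id"]]


@dataclass
class CqMatrix:
    """Replicate-collapsed quantification cycles, genes x samples.

    Parameters
    ----------
    cq : DataFrame
        Genes in rows (index = gene symbols), samples in columns. Complete-case:
        no missing cells; all values finite and positive.
    annotations : DataFrame
        Indexed by sample id, columns ``limb``, ``treatment``, ``timepoint``
        (and optionally ``animal_id``), aligned with ``cq.columns``.
    replicate_sd : DataFrame, optional
        Within-replicate SD (cycles) per (gene, sample), same shape as ``cq``.
    """

    cq: pd.DataFrame
    annotations: pd.DataFrame
    replicate_sd: pd.DataFrame | None = None

    def __post_init__(self):
        self.cq = self.cq.astype(float)
        if self.cq.columns.duplicated().any():
            raise DataIntegrityError("duplicate sample ids")
        if self.cq.index.duplicated().any():
            raise DataIntegrityError("duplicate gene symbols")
        vals = self.cq.to_numpy()
        if not np.isfinite(vals).all():
            raise DataIntegrityError("Cq matrix contains missing or non-finite values")
        if (vals <= 0).any():
            raise DataIntegrityError("Cq values must be positive cycle numbers")
        self.annotations = _check_annotations(self.annotations, list(self.cq.columns))
        if self.replicate_sd is not None:
            self.replicate_sd = self.replicate_sd.reindex(
                index=self.cq.index, columns=self.cq.columns
            )

    # -- basic introspection -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def n_genes(self) -> int:
        return self.cq.shape[0]

    @property
    def n_samples(self) -> int:
        return self.cq.shape[1]

    # -- manipulation --------------------------------------------------------
    def subset(self, sample_ids: Iterable[str]) -> "CqMatrix":
        """Return a new matrix restricted to ``sample_ids`` (original order kept)."""
        wanted = set(sample_ids)
        keep = [s for s in self.sample_ids if s in wanted]
        return CqMatrix(
            cq=self.cq[keep],
            annotations=self.annotations.loc[keep],
            replicate_sd=None if self.replicate_sd is None else self.replicate_sd[keep],
        )

    def apply_spec(self, spec: SubsetSpec) -> "CqMatrix":
        mask = spec.mask(self.annotations)
        return self.subset(self.annotations.index[mask])

    def to_wide_frame(self) -> pd.DataFrame:
        """Samples in rows, factor columns then one column per gene."""
        wide = self.annotations[list(FACTORS)].copy()
        for g in self.genes:
            wide[g] = self.cq.loc[g]
        wide.index.name = "sample"
        return wide

    def write(self, path, sep: str = ",") -> None:
        """Write the collapsed matrix as wide-format delimited text."""
        self.to_wide_frame().to_csv(path, sep=sep)


@dataclass
class RQMatrix:
    """Linear relative quantities with the efficiency and calibrator that produced them.

    ``rq = efficiency ** (calibrator_cq - cq)`` per gene; with the default
    per-gene minimum-Cq calibrator every gene's maximum RQ is exactly 1.
    """

    rq: pd.DataFrame
    annotations: pd.DataFrame
    efficiency: float
    calibrator_cq: pd.Series

    def __post_init__(self):
        if (self.rq.to_numpy() <= 0).any():
            raise DataIntegrityError("RQ values must be strictly positive")

    @property
    def genes(self) -> list[str]:
        return list(self.rq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rq.columns)

    def log2(self) -> pd.DataFrame:
        return np.log2(self.rq)

    def subset(self, sample_ids: Iterable[str]) -> "RQMatrix":
        wanted = set(sample_ids)
        keep = [s for s in self.sample_ids if s in wanted]
        return RQMatrix(
            rq=self.rq[keep],
            annotations=self.annotations.loc[keep],
            efficiency=self.efficiency,
            calibrator_cq=self.calibrator_cq,
        )


# ---------------------------------------------------------------------------
# replicate collapsing


def collapse_replicates(
    cq_replicates: Sequence[float], flag_threshold: float = REPLICATE_SD_FLAG
) -> tuple[float, float]:
    """Collapse technical replicate Cq values to (mean, SD).

    SD uses the unbiased (n-1) denominator; a single replicate yields SD 0.
    Replicate sets with SD above ``flag_threshold`` cycles are logged, never
    dropped: silent mutation of data is avoided.
    """
    arr = np.asarray(list(cq_replicates), dtype=float)
    if arr.size == 0:
        raise DataIntegrityError("empty replicate set")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if sd > flag_threshold:
        log.warning(
            "replicate SD %.3f cycles exceeds flag threshold %.2f (values %s)",
            sd, flag_threshold, np.round(arr, 3).tolist(),
        )
    return mean, sd


# ---------------------------------------------------------------------------
# loading / writing


def _read_delimited(path, sep) -> pd.DataFrame:
    try:
        if sep is None:
            return pd.read_csv(path, sep=None, engine="python")
        return pd.read_csv(path, sep=sep)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pandas raises a zoo of parser errors
        raise FormatError(f"could not parse {path}: {exc}") from exc


def load_cq_table(
    path,
    layout: str = "long",
    sep: str | None = None,
    sample_col: str = "sample",
    gene_col: str = "gene",
    cq_col: str = "cq",
    replicate_col: str = "replicate",
    flag_threshold: float = REPLICATE_SD_FLAG,
) -> CqMatrix:
    """Load a delimited Cq table (long or wide layout) into a :class:`CqMatrix`.

    Long layout: one row per well or per (sample, gene), columns
    ``sample, gene, cq`` plus optional ``replicate`` and the factor columns
    ``limb, treatment, timepoint`` (``animal_id`` optional). Wide layout: one
    row per sample, one column per gene, plus factor columns. The delimiter is
    auto-detected (comma or tab) unless ``sep`` is given.

    Technical replicates are collapsed to their mean (SD retained); samples
    missing any gene are dropped with a warning — every downstream algorithm
    assumes a rectangular, complete matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_delimited(path, sep)
    df.columns = [str(c).strip() for c in df.columns]

    if layout == "long":
        required = [sample_col, gene_col, cq_col]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: long layout requires columns {missing}")
        has_rep = replicate_col in df.columns
        key_cols = [sample_col, gene_col] + ([replicate_col] if has_rep else [])
        dup = df.duplicated(subset=key_cols)
        if has_rep and dup.any():
            rows = df.loc[dup, key_cols].to_records(index=False).tolist()
            raise DataIntegrityError(f"duplicate (sample, gene, replicate) rows: {rows[:5]}")
        if not pd.api.types.is_numeric_dtype(df[cq_col]):
            bad = df.loc[pd.to_numeric(df[cq_col], errors="coerce").isna()].index
            raise FormatError(
                f"{path}: non-numeric Cq value near line {int(bad[0]) + 2}"
            )
        collapsed = (
            df.groupby([sample_col, gene_col], sort=False)[cq_col]
            .apply(lambda v: collapse_replicates(v.to_numpy(), flag_threshold))
            .reset_index()
        )
        collapsed[["mean", "sd"]] = pd.DataFrame(
            collapsed[cq_col].tolist(), index=collapsed.index
        )
        cq_wide = collapsed.pivot(index=gene_col, columns=sample_col, values="mean")
        sd_wide = collapsed.pivot(index=gene_col, columns=sample_col, values="sd")
        # keep file order for genes and samples
        gene_order = list(dict.fromkeys(df[gene_col]))
        sample_order = list(dict.fromkeys(df[sample_col]))
        cq_wide = cq_wide.reindex(index=gene_order, columns=sample_order)
        sd_wide = sd_wide.reindex(index=gene_order, columns=sample_order)

        ann_cols = [c for c in (*FACTORS, "animal_id") if c in df.columns]
        ann = df[[sample_col, *ann_cols]].drop_duplicates(subset=sample_col)
        if ann.duplicated(subset=sample_col).any():
            raise DataIntegrityError("conflicting annotations for a sample")
        ann = ann.set_index(sample_col).reindex(sample_order)
    elif layout == "wide":
        if sample_col in df.columns:
            df = df.set_index(sample_col)
        else:
            df = df.set_index(df.columns[0])
        ann_cols = [c for c in (*FACTORS, "animal_id") if c in df.columns]
        gene_cols = [c for c in df.columns if c not in ann_cols]
        cq_wide = df[gene_cols].T
        cq_wide = cq_wide.apply(pd.to_numeric, errors="coerce")
        sd_wide = None
        ann = df[ann_cols]
        sample_order = list(df.index)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    # complete-case enforcement: drop samples with any missing gene value
    incomplete = cq_wide.columns[cq_wide.isna().any(axis=0)].tolist()
    if incomplete:
        log.warning("dropping %d incomplete sample(s): %s", len(incomplete), incomplete)
        cq_wide = cq_wide.drop(columns=incomplete)
        if sd_wide is not None:
            sd_wide = sd_wide.drop(columns=incomplete)
        ann = ann.drop(index=incomplete)

    if cq_wide.shape[0] < 3:
        raise DimensionError(
            f"only {cq_wide.shape[0]} gene(s) after load; stability analysis needs >= 3"
        )
    cq_wide.index.name = "gene"
    cq_wide.columns.name = "sample"
    return CqMatrix(cq=cq_wide, annotations=ann, replicate_sd=sd_wide)


def write_cq_table(cq: CqMatrix, path, sep: str = ",") -> None:
    """Write a collapsed matrix as wide-format delimited text (round-trippable)."""
    cq.write(path, sep=sep)


# ---------------------------------------------------------------------------
# RQ conversion


def cq_to_rq(cq: CqMatrix, efficiency: float = 2.0) -> RQMatrix:
    """Convert Cq to linear relative quantities, ``RQ = E**(calibrator - Cq)``.

    The calibrator is each gene's minimum Cq (its most concentrated sample), so
    RQ lies in (0, 1] and each gene's maximum RQ is exactly 1. Any per-gene
    anchor cancels in every downstream ratio-based statistic; the minimum is
    the geNorm convention. Efficiency is a single run-wide constant
    (2.0 = perfect doubling each cycle).
    """
    lo, hi = EFFICIENCY_RANGE
    if not (lo <= efficiency <= hi):
        raise ValueError(f"efficiency {efficiency} outside plausible range [{lo}, {hi}]")
    calibrator = cq.cq.min(axis=1)
    rq = efficiency ** cq.cq.rsub(calibrator, axis=0)
    return RQMatrix(
        rq=rq,
        annotations=cq.annotations,
        efficiency=float(efficiency),
        calibrator_cq=calibrator,
    )


# ---------------------------------------------------------------------------
# canonical subsetting


def make_subsets(
    cq: CqMatrix, extra: Sequence[SubsetSpec] = (), min_samples: int = 2
) -> dict[str, CqMatrix]:
    """Build the five canonical data subsets plus any user-defined specs.

    Canonical subsets: ``all_data``, ``all_uninjured``, ``all_injured``,
    ``all_rapamycin``, ``all_vehicle``. Subsets with fewer than ``min_samples``
    samples are excluded (logged as errors); subsets with fewer than 3 samples
    draw a warning since correlations become degenerate.
    """
    out: dict[str, CqMatrix] = {}
    for spec in (*CANONICAL_SUBSETS, *extra):
        sub = cq.apply_spec(spec)
        n = sub.n_samples
        if n < min_samples:
            log.error("subset %s has %d sample(s); excluded from analysis", spec.name, n)
            continue
        if n < 3:
            log.warning("subset %s has only %d samples", spec.name, n)
        log.info("subset %s: %d samples", spec.name, n)
        out[spec.name] = sub
    return out
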