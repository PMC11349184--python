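import numpy as np
import pandas as pd
import pytest

from refstab import CqMatrix, cq_to_rq, default_study_config, simulate_dataset


def make_annotations(n, limbs=None, treatments=None, timepoints=None):
    """Cyclic annotations covering all factor levels for n samples."""
    limbs = limbs or ["injured", "uninjured"]
    treatments = treatments or ["rapamycin", "vehicle"]
    timepoints = timepoints or ["d7", "d21"]
    return pd.DataFrame(
        {
            "limb": [limbs[i % len(limbs)] for i in range(n)],
            "treatment": [treatments[(i // 2) % len(treatments)] for i in range(n)],
            "timepoint": [timepoints[(i // 4) % len(timepoints)] for i in range(n)],
        },
        index=[f"S{i + 1:02d}" for i in range(n)],
    )


def build_cq(values, genes=None, annotations=None):
    """CqMatrix from a 2-D array (genes x samples) with generated annotations."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    ann = annotations if annotations is not None else make_annotations(values.shape[1])
    cq = pd.DataFrame(values, index=genes, columns=ann.index)
    return CqMatrix(cq=cq, annotations=ann)


def random_cq(rng, n_genes, n_samples, base=20.0, spread=2.0):
    """Random positive Cq matrix around plausible cycle numbers."""
    vals = base + spread * rng.standard_normal((n_genes, n_samples))
    return build_cq(vals)


@pytest.fixture(scope="session")
def study_cq():
    """One draw from the default 11-gene / 35-sample study configuration."""
    cq, _ = simulate_dataset(default_study_config(seed=1))
    return cq


@pytest.fixture(scope="session")
def study_rq(study_cq):
    return cq_to_rq(study_cq, efficiency=2.0)


@pytest.fixture(scope="session")
def study_results(study_cq):
    from refstab import ReferenceGeneStability

    return ReferenceGeneStability(study_cq).fit()


@pytest.fixture
def toy_cq():
    """Small handmade matrix: 3 genes x 4 samples."""
    return build_cq(
        [
            [20.0, 21.0, 22.0, 20.5],
            [25.0, 25.5, 26.5, 25.2],
            [18.0, 19.2, 20.1, 18.4],
        ],
        genes=["A", "B", "C"],
    )
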