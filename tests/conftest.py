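import numpy as np
import pandas as pd
import pytest

from imglia import CountMatrix, SimulationConfig, generate_counts


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes x 4 samples, two cell types, one study."""
    counts = pd.DataFrame(
        {
            "m1": [10, 0, 5],
            "m2": [12, 1, 6],
            "g1": [40, 2, 5],
            "g2": [44, 3, 7],
        },
        index=["GA", "GB", "GC"],
    )
    meta = pd.DataFrame(
        {
            "cell_type": ["monocyte", "monocyte", "iMG", "iMG"],
            "study": ["s1"] * 4,
        },
        index=pd.Index(["m1", "m2", "g1", "g2"], name="sample_id"),
    )
    return CountMatrix(counts, meta)


@pytest.fixture(scope="session")
def default_study():
    """One default five-population, two-study simulation (seed 3)."""
    return generate_counts(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def two_group_study():
    """20 vs 20 samples, planted log2FC = 2 on 100 signature genes."""
    cfg = SimulationConfig(
        n_genes=2000,
        n_signature=100,
        signature_log2fc=2.0,
        batch_log2shift_sd=0.0,
        samples_per_group={"monocyte": 20, "iMG": 20},
        studies={"monocyte": "a", "iMG": "a"},
        effect_multipliers={"monocyte": 0.0, "iMG": 1.0},
        seed=5,
    )
    return generate_counts(cfg)


def group_means_log2fc(study, numerator="iMG", denominator="monocyte"):
    """Naive oracle: log2 ratio of group means after truth-based depth
    normalization.

    Each sample is scaled by its mean count over the *non-signature*
    genes (known from the planted truth), which removes both library-size
    and composition differences without touching any package estimator.
    """
    m = study.counts
    stable = [g for g in m.gene_ids if g not in study.truth_signature]
    scale = m.counts.loc[stable].mean(axis=0)
    norm = m.counts / scale
    num = norm[m.samples_of(numerator)].mean(axis=1)
    den = norm[m.samples_of(denominator)].mean(axis=1)
    return np.log2((num + 1e-3) / (den + 1e-3))
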