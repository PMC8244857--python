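import numpy as np
import pandas as pd
import pytest

import tissuelens as tl
from tissuelens.containers import CLASS_CANCER, CLASS_NORMAL


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 300 genes, 3 tissues, 20 tumours per cancer."""
    return tl.SyntheticConfig(
        n_genes=300, n_tissues=3, samples_per_cancer=20, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return tl.generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the package's reference study conditions."""
    return tl.generate_cohort(tl.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_stats(default_cohort):
    normal, cancer, design, surv, truth = default_cohort
    pairing = tl.pairing_from_design(design)
    cm = tl.compute_group_means(cancer)
    nm = tl.compute_group_means(normal)
    return {
        "pairing": pairing,
        "cancer_means": cm,
        "normal_means": nm,
        "c_star": tl.compute_specificity(cm, CLASS_CANCER),
        "n_star": tl.compute_specificity(nm, CLASS_NORMAL),
        "rel": tl.compute_relative_expression(cm, nm, pairing),
    }


def make_expression(values: np.ndarray, groups: list[str], classes: list[str],
                    paired: list[str] | None = None) -> tl.ExpressionMatrix:
    """Build an ExpressionMatrix from an array and per-sample metadata."""
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    design = pd.DataFrame(
        {
            "sample": samples,
            "group": groups,
            "class": classes,
            "paired_group": paired or [""] * n_samples,
        }
    )
    return tl.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), design
    )
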