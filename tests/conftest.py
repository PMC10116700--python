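import numpy as np
import pandas as pd
import pytest

import seedcomp as sc
from seedcomp.core import SEED_STAGES, TISSUES, sample_name


def matrix_from_means(means_by_genotype, unit="FPKM", n_replicates=3,
                      noise_sd=0.0, seed=0):
    """Build an ExpressionMatrix from {genotype: DataFrame features x tissues}.

    Replicates are mean * 2**N(0, noise_sd^2), exactly the generator's noise
    model; noise_sd=0 gives replicates equal to the mean.
    """
    rng = np.random.default_rng(seed)
    cols, data = [], []
    first = next(iter(means_by_genotype.values()))
    for genotype, means in means_by_genotype.items():
        for tissue in means.columns:
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd, size=len(means))
                cols.append(sample_name(genotype, tissue, rep))
                data.append(means[tissue].to_numpy() * np.exp2(noise))
    frame = pd.DataFrame(np.column_stack(data), index=first.index,
                         columns=cols)
    return sc.ExpressionMatrix(frame, unit)


def flat_means(levels: dict, tissues=TISSUES) -> pd.DataFrame:
    """features x tissues frame with one constant level per feature."""
    return pd.DataFrame({t: pd.Series(levels) for t in tissues})


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across tests."""
    return sc.generate_dataset(sc.SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_gene_det(default_dataset):
    return sc.call_degs(default_dataset.genes)


@pytest.fixture(scope="session")
def default_mirna_det(default_dataset):
    return sc.call_degs(default_dataset.mirnas,
                        thresholds=sc.MIRNA_THRESHOLDS)
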