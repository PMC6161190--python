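import numpy as np
import pytest

from psdnet.quantify import AbundanceTensor
from psdnet.simulate import SimConfig


def make_tensor(values, peptides=None, regions=None, replicates=None):
    """Build a small AbundanceTensor from a (P, R, B) nested list/array."""
    arr = np.asarray(values, dtype=float)
    P, R, B = arr.shape
    return AbundanceTensor(
        intensities=arr,
        proteins=[f"P{i+1}" for i in range(P)],
        regions=regions or [f"R{i+1}" for i in range(R)],
        replicates=replicates or [f"b{i+1}" for i in range(B)],
        n_unique_peptides=np.asarray(peptides if peptides is not None else [3] * P),
    )


@pytest.fixture
def clean_config():
    """Small noiseless config with no confounding effects: planted DE only."""
    return SimConfig(
        n_proteins=60,
        n_regions=4,
        n_replicates=3,
        n_modules=3,
        frac_de=0.3,
        effect_fold=2.0,
        noise_cv=0.0,
        module_effect_sd=0.0,
        frac_coupled=0.0,
        frac_single_peptide=0.0,
        frac_unstable=0.0,
        seed=11,
    )


@pytest.fixture
def small_config():
    """Small noisy config with module structure, for structural tests."""
    return SimConfig(
        n_proteins=80,
        n_regions=5,
        n_replicates=4,
        n_modules=4,
        frac_de=0.2,
        noise_cv=0.1,
        module_effect_sd=0.5,
        frac_coupled=0.1,
        n_terms=15,
        seed=5,
    )
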