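import numpy as np
import pytest

from basestack import synthetic_data as syn


@pytest.fixture(scope="session")
def gre():
    """Ideal unmethylated GRE duplex (15 bp)."""
    return syn.build_bdna(syn.GRE, structure_id="GRE")


@pytest.fixture(scope="session")
def smgre():
    """Side-methylated GRE duplex, ideal fiber geometry (no slide)."""
    return syn.build_bdna(syn.SMGRE, crick_methylations=syn.SMGRE_CRICK_MC,
                          structure_id="smGRE")


@pytest.fixture(scope="session")
def smgre_slid():
    """Side-methylated GRE with the documented methylation-coupled slide."""
    overrides = syn.methylation_slide_steps(syn.SMGRE, syn.SMGRE_CRICK_MC)
    return syn.build_bdna(syn.SMGRE, step_params=overrides,
                          crick_methylations=syn.SMGRE_CRICK_MC,
                          structure_id="smGRE-slid")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
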