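import numpy as np
import pytest

from hcymr import datasets, harmonize
from hcymr.summary_data import HarmonizedDataset, SNPAssociation


@pytest.fixture(scope="session")
def exposure():
    return datasets.load_exposure()


@pytest.fixture(scope="session")
def nafld_ds(exposure):
    return harmonize(exposure, datasets.load_outcome("NAFLD"), outcome_label="NAFLD")


@pytest.fixture(scope="session")
def nash_ds(exposure):
    return harmonize(exposure, datasets.load_outcome("NASH"), outcome_label="NASH")


@pytest.fixture(scope="session")
def cirrhosis_ds(exposure):
    return harmonize(exposure, datasets.load_outcome("Cirrhosis"), outcome_label="Cirrhosis")


@pytest.fixture
def toy_ds():
    """Small hand-built dataset with unequal weights, J=4."""
    return HarmonizedDataset(
        snps=["rs1", "rs2", "rs3", "rs4"],
        beta_exposure=np.array([0.10, 0.08, -0.05, 0.12]),
        se_exposure=np.array([0.01, 0.01, 0.008, 0.012]),
        beta_outcome=np.array([0.02, 0.03, -0.01, 0.05]),
        se_outcome=np.array([0.04, 0.05, 0.04, 0.06]),
    )


def make_assoc(rsid, beta=0.05, se=0.01, pvalue=1e-9, ea="A", oa="G", **kw):
    return SNPAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se, pvalue=pvalue, **kw
    )
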