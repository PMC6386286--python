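import numpy as np
import pandas as pd
import pytest

from twinmr import HarmonizedMRData, build_doc_model
from twinmr.pipeline import DEMO_PHENOTYPES, demo_truth_spec


@pytest.fixture
def doc_model():
    return build_doc_model(DEMO_PHENOTYPES["metabolites"],
                           DEMO_PHENOTYPES["lipids"],
                           DEMO_PHENOTYPES["bmd"])


@pytest.fixture
def truth_spec():
    return demo_truth_spec()


def make_harmonized(bx, by, se_x=0.01, se_y=0.01) -> HarmonizedMRData:
    """Harmonized MR data straight from effect arrays (test shortcut)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    n = bx.size
    se_x = np.broadcast_to(np.asarray(se_x, dtype=float), (n,))
    se_y = np.broadcast_to(np.asarray(se_y, dtype=float), (n,))
    return HarmonizedMRData(pd.DataFrame({
        "SNP": [f"rs{i + 1:04d}" for i in range(n)],
        "effect_allele": "A", "other_allele": "G",
        "eaf_exposure": 0.3, "eaf_outcome": 0.3,
        "beta_exposure": bx, "se_exposure": se_x,
        "beta_outcome": by, "se_outcome": se_y,
    }))
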