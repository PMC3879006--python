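import numpy as np
import pandas as pd
import pytest

import mrewas as m


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort (n=50) with its latent confounder."""
    cohort, u = m.gen_cohort(m.CohortSpec(seed=42))
    return cohort, u


@pytest.fixture(scope="session")
def strong_cohort():
    """n=50 cohort with a deliberately strong first stage, for
    calibration and power checks."""
    cohort, u = m.gen_cohort(
        m.CohortSpec(n=50, alpha1=0.6, sigma_x=0.15, seed=7))
    return cohort, u


@pytest.fixture()
def fixture_panel_100():
    """100-probe panel with 10 sex-chromosome, 5 cross-reactive and 3
    missing-value probes (disjoint), over the default cohort."""
    cohort, u = m.gen_cohort(m.CohortSpec(seed=1))
    ann, miss = m.gen_probe_panel(100, 0.10, 0.05, 0.03, seed=1)
    profile = m.EffectProfile.null(100, beta0=0.8, sigma_y=0.05)
    panel = m.gen_methylation(cohort, u, profile, ann, seed=1,
                              missing_probes=miss)
    return panel


def transformed_matrix(panel):
    return pd.DataFrame(m.transform_beta(panel.betas.to_numpy()),
                        index=panel.betas.index,
                        columns=panel.betas.columns)
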