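import numpy as np
import pandas as pd
import pytest

from methburden import synthdata as sd


@pytest.fixture(scope="session")
def default_cohort():
    """Medium synthetic cohort with the study's sample-size design."""
    return sd.generate_cohort(sd.CohortConfig(n_probes=5000, seed=42))


@pytest.fixture(scope="session")
def pair_resources(default_cohort):
    c = default_cohort
    return sd.generate_pair_tables(c.truth, c.annotation, c.betas, c.samples,
                                   sd.PairConfig(seed=2))


def toy_dmp(probes, p, delta, stratum="female"):
    return pd.DataFrame(
        dict(stratum=stratum, family="autosomal+all",
             delta_beta=np.asarray(delta, float),
             moderated_t=np.zeros(len(probes)),
             p=np.asarray(p, float), adj_p=np.nan,
             se=np.ones(len(probes))),
        index=pd.Index(probes, name="probe_id"))
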