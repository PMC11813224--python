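import pytest

from abtrim import KineticParams, default_graph

WT_Q = {
    "Aβ49→Aβ46": 0.9,
    "Aβ46→Aβ43": 0.6,
    "Aβ43→Aβ40": 0.7,
    "Aβ48→Aβ45": 0.8,
    "Aβ45→Aβ42": 0.5,
    "Aβ42→Aβ38": 0.2,
}


@pytest.fixture(scope="session")
def graph():
    return default_graph()


@pytest.fixture()
def wt_params():
    return KineticParams(
        kcat=2.0,
        enzyme_conc=30.0,
        time=16.0,
        branch_p49=0.5,
        continue_prob=dict(WT_Q),
        noise_cv=0.1,
        n_replicates=4,
        seed=20,
    )
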