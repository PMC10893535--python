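import pytest

import cleavemap as cm


@pytest.fixture(scope="session")
def study_run():
    """One full study-condition simulation plus pipeline call (seed 7)."""
    substrates, reads = cm.simulate_study(seed=7)
    result = cm.call(reads, substrates)
    return substrates, reads, result


@pytest.fixture(scope="session")
def clean_run():
    """A noise-free run (no background breaks, no read errors, full ligation)
    sized down for speed; used for exact-recovery oracles."""
    model = cm.DigestionModel(
        background_break_rate=0.0, read_error_rate=0.0, n_molecules=500
    )
    substrates, reads = cm.simulate_study(
        seed=11, model=model, n_reads=10_000, ligation_prob=1.0
    )
    result = cm.call(reads, substrates)
    return substrates, reads, result


@pytest.fixture()
def toy_substrate():
    return cm.Substrate(
        id="toy",
        sequence="GGGCC" + "UACAUA" + "CCGGGAGCUCAGGAUCC",
        planted_sites=(6,),
    )
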