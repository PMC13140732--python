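import pytest
from hypothesis import HealthCheck, settings

from pepgen import PeptideRecord
from pepgen.lstm import PeptideLSTM

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

VMP3 = "ARFLEVWQRTYCKA"
QK = "KLTWQELYQLKYKGI"


@pytest.fixture(scope="session")
def vmp3():
    return VMP3


@pytest.fixture(scope="session")
def qk():
    return QK


@pytest.fixture
def tiny_corpus():
    """Six hand-picked, mutually dissimilar short peptides."""
    seqs = [
        "ARNDKWYA", "LLEQMKTS", "WFHCPGIV", "KYEDRNTM",
        "QSAVLWFC", "MHGTPYRE",
    ]
    return [PeptideRecord(id=f"p{i}", sequence=s) for i, s in enumerate(seqs)]


@pytest.fixture(scope="session")
def memorizing_estimator():
    """An LSTM trained for 200 epochs on one peptide repeated 32x."""
    est = PeptideLSTM(epochs=200, holdout_fraction=0.0, seed=1)
    est.fit(["ARNDKWYA"] * 32)
    return est
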