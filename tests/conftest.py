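import pytest

from coreceptor import hydro
from coreceptor.seqann import ProteinRecord, segment_domains


@pytest.fixture(scope="session")
def fold_bands():
    return hydro.load_fold_bands()


@pytest.fixture()
def toy_record():
    """Minimal canonical AUX/IAA-like sequence: KR at 3-4, degron at 9-18,
    VKV (PB1 start) at 24."""
    return ProteinRecord(id="toy", sequence="MAKRAAAAVGWPPVRSIRAAAAAVKVDD")


@pytest.fixture()
def toy_annotation(toy_record):
    return segment_domains(toy_record)
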