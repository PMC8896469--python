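import pytest

from memds.refmodel import ArtifactClassPolicy, hbb_roi, hbd_roi


@pytest.fixture(scope="session")
def hbb():
    return hbb_roi()


@pytest.fixture(scope="session")
def hbd():
    return hbd_roi()


@pytest.fixture(scope="session")
def rois(hbb, hbd):
    return {"HBB": hbb, "HBD": hbd}


@pytest.fixture(scope="session")
def policy():
    return ArtifactClassPolicy()


def make_read(insert, primary="A" * 14, id1="AACC", secondary="CCCCC", id2="AACC",
              read_id="r0", qual_char="I"):
    """Assemble a merged-read record with the standard layout."""
    seq = primary + id1 + insert + secondary + id2
    return (read_id, seq, qual_char * len(seq))
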