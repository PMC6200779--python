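import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pqsurvey import ScanParams


@pytest.fixture
def default_params():
    return ScanParams()


@pytest.fixture
def write_text(tmp_path):
    def _write(name: str, content: str) -> Path:
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write


GFF3_HEADER = "##gff-version 3\n"


@pytest.fixture
def simple_gff3(write_text):
    """Three genes: two stranded, one unstranded (skipped on extraction)."""
    body = (
        GFF3_HEADER
        + "c1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        + "c1\tsrc\tgene\t301\t400\t.\t-\t.\tID=g2\n"
        + "c1\tsrc\tgene\t501\t600\t.\t.\t.\tID=g3\n"
    )
    return write_text("simple.gff3", body)
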