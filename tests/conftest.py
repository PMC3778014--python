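import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_fasta(tmp_path):
    p = tmp_path / "g.fasta"
    p.write_text(">s1\nACGTACGTAC\n>s2\nGGGGCCCC\n")
    return p


@pytest.fixture
def tiny_gff(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(
        "##gff-version 3\n"
        "s1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
        "s1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        "s1\tsrc\texon\t1\t50\t.\t+\t.\tID=g1.t1.e1;Parent=g1.t1\n"
        "s1\tsrc\texon\t61\t100\t.\t+\t.\tID=g1.t1.e2;Parent=g1.t1\n"
    )
    return p
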