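import shutil

import pytest

from pgxkit import load_knowledge_base, load_packaged_kb
from pgxkit.kb import packaged_kb_path


@pytest.fixture(scope="session")
def kb():
    """The packaged knowledge base."""
    return load_packaged_kb()


@pytest.fixture(scope="session")
def kb_dir_copy(tmp_path_factory):
    """A writable copy of the packaged KB directory."""
    dest = tmp_path_factory.mktemp("kbcopy") / "kb"
    shutil.copytree(packaged_kb_path(), dest)
    return dest


@pytest.fixture(scope="session")
def kb_with_cis(tmp_path_factory):
    """Packaged KB extended with a synthetic cis haplotype allele carrying
    both the *2- and *17-defining variants on one chromosome (such alleles
    are reported in cohorts but not printed with definitions; this one is a
    synthetic test construct)."""
    dest = tmp_path_factory.mktemp("kbcis") / "kb"
    shutil.copytree(packaged_kb_path(), dest)
    with open(dest / "alleles.tsv", "a") as fh:
        fh.write("CYP2C19\t*2+*17\tunknown\t\t\n")
    with open(dest / "allele_variants.tsv", "a") as fh:
        fh.write("CYP2C19\t*2+*17\trsV2\tA\n")
        fh.write("CYP2C19\t*2+*17\trsV17\tT\n")
    return load_knowledge_base(dest)
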