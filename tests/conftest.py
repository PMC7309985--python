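import numpy as np
import pytest

from cichlidsv.core import GenomicInterval, SVClass, SVRecord
from cichlidsv.dollo import PhyloTree

RADIATION_TREE = ("(((Mzebra:1.0,Pnyererei:1.0):2.0,Hburtoni:3.0):3.0,"
                  "Nbrichardi:6.0):4.0;")


@pytest.fixture
def tree() -> PhyloTree:
    return PhyloTree.from_newick(RADIATION_TREE)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_record(start, end, sv_class=SVClass.DEL, species="Mzebra",
                caller="delly", rid=None, contig="lg1", n_read_pairs=10,
                n_libraries=3, score=None, **kw) -> SVRecord:
    rid = rid or f"{caller}_{contig}_{start}_{end}"
    return SVRecord(
        interval=GenomicInterval(contig, start, end), sv_class=sv_class,
        species=species, caller=caller, record_id=rid,
        n_libraries=n_libraries, n_read_pairs=n_read_pairs, score=score, **kw)
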