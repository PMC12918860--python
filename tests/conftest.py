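import numpy as np
import pytest

from somamotif.genome import Reference
from somamotif.catalogue_io import MutationRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_reference():
    """Deterministic 600 bp two-contig reference with known motif content."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    seqs = {
        "chr1": "".join(rng.choice(bases, size=400)),
        "chr2": "".join(rng.choice(bases, size=200)),
    }
    return Reference(seqs)


def make_snv(chrom="chr1", pos=100, ref="C", alt="T", af=0.5,
             sample_id="S1", donor_id="D1", **kw):
    return MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, af=af,
                          sample_id=sample_id, donor_id=donor_id, **kw)
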