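import numpy as np
import pytest

from cpgnet import seqdata


@pytest.fixture
def tiny_genome() -> seqdata.GenomeSequence:
    """A 40 bp contig with CG dinucleotides at known positions (8, 20, 30)."""
    seq = "AATTGGCCCG" + "ATATATATAT" + "CGTTAACCGG" + "ACGTACGTAC"
    g = seqdata.GenomeSequence(name="chrT", residues=seq)
    assert g.residues[8:10] == "CG" and g.residues[20:22] == "CG"
    return g


@pytest.fixture
def balanced_sites() -> list[seqdata.CpGSite]:
    rng = np.random.default_rng(42)
    sites = []
    for i in range(60):
        beta = float(rng.uniform(60, 100)) if i % 2 else float(rng.uniform(0, 40))
        sites.append(seqdata.CpGSite(chrom="chrT", pos=100 + 10 * i, beta=beta))
    return sites
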