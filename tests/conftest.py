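import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from repseq.synthetic_data import get_reference
from repseq.umi_pipeline import ClonotypeTable, SampleId, TABLE_COLUMNS

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return get_reference()


def make_table(counts, chain="alpha", donor="D01", visit=1,
               subset="CD4_naive", cdr3s=None):
    """Build a small clonotype table from clone → UMI-count mapping."""
    ref = get_reference()
    v_names = ref.v_names(chain)
    j_names = ref.j_names(chain)
    rows = []
    # fixed sense-codon vocabulary keeps junctions translatable
    codons = ["TGT", "GCA", "AGT", "CTT", "GAA", "CAA", "TAT", "TTT",
              "GGT", "CAT", "ATT", "AAA"]
    for i, n in enumerate(counts):
        if cdr3s is not None:
            nt = cdr3s[i]
        else:
            picks = [codons[(i // len(codons) ** k) % len(codons)]
                     for k in range(4)]
            nt = "".join(picks)
        from Bio.Seq import Seq
        aa = str(Seq(nt).translate())
        # V/J follow the CDR3 content so identical junctions share a key
        # across tables
        h = sum(ord(c) for c in nt)
        rows.append((chain, v_names[h % len(v_names)],
                     j_names[h % len(j_names)], nt, aa, int(n)))
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return ClonotypeTable(SampleId(donor, visit, subset, chain), df)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
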