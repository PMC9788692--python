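import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from varmotif.io import MotifAlignment
from varmotif.synth import default_profile, generate_motif_pair

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

TOY_STOCKHOLM = """\
# STOCKHOLM 1.0
#=GF ID toy
#=GS seq1 GENE PRK07324
#=GS seq1 PHYLUM Firmicutes
#=GS seq1 ENV gut
#=GS seq2 GENE COG2076
#=GS seq2 ENV non_gut
#=GS seq3 DE some free text
seq1         GGAAUC
seq2         GGA-UC
seq3         GG--UC
#=GC SS_cons <<..>>
//
"""


@pytest.fixture
def toy_stockholm(tmp_path):
    path = tmp_path / "toy.sto"
    path.write_text(TOY_STOCKHOLM)
    return path


def make_alignment(rows, ss, name="test", metadata=None):
    """Build a MotifAlignment from (id, seq) pairs or bare sequences."""
    if rows and isinstance(rows[0], str):
        rows = [(f"s{i}", seq) for i, seq in enumerate(rows, start=1)]
    ids = [r[0] for r in rows]
    seqs = [r[1] for r in rows]
    return MotifAlignment(name, ids, seqs, ss, metadata or {})


@pytest.fixture
def make_aln():
    return make_alignment


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def motif_pair(profile):
    """One seeded pair of synthetic motif alignments plus its truth record."""
    return generate_motif_pair(profile, 200, 200, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
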