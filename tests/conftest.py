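import numpy as np
import pandas as pd
import pytest

from clonoshift.repertoire import Repertoire


def rep_from_freqs(
    freqs,
    vj=None,
    cdr3=None,
    counts=None,
    productive=None,
    sample_id="test",
    chain="TRB",
    **kwargs,
):
    """Build a small repertoire directly from a frequency vector."""
    freqs = np.asarray(freqs, dtype=float)
    n = len(freqs)
    if cdr3 is None:
        cdr3 = [f"CASS{i:04d}F" for i in range(n)]
    if vj is None:
        vj = [(f"TRBV{i + 1}", f"TRBJ{i % 3 + 1}") for i in range(n)]
    clones = pd.DataFrame(
        {
            "cdr3_aa": cdr3,
            "cdr3_nt": "",
            "v_gene": [v for v, _ in vj],
            "j_gene": [j for _, j in vj],
            "count": counts if counts is not None else np.nan,
            "frequency": freqs,
            "productive": productive if productive is not None else True,
        }
    )
    return Repertoire(
        sample_id=sample_id, chain=chain, clones=clones, **kwargs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230824)


def random_frequency_vector(rng, n=None, max_n=50):
    """Random normalized frequency vector for brute-force comparisons."""
    if n is None:
        n = int(rng.integers(1, max_n + 1))
    w = rng.exponential(size=n) + 1e-9
    return w / w.sum()
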