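"""Per-repertoire diversity and clonal-expansion statistics.

Clonality is the normalized Shannon entropy complement

    clonality = 1 - H / log2(n),    H = -sum_i f_i log2 f_i

with f_i the clone frequencies and n the number of unique clones: 0 for a
perfectly even repertoire, 1 for a monoclonal one.  Entropy is in bits
throughout this module (the divergence module uses nats; the two bases are
deliberately not unified).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .repertoire import Repertoire, _sorted_clones

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-6


@dataclass
class DiversitySummary:
    sample_id: str
    n_clones: int
    shannon_entropy_bits: float
    clonality: float
    top_k_cumfreq: float
    expanded_cumfreq: float


def shannon_entropy(rep: Repertoire) -> float:
    """Shannon entropy of the clone-frequency distribution, in bits.

    Zero-frequency clones contribute nothing.  Raises :class:`DataError` when
    frequencies do not sum to 1 (within 1e-6).
    """
    rep.check_normalized(_NORM_TOL)
    f = rep.frequencies
    f = f[f > 0]
    return float(-(f * np.log2(f)).sum())


def clonality(rep: Repertoire) -> float:
    """Normalized clonality in [0, 1].

    A single-clone repertoire has an undefined normalizer (log2 1 = 0); it is
    returned as 1.0, the monoclonal limit, with a warning.
    """
    n = rep.n_clones
    if n == 1:
        logger.warning(
            "sample %s: single-clone repertoire, clonality set to 1.0",
            rep.sample_id,
        )
        return 1.0
    value = 1.0 - shannon_entropy(rep) / np.log2(n)
    # clamp away float dust at the boundaries
    return float(min(1.0, max(0.0, value)))


def cumulative_top_frequency(rep: Repertoire, k: int = 10) -> float:
    """Summed frequency of the k most frequent clones (all clones if k > n)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ordered = _sorted_clones(rep.clones)
    return float(ordered["frequency"].head(k).sum())


def expanded_clone_frequency(rep: Repertoire, threshold: float = 0.01) -> float:
    """Summed frequency of clones strictly above ``threshold`` (default 1%)."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    f = rep.frequencies
    return float(f[f > threshold].sum())


def diversity_summary(
    rep: Repertoire, top_k: int = 10, expanded_threshold: float = 0.01
) -> DiversitySummary:
    """All per-sample statistics in one record."""
    return DiversitySummary(
        sample_id=rep.sample_id,
        n_clones=rep.n_clones,
        shannon_entropy_bits=shannon_entropy(rep),
        clonality=clonality(rep),
        top_k_cumfreq=cumulative_top_frequency(rep, top_k),
        expanded_cumfreq=expanded_clone_frequency(rep, expanded_threshold),
    )
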