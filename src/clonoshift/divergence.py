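"""Paired pre/post repertoire divergence and its clonality decomposition.

Two flavors of Jensen-Shannon divergence (JSD, natural log, bounded by ln 2)
between a mouse's pre- and post-treatment repertoires:

* ``jsd_vj``   -- over the VJ-gene-pair usage distribution (frequency
  weighted), sensitive to *which* receptors carry the mass;
* ``jsd_rank`` -- over the rank-frequency vector of the top-N clones with
  clone identity discarded, sensitive only to the *shape* of the clone-size
  distribution, i.e. to clonality.

Regressing the VJ divergence of the top-N subsets on the rank divergence
attributes repertoire turnover to clonal re-weighting (R^2 near 1) versus
recruitment of new VJ usage (R^2 drops).

The rank construction aligns both repertoires rank-to-rank after truncation
to the same ``n_top``; when one repertoire has fewer clones its missing
ranks are zero-probability categories.  This is one reasonable construction
of a rank-based divergence, chosen here for determinism and symmetry, and is
documented as this package's own convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, StatsError
from .repertoire import Repertoire, top_n_subset

LN2 = float(np.log(2.0))

_NORM_TOL = 1e-6


@dataclass
class CategoricalDistribution:
    """Probability vector over labelled categories (VJ pairs or ranks)."""

    categories: list
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.categories) != len(self.probabilities):
            raise DataError("categories and probabilities differ in length")
        if (self.probabilities < -1e-12).any():
            raise DataError("negative probability")
        total = float(self.probabilities.sum())
        if abs(total - 1.0) > 1e-6:
            raise DataError(f"probabilities sum to {total:.6g}, not 1")

    def as_mapping(self) -> dict:
        return dict(zip(self.categories, self.probabilities))


@dataclass
class DivergenceResult:
    mouse_id: str
    chain: str
    jsd_vj: float
    jsd_rank: float
    jsd_vj_top: float
    n_top: int | None


def vj_distribution(rep: Repertoire) -> CategoricalDistribution:
    """Frequency-weighted usage distribution over (V gene, J gene) pairs.

    Each pair's probability is the summed frequency of its clones, so an
    expanding clone moves usage mass with it.
    """
    clones = rep.clones
    bad = clones["v_gene"].isin(["", "nan"]) | clones["j_gene"].isin(["", "nan"])
    if bad.any():
        offenders = clones.loc[bad, "cdr3_aa"].tolist()[:10]
        raise DataError(f"missing V/J gene calls for clones {offenders}")
    grouped = (
        clones.assign(vj=clones["v_gene"] + "|" + clones["j_gene"])
        .groupby("vj", sort=True)["frequency"]
        .sum()
    )
    probs = grouped.to_numpy(dtype=float)
    total = probs.sum()
    if total <= 0:
        raise DataError(f"sample {rep.sample_id!r}: zero total frequency")
    return CategoricalDistribution(list(grouped.index), probs / total)


def rank_distribution(rep: Repertoire, n_top: int = 700) -> CategoricalDistribution:
    """Renormalized frequencies of the top ``n_top`` clones, indexed by rank.

    Clone identity is discarded: two repertoires with identical sorted
    frequency vectors are indistinguishable here by construction.  700 keeps
    down-sampling minimal for deep bulk repertoires while equalizing support.
    """
    sub = top_n_subset(rep, n_top, renormalize=True)
    return CategoricalDistribution(
        list(range(1, sub.n_clones + 1)), sub.frequencies
    )


def kullback_leibler(p: np.ndarray, q: np.ndarray) -> float:
    """KL divergence sum_i p_i ln(p_i/q_i) in nats; p_i = 0 terms vanish."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / q[mask])).sum())


def jensen_shannon_divergence(
    p: CategoricalDistribution, q: CategoricalDistribution
) -> float:
    """JSD(P||Q) = KLD(P||M)/2 + KLD(Q||M)/2 with M the midpoint, in nats.

    The two distributions are aligned on the union of their categories
    (absent category -> probability 0).  Bounded by ln 2, zero iff P = Q.
    """
    cats = sorted(set(p.categories) | set(q.categories), key=str)
    pm = p.as_mapping()
    qm = q.as_mapping()
    pv = np.array([pm.get(c, 0.0) for c in cats])
    qv = np.array([qm.get(c, 0.0) for c in cats])
    for name, v in (("P", pv), ("Q", qv)):
        if abs(v.sum() - 1.0) > _NORM_TOL:
            raise DataError(f"{name} is not normalized (sum {v.sum():.6g})")
    m = (pv + qv) / 2.0
    return 0.5 * kullback_leibler(pv, m) + 0.5 * kullback_leibler(qv, m)


def paired_divergence(
    pre: Repertoire, post: Repertoire, n_top: int = 700
) -> DivergenceResult:
    """Divergence between a mouse's paired pre- and post-treatment repertoires.

    Returns the full-repertoire VJ divergence, the rank divergence on the
    top-``n_top`` clones, and the VJ divergence restricted to those same
    top-``n_top`` subsets (the quantity regressed on the rank divergence in
    the decomposition).
    """
    if pre.chain != post.chain:
        raise DataError(
            f"chain mismatch: {pre.sample_id} is {pre.chain}, "
            f"{post.sample_id} is {post.chain}"
        )
    jsd_vj = jensen_shannon_divergence(vj_distribution(pre), vj_distribution(post))
    jsd_rank = jensen_shannon_divergence(
        rank_distribution(pre, n_top), rank_distribution(post, n_top)
    )
    jsd_vj_top = jensen_shannon_divergence(
        vj_distribution(top_n_subset(pre, n_top)),
        vj_distribution(top_n_subset(post, n_top)),
    )
    return DivergenceResult(
        mouse_id=pre.sample_id,
        chain=pre.chain,
        jsd_vj=jsd_vj,
        jsd_rank=jsd_rank,
        jsd_vj_top=jsd_vj_top,
        n_top=n_top,
    )


def variance_explained(x, y) -> tuple[float, float, float, float]:
    """Ordinary least squares of y on x.

    Returns ``(r_squared, p_value, slope, intercept)``; the p-value is the
    two-sided test of zero slope (equivalent to the model F-test for simple
    regression).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise StatsError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise StatsError("zero variance in x: regression undefined")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.pvalue), float(fit.slope), float(
        fit.intercept
    )
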