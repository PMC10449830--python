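"""Gene-signature construction, enrichment scoring, and composition tests.

A cluster signature is the set of genes that (i) are upregulated in a
single-cell cluster (log2 fold change above a threshold at adjusted
p < 0.01) AND (ii) rise in treated bulk tumors (fold change above a second
threshold at adjusted p < 0.01); the single-cell log2 fold changes become
per-gene weights.  A sample's enrichment score is then

    ES = sum_i GE_i * log2FC_i / n

the weighted mean of its log-scale expression over the n signature genes
present in the matrix.

The module also houses the Fisher-exact composition-enrichment test used to
compare cell-subset proportions between treatment groups, and the group
balancer that equalizes per-group cell numbers before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, StatsError

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "log2fc", "adj_p"]


@dataclass(frozen=True)
class GeneSignature:
    """Gene -> log2 fold-change weight mapping with provenance label."""

    name: str
    weights: dict

    def __post_init__(self) -> None:
        if len(self.weights) < 1:
            raise DataError(f"signature {self.name!r} is empty")
        bad = [g for g, w in self.weights.items() if not np.isfinite(w)]
        if bad:
            raise DataError(f"signature {self.name!r}: non-finite weights {bad[:5]}")

    @property
    def n(self) -> int:
        return len(self.weights)

    @property
    def genes(self) -> list:
        return list(self.weights)


def _check_de_table(de: pd.DataFrame, which: str) -> None:
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise DataError(f"{which} DE table missing columns {missing}")
    if de["gene"].duplicated().any():
        raise DataError(f"{which} DE table has duplicate gene symbols")


def build_cluster_signature(
    de_sc: pd.DataFrame,
    de_bulk: pd.DataFrame,
    name: str = "cluster",
    sc_log2fc_min: float = 0.5,
    p_max: float = 0.01,
    bulk_fc_min: float = 1.3,
    pct_min: float | None = None,
) -> GeneSignature:
    """Intersect single-cell and bulk differential-expression filters.

    A gene enters the signature iff it passes BOTH:

    * single-cell: ``log2fc > sc_log2fc_min`` and ``adj_p < p_max``
      (optionally also ``pct > pct_min``, the fraction of cluster cells
      expressing it);
    * bulk: fold change ``2**log2fc > bulk_fc_min`` and ``adj_p < p_max``,
      up in treated tumors.

    Weights are the single-cell log2 fold changes.  Raises
    :class:`DataError` with filter attrition counts when nothing survives.
    """
    _check_de_table(de_sc, "single-cell")
    _check_de_table(de_bulk, "bulk")
    sc_pass = (de_sc["log2fc"] > sc_log2fc_min) & (de_sc["adj_p"] < p_max)
    if pct_min is not None:
        if "pct" not in de_sc.columns:
            raise DataError("pct_min given but single-cell table has no 'pct'")
        sc_pass &= de_sc["pct"] > pct_min
    sc_genes = set(de_sc.loc[sc_pass, "gene"])
    bulk_pass = (2.0 ** de_bulk["log2fc"] > bulk_fc_min) & (
        de_bulk["adj_p"] < p_max
    )
    bulk_genes = set(de_bulk.loc[bulk_pass, "gene"])
    kept = sc_genes & bulk_genes
    if not kept:
        raise DataError(
            f"signature {name!r} is empty: {len(sc_genes)} genes passed the "
            f"single-cell filter, {len(bulk_genes)} the bulk filter, 0 both"
        )
    weights = dict(
        de_sc.set_index("gene").loc[sorted(kept), "log2fc"].items()
    )
    return GeneSignature(name=name, weights=weights)


def combined_signature(sigs: list, name: str) -> GeneSignature:
    """Union of signatures; a gene shared between clusters keeps its largest
    |log2fc| weight."""
    if len(sigs) < 2:
        raise ValueError("need at least 2 signatures to combine")
    weights: dict = {}
    for sig in sigs:
        for gene, w in sig.weights.items():
            if gene not in weights or abs(w) > abs(weights[gene]):
                weights[gene] = w
    return GeneSignature(name=name, weights=weights)


def enrichment_score(
    expr: pd.DataFrame, sig: GeneSignature, sample
) -> float:
    """Weighted-mean enrichment score of one sample (column of ``expr``).

    ``expr`` is a genes x samples table of log-scale expression.  Signature
    genes absent from the matrix are dropped and n reduced accordingly (the
    drop count is logged); with zero genes present this is a
    :class:`DataError`.
    """
    present = [g for g in sig.genes if g in expr.index]
    if not present:
        raise DataError(
            f"signature {sig.name!r}: none of {sig.n} genes present in matrix"
        )
    if len(present) < sig.n:
        logger.info(
            "signature %s: %d of %d genes absent from matrix",
            sig.name,
            sig.n - len(present),
            sig.n,
        )
    ge = expr.loc[present, sample].to_numpy(dtype=float)
    w = np.array([sig.weights[g] for g in present])
    return float((ge * w).sum() / len(present))


def enrichment_scores(expr: pd.DataFrame, sig: GeneSignature) -> pd.Series:
    """Enrichment score of every sample, as a Series indexed like columns."""
    return pd.Series(
        {s: enrichment_score(expr, sig, s) for s in expr.columns},
        name=sig.name,
    )


def scale_scores(scores, ddof: int = 1) -> np.ndarray:
    """Z-scores (mean 0, sd 1; sample sd by default) for model covariates."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise StatsError("need at least 2 samples to scale")
    sd = scores.std(ddof=ddof)
    if sd == 0:
        raise StatsError("zero variance: scores cannot be scaled")
    return (scores - scores.mean()) / sd


def load_cdc1_signature() -> list:
    """The packaged 21-gene anti-CD40 activated cDC1 gene list."""
    text = (
        resources.files("clonoshift.data")
        .joinpath("cdc1_cd40_signature.txt")
        .read_text()
    )
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def signature_mean_score(
    expr: pd.DataFrame, gene_list: list, groups: pd.Series
) -> tuple[pd.Series, float, float]:
    """Unweighted arithmetic-mean score plus a two-group Welch t-test.

    Used for fixed external gene lists (the cDC1 activation signature):
    per-sample mean of log-scale expression over the genes present, compared
    between the two groups in ``groups`` with a two-sided Welch t-test.

    Returns ``(per_sample_means, t_statistic, p_value)``.
    """
    present = [g for g in gene_list if g in expr.index]
    if not present:
        raise DataError("no signature genes present in matrix")
    means = expr.loc[present].mean(axis=0)
    groups = pd.Series(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise StatsError(f"need exactly 2 groups, got {list(labels)}")
    a = means[groups[groups == labels[0]].index]
    b = means[groups[groups == labels[1]].index]
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs at least 2 samples for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return means, float(t), float(p)


@dataclass
class CompositionTest:
    """Fisher-exact enrichment of one cell subset in treated vs reference."""

    label: str
    table: np.ndarray
    odds_ratio: float
    p: float
    q: float
    significant: bool


def _sample_odds_ratio(table: np.ndarray) -> float:
    """Cross-product odds ratio with Haldane-Anscombe 0.5 correction applied
    only when a zero cell would make it degenerate."""
    a, b, c, d = table.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def composition_enrichment(
    tables: dict, alpha: float = 0.05, or_min: float = 1.5
) -> list:
    """Fisher exact test per 2x2 table with family-wise BH-FDR adjustment.

    ``tables`` maps subset label -> 2x2 counts laid out as
    ``[[in-subset treated, in-subset reference],
    [out-of-subset treated, out-of-subset reference]]``.

    A subset is significant when its BH-adjusted p is below ``alpha`` AND
    the odds ratio shows at least ``or_min``-fold enrichment or (reciprocal)
    depletion, i.e. OR > or_min or OR < 1/or_min.  An odds ratio is never
    negative, so depletion is the reciprocal bound.
    """
    if not tables:
        return []
    labels, arrays, pvals, ors = [], [], [], []
    for label, table in tables.items():
        arr = np.asarray(table, dtype=int)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise DataError(f"{label}: need a nonnegative 2x2 table")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise DataError(f"{label}: zero margin in contingency table")
        _, p = stats.fisher_exact(arr, alternative="two-sided")
        labels.append(label)
        arrays.append(arr)
        pvals.append(float(p))
        ors.append(_sample_odds_ratio(arr))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for label, arr, orr, p, q in zip(labels, arrays, ors, pvals, qvals):
        sig = (q < alpha) and (orr > or_min or orr < 1.0 / or_min)
        out.append(
            CompositionTest(
                label=label,
                table=arr,
                odds_ratio=float(orr),
                p=p,
                q=float(q),
                significant=bool(sig),
            )
        )
    return out


def balance_group_sizes(
    group_sizes: dict, per_group="min", strict: bool = False
) -> tuple[dict, int]:
    """Equal per-group cell retention before pooled analyses.

    ``per_group="min"`` keeps the smallest group's size from every group
    (the design that avoids abundance bias in pooled clustering); an integer
    keeps ``min(requested, available)`` per group, or errors in strict mode
    when a group cannot supply the request.

    Returns ``(per-group retained counts, total retained)``.
    """
    if not group_sizes:
        raise DataError("no groups supplied")
    if any(n < 1 for n in group_sizes.values()):
        raise DataError("all group sizes must be >= 1")
    if per_group == "min":
        target = min(group_sizes.values())
    else:
        target = int(per_group)
        if target < 1:
            raise ValueError("per_group must be >= 1")
    retained = {}
    for group, n in group_sizes.items():
        if target > n:
            if strict:
                raise DataError(
                    f"group {group!r}: requested {target} of {n} cells"
                )
            logger.warning(
                "group %s: requested %d of %d cells; keeping all", group, target, n
            )
        retained[group] = min(target, n)
    return retained, sum(retained.values())


def sample_balanced_cells(
    cell_groups: pd.Series, per_group="min", seed: int = 0
) -> pd.Index:
    """Seeded without-replacement draw realizing :func:`balance_group_sizes`.

    ``cell_groups`` maps cell identifier (index) -> group label; returns the
    retained cell identifiers.
    """
    cell_groups = pd.Series(cell_groups)
    sizes = cell_groups.value_counts().to_dict()
    retained, _ = balance_group_sizes(sizes, per_group=per_group)
    rng = np.random.default_rng(seed)
    keep = []
    for group, n_keep in retained.items():
        members = cell_groups.index[cell_groups == group].to_numpy()
        keep.extend(rng.choice(members, size=n_keep, replace=False))
    return pd.Index(keep)
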