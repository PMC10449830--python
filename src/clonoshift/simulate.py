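"""Synthetic inputs with known ground truth for every pipeline stage.

Generators for: power-law TCR repertoires with VJ usage and planted
antigen-signature clones; treatment effects (clonal expansion and/or
VJ-biased recruitment) with multinomial resequencing; log-scale expression
studies with planted signature genes; proportional-hazards survival
cohorts; and tumor-growth trajectories of each response archetype.

Every generator is a pure function of (config, seed).  They emulate the
statistical structure of the real measurements (heavy-tailed clone sizes,
read-sampling noise, Gaussian expression noise, exponential survival with
independent censoring) but none of the underlying biology: no V(D)J
recombination model, no thymic selection, no antigen-affinity dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .antigen import TCRSignature
from .errors import ConfigError
from .repertoire import CLONE_COLUMNS, Repertoire
from .response import GrowthSeries
from .scoring import GeneSignature
from .survival import SurvivalRecord

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_cdr3(rng: np.random.Generator, taken: set) -> str:
    """Random 9-17-mer amino-acid string, collision-checked against ``taken``."""
    while True:
        k = int(rng.integers(9, 18))
        seq = "C" + "".join(rng.choice(_AA, size=k - 2)) + "F"
        if seq not in taken:
            taken.add(seq)
            return seq


def make_tcr_signature(
    n: int = 50, seed: int = 0, name: str = "AH1-like"
) -> TCRSignature:
    """A toy antigen signature of ``n`` unique CDR3B sequences."""
    rng = np.random.default_rng(seed)
    taken: set = set()
    return TCRSignature(
        name, frozenset(_random_cdr3(rng, taken) for _ in range(n))
    )


@dataclass(frozen=True)
class VJPools:
    """V and J gene label sets with usage probabilities."""

    v_labels: tuple
    v_probs: tuple
    j_labels: tuple
    j_probs: tuple

    def __post_init__(self) -> None:
        for labels, probs in ((self.v_labels, self.v_probs),
                              (self.j_labels, self.j_probs)):
            if len(labels) != len(probs):
                raise ConfigError("labels/probabilities length mismatch")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError("usage probabilities must sum to 1")


def default_vj_pools(n_v: int = 20, n_j: int = 12, decay: float = 0.15) -> VJPools:
    """Geometric-decay usage over TRBV1..n_v and TRBJ1..n_j (uneven usage is
    the norm in real repertoires)."""
    vw = np.exp(-decay * np.arange(n_v))
    jw = np.exp(-decay * np.arange(n_j))
    return VJPools(
        v_labels=tuple(f"TRBV{i + 1}" for i in range(n_v)),
        v_probs=tuple(vw / vw.sum()),
        j_labels=tuple(f"TRBJ{i + 1}" for i in range(n_j)),
        j_probs=tuple(jw / jw.sum()),
    )


def shifted_vj_pools(pools: VJPools, shift: int = 5) -> VJPools:
    """Rotate usage probabilities over the labels: same genes, displaced
    preference, for modelling VJ-biased recruitment."""
    return VJPools(
        v_labels=pools.v_labels,
        v_probs=tuple(np.roll(pools.v_probs, shift)),
        j_labels=pools.j_labels,
        j_probs=tuple(np.roll(pools.j_probs, shift)),
    )


def concentrated_vj_pools(
    pools: VJPools, rng: np.random.Generator, n_v: int = 2, n_j: int = 2
) -> VJPools:
    """Restrict usage to a random handful of V and J genes.

    Models an antigen-focused recruitment wave: the incoming clones share a
    few rearrangement families, so their VJ footprint is narrow and
    mouse-specific.
    """
    v_idx = rng.choice(len(pools.v_labels), size=n_v, replace=False)
    j_idx = rng.choice(len(pools.j_labels), size=n_j, replace=False)
    v_probs = np.zeros(len(pools.v_labels))
    j_probs = np.zeros(len(pools.j_labels))
    v_probs[v_idx] = rng.dirichlet(np.ones(n_v))
    j_probs[j_idx] = rng.dirichlet(np.ones(n_j))
    return VJPools(
        v_labels=pools.v_labels,
        v_probs=tuple(v_probs),
        j_labels=pools.j_labels,
        j_probs=tuple(j_probs),
    )


@dataclass(frozen=True)
class RepertoireSimConfig:
    """Repertoire generator settings.

    ``frequency_law`` is ``"power_law"`` (i.i.d. Pareto clone weights with
    tail index ``alpha``; 1.5 gives realistically heavy-tailed clone sizes)
    or ``"dirichlet"`` (symmetric concentration ``conc``; large values give
    near-even repertoires).  ``signature_clones`` clones drawn from
    ``signature`` are planted with total frequency ``signature_mass``.
    ``sequencing_depth`` multinomially resamples reads (None keeps exact
    frequencies).
    """

    n_clones: int = 1000
    frequency_law: str = "power_law"
    alpha: float = 1.5
    conc: float = 1.0
    vj_pools: VJPools = field(default_factory=default_vj_pools)
    signature: TCRSignature | None = None
    signature_clones: int = 0
    signature_mass: float = 0.0
    sequencing_depth: int | None = 100_000
    chain: str = "TRB"

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ConfigError("n_clones must be >= 1")
        if not 0.0 <= self.signature_mass < 1.0:
            raise ConfigError("signature_mass must be in [0, 1)")
        if self.signature_clones > 0:
            if self.signature is None:
                raise ConfigError("signature_clones > 0 needs a signature")
            if self.signature_clones > len(self.signature):
                raise ConfigError("signature has too few sequences")
            if self.signature_clones > self.n_clones:
                raise ConfigError("more signature clones than clones")
            if self.signature_mass <= 0:
                raise ConfigError("planted clones need signature_mass > 0")
        if self.frequency_law not in ("power_law", "dirichlet"):
            raise ConfigError(f"unknown frequency law {self.frequency_law!r}")


def _base_weights(cfg: RepertoireSimConfig, n: int, rng) -> np.ndarray:
    if cfg.frequency_law == "power_law":
        w = 1.0 + rng.pareto(cfg.alpha, size=n)
    else:
        w = rng.dirichlet(np.full(n, cfg.conc))
    return w / w.sum()


def simulate_repertoire(
    cfg: RepertoireSimConfig, seed: int, sample_id: str = "sim"
) -> Repertoire:
    """Draw one repertoire from ``cfg``; pure function of (cfg, seed)."""
    rng = np.random.default_rng(seed)
    n_bg = cfg.n_clones - cfg.signature_clones
    freqs = _base_weights(cfg, n_bg, rng) * (1.0 - cfg.signature_mass)
    taken: set = set(cfg.signature.cdr3b_sequences) if cfg.signature else set()
    cdr3 = [_random_cdr3(rng, taken) for _ in range(n_bg)]
    if cfg.signature_clones:
        sig_seqs = rng.choice(
            sorted(cfg.signature.cdr3b_sequences),
            size=cfg.signature_clones,
            replace=False,
        )
        sig_w = 1.0 + rng.pareto(cfg.alpha, size=cfg.signature_clones)
        sig_freqs = sig_w / sig_w.sum() * cfg.signature_mass
        freqs = np.concatenate([freqs, sig_freqs])
        cdr3 = cdr3 + list(sig_seqs)
    n = len(freqs)
    v = rng.choice(cfg.vj_pools.v_labels, size=n, p=cfg.vj_pools.v_probs)
    j = rng.choice(cfg.vj_pools.j_labels, size=n, p=cfg.vj_pools.j_probs)
    clones = pd.DataFrame(
        {
            "cdr3_aa": cdr3,
            "cdr3_nt": "",
            "v_gene": v,
            "j_gene": j,
            "count": np.nan,
            "frequency": freqs,
            "productive": True,
        }
    )
    rep = Repertoire(sample_id=sample_id, chain=cfg.chain, clones=clones)
    if cfg.sequencing_depth is not None:
        rep = resample_reads(rep, cfg.sequencing_depth, rng)
    return rep


def resample_reads(
    rep: Repertoire, depth: int, rng: np.random.Generator
) -> Repertoire:
    """Multinomial read sampling at the given depth; unseen clones drop out.

    This is what makes a 2e-5 frequency floor meaningful: at depth 1e5 it
    corresponds to clones seen in at most two reads.
    """
    counts = rng.multinomial(depth, rep.frequencies / rep.frequencies.sum())
    clones = rep.clones.copy()
    clones["count"] = counts
    clones = clones[clones["count"] > 0].reset_index(drop=True)
    clones["frequency"] = clones["count"] / depth
    return replace(rep, clones=clones)


@dataclass(frozen=True)
class TreatmentEffectConfig:
    """Post-treatment transformation of a pre-treatment repertoire.

    Two clonality-only mechanisms (both preserve clone identity): a power
    tilt ``f_i -> f_i ** tilt_exponent`` that sharpens the whole frequency
    distribution (exponent > 1), and multiplicative expansion of a random
    clone fraction.  Independently, ``recruit_n`` novel clones are added;
    recruits draw VJ pairs from ``recruit_vj_bias`` when given (shifting
    usage, hence VJ divergence) or from the pre-treatment repertoire's own
    empirical VJ usage otherwise, and carry ``recruit_mass_scale`` times
    the pre-treatment mean per-clone mass.
    """

    tilt_exponent: float = 1.0
    expansion_fraction: float = 0.0
    expansion_factor: float = 1.0
    recruit_n: int = 0
    recruit_vj_bias: VJPools | None = None
    recruit_alpha: float = 1.5
    recruit_mass_scale: float = 1.0
    sequencing_depth: int | None = 100_000

    def __post_init__(self) -> None:
        if self.tilt_exponent < 1.0:
            raise ConfigError("tilt_exponent must be >= 1")
        if not 0.0 <= self.expansion_fraction <= 1.0:
            raise ConfigError("expansion_fraction must be in [0, 1]")
        if self.expansion_factor < 1.0:
            raise ConfigError("expansion_factor must be >= 1")
        if self.recruit_n < 0:
            raise ConfigError("recruit_n must be >= 0")
        if self.recruit_mass_scale <= 0:
            raise ConfigError("recruit_mass_scale must be > 0")


def apply_treatment_effect(
    pre: Repertoire, cfg: TreatmentEffectConfig, seed: int
) -> Repertoire:
    """Derive a post-treatment repertoire from ``pre`` under ``cfg``."""
    rng = np.random.default_rng(seed)
    clones = pre.clones.copy().reset_index(drop=True)
    freqs = clones["frequency"].to_numpy(dtype=float).copy()
    n = len(freqs)
    if cfg.tilt_exponent > 1.0:
        freqs = freqs**cfg.tilt_exponent
        freqs /= freqs.sum()
    n_exp = int(round(cfg.expansion_fraction * n))
    if n_exp > 0 and cfg.expansion_factor > 1.0:
        idx = rng.choice(n, size=n_exp, replace=False)
        freqs[idx] *= cfg.expansion_factor
    clones["frequency"] = freqs
    if cfg.recruit_n > 0:
        taken = set(clones["cdr3_aa"])
        new_cdr3 = [_random_cdr3(rng, taken) for _ in range(cfg.recruit_n)]
        w = 1.0 + rng.pareto(cfg.recruit_alpha, size=cfg.recruit_n)
        # recruits carry recruit_mass_scale times the mean per-clone mass of
        # the pre-treatment repertoire
        new_freqs = (
            w / w.sum()
            * (freqs.sum() * cfg.recruit_n / n)
            * cfg.recruit_mass_scale
        )
        if cfg.recruit_vj_bias is not None:
            pools = cfg.recruit_vj_bias
            new_v = rng.choice(pools.v_labels, size=cfg.recruit_n, p=pools.v_probs)
            new_j = rng.choice(pools.j_labels, size=cfg.recruit_n, p=pools.j_probs)
        else:
            donor = rng.choice(n, size=cfg.recruit_n, p=freqs / freqs.sum())
            new_v = clones["v_gene"].to_numpy()[donor]
            new_j = clones["j_gene"].to_numpy()[donor]
        recruits = pd.DataFrame(
            {
                "cdr3_aa": new_cdr3,
                "cdr3_nt": "",
                "v_gene": new_v,
                "j_gene": new_j,
                "count": np.nan,
                "frequency": new_freqs,
                "productive": True,
            }
        )
        clones = pd.concat([clones, recruits], ignore_index=True)[CLONE_COLUMNS]
    post = Repertoire(
        sample_id=pre.sample_id,
        chain=pre.chain,
        clones=clones,
        tissue=pre.tissue,
        timepoint="post",
    ).normalized()
    if cfg.sequencing_depth is not None:
        post = resample_reads(post, cfg.sequencing_depth, rng)
    return post


def simulate_paired_cohort(
    n_mice: int = 24,
    n_clones: int = 2000,
    sequencing_depth: int = 100_000,
    recruit_fraction: float = 0.0,
    seed: int = 0,
) -> list:
    """Paired pre/post repertoires for a cohort of simulated mice.

    Each mouse gets its own pre-treatment repertoire and a clonality-only
    treatment effect of mouse-specific strength: a power tilt with exponent
    U(1.02, 1.35), spreading divergences over a usable dynamic range while
    keeping clone identities fixed.  With ``recruit_fraction > 0``, that
    fraction of the clone count is additionally recruited as novel clones
    concentrated in a mouse-specific handful of VJ pairs, with per-mouse
    recruited mass (log-uniform over 0.3-3x the mean clone mass) -- VJ
    turnover that rank-based divergence is largely blind to.

    Returns a list of ``(pre, post)`` pairs.
    """
    rng = np.random.default_rng(seed)
    pools = default_vj_pools()
    pairs = []
    for m in range(n_mice):
        cfg = RepertoireSimConfig(
            n_clones=n_clones,
            vj_pools=pools,
            sequencing_depth=sequencing_depth,
        )
        pre = simulate_repertoire(
            cfg, seed=int(rng.integers(2**31)), sample_id=f"mouse{m:02d}"
        )
        bias = None
        recruit_n = 0
        mass_scale = 1.0
        if recruit_fraction > 0:
            recruit_n = int(round(recruit_fraction * n_clones))
            bias = concentrated_vj_pools(pools, rng)
            mass_scale = float(
                np.exp(rng.uniform(np.log(0.3), np.log(3.0)))
            )
        effect = TreatmentEffectConfig(
            tilt_exponent=float(rng.uniform(1.02, 1.35)),
            recruit_n=recruit_n,
            recruit_vj_bias=bias,
            recruit_mass_scale=mass_scale,
            sequencing_depth=sequencing_depth,
        )
        post = apply_treatment_effect(pre, effect, seed=int(rng.integers(2**31)))
        pairs.append((pre, post))
    return pairs


def make_expression_signature(
    n_genes: int = 30, seed: int = 0, name: str = "planted"
) -> GeneSignature:
    """A planted gene signature with log2FC weights in [0.6, 2.5]."""
    rng = np.random.default_rng(seed)
    weights = {
        f"SIG{i:03d}": float(rng.uniform(0.6, 2.5)) for i in range(n_genes)
    }
    return GeneSignature(name=name, weights=weights)


@dataclass
class ExpressionStudy:
    """Simulated two-group expression study with consistent DE tables.

    ``expr``: genes x samples log2-scale expression; ``groups``: sample ->
    "treated"/"control"; ``de_bulk``: per-gene log2FC / Welch p / BH
    adjusted p computed from ``expr`` itself; ``de_sc``: a single-cell-style
    DE table in which the planted genes carry their true weights (strong
    cluster markers) and background genes are null.
    """

    expr: pd.DataFrame
    groups: pd.Series
    de_bulk: pd.DataFrame
    de_sc: pd.DataFrame
    signature: GeneSignature


def simulate_expression_study(
    signature: GeneSignature,
    n_per_group: int = 20,
    effect_scale: float = 1.0,
    noise_sd: float = 0.1,
    n_background: int = 200,
    seed: int = 0,
) -> ExpressionStudy:
    """Two-group log-scale expression with signature genes shifted in the
    treated group by ``effect_scale * weight``; Gaussian noise throughout."""
    rng = np.random.default_rng(seed)
    genes = signature.genes + [f"BG{i:04d}" for i in range(n_background)]
    n_genes = len(genes)
    baseline = rng.uniform(4.0, 10.0, size=n_genes)
    samples = [f"T{i:02d}" for i in range(n_per_group)] + [
        f"C{i:02d}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["treated"] * n_per_group + ["control"] * n_per_group, index=samples
    )
    shift = np.zeros(n_genes)
    shift[: signature.n] = effect_scale * np.array(
        [signature.weights[g] for g in signature.genes]
    )
    data = np.empty((n_genes, 2 * n_per_group))
    for col, sample in enumerate(samples):
        mu = baseline + (shift if groups[sample] == "treated" else 0.0)
        data[:, col] = mu + rng.normal(0.0, noise_sd, size=n_genes)
    expr = pd.DataFrame(data, index=genes, columns=samples)

    treated = expr.loc[:, groups == "treated"]
    control = expr.loc[:, groups == "control"]
    log2fc = treated.mean(axis=1) - control.mean(axis=1)
    _, pvals = stats.ttest_ind(treated, control, axis=1, equal_var=False)
    _, adj_p, _, _ = multipletests(pvals, method="fdr_bh")
    de_bulk = pd.DataFrame(
        {"gene": genes, "log2fc": log2fc.values, "adj_p": adj_p}
    )
    sc_rows = []
    for gene in genes:
        if gene in signature.weights:
            sc_rows.append(
                (gene, signature.weights[gene], 1e-6, float(rng.uniform(0.7, 0.99)))
            )
        else:
            sc_rows.append(
                (
                    gene,
                    float(rng.normal(0.0, 0.1)),
                    float(rng.uniform(0.2, 1.0)),
                    float(rng.uniform(0.05, 0.5)),
                )
            )
    de_sc = pd.DataFrame(sc_rows, columns=["gene", "log2fc", "adj_p", "pct"])
    return ExpressionStudy(
        expr=expr, groups=groups, de_bulk=de_bulk, de_sc=de_sc,
        signature=signature,
    )


def simulate_survival_cohort(
    scores,
    log_hr: float,
    baseline_rate: float = 0.01,
    censor_rate: float = 0.005,
    seed: int = 0,
    covariate_corr: float = 0.0,
) -> list:
    """Proportional-hazards cohort: T_i ~ Exp(rate = baseline * exp(b*s_i)).

    Independent exponential censoring at ``censor_rate``; covariates (age,
    numeric stage, scaled CD3E) are drawn with optional correlation
    ``covariate_corr`` between CD3E and the score but have no effect on the
    hazard, so the score coefficient is the only true signal.
    """
    if baseline_rate <= 0 or censor_rate < 0:
        raise ConfigError("rates must be positive (censor_rate may be 0)")
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(scores)
    rate = baseline_rate * np.exp(log_hr * scores)
    event_t = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_t = np.full(n, np.inf)
    time = np.minimum(event_t, censor_t)
    event = event_t <= censor_t
    age = rng.normal(60.0, 10.0, size=n)
    stage = rng.integers(1, 5, size=n)
    cd3e = covariate_corr * scores + math.sqrt(
        max(0.0, 1.0 - covariate_corr**2)
    ) * rng.normal(size=n)
    return [
        SurvivalRecord(
            sample_id=f"P{i:04d}",
            time=float(time[i]),
            event=bool(event[i]),
            covariates={
                "score": float(scores[i]),
                "age": float(age[i]),
                "stage": int(stage[i]),
                "cd3e": float(cd3e[i]),
            },
        )
        for i in range(n)
    ]


# RTV archetypes over 8 post-randomization timepoints; chosen with margin so
# that multiplicative jitter up to ~20% cannot change the category.
_GROWTH_ARCHETYPES = {
    "PD": [1.0, 1.2, 1.5, 1.8, 2.2, 2.6, 3.0, 3.5],
    "SD": [1.0, 0.95, 0.9, 0.85, 0.9, 0.95, 1.0, 1.05],
    "PR": [1.0, 0.8, 0.5, 0.3, 0.35, 0.5, 0.7, 0.9],
    "CR": [1.0, 0.6, 0.3, 0.0, 0.0, 0.1, 0.3, 0.5],
    "MCR": [1.0, 0.7, 0.4, 0.2, 0.1, 0.0, 0.0, 0.0],
}

# jitter clamps guaranteeing the archetype's category survives noise
_GROWTH_CLAMPS = {
    "PD": lambda r, end: max(r, 1.35) if end else max(r, 0.55),
    "SD": lambda r, end: min(max(r, 0.55), 1.2),
    "PR": lambda r, end: min(max(r, 0.02), 1.2),
    "CR": lambda r, end: max(r, 0.05) if end else r,
    "MCR": lambda r, end: r,
}


def simulate_growth_series(
    category: str,
    seed: int,
    jitter: float = 0.05,
    ref_day: int = 11,
    ref_volume: float = 65.0,
    measure_every: int = 3,
    animal_id: str | None = None,
) -> GrowthSeries:
    """A tumor-volume trajectory whose true response class is ``category``.

    With ``jitter=0`` the canonical archetype is returned exactly; positive
    jitter perturbs each nonzero RTV multiplicatively and then clamps it so
    the requested category is preserved by construction.
    """
    if category not in _GROWTH_ARCHETYPES:
        raise ConfigError(
            f"unknown category {category!r}; known: {sorted(_GROWTH_ARCHETYPES)}"
        )
    rng = np.random.default_rng(seed)
    rtv = np.array(_GROWTH_ARCHETYPES[category], dtype=float)
    clamp = _GROWTH_CLAMPS[category]
    last = len(rtv) - 1
    for i in range(1, len(rtv)):
        if rtv[i] == 0.0:
            continue
        noisy = rtv[i] * (1.0 + rng.uniform(-jitter, jitter))
        rtv[i] = clamp(noisy, i == last)
    days = ref_day + measure_every * np.arange(len(rtv))
    return GrowthSeries(
        animal_id=animal_id or f"{category}-{seed}",
        days=days,
        volumes=rtv * ref_volume,
        ref_day=ref_day,
    )
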