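"""Survival association of enrichment scores.

Two complementary analyses, mirroring common clinical-cohort practice:

* median split of the scores into "low"/"high" followed by a two-group
  log-rank test (implemented directly from the risk table so it can be
  oracle-checked);
* multivariable Cox proportional-hazards regression of the scaled score
  plus clinical covariates (delegated to lifelines, Efron tie handling),
  e.g. age, menopausal state, Nottingham Prognostic Index and scaled CD3E
  expression for a breast-cancer cohort, or age, numeric AJCC stage and
  scaled CD3E for a melanoma cohort.

Records with missing covariates are dropped (complete-case analysis, with
the exclusion count logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .errors import DataError, StatsError

logger = logging.getLogger(__name__)


@dataclass
class SurvivalRecord:
    """One subject: follow-up time (months), death indicator, covariates.

    Subjects alive at last follow-up, or dead of unrelated causes, carry
    ``event=False`` (censored).
    """

    sample_id: str
    time: float
    event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataError(f"{self.sample_id}: negative follow-up time")


def records_to_frame(records: list) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "time": r.time, "event": bool(r.event)}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def median_split(scores) -> np.ndarray:
    """Label each sample "high" (score > median) or "low" (score <= median).

    Ties at the median go to "low"; an all-equal vector is all "low" with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise StatsError("need at least 2 samples to split")
    med = float(np.median(scores))
    labels = np.where(scores > med, "high", "low")
    if (labels == "low").all():
        logger.warning("median split degenerate: all scores <= median")
    return labels


def logrank_test(records: list, groups) -> tuple[float, float]:
    """Two-group log-rank test from the observed-minus-expected risk table.

    At each distinct event time t, with n_g subjects at risk and d_g events
    in group g, group 1's expected events are d * n1 / n and the
    hypergeometric variance is d (n1/n)(n2/n)(n-d)/(n-1).  The statistic
    (O1 - E1)^2 / V is chi-square with 1 df under the null.

    Returns ``(chi_square, p)``.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=bool)
    if len(time) != len(groups):
        raise ValueError("records and groups differ in length")
    if not event.any():
        raise StatsError("no events: log-rank test undefined")
    is1 = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & is1).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & is1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxCoefficient:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float


def cox_model(
    records: list,
    covariate_names: list,
    score_name: str | None = None,
) -> dict:
    """Multivariable Cox proportional-hazards fit (Efron ties, Wald CIs).

    ``covariate_names`` selects the adjustment covariates; ``score_name``
    (if given) is the enrichment score of interest and is appended.  Returns
    a mapping covariate -> :class:`CoxCoefficient`.
    """
    use = list(covariate_names)
    if score_name is not None and score_name not in use:
        use.append(score_name)
    frame = records_to_frame(records)
    missing_cols = [c for c in use if c not in frame.columns]
    if missing_cols:
        raise DataError(f"covariates absent from records: {missing_cols}")
    data = frame[["time", "event"] + use].apply(pd.to_numeric)
    complete = data.dropna()
    if len(complete) < len(data):
        logger.info(
            "complete-case analysis: dropped %d of %d records with missing "
            "covariates",
            len(data) - len(complete),
            len(data),
        )
    n_events = int(complete["event"].sum())
    if n_events < len(use) + 1:
        raise StatsError(
            f"{n_events} events for {len(use)} covariates: model underdetermined"
        )
    fitter = CoxPHFitter()
    try:
        fitter.fit(complete, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        raise StatsError(f"Cox fit failed: {exc}") from exc
    out = {}
    summary = fitter.summary
    for cov in use:
        row = summary.loc[cov]
        out[cov] = CoxCoefficient(
            covariate=cov,
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(np.exp(row["coef lower 95%"])),
            ci_high=float(np.exp(row["coef upper 95%"])),
            p=float(row["p"]),
            coef=float(row["coef"]),
            se=float(row["se(coef)"]),
        )
    return out


#: AJCC pathologic stage -> ordinal severity, as used for melanoma cohorts
AJCC_NUMERIC = {
    "I": 1, "IA": 1, "IB": 1,
    "II": 2, "IIA": 2, "IIB": 2, "IIC": 2,
    "III": 3, "IIIA": 3, "IIIB": 3, "IIIC": 3,
    "IV": 4,
}


def ajcc_to_numeric(stage: str) -> int:
    """Map an AJCC stage label (I..IV with letter substages) to 1..4."""
    key = str(stage).strip().upper().removeprefix("STAGE").strip()
    if key not in AJCC_NUMERIC:
        raise DataError(f"unknown AJCC stage label {stage!r}")
    return AJCC_NUMERIC[key]
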