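"""Signature risk score and survival stratification.

A patient's risk score is the mean copy-number level (log2 ratio) over the
signature genes, each gene summarized by the mean of its supporting blocks.
The cohort median splits patients into groups; because the signature tracks
copy-number LOSS in recurrence, scores at or below the median are the
high-risk group.  Prognostic value is assessed with the Kaplan–Meier
product-limit estimator, the two-group log-rank test, and Cox proportional
hazards (Efron tie handling), including the multivariate model adjusting
for age (cutoff 60), stage (II vs III/IV) and gender (M vs F, reference F).

Kaplan–Meier, log-rank and Cox fits are delegated to lifelines; this module
owns the scoring, dichotomization, covariate encodings, and an exact
label-permutation alternative for the log-rank p at small n.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "RiskResult",
    "CoxConvergenceError",
    "risk_score",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "table3_covariates",
    "stratify",
    "apply_signature_external",
]

HIGH, LOW = "high_risk", "low_risk"


class CoxConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (e.g. monotone likelihood)."""


@dataclass
class RiskResult:
    """Per-patient risk stratification plus cohort-level survival statistics."""

    scores: pd.Series
    groups: pd.Series  # values HIGH / LOW
    threshold: float
    km: dict  # group -> DataFrame(time, survival, at_risk)
    logrank_chi2: float
    logrank_p: float
    cox_univariate: Optional[pd.DataFrame] = None
    cox_multivariate: Optional[pd.DataFrame] = None

    def to_json(self, path) -> None:
        payload = {
            "threshold": self.threshold,
            "scores": {k: float(v) for k, v in self.scores.items()},
            "groups": dict(self.groups),
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "km": {g: df.to_dict("list") for g, df in self.km.items()},
        }
        for name in ("cox_univariate", "cox_multivariate"):
            df = getattr(self, name)
            payload[name] = None if df is None else df.reset_index().to_dict("list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def risk_score(block_matrix: pd.DataFrame, sig) -> pd.Series:
    """Mean log2 copy-number level over signature genes, per patient.

    Each gene is first summarized as the mean of its supporting blocks
    (missing block values ignored); the score is the mean over genes.  A
    gene with no supporting block present in the matrix is dropped with a
    warning when at least two genes remain, otherwise it is an error.
    """
    if len(sig.genes) == 0:
        raise ValueError("signature is empty")
    per_gene = {}
    dropped = []
    for row in sig.genes.itertuples():
        present = [b for b in row.supporting_blocks if b in block_matrix.index]
        if not present:
            dropped.append(row.symbol)
            continue
        per_gene[row.symbol] = block_matrix.loc[present].mean(axis=0)
    if dropped:
        if len(per_gene) < 2:
            raise ValueError(f"too few signature genes with data (dropped {dropped})")
        warnings.warn(f"signature genes without supporting blocks dropped: {dropped}")
    scores = pd.DataFrame(per_gene).mean(axis=1)
    scores.name = "risk_score"
    return scores


def dichotomize(scores: pd.Series, tie_policy: str = "high") -> tuple:
    """Split patients at the median score; returns ``(groups, threshold)``.

    Loss implies risk, so scores at or below the median are high-risk
    (``tie_policy='high'``, the default, sends exact-median scores to
    high-risk; ``'low'`` sends them to low-risk).  All-identical scores
    admit no split and raise.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 patients to dichotomize")
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical: no median split possible")
    med = float(np.median(scores.to_numpy()))
    if tie_policy == "high":
        high = scores <= med
    elif tie_policy == "low":
        high = scores < med
    else:
        raise ValueError("tie_policy must be 'high' or 'low'")
    groups = pd.Series(np.where(high, HIGH, LOW), index=scores.index, name="risk_group")
    return groups, med


def km_estimate(times, events, groups) -> dict:
    """Product-limit survival curve per group.

    Returns ``{group: DataFrame(time, survival, at_risk)}``; curves start
    at S(0)=1 and censored subjects shrink risk sets without steps.
    """
    times = pd.Series(np.asarray(times, dtype=float))
    events = pd.Series(np.asarray(events, dtype=bool))
    groups = pd.Series(np.asarray(groups))
    if len(times) == 0:
        raise ValueError("no patients")
    if (times < 0).any():
        raise ValueError("negative survival times")
    out = {}
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has no patients")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        out[str(g)] = pd.DataFrame(
            {"time": surv.index.to_numpy(float), "survival": surv.to_numpy(float),
             "at_risk": tab["at_risk"].reindex(surv.index).to_numpy(float)}
        )
    return out


def _logrank_chi2(times: np.ndarray, events: np.ndarray, in_g1: np.ndarray) -> float:
    """Standard two-group log-rank chi-square (hypergeometric variance)."""
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], in_g1[order]
    uniq = np.unique(t[e])
    obs_minus_exp = 0.0
    var = 0.0
    for tj in uniq:
        at_risk = t >= tj
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        d = (e & (t == tj)).sum()
        d1 = (e & (t == tj) & g).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(obs_minus_exp**2 / var)


def logrank_test(times, events, groups, p_method: str = "asymptotic") -> tuple:
    """Two-group log-rank test; returns ``(chi2, p)``.

    ``p_method='asymptotic'`` uses the 1-df chi-square reference
    (lifelines).  ``p_method='permutation'`` computes an exact
    label-permutation p by enumerating every assignment of patients to the
    two group sizes (small cohorts only), with the chi-square statistic as
    the permutation statistic.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 non-empty groups, got {list(labels)}")
    in_g1 = groups == labels[0]
    if p_method == "asymptotic":
        res = _ll_logrank(times[in_g1], times[~in_g1], events[in_g1], events[~in_g1])
        return float(res.test_statistic), float(res.p_value)
    if p_method != "permutation":
        raise ValueError("p_method must be 'asymptotic' or 'permutation'")
    n, n1 = len(times), int(in_g1.sum())
    from math import comb

    if comb(n, n1) > 500_000:
        raise ValueError("exact permutation log-rank is limited to small cohorts")
    observed = _logrank_chi2(times, events, in_g1)
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        stat = _logrank_chi2(times, events, mask)
        count += stat >= observed - 1e-12
        total += 1
    return observed, count / total


def cox_fit(covariates: pd.DataFrame, times, events, ties: str = "efron") -> pd.DataFrame:
    """Cox proportional-hazards fit; returns per-covariate HR, 95% CI, p.

    Maximum partial likelihood with Efron tie handling (Breslow available),
    Wald confidence intervals and p-values.  Constant covariates and
    non-convergence (including monotone likelihood from perfect separation)
    raise rather than returning silently wrong estimates.
    """
    covariates = pd.DataFrame(covariates).astype(float)
    constant = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates: {constant}")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=bool).astype(int)
    if df["_event"].sum() < 1:
        raise ValueError("no events observed")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event", show_progress=False)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise CoxConvergenceError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    out = pd.DataFrame(
        {
            "hazard_ratio": s["exp(coef)"],
            "ci95_low": s["exp(coef) lower 95%"],
            "ci95_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    out.index.name = "covariate"
    return out


def table3_covariates(clinical: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Multivariate-model design matrix: signature + age + stage + gender.

    Encodings: ``low_risk_signature`` 1 for the low-risk group (the
    signature's protective level); ``age_ge_60`` 1 for age >= 60;
    ``stage_ii`` 1 for TNM stage II vs III/IV; ``male`` 1 for M (F is the
    reference level).
    """
    cl = clinical.set_index("patient_id").loc[groups.index]
    stage = cl["stage"].astype(str).str.upper().str.strip()
    return pd.DataFrame(
        {
            "low_risk_signature": (groups == LOW).astype(int),
            "age_ge_60": (cl["age"] >= 60).astype(int),
            "stage_ii": (stage.str.startswith("II") & ~stage.str.startswith("III")).astype(int),
            "male": (cl["sex"] == "M").astype(int),
        },
        index=groups.index,
    )


def _survival_arrays(clinical: pd.DataFrame, patients, time_col: str, event_col: str):
    cl = clinical.set_index("patient_id")
    missing = [p for p in patients if p not in cl.index]
    if missing:
        raise ValueError(f"patients absent from clinical table: {missing[:5]}")
    sub = cl.loc[patients]
    if sub[time_col].isna().any() or sub[event_col].isna().any():
        raise ValueError(f"missing {time_col}/{event_col} for some patients")
    return sub[time_col].to_numpy(float), sub[event_col].to_numpy(bool)


def stratify(
    block_matrix: pd.DataFrame,
    sig,
    clinical: pd.DataFrame,
    time_col: str = "rfs_time",
    event_col: str = "rfs_event",
    tie_policy: str = "high",
    with_cox: bool = True,
) -> RiskResult:
    """Score, median-split, and evaluate survival for a cohort.

    Runs the full discovery-side evaluation: risk score per patient, median
    dichotomization, per-group Kaplan–Meier curves, log-rank test, and (with
    ``with_cox``) univariate Cox on the low-risk indicator plus the
    multivariate model with age/stage/gender.  Cox failures at desk-scale n
    degrade to ``None`` with a warning rather than aborting stratification.
    """
    scores = risk_score(block_matrix, sig)
    groups, threshold = dichotomize(scores, tie_policy=tie_policy)
    times, events = _survival_arrays(clinical, list(scores.index), time_col, event_col)
    km = km_estimate(times, events, groups.to_numpy())
    chi2, p = logrank_test(times, events, groups.to_numpy())
    uni = multi = None
    if with_cox:
        low = (groups == LOW).astype(int).to_frame("low_risk_signature")
        try:
            uni = cox_fit(low, times, events)
        except (CoxConvergenceError, ValueError) as exc:
            warnings.warn(f"univariate Cox unavailable: {exc}")
        try:
            design = table3_covariates(clinical, groups)
            design = design.loc[:, design.nunique() > 1]
            multi = cox_fit(design, times, events)
        except (CoxConvergenceError, ValueError) as exc:
            warnings.warn(f"multivariate Cox unavailable: {exc}")
    return RiskResult(
        scores=scores, groups=groups, threshold=threshold, km=km,
        logrank_chi2=chi2, logrank_p=p, cox_univariate=uni, cox_multivariate=multi,
    )


def apply_signature_external(
    matrix: pd.DataFrame,
    sig,
    clinical: pd.DataFrame,
    probes: pd.DataFrame = None,
    time_col: str = "rfs_time",
    event_col: str = "rfs_event",
    tie_policy: str = "high",
) -> RiskResult:
    """Apply a discovered signature to an external cohort.

    ``matrix`` may be gene-level (rows indexed by gene symbol) or
    probe-level (rows indexed by probe id, with ``probes`` annotation for
    interval-overlap matching).  Matching is by symbol first, interval
    overlap as fallback; fewer than two matchable signature genes is an
    error.  Scoring, dichotomization, KM and log-rank then follow the same
    path as discovery.
    """
    if len(sig.genes) == 0:
        raise ValueError("signature is empty")
    per_gene = {}
    for row in sig.genes.itertuples():
        support = [b for b in row.supporting_blocks if b in matrix.index]
        if support:
            # a block-level matrix (e.g. the discovery cohort itself):
            # reuse the discovery scoring path verbatim
            per_gene[row.symbol] = matrix.loc[support].mean(axis=0)
        elif row.symbol in matrix.index:
            per_gene[row.symbol] = matrix.loc[row.symbol]
        elif probes is not None:
            hit = probes[
                (probes["chromosome"] == row.chromosome)
                & (probes["start"] < row.end)
                & (probes["end"] > row.start)
            ]
            present = [p for p in hit["probe_id"] if p in matrix.index]
            if present:
                per_gene[row.symbol] = matrix.loc[present].mean(axis=0)
    if len(per_gene) < 2:
        raise ValueError(
            f"only {len(per_gene)} signature genes matchable in external matrix (need >= 2)"
        )
    scores = pd.DataFrame(per_gene).mean(axis=1)
    scores.name = "risk_score"
    groups, threshold = dichotomize(scores, tie_policy=tie_policy)
    times, events = _survival_arrays(clinical, list(scores.index), time_col, event_col)
    km = km_estimate(times, events, groups.to_numpy())
    chi2, p = logrank_test(times, events, groups.to_numpy())
    return RiskResult(scores=scores, groups=groups, threshold=threshold, km=km,
                      logrank_chi2=chi2, logrank_p=p)
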