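"""Endpoint and subgroup analyses for the trial.

Sign conventions, used consistently everywhere:

* ``d_glucose`` (the model outcome) is week-12 minus baseline fasting
  glucose; a negative treatment coefficient means BSE lowered glucose.
* ``improvement`` is baseline minus week-12 (positive = reduction); the two
  are exact negatives.

All models are ordinary least squares via statsmodels on the full analysis
set (completers — participants with clinical measures after randomization);
no imputation, and confidence intervals are not adjusted for multiple
comparisons (a Benjamini–Hochberg utility exists but is never applied
implicitly).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .datamodel import DomainError, TrialDataset
from .indices import homa_ir

log = logging.getLogger("bsetrial")

RESPONDER_THRESHOLD = 0.3   # mmol/l reduction, inclusive
REMISSION_GLUCOSE = 6.1     # mmol/l, strict <


@dataclass
class EffectEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    model_descriptor: str

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_value": self.p_value,
            "n": self.n_used, "model": self.model_descriptor,
        }


def _effect(res, term: str, descriptor: str) -> EffectEstimate:
    ci = res.conf_int().loc[term]
    return EffectEstimate(
        estimate=float(res.params[term]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_value=float(res.pvalues[term]),
        n_used=int(res.nobs), model_descriptor=descriptor,
    )


def _analysis_frame(dataset: TrialDataset) -> pd.DataFrame:
    """Completer rows with treatment indicator, glucose change, improvement,
    baseline BMI and HOMA-IR change."""
    df = dataset.completers().copy()
    if df["arm"].nunique() < 2:
        raise DomainError("both arms must be present")
    df["treat"] = (df["arm"] == "BSE").astype(int)
    df["d_glucose"] = df["week12_glucose"] - df["baseline_glucose"]
    df["improvement"] = -df["d_glucose"]
    if {"baseline_insulin", "week12_insulin"} <= set(df.columns):
        df["d_homa_ir"] = (
            homa_ir(df["week12_glucose"], df["week12_insulin"])
            - homa_ir(df["baseline_glucose"], df["baseline_insulin"])
        )
        df["baseline_homa_ir"] = homa_ir(df["baseline_glucose"],
                                         df["baseline_insulin"])
    return df


def primary_endpoint_model(dataset: TrialDataset,
                           homa_covariate: str = "baseline") -> EffectEstimate:
    """Primary endpoint: glucose change on treatment, adjusted for baseline
    BMI and variation in HOMA-IR.

    ``homa_covariate='baseline'`` (default) adjusts for between-participant
    variation in baseline HOMA-IR, a pre-randomization covariate.
    ``'change'`` uses the week-12 − baseline HOMA-IR difference instead;
    note that the change in HOMA-IR contains the outcome glucose and acts as
    a post-treatment mediator, so it attenuates the treatment coefficient —
    it is offered as a sensitivity reading of the ambiguous wording, not as
    the default.
    """
    df = _analysis_frame(dataset)
    if (df.groupby("arm").size() < 2).any():
        raise DomainError("need >= 2 completers per arm")
    cov = {"change": "d_homa_ir", "baseline": "baseline_homa_ir"}[homa_covariate]
    formula = f"d_glucose ~ treat + baseline_bmi + {cov}"
    res = smf.ols(formula, data=df).fit()
    return _effect(res, "treat", formula)


def ancova_model(dataset: TrialDataset) -> EffectEstimate:
    """ANCOVA: week-12 glucose on baseline glucose and treatment."""
    df = _analysis_frame(dataset)
    formula = "week12_glucose ~ baseline_glucose + treat"
    res = smf.ols(formula, data=df).fit()
    return _effect(res, "treat", formula)


def interaction_model(dataset: TrialDataset, cluster_labels,
                      drop_single_arm_groups: bool = True) -> dict:
    """Treatment × subgroup interaction on glucose change.

    ``cluster_labels`` aligns with the dataset rows (by participant_id if a
    Series indexed by it, else positionally with the full table).  Returns
    ``{'interaction_p': joint Wald p, 'contrasts': {group: EffectEstimate}}``
    where each contrast is the within-group BSE-minus-placebo difference in
    glucose change.
    """
    df = dataset.table.copy()
    df["cluster"] = np.asarray(cluster_labels)
    df = df[df["completed"].astype(bool)].copy()
    df["treat"] = (df["arm"] == "BSE").astype(int)
    df["d_glucose"] = df["week12_glucose"] - df["baseline_glucose"]

    present = df.groupby("cluster")["arm"].nunique()
    bad = present[present < 2].index.tolist()
    if bad and drop_single_arm_groups:
        warnings.warn(f"dropping groups present in one arm only: {bad}")
        df = df[~df["cluster"].isin(bad)]
    groups = sorted(df["cluster"].unique())
    if len(groups) < 2:
        raise DomainError("need >= 2 groups present in both arms")

    formula = "d_glucose ~ treat * C(cluster)"
    res = smf.ols(formula, data=df).fit()
    inter_terms = [t for t in res.params.index if t.startswith("treat:")]
    joint = res.wald_test(", ".join(f"{t} = 0" for t in inter_terms), scalar=True)
    contrasts = {}
    ref = groups[0]
    for g in groups:
        combo = "treat" if g == ref else f"treat + treat:C(cluster)[T.{g}]"
        tt = res.t_test(combo)
        ci = tt.conf_int()[0]
        contrasts[g] = EffectEstimate(
            estimate=float(tt.effect[0]), ci_low=float(ci[0]),
            ci_high=float(ci[1]), p_value=float(tt.pvalue),
            n_used=int((df["cluster"] == g).sum()),
            model_descriptor=f"{formula} :: {combo}",
        )
    return {"interaction_p": float(joint.pvalue), "contrasts": contrasts,
            "n_used": int(res.nobs), "formula": formula}


def classify_responders(dataset: TrialDataset, mode: str = "fixed",
                        threshold: float = RESPONDER_THRESHOLD) -> pd.DataFrame:
    """Label BSE-arm completers as pronounced responders.

    ``fixed``: improvement ≥ threshold (inclusive).  ``quantile``: the
    threshold is the 75th percentile of BSE-arm improvements (also
    inclusive, so ties at the quartile count as responders).
    """
    df = _analysis_frame(dataset)
    bse = df[df["arm"] == "BSE"].copy()
    if not len(bse):
        raise DomainError("no BSE-arm completers")
    if mode == "quantile":
        threshold = float(np.percentile(bse["improvement"], 75))
    elif mode != "fixed":
        raise DomainError("mode must be 'fixed' or 'quantile'")
    bse["pronounced_responder"] = bse["improvement"] >= threshold
    return bse[["participant_id", "improvement", "pronounced_responder"]]


def classify_remission(dataset: TrialDataset,
                       glucose_threshold: float = REMISSION_GLUCOSE) -> pd.DataFrame:
    """Remission of impaired fasting glucose: week-12 glucose strictly below
    6.1 mmol/l, among BSE-arm completers."""
    df = _analysis_frame(dataset)
    bse = df[df["arm"] == "BSE"].copy()
    bse["remission"] = bse["week12_glucose"] < glucose_threshold
    return bse[["participant_id", "week12_glucose", "improvement", "remission"]]


def log_abundance(abundance, pseudocount: Optional[float] = None) -> np.ndarray:
    """Log-transform with a pseudocount of half the smallest nonzero value
    when zeros are present."""
    x = np.asarray(abundance, dtype=float)
    if np.any(x < 0):
        raise DomainError("abundances must be non-negative")
    if np.any(x == 0):
        nonzero = x[x > 0]
        if not len(nonzero):
            raise DomainError("all abundances zero")
        if pseudocount is None:
            pseudocount = nonzero.min() / 2.0
        x = x + pseudocount
    return np.log(x)


def bt2160_cluster_interaction(d_glucose, bt2160, is_mard, bsa) -> dict:
    """BT2160 × subgroup interaction on the BSE-arm glucose change.

    OLS of glucose change on log BT2160 abundance, the MARD-vs-other
    indicator, their interaction, and body surface area.  Returns the
    interaction coefficient as the headline estimate.
    """
    df = pd.DataFrame({
        "d_glucose": np.asarray(d_glucose, dtype=float),
        "log_bt": log_abundance(bt2160),
        "is_mard": np.asarray(is_mard, dtype=int),
        "bsa": np.asarray(bsa, dtype=float),
    }).dropna()
    formula = "d_glucose ~ log_bt * is_mard + bsa"
    res = smf.ols(formula, data=df).fit()
    return {
        "interaction": _effect(res, "log_bt:is_mard", formula),
        "bt_main": _effect(res, "log_bt", formula),
        "n_used": int(res.nobs),
    }


def stratified_by_median(improvement, bt2160, is_mard) -> dict:
    """Median split on BT2160 abundance (ties to the lower stratum), then a
    MARD-vs-pooled-others improvement contrast by OLS within each stratum."""
    df = pd.DataFrame({
        "improvement": np.asarray(improvement, dtype=float),
        "bt": np.asarray(bt2160, dtype=float),
        "is_mard": np.asarray(is_mard, dtype=int),
    }).dropna()
    med = df["bt"].median()
    df["stratum"] = np.where(df["bt"] > med, "above", "below")
    out = {"median": float(med), "contrasts": {}}
    for stratum, sub in df.groupby("stratum"):
        cells = sub.groupby("is_mard").size()
        if len(cells) < 2 or (cells < 2).any():
            warnings.warn(f"stratum {stratum!r} lacks filled cells; skipped")
            continue
        res = smf.ols("improvement ~ is_mard", data=sub).fit()
        out["contrasts"][stratum] = _effect(
            res, "is_mard", f"improvement ~ is_mard | bt2160 {stratum} median"
        )
    return out


def remission_model(remission, bt2160, ggt, family: str = "linear") -> dict:
    """Regression of remission on log BT2160 abundance and GGT.

    ``linear`` (default) fits a linear probability model, whose plain R²
    matches the published quantity's family; ``logistic`` is the sensitivity
    alternative (McFadden pseudo-R²).
    """
    y = np.asarray(remission, dtype=float)
    if np.all(y == y[0]):
        raise DomainError("remission outcome is constant")
    df = pd.DataFrame({
        "remission": y,
        "log_bt": log_abundance(bt2160),
        "ggt": np.asarray(ggt, dtype=float),
    }).dropna()
    if family == "linear":
        res = smf.ols("remission ~ log_bt + ggt", data=df).fit()
        r2 = float(res.rsquared)
    elif family == "logistic":
        res = smf.logit("remission ~ log_bt + ggt", data=df).fit(disp=0)
        r2 = float(res.prsquared)
    else:
        raise DomainError("family must be 'linear' or 'logistic'")
    return {
        "r_squared": r2,
        "p_values": {k: float(v) for k, v in res.pvalues.items()
                     if k != "Intercept"},
        "n_used": int(res.nobs),
        "family": family,
    }


def benjamini_hochberg(p_values, alpha: float = 0.05):
    """FDR adjustment utility (off by default everywhere)."""
    reject, adj, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return reject, adj
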