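"""Synthetic-data generators for the whole pipeline.

Everything downstream (clustering, response models, microbiome statistics,
mixture fitting, power checks) is exercised on data produced here, since the
trial's participant-level records and the reference cohort behind the
diabetes subtypes are not public.  The generators emulate the statistical
structure the trial reported:

* a reference cohort drawn from a four-cluster Gaussian mixture over the
  clustering features (BMI, age, fasting glucose, C-peptide, HbA1c), with
  MARD-like (low BMI / low insulin resistance), SIRD-like (high BMI, high
  insulin/C-peptide), MOD-like (high BMI, moderate resistance) and a
  SIDD-like component absent from the trial mix;
* a trial cohort whose baseline marginals are calibrated to the published
  baseline table (mean fasting glucose 6.4 mmol/l, BMI 32.1 kg/m², insulin
  18.9 mIE/l, C-peptide 1.22 nmol/l) and whose 12-week glycaemic improvement
  (baseline − week-12 glucose) is Normal(placebo drift + per-cluster BSE
  effect, 0.63);
* serum sulforaphane from a two-component equal-variance Gaussian mixture
  (means 0.2 and 1.3 nmol/ml, common SD 0.55 — the modes sit two common SDs
  apart);
* a compositional microbiome table with one designated BT2160 operon
  feature whose relative abundance averages 0.032 in the high-sulforaphane
  stratum and 0.022 in the low stratum, and whose log-abundance has a
  rank-calibrated (Gaussian-copula) dependence on glycaemic improvement in
  MARD-like BSE recipients.

Every generator is deterministic under its ``seed``.  Latent ground truth
(true cluster, true sulforaphane component) is returned separately from the
observed tables and never written by the table writers.
"""

from __future__ import annotations

import functools
import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import spearmanr

from .datamodel import DomainError, TrialDataset
from .microbiome import AbundanceTable

log = logging.getLogger("bsetrial")

CLUSTER_FEATURES = ("glucose", "insulin", "c_peptide", "hba1c", "bmi", "age")

#: internal seed for copula calibration — part of the preset definition, so
#: calibrated coefficients do not drift with the user's simulation seed
_CALIBRATION_SEED = 987_654_321


@dataclass
class ClusterSpec:
    label: str
    feature_means: Mapping[str, float]
    feature_sds: Mapping[str, float]
    mixing_weight: float

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.feature_sds.values()):
            raise DomainError(f"cluster {self.label}: SDs must be positive")
        if self.mixing_weight < 0:
            raise DomainError(f"cluster {self.label}: negative mixing weight")


@dataclass
class TrialGenSpec:
    """Full generation recipe for one preset (see presets/*.yaml)."""

    name: str
    clusters: Sequence[ClusterSpec]
    n_per_arm: tuple = (44, 45)
    placebo_change_mean: float = 0.1
    change_sd: float = 0.63
    effect_by_cluster: Mapping[str, float] = field(default_factory=dict)
    dropout_rate: float = 0.0
    sulforaphane: Mapping[str, float] = field(default_factory=dict)
    bt2160: Mapping[str, object] = field(default_factory=dict)
    reference_mix: Optional[Mapping[str, float]] = None
    n_reference: int = 8980

    def __post_init__(self) -> None:
        if self.change_sd <= 0:
            raise DomainError("change_sd must be positive")
        total = sum(c.mixing_weight for c in self.clusters)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise DomainError(f"cluster mixing weights sum to {total}, not 1")
        if not 0 <= self.dropout_rate < 1:
            raise DomainError("dropout_rate must be in [0, 1)")
        s = self.sulforaphane
        if s and not s["mean_low"] < s["mean_high"]:
            raise DomainError("sulforaphane mixture means must be ordered")
        if s and s.get("common_sd", 1.0) <= 0:
            raise DomainError("sulforaphane common_sd must be positive")
        rho = self.bt2160.get("spearman_target")
        if rho is not None and not abs(rho) < 1:
            raise DomainError("|spearman_target| must be < 1")

    @property
    def labels(self) -> tuple:
        return tuple(c.label for c in self.clusters)

    def weights(self) -> np.ndarray:
        return np.array([c.mixing_weight for c in self.clusters])


def _preset_text(name: str) -> str:
    res = importlib.resources.files("bsetrial").joinpath(f"presets/{name}.yaml")
    return res.read_text()


def load_preset(name: str) -> TrialGenSpec:
    """Load a packaged preset by name (``trial_table1``, ``uniform_effect``,
    ``bt2160``, ``stratified_bt2160``, ``sulforaphane``)."""
    raw = yaml.safe_load(_preset_text(name))
    while "extends" in raw:
        base = yaml.safe_load(_preset_text(raw.pop("extends")))
        base.update(raw)
        raw = base
    clusters = [
        ClusterSpec(label=lab,
                    feature_means=cfg["means"],
                    feature_sds=cfg["sds"],
                    mixing_weight=cfg["weight"])
        for lab, cfg in raw.pop("clusters").items()
    ]
    raw["n_per_arm"] = tuple(raw.get("n_per_arm", (44, 45)))
    return TrialGenSpec(clusters=clusters, **raw)


# ---------------------------------------------------------------------------
# reference cohort
# ---------------------------------------------------------------------------

def generate_reference_cohort(n: int, specs: Sequence[ClusterSpec], seed: int = 0,
                              features: Sequence[str] = ("bmi", "age", "glucose",
                                                         "c_peptide", "hba1c"),
                              weights: Optional[Sequence[float]] = None
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a reference cohort from the cluster Gaussian mixture.

    Returns ``(features_table, latent_labels)``; the latent labels exist for
    recovery testing only and are not part of the observed table.
    """
    k = len(specs)
    if n < k:
        raise DomainError(f"n={n} smaller than number of clusters k={k}")
    w = np.array([s.mixing_weight for s in specs], dtype=float) \
        if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    assign = rng.choice(k, size=n, p=w)
    cols = {}
    for f in features:
        mu = np.array([s.feature_means[f] for s in specs])
        sd = np.array([s.feature_sds[f] for s in specs])
        cols[f] = rng.normal(mu[assign], sd[assign])
    table = pd.DataFrame(cols)
    labels = pd.Series([specs[i].label for i in assign], name="latent_cluster")
    return table, labels


def generate_reference_from_preset(spec: TrialGenSpec, n: Optional[int] = None,
                                   seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Reference cohort drawn with the preset's reference mixing weights
    (all four clusters occupied, unlike the trial mix)."""
    if spec.reference_mix is None:
        raise DomainError(f"preset {spec.name} has no reference_mix")
    weights = [spec.reference_mix[c.label] for c in spec.clusters]
    return generate_reference_cohort(n if n is not None else spec.n_reference,
                                     spec.clusters, seed=seed, weights=weights)


# ---------------------------------------------------------------------------
# trial cohort
# ---------------------------------------------------------------------------

def _positive_normal(rng, mean, sd, name, max_rounds: int = 100) -> np.ndarray:
    """Normal draws with non-positive values resampled (logged)."""
    x = rng.normal(mean, sd)
    total = 0
    for _ in range(max_rounds):
        bad = x <= 0
        if not bad.any():
            if total:
                log.info("resampled %d non-positive draws of %s", total, name)
            return x
        total += int(bad.sum())
        x = np.where(bad, rng.normal(mean, sd), x)
    raise DomainError(f"could not draw positive values for {name}")


def generate_trial_cohort(spec: TrialGenSpec, seed: int = 0,
                          n_per_arm: Optional[tuple] = None) -> TrialDataset:
    """Generate a randomized two-arm trial cohort.

    Week-12 glucose is baseline − improvement, with improvement ~
    Normal(placebo drift + arm × per-cluster effect, change SD); improvement
    is positive when glucose falls.  Latent cluster and sulforaphane
    component live in ``dataset.latent``.
    """
    rng = np.random.default_rng(seed)
    n_bse, n_pla = n_per_arm if n_per_arm is not None else spec.n_per_arm
    n = n_bse + n_pla
    arm = np.array(["BSE"] * n_bse + ["placebo"] * n_pla)
    k = len(spec.clusters)
    assign = rng.choice(k, size=n, p=spec.weights() / spec.weights().sum())
    labels = np.array(spec.labels)[assign]

    cols: dict = {"participant_id": [f"P{i+1:06d}" for i in range(n)], "arm": arm}
    base = {}
    for f in CLUSTER_FEATURES:
        mu = np.array([c.feature_means[f] for c in spec.clusters])[assign]
        sd = np.array([c.feature_sds[f] for c in spec.clusters])[assign]
        base[f] = _positive_normal(rng, mu, sd, f)
    cols["age"] = np.round(base["age"], 1)
    cols["height"] = rng.normal(172.0, 9.0, size=n)
    cols["weight"] = base["bmi"] * (cols["height"] / 100.0) ** 2

    waist = 2.8 * base["bmi"] + 20.0 + rng.normal(0.0, 4.0, size=n)
    tg = np.exp(rng.normal(math.log(1.45) - 0.35**2 / 2, 0.35, size=n))
    ggt = np.exp(rng.normal(math.log(0.7) - 0.55**2 / 2, 0.55, size=n))
    for name, vals in (("glucose", base["glucose"]), ("insulin", base["insulin"]),
                       ("c_peptide", base["c_peptide"]), ("hba1c", base["hba1c"]),
                       ("bmi", base["bmi"]), ("waist", waist),
                       ("triglycerides", tg), ("ggt", ggt)):
        cols[f"baseline_{name}"] = vals

    effect = np.array([spec.effect_by_cluster.get(lab, 0.0) for lab in labels])
    improvement = (spec.placebo_change_mean
                   + np.where(arm == "BSE", effect, 0.0)
                   + rng.normal(0.0, spec.change_sd, size=n))
    week12_glucose = cols["baseline_glucose"] - improvement
    bad = week12_glucose <= 0
    for _ in range(100):
        if not bad.any():
            break
        improvement = np.where(
            bad,
            spec.placebo_change_mean + np.where(arm == "BSE", effect, 0.0)
            + rng.normal(0.0, spec.change_sd, size=n),
            improvement,
        )
        week12_glucose = cols["baseline_glucose"] - improvement
        log.info("resampled %d improvements producing non-positive glucose",
                 int(bad.sum()))
        bad = week12_glucose <= 0
    else:
        raise DomainError("persistent non-positive week-12 glucose")

    completed = rng.random(n) >= spec.dropout_rate
    cols["completed"] = completed
    cols["week12_glucose"] = np.where(completed, week12_glucose, np.nan)
    week12_noise = {
        "insulin": (cols["baseline_insulin"], 2.0, True),
        "c_peptide": (cols["baseline_c_peptide"], 0.08, True),
        "hba1c": (cols["baseline_hba1c"], 1.5, False),
        "bmi": (cols["baseline_bmi"], 0.5, True),
        "waist": (cols["baseline_waist"], 2.0, True),
        "triglycerides": (cols["baseline_triglycerides"], 0.15, True),
        "ggt": (cols["baseline_ggt"], 0.08, True),
    }
    for name, (b, sd, positive) in week12_noise.items():
        v = _positive_normal(rng, b, sd, f"week12_{name}") if positive \
            else rng.normal(b, sd)
        cols[f"week12_{name}"] = np.where(completed, v, np.nan)

    # serum sulforaphane: measured post-treatment in the BSE arm only
    sulf_component = np.full(n, "", dtype=object)
    sulf_values = np.full(n, np.nan)
    if spec.sulforaphane:
        s = spec.sulforaphane
        comp_high = rng.random(n) < s.get("weight_high", 0.5)
        sulf_component = np.where(comp_high, "high", "low")
        mu = np.where(comp_high, s["mean_high"], s["mean_low"])
        draws = rng.normal(mu, s["common_sd"])
        measurable = (arm == "BSE") & completed
        sulf_values = np.where(measurable, draws, np.nan)
    cols["serum_sulforaphane"] = sulf_values

    table = pd.DataFrame(cols)
    latent = pd.DataFrame({
        "participant_id": cols["participant_id"],
        "cluster": labels,
        "sulf_component": sulf_component,
        "improvement": improvement,
    })
    return TrialDataset(table=table,
                        metadata={"preset": spec.name, "seed": seed,
                                  "n_per_arm": (n_bse, n_pla)},
                        latent=latent)


# ---------------------------------------------------------------------------
# serum sulforaphane
# ---------------------------------------------------------------------------

def generate_sulforaphane(n: int, mean_low: float = 0.2, mean_high: float = 1.3,
                          common_sd: float = 0.55, weight_high: float = 0.5,
                          seed: int = 0, truncate: bool = False
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw serum concentrations (nmol/ml) from the two-component
    equal-variance Gaussian mixture; returns ``(values, latent_component)``.

    By default the exact mixture is sampled so that recovery of the
    component means is well-defined; ``truncate=True`` rejection-samples
    each component above zero instead (shifting component means upward).
    """
    if common_sd <= 0:
        raise DomainError("common_sd must be positive")
    if not mean_low < mean_high:
        raise DomainError("mixture means must be ordered")
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < weight_high
    mu = np.where(comp, mean_high, mean_low)
    x = rng.normal(mu, common_sd)
    if truncate:
        for _ in range(1000):
            neg = x < 0
            if not neg.any():
                break
            x = np.where(neg, rng.normal(mu, common_sd), x)
    labels = np.where(comp, "high", "low")
    return x, labels


# ---------------------------------------------------------------------------
# microbiome
# ---------------------------------------------------------------------------

def _spearman_for_copula(c: float, mu_mix: np.ndarray, sigma_log: float,
                         z_imp: np.ndarray, eps: np.ndarray) -> float:
    zb = c * z_imp + math.sqrt(max(1.0 - c * c, 0.0)) * eps
    logb = mu_mix + sigma_log * zb
    return spearmanr(logb, z_imp).statistic


@functools.lru_cache(maxsize=32)
def calibrate_copula(spearman_target: float, w_high: float, mu_high: float,
                     mu_low: float, sigma_log: float,
                     n_cal: int = 200_000) -> float:
    """Latent-normal copula coefficient that yields the target Spearman
    correlation between log BT2160 (a two-component lognormal mixture over
    sulforaphane strata) and a normal improvement score.

    Solved numerically on a fixed-seed calibration sample; deterministic for
    a given preset.
    """
    if not abs(spearman_target) < 1:
        raise DomainError("|spearman_target| must be < 1")
    rng = np.random.default_rng(_CALIBRATION_SEED)
    z_imp = rng.standard_normal(n_cal)
    eps = rng.standard_normal(n_cal)
    s = rng.random(n_cal) < w_high
    mu_mix = np.where(s, mu_high, mu_low)
    f = lambda c: _spearman_for_copula(c, mu_mix, sigma_log, z_imp, eps) \
        - spearman_target
    return brentq(f, -0.999, 0.999, xtol=1e-4)


def generate_microbiome(n_features: int, spec: TrialGenSpec,
                        cohort: TrialDataset, seed: int = 0,
                        bt_feature: str = "BT2160") -> AbundanceTable:
    """Generate a compositional abundance table linked to a trial cohort.

    One feature is the BT2160 operon regulator: its relative abundance is
    lognormal within each latent sulforaphane stratum with stratum means set
    by the preset (defaults 0.032 high / 0.022 low), and in MARD-like BSE
    recipients its log has a Gaussian-copula dependence on glycaemic
    improvement calibrated to the preset's Spearman target.  The remaining
    features are lognormal noise closed to sum 1 − BT2160 per sample.
    """
    bt = dict(spec.bt2160)
    if not bt:
        raise DomainError(f"preset {spec.name} has no bt2160 section")
    sigma_log = float(bt.get("sigma_log", 0.5))
    mode = bt.get("mode", "strata")
    latent = cohort.latent
    if latent is None:
        raise DomainError("cohort has no latent frame; generate it first")
    n = cohort.n
    arm = cohort.table["arm"].to_numpy()
    improvement = latent["improvement"].to_numpy(dtype=float)
    cluster = latent["cluster"].to_numpy()
    stratum = latent["sulf_component"].to_numpy()

    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)

    # standardized improvement score within each (cluster, arm) cell — the
    # generator knows the true cell means, so z_imp is exactly N(0, 1)
    effect = np.array([spec.effect_by_cluster.get(c, 0.0) for c in cluster])
    cell_mean = spec.placebo_change_mean + np.where(arm == "BSE", effect, 0.0)
    z_imp = (improvement - cell_mean) / spec.change_sd

    if mode == "strata":
        mu_high = math.log(float(bt["mean_high"])) - sigma_log**2 / 2
        mu_low = math.log(float(bt["mean_low"])) - sigma_log**2 / 2
        mu = np.where(stratum == "high", mu_high, mu_low)
        target = bt.get("spearman_target")
        c = 0.0
        if target is not None:
            w_high = float(spec.sulforaphane.get("weight_high", 0.5))
            c = calibrate_copula(float(target), w_high, mu_high, mu_low,
                                 sigma_log)
    elif mode == "single":
        mu = np.full(n, math.log(float(bt["mean"])) - sigma_log**2 / 2)
        if "rho_z" in bt and bt["rho_z"] is not None:
            c = float(bt["rho_z"])
        else:
            # calibrate the above-median MARD-vs-other improvement contrast:
            # contrast = base effect difference + change_sd·rho·sqrt(2/pi)
            target = float(bt["above_median_contrast"])
            eff = spec.effect_by_cluster
            mix = dict(zip(spec.labels, spec.weights()))
            other_effs = [eff.get(lab, 0.0) for lab in spec.labels
                          if lab != "MARD-like" and mix[lab] > 0]
            if len(set(other_effs)) > 1:
                raise DomainError(
                    "above_median_contrast calibration requires a common "
                    "effect in the non-MARD clusters"
                )
            base_diff = eff.get("MARD-like", 0.0) - (other_effs[0] if other_effs else 0.0)
            c = (target - base_diff) / (spec.change_sd * math.sqrt(2.0 / math.pi))
            if not abs(c) < 1:
                raise DomainError("above_median_contrast unreachable")
    else:
        raise DomainError(f"unknown bt2160 mode {mode!r}")

    dependent = (cluster == "MARD-like") & (arm == "BSE") & ~np.isnan(z_imp)
    z_bt = np.where(dependent,
                    c * np.nan_to_num(z_imp) + math.sqrt(1 - c * c) * eps,
                    eps)
    bt_abund = np.exp(mu + sigma_log * z_bt)
    bt_abund = np.minimum(bt_abund, 0.99)  # compositional guard

    other = np.exp(rng.normal(0.0, 1.0, size=(n, n_features - 1)))
    other *= ((1.0 - bt_abund) / other.sum(axis=1))[:, None]
    values = np.column_stack([bt_abund, other])
    feature_ids = [bt_feature] + [f"gene_{i:05d}" for i in range(1, n_features)]
    sample_ids = cohort.table["participant_id"].to_numpy()
    meta = pd.DataFrame({"participant_id": sample_ids, "arm": arm,
                         "visit": "baseline"},
                        index=pd.Index(sample_ids, name="sample_id"))
    df = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                      columns=feature_ids)
    return AbundanceTable(values=df, metadata=meta)
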