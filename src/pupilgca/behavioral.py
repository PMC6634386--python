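"""Behavioral arm: screening, inverse-RT and accuracy mixed models, Bayes factors.

Latencies are analysed as -1000/RT (inverse RT), which normalizes the
positive skew of latency distributions while preserving order (faster
responses are more negative).  Screening follows the emulated protocol:
participants below 75% correct are excluded, word pairs below 60%
accuracy are discarded, and the latency analysis additionally drops
error trials and correct responses faster than 250 ms (all strict
inequalities).  The RT model has sum-coded type and strength fixed
effects with by-participant slopes and crossed by-item intercepts; after
an initial fit, observations with standardized marginal residuals beyond
3 SD are removed and the model is refitted once.  Model comparisons use
the BIC approximation to the Bayes factor, BF = exp(dBIC / 2), from ML
fits on identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from sklearn.base import BaseEstimator

from .design import STRENGTH_FACTOR, TYPE_FACTOR
from .glmm import GlmmComponent, fit_logistic_glmm
from .lmm import LmmFit, ModelSpec, directional_pvalues, fit_lmm, fit_lmm_fixed_structure

__all__ = [
    "ScreeningRules",
    "ScreeningResult",
    "ModelComparison",
    "transform_rt",
    "apply_screening",
    "ReactionTimeModel",
    "AccuracyModel",
    "refit_without_outliers",
    "bic_bayes_factor",
]


def transform_rt(rt_ms):
    """Inverse reaction time, -1000/rt: negative, order-preserving.

    Raises
    ------
    ValueError
        For non-positive reaction times.
    """
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("reaction times must be positive")
    out = -1000.0 / rt
    return float(out) if np.isscalar(rt_ms) else out


@dataclass
class ScreeningRules:
    """Exclusion thresholds; all comparisons are strict as published."""

    participant_min_accuracy: float = 0.75
    item_min_accuracy: float = 0.60
    rt_min_ms: float = 250.0
    errors_excluded_from_rt: bool = True
    experimental_only: bool = True  # restrict the models to non-filler trials

    def validate(self):
        for f in ("participant_min_accuracy", "item_min_accuracy"):
            v = getattr(self, f)
            if not (0 <= v <= 1):
                raise ValueError(f"{f} must be in [0, 1]")
        if self.rt_min_ms < 0:
            raise ValueError("rt_min_ms must be >= 0")


@dataclass
class ScreeningResult:
    """Screened record sets plus a per-rule removal account."""

    records: pd.DataFrame = field(repr=False)       # after participant + item screens
    rt_records: pd.DataFrame = field(repr=False)    # latency-analysis subset
    accuracy_records: pd.DataFrame = field(repr=False)
    participants_excluded: list = field(default_factory=list)
    items_excluded: list = field(default_factory=list)
    n_trials_in: int = 0
    trials_dropped_participant_screen: int = 0
    trials_dropped_item_screen: int = 0
    error_trials_dropped_rt: int = 0
    fast_trials_dropped_rt: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("trials_in", self.n_trials_in),
            ("participants_excluded", len(self.participants_excluded)),
            ("trials_dropped_participant_screen", self.trials_dropped_participant_screen),
            ("items_excluded", len(self.items_excluded)),
            ("trials_dropped_item_screen", self.trials_dropped_item_screen),
            ("error_trials_dropped_rt", self.error_trials_dropped_rt),
            ("fast_trials_dropped_rt", self.fast_trials_dropped_rt),
            ("rt_analysis_trials", len(self.rt_records)),
            ("accuracy_analysis_trials", len(self.accuracy_records)),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def apply_screening(records: pd.DataFrame, rules: ScreeningRules | None = None) -> ScreeningResult:
    """Apply the behavioral exclusion rules in their published order.

    Participant screen first (accuracy strictly below 75% over all their
    trials), then item screen (strictly below 60% over retained
    participants), then — for the latency subset only — error trials and
    correct RTs strictly below 250 ms.  The accuracy subset keeps error
    trials.

    Raises
    ------
    RuntimeError
        If nothing survives screening.
    """
    if rules is None:
        rules = ScreeningRules()
    rules.validate()
    req = {"participant", "item", "sem_type", "strength", "rt_ms", "accuracy"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    res = ScreeningResult(
        records=records, rt_records=records, accuracy_records=records, n_trials_in=len(records)
    )
    part_acc = records.groupby("participant")["accuracy"].mean()
    res.participants_excluded = sorted(part_acc.index[part_acc < rules.participant_min_accuracy])
    kept = records[~records["participant"].isin(res.participants_excluded)].copy()
    res.trials_dropped_participant_screen = len(records) - len(kept)

    item_acc = kept.groupby("item")["accuracy"].mean()
    res.items_excluded = sorted(item_acc.index[item_acc < rules.item_min_accuracy])
    n_before = len(kept)
    kept = kept[~kept["item"].isin(res.items_excluded)].copy()
    res.trials_dropped_item_screen = n_before - len(kept)
    if kept.empty:
        raise RuntimeError("no trials survive behavioral screening")
    res.records = kept

    model_set = kept[kept["sem_type"] != "filler"] if rules.experimental_only else kept
    res.accuracy_records = model_set.copy()

    rt_set = model_set
    if rules.errors_excluded_from_rt:
        res.error_trials_dropped_rt = int((rt_set["accuracy"] == 0).sum())
        rt_set = rt_set[rt_set["accuracy"] == 1]
    res.fast_trials_dropped_rt = int((rt_set["rt_ms"] < rules.rt_min_ms).sum())
    rt_set = rt_set[rt_set["rt_ms"] >= rules.rt_min_ms].copy()
    if rt_set.empty:
        raise RuntimeError("no trials survive the latency screen")
    rt_set["neg_inv_rt"] = transform_rt(rt_set["rt_ms"].to_numpy())
    res.rt_records = rt_set
    return res


def _coded_records(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    df["type"] = TYPE_FACTOR.code(df["sem_type"])
    df["strength"] = STRENGTH_FACTOR.code(df["strength"])
    return df


def refit_without_outliers(
    fit: LmmFit, data: pd.DataFrame, spec: ModelSpec, k: float = 3.0
) -> tuple[LmmFit, float]:
    """Drop observations with |standardized marginal residual| > k; refit once.

    Marginal residuals are response minus the fixed-effect prediction of
    the initial fit, standardized by their own SD.  Returns the refitted
    model and the removed fraction.  Removal is single-pass by design.
    """
    x = np.asarray(dmatrix(spec.fixed, data))
    beta = fit.params["estimate"].to_numpy()
    resid = data[spec.response].to_numpy() - x @ beta
    sd = resid.std()
    if sd == 0:
        return fit, 0.0
    z = resid / sd
    keep = np.abs(z) <= k
    frac = float(1.0 - keep.mean())
    if frac == 0.0:
        return fit, 0.0
    refit = fit_lmm(data[keep], spec)
    refit.notes.append(f"refit after removing {frac:.3%} outliers (|z| > {k})")
    return refit, frac


class ReactionTimeModel(BaseEstimator):
    """Inverse-RT linear mixed model with crossed random effects.

    Model: ``-1000/rt ~ type * strength`` with by-participant slopes for
    both factors and their interaction, and crossed by-item intercepts
    (independent variance components).  After the initial fit,
    observations with standardized marginal residuals beyond
    ``outlier_k`` SD are removed and the model refitted once.

    Attributes
    ----------
    initial_fit_ : LmmFit before outlier removal.
    fit_ : the reported fit (after the outlier pass).
    outlier_fraction_ : fraction of observations removed.
    """

    def __init__(self, outlier_k: float = 3.0, reml: bool = True,
                 directions: dict | None = None):
        self.outlier_k = outlier_k
        self.reml = reml
        self.directions = directions

    def _spec(self, reml: bool, fixed: str = "type * strength") -> ModelSpec:
        return ModelSpec(
            response="neg_inv_rt",
            fixed=fixed,
            group="participant",
            slope_terms=("type", "strength", "type:strength"),
            crossed_intercepts=("item",),
            reml=reml,
        )

    def fit(self, X: pd.DataFrame, y=None):
        df = _coded_records(X)
        if "neg_inv_rt" not in df.columns:
            df["neg_inv_rt"] = transform_rt(df["rt_ms"].to_numpy())
        spec = self._spec(self.reml)
        self.initial_fit_ = fit_lmm(df, spec)
        fit, frac = refit_without_outliers(self.initial_fit_, df, spec, k=self.outlier_k)
        if self.directions:
            fit = directional_pvalues(fit, self.directions)
        self.fit_ = fit
        self.outlier_fraction_ = frac
        self._data = df
        return self

    def interaction_comparison(self) -> "ModelComparison":
        """BF for dropping the interaction, from ML fits on identical data.

        Both models are forced onto the same random structure (the rung
        the full ML fit converged at); comparing BICs across different
        random structures would confound the fixed-effect question with
        the fallback ladder.
        """
        x = np.asarray(dmatrix(self._spec(True).fixed, self._data))
        beta = self.initial_fit_.params["estimate"].to_numpy()
        resid = self._data["neg_inv_rt"].to_numpy() - x @ beta
        keep = np.abs(resid / resid.std()) <= self.outlier_k
        data = self._data[keep]
        full = fit_lmm(data, self._spec(reml=False))
        reduced = fit_lmm_fixed_structure(
            data, self._spec(reml=False, fixed="type + strength"), full.structure
        )
        return ModelComparison(
            model_a="type + strength",
            model_b="type * strength",
            model_a_bic=reduced.bic,
            model_b_bic=full.bic,
            n_obs=full.n_obs,
        )


class AccuracyModel(BaseEstimator):
    """Logistic mixed model for trial accuracy.

    Model: ``accuracy ~ type * strength`` with a reduced random
    structure — by-participant intercepts and type slopes, plus by-item
    intercepts — estimated by the Laplace approximation.
    """

    FIXED_NAMES = ("Intercept", "type", "strength", "type:strength")

    def __init__(self, directions: dict | None = None):
        self.directions = directions

    @staticmethod
    def _design(df: pd.DataFrame, terms=("type", "strength", "interaction")) -> np.ndarray:
        cols = [np.ones(len(df))]
        if "type" in terms:
            cols.append(df["type"].to_numpy(float))
        if "strength" in terms:
            cols.append(df["strength"].to_numpy(float))
        if "interaction" in terms:
            cols.append((df["type"] * df["strength"]).to_numpy(float))
        return np.column_stack(cols)

    def _components(self, df: pd.DataFrame) -> list[GlmmComponent]:
        return [
            GlmmComponent("participant", df["participant"].to_numpy()),
            GlmmComponent("participant:type", df["participant"].to_numpy(),
                          weights=df["type"].to_numpy(float)),
            GlmmComponent("item", df["item"].to_numpy()),
        ]

    def fit(self, X: pd.DataFrame, y=None):
        df = _coded_records(X)
        fit = fit_logistic_glmm(
            df["accuracy"].to_numpy(),
            self._design(df),
            self._components(df),
            fixed_names=list(self.FIXED_NAMES),
        )
        if self.directions:
            fit = directional_pvalues(fit, self.directions)
        self.fit_ = fit
        self._data = df
        return self

    def comparison(self, reduced_terms=("strength",)) -> "ModelComparison":
        """BF comparing a reduced fixed structure against the full model."""
        df = self._data
        full = self.fit_
        reduced = fit_logistic_glmm(
            df["accuracy"].to_numpy(),
            self._design(df, terms=reduced_terms),
            self._components(df),
            fixed_names=["Intercept", *reduced_terms],
        )
        return ModelComparison(
            model_a=" + ".join(reduced_terms),
            model_b="type * strength",
            model_a_bic=reduced.bic,
            model_b_bic=full.bic,
            n_obs=full.n_obs,
        )


@dataclass
class ModelComparison:
    """BIC-based Bayes factor for model a versus model b."""

    model_a: str
    model_b: str
    model_a_bic: float
    model_b_bic: float
    n_obs: int

    @property
    def bf_ab(self) -> float:
        return bic_bayes_factor(self.model_a_bic, self.model_b_bic)


def bic_bayes_factor(bic_a: float, bic_b: float) -> float:
    """Approximate Bayes factor favoring model a: exp((BIC_b - BIC_a) / 2)."""
    return float(np.exp((bic_b - bic_a) / 2.0))
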