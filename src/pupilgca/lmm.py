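"""Linear mixed models with a documented fallback ladder.

Thin, opinionated wrapper around statsmodels ``MixedLM``.  Two random-
effect layouts are supported:

* a single grouping factor (e.g. subject) with a full-covariance
  ("maximal") random structure via ``re_formula``;
* crossed grouping factors (e.g. participant and item) expressed as
  variance components inside one grand group, which constrains the
  random-effect covariances to be diagonal (independent variances) —
  the standard way to fit crossed designs with this backend.

If the requested structure fails to converge the fitter falls back in a
fixed order — full covariance, then diagonal variance components, then
random intercepts only — and records which rung was used.  Test
statistics use the normal (z) approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["ModelSpec", "LmmFit", "fit_lmm", "directional_pvalues", "bic_from_fit"]

_GRAND_GROUP = "__all__"


@dataclass
class ModelSpec:
    """Specification of a mixed model in the package's vocabulary.

    ``slope_terms`` are the random-slope terms for the primary grouping
    factor (the random intercept is implicit); ``crossed_intercepts``
    lists additional grouping factors that get random intercepts (crossed
    with the primary factor).
    """

    response: str
    fixed: str  # patsy right-hand side
    group: str  # primary grouping factor column
    slope_terms: tuple[str, ...] = ()
    crossed_intercepts: tuple[str, ...] = ()
    reml: bool = True

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


@dataclass
class LmmFit:
    """A fitted mixed model: coefficient table, variance components, fit stats."""

    params: pd.DataFrame = field(repr=False)  # estimate, se, stat, p_two, p per term
    varcomps: dict = field(repr=False)
    loglik: float = np.nan
    bic: float = np.nan
    n_obs: int = 0
    n_params: int = 0
    converged: bool = False
    method: str = "reml"
    structure: str = ""
    notes: list = field(default_factory=list)
    resid: np.ndarray | None = field(default=None, repr=False)
    data_index: pd.Index | None = field(default=None, repr=False)

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])


def bic_from_fit(loglik: float, n_params: int, n_obs: int) -> float:
    return -2.0 * loglik + n_params * np.log(n_obs)


def _fit_once(data: pd.DataFrame, spec: ModelSpec, structure: str) -> LmmFit:
    df = data.copy()
    crossed = tuple(spec.crossed_intercepts)
    if crossed:
        # crossed factors: everything as variance components in one grand group
        df[_GRAND_GROUP] = 1
        groups = _GRAND_GROUP
        vc = {spec.group: f"0 + C({spec.group})"}
        if structure != "intercept":
            for t in spec.slope_terms:
                key = f"{spec.group}_{t}".replace(":", "_").replace(" ", "")
                vc[key] = f"0 + C({spec.group}):{t}"
        for g in crossed:
            vc[g] = f"0 + C({g})"
        re_formula = "0"
    else:
        groups = spec.group
        if structure == "maximal":
            re_formula = "1 + " + " + ".join(spec.slope_terms) if spec.slope_terms else "1"
            vc = None
        elif structure == "diagonal":
            re_formula = "1"
            vc = {
                f"vc_{t}".replace(":", "_"): f"0 + {t}" for t in spec.slope_terms
            } or None
        else:  # intercept
            re_formula = "1"
            vc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            spec.formula, df, groups=df[groups], re_formula=re_formula, vc_formula=vc
        )
        result = model.fit(reml=spec.reml, method="lbfgs", maxiter=500, gtol=1e-8)
    fe = result.fe_params
    se = result.bse_fe
    stat = fe / se
    p_two = 2.0 * stats.norm.sf(np.abs(stat))
    params = pd.DataFrame(
        {"estimate": fe, "se": se, "stat": stat, "p_two": p_two, "p": p_two}
    )
    k_re = result.cov_re.shape[0] if result.cov_re is not None else 0
    n_cov = k_re * (k_re + 1) // 2 + len(result.vcomp) + 1  # + residual variance
    n_params = len(fe) + n_cov
    loglik = float(result.llf)
    n_obs = int(result.nobs)
    varcomps = {
        "cov_re": result.cov_re.to_dict() if k_re else {},
        "vcomp": {
            name: float(v)
            for name, v in zip(result.model.exog_vc.names if vc else [], result.vcomp)
        },
        "resid_var": float(result.scale),
    }
    return LmmFit(
        params=params,
        varcomps=varcomps,
        loglik=loglik,
        bic=bic_from_fit(loglik, n_params, n_obs),
        n_obs=n_obs,
        n_params=n_params,
        converged=bool(result.converged),
        method="reml" if spec.reml else "ml",
        structure=structure,
        resid=np.asarray(result.resid),
        data_index=df.index,
    )


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LmmFit:
    """Fit a linear mixed model, falling back through simpler structures.

    Ladder: full random-effect covariance (single grouping factor only)
    -> diagonal variance components -> random intercepts only.  Crossed
    designs start at the diagonal rung.  A fit that fails every rung is
    returned from the last rung with ``converged=False`` and a note,
    never silently.

    Raises
    ------
    ValueError
        If required columns are missing or fewer than 2 groups exist.
    """
    for col in [spec.response, spec.group, *spec.crossed_intercepts]:
        if col not in data.columns:
            raise ValueError(f"model variable {col!r} not in data")
    if data[spec.group].nunique() < 2:
        raise ValueError("need at least 2 groups to fit a mixed model")
    if spec.crossed_intercepts:
        ladder = ["diagonal", "intercept"]
    else:
        ladder = ["maximal", "diagonal", "intercept"] if spec.slope_terms else ["intercept"]
    notes: list[str] = []
    last: LmmFit | None = None
    for structure in ladder:
        try:
            fit = _fit_once(data, spec, structure)
        except (np.linalg.LinAlgError, ValueError) as exc:
            notes.append(f"{structure}: failed ({exc})")
            continue
        fit.notes = notes + fit.notes
        if fit.converged:
            if notes:
                fit.notes.append(f"fell back to {structure} structure")
            return fit
        notes.append(f"{structure}: did not converge")
        last = fit
    if last is None:
        raise RuntimeError(f"mixed model could not be fitted: {notes}")
    last.notes = notes + ["no structure converged; returning last attempt"]
    return last


def fit_lmm_fixed_structure(data: pd.DataFrame, spec: ModelSpec, structure: str) -> LmmFit:
    """Fit with a prescribed random structure, no fallback.

    Used for likelihood-based model comparison, where both models must
    share the same random structure for their BICs to be comparable.
    """
    return _fit_once(data, spec, structure)


def directional_pvalues(fit: LmmFit, directions: dict) -> LmmFit:
    """One-tailed p-values for main effects with predicted directions.

    For each main-effect term with predicted sign ``+1``/``-1``:
    p = p_two/2 if the estimate matches the prediction, else 1 - p_two/2.
    Interaction terms keep their two-tailed p; supplying a direction for
    an interaction is a configuration error.
    """
    for term, d in directions.items():
        if ":" in term:
            raise ValueError(f"direction supplied for interaction term {term!r}")
        if d not in (-1, 1):
            raise ValueError(f"direction for {term!r} must be +1 or -1")
        if term not in fit.params.index:
            raise ValueError(f"term {term!r} not in fitted model")
    params = fit.params.copy()
    for term, d in directions.items():
        p2 = params.loc[term, "p_two"]
        matches = np.sign(params.loc[term, "estimate"]) == d
        params.loc[term, "p"] = p2 / 2.0 if matches else 1.0 - p2 / 2.0
    out = LmmFit(**{**fit.__dict__, "params": params})
    out.notes = fit.notes + [f"one-tailed p for {sorted(directions)}"]
    return out
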