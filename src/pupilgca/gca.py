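"""Growth curve analysis (GCA) of binned pupil trajectories.

Fits the baseline-corrected dilation time course on a third-order
orthogonal polynomial basis crossed with the sum-coded 2x2 design
(semantic type x relatedness strength), with a by-participant random
structure covering the time terms and the condition effects:

    pupil ~ (poly1 + poly2 + poly3) * type * strength
            + ((poly1 + poly2 + poly3) + type * strength | participant)

Interpretation of the fixed effects: the intercept is the average
dilation over the window, the linear term the overall slope, the
quadratic the primary curvature (more negative = steeper inverted-U),
and the cubic a secondary inflection; each condition column tests how
that shape component differs between cells of the design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .basis import PolyBasis, orthogonal_poly_basis
from .design import STRENGTH_FACTOR, TYPE_FACTOR
from .lmm import LmmFit, ModelSpec, directional_pvalues, fit_lmm

__all__ = ["GrowthCurveModel", "gca_table", "add_polynomial_columns", "plot_gca_fit"]

TIME_TERMS = ("Intercept", "poly1", "poly2", "poly3")
EFFECT_TERMS = ("Overall", "Type", "Strength", "Type:Strength")
_ROW_LABELS = {"Intercept": "Intercept", "poly1": "Linear", "poly2": "Quadratic", "poly3": "Cubic"}


def _term_name(time_term: str, effect: str) -> str:
    """Canonical coefficient name for a (time term, effect column) cell."""
    parts = [] if time_term == "Intercept" else [time_term]
    if effect == "Type":
        parts.append("type")
    elif effect == "Strength":
        parts.append("strength")
    elif effect == "Type:Strength":
        parts += ["type", "strength"]
    return ":".join(parts) if parts else "Intercept"


def add_polynomial_columns(
    binned: pd.DataFrame, order: int = 3, time_col: str = "time_ms"
) -> tuple[pd.DataFrame, PolyBasis]:
    """Attach poly1..polyk columns evaluated at each row's bin midpoint."""
    times = np.sort(binned[time_col].unique())
    basis = orthogonal_poly_basis(times, order=order)
    lookup = pd.DataFrame(basis.columns, columns=basis.names).assign(**{time_col: times})
    return binned.merge(lookup, on=time_col, how="left"), basis


def _coded(binned: pd.DataFrame) -> pd.DataFrame:
    df = binned.copy()
    if "sem_type" not in df.columns or "strength" not in df.columns:
        parts = df["condition"].str.split("-", expand=True)
        df["strength"], df["sem_type"] = parts[0], parts[1]
    df = df[df["sem_type"].isin(TYPE_FACTOR.levels)].copy()
    if df.empty:
        raise ValueError("no experimental trials (is everything a filler?)")
    df["type"] = TYPE_FACTOR.code(df["sem_type"])
    df["strength_code"] = STRENGTH_FACTOR.code(df["strength"])
    df = df.drop(columns=["strength"]).rename(columns={"strength_code": "strength"})
    return df


class GrowthCurveModel(BaseEstimator):
    """sklearn-style estimator for the pupillary growth curve model.

    Parameters
    ----------
    order : int
        Polynomial order of the time basis (default 3).
    aggregate : bool
        Average trials to participant x condition x bin means before
        fitting (default True); the random structure is by participant,
        so trial-level replicates add observations, not information, and
        aggregation keeps the fit fast and well conditioned.
    reml : bool
        Restricted maximum likelihood (default) or ML.
    directions : dict or None
        Predicted signs for main-effect terms; when given, those terms
        get one-tailed p-values (interactions stay two-tailed).

    Attributes
    ----------
    basis_ : PolyBasis fitted on the bin midpoints.
    fit_ : LmmFit with the coefficient table (16 fixed effects).
    table_ : the 4x4 report grid of "estimate (SE)" strings.
    """

    def __init__(self, order: int = 3, aggregate: bool = True, reml: bool = True,
                 directions: dict | None = None):
        self.order = order
        self.aggregate = aggregate
        self.reml = reml
        self.directions = directions

    def fit(self, X: pd.DataFrame, y=None):
        df = _coded(X)
        if self.aggregate:
            df = (
                df.groupby(["participant", "sem_type", "type", "strength", "time_ms"], as_index=False)
                .agg(pupil=("pupil", "mean"))
            )
        df, self.basis_ = add_polynomial_columns(df, order=self.order)
        poly = " + ".join(self.basis_.names)
        spec = ModelSpec(
            response="pupil",
            fixed=f"({poly}) * type * strength",
            group="participant",
            slope_terms=(*self.basis_.names, "type", "strength", "type:strength"),
            reml=self.reml,
        )
        fit = fit_lmm(df, spec)
        if self.directions:
            fit = directional_pvalues(fit, self.directions)
        self.fit_ = fit
        self.n_participants_ = df["participant"].nunique()
        self.table_ = gca_table(fit)
        return self

    @property
    def coefficients_(self) -> pd.DataFrame:
        return self.fit_.params

    def predict(self, conditions=None) -> pd.DataFrame:
        """Fixed-effect predicted trajectories per design cell."""
        if conditions is None:
            conditions = [f"{s}-{t}" for t in TYPE_FACTOR.levels for s in STRENGTH_FACTOR.levels]
        est = self.fit_.params["estimate"]
        rows = []
        for cond in conditions:
            strength, sem_type = cond.split("-")
            ct = TYPE_FACTOR.codes[sem_type]
            cs = STRENGTH_FACTOR.codes[strength]
            x = np.column_stack([np.ones(len(self.basis_.times)), self.basis_.columns])
            coef = np.array(
                [
                    [est.get(_term_name(tt, "Overall"), 0.0) for tt in TIME_TERMS],
                    [est.get(_term_name(tt, "Type"), 0.0) for tt in TIME_TERMS],
                    [est.get(_term_name(tt, "Strength"), 0.0) for tt in TIME_TERMS],
                    [est.get(_term_name(tt, "Type:Strength"), 0.0) for tt in TIME_TERMS],
                ]
            )
            pred = x @ (coef[0] + ct * coef[1] + cs * coef[2] + ct * cs * coef[3])
            rows.append(
                pd.DataFrame(
                    {"condition": cond, "time_ms": self.basis_.times, "pupil": pred}
                )
            )
        return pd.concat(rows, ignore_index=True)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def gca_table(fit: LmmFit, digits: int = 2) -> pd.DataFrame:
    """The 4x4 coefficient grid: time terms x design effects.

    Cells are "estimate (SE)" with significance markers
    (*** p<0.001, ** p<0.01, * p<0.05).

    Raises
    ------
    ValueError
        If the fit does not contain the full 16-term crossing.
    """
    expected = [
        _term_name(tt, ef) for tt in TIME_TERMS for ef in EFFECT_TERMS
    ]
    missing = [t for t in expected if t not in fit.params.index]
    if missing:
        raise ValueError(f"fit is not a full growth curve model; missing terms {missing}")
    out = pd.DataFrame(index=[_ROW_LABELS[t] for t in TIME_TERMS], columns=EFFECT_TERMS, dtype=object)
    for tt in TIME_TERMS:
        for ef in EFFECT_TERMS:
            term = _term_name(tt, ef)
            est = fit.params.loc[term, "estimate"]
            se = fit.params.loc[term, "se"]
            star = _stars(float(fit.params.loc[term, "p"]))
            cell = f"{est:.{digits}f} ({se:.{digits}f})"
            out.loc[_ROW_LABELS[tt], ef] = f"{cell} {star}".rstrip()
    out.index.name = "Term"
    return out


def plot_gca_fit(binned: pd.DataFrame, model: GrowthCurveModel, path=None):
    """Observed condition-mean trajectories with model fits overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _coded(binned)
    obs = df.groupby(["sem_type", "strength", "time_ms"], as_index=False)["pupil"].mean()
    pred = model.predict()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cond, sub in pred.groupby("condition"):
        strength, sem_type = cond.split("-")
        ct, cs = TYPE_FACTOR.codes[sem_type], STRENGTH_FACTOR.codes[strength]
        o = obs[(obs.sem_type == sem_type) & (obs.strength == cs)]
        line, = ax.plot(sub.time_ms, sub.pupil, label=cond)
        ax.plot(o.time_ms, o.pupil, "o", ms=3, color=line.get_color(), alpha=0.6)
    ax.set_xlabel("Time from word-pair onset (ms)")
    ax.set_ylabel("Baseline-corrected pupil dilation (mm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
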