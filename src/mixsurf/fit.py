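"""Least-squares fitting of Scheffe mixture models and the mixture ANOVA.

Fitting happens on the model's transformed scale.  The ANOVA follows the
convention of mixture-design software: the "Linear Mixture" source gets
the sequential (Type I) sum of squares of the q linear blending terms
after the mean, each non-linear term gets its partial (drop-one) sum of
squares from the full model, and the residual is split into lack of fit
and pure error using the design's replicate groups.  Fit statistics
(R^2, adjusted and PRESS-based predicted R^2, CV%) are those practitioners
use to choose between candidate mixture models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import Blend, MixtureDesign
from .models import ModelSpec, TermSpec, model_matrix, term_name

__all__ = ["FitResult", "AnovaTable", "fit", "anova", "reduce_model", "predict"]

#: sentinel used in place of an infinite F ratio (zero residual variance)
F_CAP = 1e12

_RCOND_MIN = 1e-10


@dataclass
class FitResult:
    """A fitted Scheffe model with per-run diagnostics and fit statistics.

    Coefficients are in transformed-response units.  ``r2_pred`` is the
    PRESS-based predicted R^2, ``cv_percent`` is 100*sqrt(MSE)/mean of the
    transformed response.
    """

    model: ModelSpec
    design: MixtureDesign
    coefficients: np.ndarray
    y_original: np.ndarray
    y_transformed: np.ndarray
    fitted_transformed: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    sd: float
    r2: float
    r2_adj: float
    r2_pred: float
    press: float
    cv_percent: float

    @property
    def n(self) -> int:
        return len(self.y_transformed)

    @property
    def p(self) -> int:
        return len(self.coefficients)

    @property
    def df_residual(self) -> int:
        return self.n - self.p

    @property
    def ss_residual(self) -> float:
        return float(self.residuals @ self.residuals)

    @property
    def ss_total(self) -> float:
        y = self.y_transformed
        return float(((y - y.mean()) ** 2).sum())

    def coefficient_table(self, aliases="ABCDEFGH") -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.model.term_names(aliases), "coefficient": self.coefficients}
        )

    def equation(self, aliases="ABCDEFGH") -> str:
        """The fitted polynomial as a printable equation on the model scale."""
        parts = []
        for name, c in zip(self.model.term_names(aliases), self.coefficients):
            sign = "-" if c < 0 else "+"
            parts.append(f"{sign} {abs(c):.6g} {name}")
        body = " ".join(parts).lstrip("+ ")
        lhs = self.model.response
        if self.model.transform.name != "identity":
            lhs = f"{self.model.transform.name}({lhs})"
        return f"{lhs} = {body}"


def _check_rank(X: np.ndarray) -> None:
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] / s[0] < _RCOND_MIN:
        raise np.linalg.LinAlgError(
            "model matrix is rank-deficient (reciprocal condition "
            f"{s[-1] / s[0]:.2e} < {_RCOND_MIN:g}); model is not estimable"
        )


def fit(design: MixtureDesign, response, model: ModelSpec) -> FitResult:
    """Least-squares fit of ``model`` to ``response`` on its transformed scale."""
    y = np.asarray(response, dtype=float)
    if y.shape != (design.n_runs,):
        raise ValueError("response length must equal the number of runs")
    tr = model.transform
    if tr.name in ("sqrt", "ln", "inverse_sqrt") and (y <= 0).any():
        bad = design.run_ids[int(np.argmax(y <= 0))]
        raise ValueError(
            f"run {bad}: non-positive response cannot be {tr.name}-transformed"
        )
    z = tr(y)
    if not np.isfinite(z).all():
        bad = design.run_ids[int(np.argmax(~np.isfinite(z)))]
        raise ValueError(f"run {bad}: transformed response is not finite")

    X = model_matrix(design.as_array(), model.terms)
    if X.shape[0] < X.shape[1]:
        raise np.linalg.LinAlgError("fewer runs than model terms")
    _check_rank(X)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    zhat = X @ beta
    e = z - zhat
    n, p = X.shape
    h = np.einsum("ij,jk,ik->i", X, np.linalg.inv(X.T @ X), X)
    rss = float(e @ e)
    sst = float(((z - z.mean()) ** 2).sum())
    mse = rss / (n - p) if n > p else np.nan
    # leave-one-out residuals; a leverage of 1 with a zero residual means the
    # deleted fit interpolates that run exactly (contributes nothing to PRESS)
    denom = 1.0 - h
    safe = denom > 1e-12
    loo = np.where(safe, e / np.where(safe, denom, 1.0),
                   np.where(np.abs(e) < 1e-10, 0.0, np.inf))
    press = float((loo**2).sum())
    if sst <= 0:
        raise ValueError("response is constant across runs; R^2 is undefined")
    r2 = 1.0 - rss / sst
    r2_adj = 1.0 - (rss / (n - p)) / (sst / (n - 1)) if n > p else np.nan
    return FitResult(
        model=model,
        design=design,
        coefficients=beta,
        y_original=y,
        y_transformed=z,
        fitted_transformed=zhat,
        residuals=e,
        leverage=h,
        sd=float(np.sqrt(mse)) if np.isfinite(mse) else np.nan,
        r2=r2,
        r2_adj=r2_adj,
        r2_pred=1.0 - press / sst,
        press=press,
        cv_percent=float(100.0 * np.sqrt(mse) / z.mean()) if np.isfinite(mse) else np.nan,
    )


@dataclass
class AnovaTable:
    """Mixture ANOVA with lack-of-fit / pure-error residual split.

    ``rows`` is a DataFrame with columns (source, ss, df, ms, f, p).
    ``lof_omitted`` flags designs without replicate runs, where the
    lack-of-fit test cannot be formed.
    """

    rows: pd.DataFrame
    lof_omitted: bool = False
    aliases: str = "ABCDEFGH"

    def __getitem__(self, source: str) -> pd.Series:
        hit = self.rows[self.rows["source"] == source]
        if hit.empty:
            raise KeyError(source)
        return hit.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def to_text(self) -> str:
        df = self.rows.copy()
        for c in ("ss", "ms", "f"):
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.4g}")
        df["p"] = df["p"].map(
            lambda v: "" if pd.isna(v) else ("<0.0001" if v < 1e-4 else f"{v:.4f}")
        )
        df["df"] = df["df"].map(lambda v: "" if pd.isna(v) else str(int(v)))
        df.columns = ["Source", "Sum of Squares", "df", "Mean Square", "F-value", "p-value"]
        return df.to_string(index=False)


def _cap_f(num_ms: float, den_ms: float) -> tuple[float, float, int]:
    """F ratio with a capped sentinel when the denominator vanishes."""
    if den_ms <= 0:
        return F_CAP, 0.0, 1
    return num_ms / den_ms, np.nan, 0


def anova(fitres: FitResult) -> AnovaTable:
    """Mixture ANOVA of a fitted model on its transformed scale.

    Linear Mixture carries the Type I (sequential) SS of the q linear
    terms after the mean; each non-linear term carries its partial
    (drop-one) SS from the full model, tested against the residual mean
    square.  The residual is split into lack of fit and pure error from
    the design's replicate groups; lack of fit is tested against pure
    error.
    """
    design = fitres.design
    model = fitres.model
    z = fitres.y_transformed
    n, p = fitres.n, fitres.p
    sst = fitres.ss_total
    rss = fitres.ss_residual
    ss_model = sst - rss
    df_model = p - 1
    df_resid = n - p
    ms_resid = rss / df_resid if df_resid > 0 else 0.0

    def f_and_p(ss, df):
        if df_resid <= 0 or ms_resid <= 0:
            return F_CAP, 0.0
        fval = (ss / df) / ms_resid
        if fval > F_CAP:  # numerically perfect fit
            return F_CAP, 0.0
        return fval, float(stats.f.sf(fval, df, df_resid))

    rows = []
    fval, pval = f_and_p(ss_model, df_model)
    rows.append(("Model", ss_model, df_model, ss_model / df_model, fval, pval))

    # Type I SS of the linear blending terms, entered right after the mean
    q = design.q
    linear_terms = [t for t in model.terms if t.is_linear]
    Xl = model_matrix(design.as_array(), linear_terms)
    beta_l, *_ = np.linalg.lstsq(Xl, z, rcond=None)
    ss_linear = sst - float(((z - Xl @ beta_l) ** 2).sum())
    df_linear = q - 1
    fval, pval = f_and_p(ss_linear, df_linear)
    rows.append(("Linear Mixture", ss_linear, df_linear, ss_linear / df_linear, fval, pval))

    # partial (drop-one) SS for every non-linear term
    X = model_matrix(design.as_array(), model.terms)
    for k, term in enumerate(model.terms):
        if term.is_linear:
            continue
        Xr = np.delete(X, k, axis=1)
        br, *_ = np.linalg.lstsq(Xr, z, rcond=None)
        ss_term = float(((z - Xr @ br) ** 2).sum()) - rss
        fval, pval = f_and_p(ss_term, 1)
        rows.append((term_name(term), ss_term, 1, ss_term, fval, pval))

    rows.append(("Residual", rss, df_resid,
                 ms_resid if df_resid > 0 else np.nan, np.nan, np.nan))

    ss_pe = 0.0
    for g in design.replicate_groups:
        zg = z[g]
        ss_pe += float(((zg - zg.mean()) ** 2).sum())
    df_pe = design.pure_error_df
    lof_omitted = df_pe == 0
    if not lof_omitted:
        ss_lof = rss - ss_pe
        df_lof = df_resid - df_pe
        ms_pe = ss_pe / df_pe
        if df_lof > 0:
            ms_lof = ss_lof / df_lof
            if ms_pe <= 0 or ms_lof / ms_pe > F_CAP:
                f_lof, p_lof = F_CAP, 0.0
            else:
                f_lof = ms_lof / ms_pe
                p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            ms_lof, f_lof, p_lof = np.nan, np.nan, np.nan
        rows.append(("Lack of Fit", ss_lof, df_lof, ms_lof, f_lof, p_lof))
        rows.append(("Pure Error", ss_pe, df_pe, ms_pe, np.nan, np.nan))
    rows.append(("Cor Total", sst, n - 1, np.nan, np.nan, np.nan))

    frame = pd.DataFrame(rows, columns=["source", "ss", "df", "ms", "f", "p"])
    return AnovaTable(rows=frame, lof_omitted=lof_omitted)


def reduce_model(
    design: MixtureDesign, response, model: ModelSpec, alpha: float = 0.05
) -> ModelSpec:
    """Backward elimination of non-significant non-linear terms.

    Repeatedly drops the non-linear term with the largest partial-F
    p-value above ``alpha`` and refits, until every remaining non-linear
    term is significant.  Linear blending terms are never dropped.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    terms = list(model.terms)
    while True:
        spec = ModelSpec(model.response, terms, model.transform, model.units)
        res = fit(design, response, spec)
        tab = anova(res)
        worst, worst_p = None, alpha
        for t in spec.nonlinear_terms:
            pv = tab[term_name(t)]["p"]
            if np.isnan(pv):
                continue
            if pv > worst_p:
                worst, worst_p = t, pv
        if worst is None:
            return spec
        terms = [t for t in terms if t != worst]


def predict(fitres: FitResult, blend) -> float:
    """Evaluate the fitted model at a blend, back-transformed to original units.

    A negative prediction on the sqrt scale is clamped to zero with a
    warning (the back-transform would otherwise silently square it into a
    positive value).
    """
    if isinstance(blend, Blend):
        x = blend.as_array()
    else:
        x = Blend(blend).as_array()
    zhat = (model_matrix(x[None, :], fitres.model.terms) @ fitres.coefficients).item()
    tr = fitres.model.transform
    if tr.name == "sqrt" and zhat < 0:
        warnings.warn(
            f"negative sqrt-scale prediction ({zhat:.4g}) clamped to 0", RuntimeWarning
        )
        zhat = 0.0
    return float(tr.inverse(zhat))
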