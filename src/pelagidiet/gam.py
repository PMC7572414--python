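"""Penalized-spline additive regression with AIC stepwise selection.

Models of the form

    g(E[y]) = beta_0 + sum_j f_j(x_j) + factor effects

where each f_j is a cubic regression spline with basis dimension 4 (the
small basis deliberately limits wiggliness), penalized by its integrated
squared second derivative.  Smoothing parameters are chosen by GCV;
families are gaussian-identity, gaussian-log (log-transformed response
with Gaussian errors) and gamma-log (penalized IRLS).  The family is
chosen by Shapiro-Wilk normality of the raw then log response.  Term
selection is forward-then-backward stepwise on AIC with a decrease
threshold of 2 (ties resolved toward fewer terms).

Effective degrees of freedom (edf) per smooth are the trace of the
influence map restricted to that smooth's (sum-to-zero centered) block:
heavy penalization collapses a smooth to its linear component (edf -> 1),
no penalization saturates the centered basis (edf -> k - 1 = 3).

Collinearity screening reports pairwise Pearson correlations and
generalized variance-inflation factors (GVIF, determinant-ratio form),
flagging |r| >= 0.70 or GVIF >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import solve
from scipy.stats import shapiro
import scipy.stats as sps

__all__ = [
    "SmoothBasis",
    "AdditiveModelFit",
    "CollinearityReport",
    "collinearity_diagnostics",
    "choose_family",
    "fit_additive_model",
    "stepwise_select",
]

FAMILIES = {"gaussian-identity", "gaussian-log", "gamma-log"}
_DEGREE = 3


# ---------------------------------------------------------------------------
# spline basis with exact curvature penalty


class SmoothBasis:
    """Cubic B-spline basis of dimension k with curvature penalty.

    Knots are placed at quantiles of the training covariate (with k = 4
    there are no interior knots, so the basis spans cubics on the data
    range).  The penalty matrix P_ij = integral of B_i'' B_j'' is computed
    exactly by Gauss-Legendre quadrature (the integrand is piecewise
    quadratic).  The basis is centered (columns sum to zero over the
    training data) to absorb the identifiability constraint; the centered
    block has k - 1 columns and the penalty's null space within it is the
    linear trend.
    """

    def __init__(self, x: np.ndarray, k: int = 4):
        x = np.asarray(x, dtype=float)
        if k < 4:
            raise ValueError("basis dimension must be >= 4 for cubics")
        lo, hi = x.min(), x.max()
        if hi <= lo:
            raise ValueError("constant covariate cannot be smoothed")
        n_interior = k - _DEGREE - 1
        interior = (np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
                    if n_interior > 0 else np.array([]))
        self.t = np.concatenate([[lo] * (_DEGREE + 1), interior,
                                 [hi] * (_DEGREE + 1)])
        self.k = k
        self.lo, self.hi = lo, hi
        full = self._design(x)
        self.col_means = full.mean(axis=0)
        # absorb the sum-to-zero constraint: Z spans null(1'B)
        c = full.sum(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(c)
        self.Z = vt[1:].T                       # k x (k-1)
        pen = self.Z.T @ self._raw_penalty() @ self.Z
        # normalize to unit spectral norm: lambda becomes dimensionless and
        # fits are invariant to affine rescaling of the covariate
        top = np.linalg.eigvalsh(pen).max()
        self.penalty = pen / top if top > 0 else pen

    def _design(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.lo, self.hi)
        return BSpline.design_matrix(xc, self.t, _DEGREE).toarray()

    def _raw_penalty(self) -> np.ndarray:
        t, k = self.t, self.k
        p = np.zeros((k, k))
        # 2nd derivatives of the basis functions as BSpline objects
        d2 = [BSpline(t, np.eye(k)[i], _DEGREE).derivative(2) for i in range(k)]
        gauss_x, gauss_w = np.polynomial.legendre.leggauss(3)
        breaks = np.unique(t)
        for a, b in zip(breaks[:-1], breaks[1:]):
            mid, half = 0.5 * (a + b), 0.5 * (b - a)
            xs = mid + half * gauss_x
            vals = np.array([f(xs) for f in d2])       # k x 3
            p += half * (vals * gauss_w) @ vals.T
        return p

    def transform(self, x) -> np.ndarray:
        b = self._design(np.asarray(x, dtype=float))
        return (b - self.col_means) @ self.Z


# ---------------------------------------------------------------------------
# model terms


def _encode_factor(values: pd.Series, levels=None):
    cat = pd.Categorical(values, categories=levels)
    levels = list(cat.categories)
    dummies = pd.get_dummies(cat, drop_first=True).to_numpy(dtype=float)
    names = [f"{levels[0]}->{lv}" for lv in levels[1:]]
    return dummies, names, levels


@dataclass
class AdditiveModelFit:
    response: str
    family: str
    smooth_terms: list
    factor_terms: list
    edf: dict                 # per smooth term
    edf_total: float
    coefficients: pd.DataFrame   # parametric coefficients with SE
    aic: float
    deviance_explained: float    # percent
    smoothing_params: dict
    fitted_values: np.ndarray
    f_statistics: dict = field(default_factory=dict)  # approximate
    _predict_ctx: dict = field(default_factory=dict, repr=False)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        ctx = self._predict_ctx
        cols = [np.ones((len(data), 1))]
        for term, (levels, _) in zip(self.factor_terms, ctx["factors"]):
            d, _, _ = _encode_factor(data[term], levels=levels)
            cols.append(d)
        for term in self.smooth_terms:
            cols.append(ctx["bases"][term].transform(data[term].to_numpy()))
        eta = np.concatenate(cols, axis=1) @ ctx["beta"]
        if self.family == "gamma-log":
            return np.exp(eta)
        if self.family == "gaussian-log":
            return np.exp(eta)  # response-scale point prediction (no bias adj)
        return eta


def _deviance(y, mu, family):
    if family.startswith("gaussian"):
        return float(((y - mu) ** 2).sum())
    # gamma deviance
    return float(2 * np.sum(-np.log(y / mu) + (y - mu) / mu))


def _pirls(y, X, lam_blocks, family, max_iter=50, tol=1e-8):
    """Penalized (I)RLS.  Returns beta, edf diag, deviance, final weights."""
    n, p = X.shape
    P = np.zeros((p, p))
    for sl, lam, pen in lam_blocks:
        P[sl, sl] = lam * pen
    if family != "gamma-log":
        xtx = X.T @ X
        beta = solve(xtx + P, X.T @ y, assume_a="pos")
        F = solve(xtx + P, xtx, assume_a="pos")
        mu = X @ beta
        return beta, np.diag(F), _deviance(y, mu, family), np.ones(n), F
    # gamma with log link: working weights are 1, z = eta + (y - mu)/mu
    eta = np.log(np.clip(y, np.quantile(y, 0.05), None))
    beta = None
    for _ in range(max_iter):
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        xtx = X.T @ X
        beta_new = solve(xtx + P, X.T @ z, assume_a="pos")
        eta_new = X @ beta_new
        if beta is not None and np.max(np.abs(eta_new - eta)) < tol:
            beta, eta = beta_new, eta_new
            break
        beta, eta = beta_new, eta_new
    else:
        raise RuntimeError("penalized IRLS did not converge")
    F = solve(X.T @ X + P, X.T @ X, assume_a="pos")
    mu = np.exp(eta)
    return beta, np.diag(F), _deviance(y, mu, family), np.ones(n), F


def _gcv_score(y, X, lam_blocks, family):
    _, edf_diag, dev, _, _ = _pirls(y, X, lam_blocks, family)
    n = len(y)
    edf = edf_diag.sum()
    denom = max(n - edf, 1e-8)
    return n * dev / denom**2


def fit_additive_model(
    data: pd.DataFrame,
    response: str,
    smooth_terms=(),
    factor_terms=(),
    family: str = "gaussian-identity",
    basis_dim: int = 4,
    lambdas: dict | None = None,
    lambda_grid=None,
) -> AdditiveModelFit:
    """Fit a penalized-spline additive model.

    ``smooth_terms`` are numeric column names (cubic spline, basis
    dimension ``basis_dim``); ``factor_terms`` are categorical columns
    (treatment coding, first level reference).  Smoothing parameters are
    chosen per term by coordinate-wise GCV grid search unless supplied in
    ``lambdas``.  Interaction candidates named "a:b" are handled as linear
    product terms.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; one of {sorted(FAMILIES)}")
    y_raw = data[response].to_numpy(dtype=float)
    if family == "gaussian-log" or family == "gamma-log":
        bad = np.where(y_raw <= 0)[0]
        if len(bad):
            raise ValueError(
                f"{family} requires a positive response; offending rows: "
                f"{bad[:10].tolist()}")
    y = np.log(y_raw) if family == "gaussian-log" else y_raw

    cols = [np.ones((len(data), 1))]
    names = ["Intercept"]
    factors_ctx = []
    for term in factor_terms:
        d, dnames, levels = _encode_factor(data[term])
        if d.shape[1] == 0:
            raise ValueError(f"factor {term!r} has a single level")
        cols.append(d)
        names += [f"{term}[{nm}]" for nm in dnames]
        factors_ctx.append((levels, d.shape[1]))

    smooth_terms = list(smooth_terms)
    bases, blocks = {}, []
    start = sum(c.shape[1] for c in cols)
    for term in smooth_terms:
        if ":" in term:  # linear interaction surrogate
            a, b = term.split(":")
            prod = (data[a].to_numpy(float) * data[b].to_numpy(float))[:, None]
            prod = prod - prod.mean()
            cols.append(prod)
            names.append(term)
            start += 1
            continue
        x = data[term].to_numpy(dtype=float)
        basis = SmoothBasis(x, k=basis_dim)
        bases[term] = basis
        block = basis.transform(x)
        cols.append(block)
        names += [f"s({term}).{i}" for i in range(block.shape[1])]
        blocks.append((term, slice(start, start + block.shape[1]), basis.penalty))
        start += block.shape[1]

    X = np.concatenate(cols, axis=1)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} too small for {p} coefficients")

    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 8, 13)
    lam = {t: (lambdas or {}).get(t, 1.0) for t, _, _ in blocks}
    if lambdas is None and blocks:
        # coordinate-descent GCV with a parsimony rule: among candidates
        # whose GCV is within 1% of the minimum, take the largest lambda
        # (smoothest fit); plain argmin-GCV is known to undersmooth when
        # the profile is nearly flat
        for _ in range(2):
            for term, sl, pen in blocks:
                scores = []
                for cand in lambda_grid:
                    trial = dict(lam, **{term: cand})
                    lb = [(s, trial[t2], p2) for t2, s, p2 in blocks]
                    scores.append(_gcv_score(y, X, lb, family))
                scores = np.asarray(scores)
                ok = scores <= scores.min() * 1.01
                lam[term] = float(lambda_grid[np.where(ok)[0].max()])

    lam_blocks = [(sl, lam[t], pen) for t, sl, pen in blocks]
    beta, edf_diag, dev, w, F = _pirls(y, X, lam_blocks, family)

    # null deviance for D
    null_lb = []
    ones = np.ones((n, 1))
    if family == "gamma-log":
        beta0, _, null_dev, _, _ = _pirls(y, ones, null_lb, family)
    else:
        null_dev = _deviance(y, np.full(n, y.mean()), family)
    D = 100.0 * (1.0 - dev / null_dev) if null_dev > 0 else 0.0

    edf_total = float(edf_diag.sum())
    edf = {t: float(edf_diag[sl].sum()) for t, sl, _ in blocks}

    # scale and parametric coefficient SEs
    phi = dev / max(n - edf_total, 1e-8)
    Vb = np.linalg.inv(X.T @ X + _assemble_penalty(p, lam_blocks)) * phi
    se = np.sqrt(np.diag(Vb))
    n_param = 1 + sum(k for _, k in factors_ctx) + sum(
        1 for t in smooth_terms if ":" in t)
    param_idx = [i for i in range(p) if not names[i].startswith("s(")][:n_param]
    coef = pd.DataFrame({"estimate": beta[param_idx], "se": se[param_idx]},
                        index=[names[i] for i in param_idx])

    # log-likelihood-based AIC with effective df
    if family == "gamma-log":
        mu = np.exp(X @ beta)
        shape = 1.0 / max(phi, 1e-12)
        ll = float(sps.gamma.logpdf(y, a=shape, scale=mu / shape).sum())
    else:
        sig2 = dev / n
        ll = -0.5 * n * (np.log(2 * np.pi * sig2) + 1.0)
    aic = -2.0 * ll + 2.0 * (edf_total + 1.0)

    fitted = np.exp(X @ beta) if family != "gaussian-identity" else X @ beta

    fstat = {}
    for t, sl, _ in blocks:
        contrib = X[:, sl] @ beta[sl]
        fstat[t] = float((contrib @ contrib) / max(edf[t], 1e-8) / max(phi, 1e-12))

    return AdditiveModelFit(
        response=response, family=family,
        smooth_terms=smooth_terms, factor_terms=list(factor_terms),
        edf=edf, edf_total=edf_total, coefficients=coef, aic=float(aic),
        deviance_explained=float(np.clip(D, 0.0, 100.0)),
        smoothing_params=lam, fitted_values=fitted, f_statistics=fstat,
        _predict_ctx={"beta": beta, "bases": bases, "factors": factors_ctx},
    )


def _assemble_penalty(p, lam_blocks):
    P = np.zeros((p, p))
    for sl, lam, pen in lam_blocks:
        P[sl, sl] = lam * pen
    return P


# ---------------------------------------------------------------------------
# family choice and collinearity screening


@dataclass
class FamilyDecision:
    family: str
    path: list  # (step, W, p_value)


def choose_family(y, alpha: float = 0.05) -> FamilyDecision:
    """Shapiro-Wilk decision path: raw normal -> gaussian-identity; log
    normal -> gaussian-log; otherwise gamma-log (requires y > 0)."""
    y = np.asarray(y, dtype=float)
    if len(y) < 3 or not np.isfinite(y).all():
        raise ValueError("need >= 3 finite response values")
    w, p = shapiro(y)
    path = [("shapiro_raw", float(w), float(p))]
    if p >= alpha:
        return FamilyDecision("gaussian-identity", path)
    bad = np.where(y <= 0)[0]
    if len(bad):
        raise ValueError(
            f"non-normal response with non-positive values cannot take the "
            f"log/gamma path; offending rows: {bad[:10].tolist()}")
    w, p = shapiro(np.log(y))
    path.append(("shapiro_log", float(w), float(p)))
    if p >= alpha:
        return FamilyDecision("gaussian-log", path)
    return FamilyDecision("gamma-log", path)


@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    gvif: pd.Series
    corr_flags: list
    gvif_flags: list

    @property
    def passed(self) -> bool:
        return not self.corr_flags and not self.gvif_flags


def collinearity_diagnostics(
    design: pd.DataFrame,
    corr_threshold: float = 0.70,
    gvif_threshold: float = 3.0,
) -> CollinearityReport:
    """Pearson correlations and determinant-ratio GVIF per term.

    Numeric columns are one term each; categorical/object columns are
    dummy-coded and treated as one multi-df term.  GVIF_j =
    det(R_j) det(R_-j) / det(R) over the model-matrix correlation matrix
    (1 by convention for a single predictor).
    """
    if design.shape[1] < 1 or len(design) < 3:
        raise ValueError("need >= 1 predictor and >= 3 rows")
    for c in design.columns:
        if design[c].nunique() < 2:
            raise ValueError(f"constant predictor {c!r}")

    numeric = design.select_dtypes(include=[np.number])
    corr = numeric.corr(method="pearson") if numeric.shape[1] >= 2 else pd.DataFrame()
    corr_flags = []
    for i, a in enumerate(corr.columns):
        for b in corr.columns[i + 1:]:
            if abs(corr.loc[a, b]) >= corr_threshold:
                corr_flags.append((a, b, float(corr.loc[a, b])))

    # model matrix with term grouping
    mats, spans = [], {}
    pos = 0
    for c in design.columns:
        if c in numeric.columns:
            m = design[[c]].to_numpy(dtype=float)
        else:
            m, _, _ = _encode_factor(design[c])
        mats.append(m)
        spans[c] = slice(pos, pos + m.shape[1])
        pos += m.shape[1]
    M = np.concatenate(mats, axis=1)
    if M.shape[1] == 1:
        gvif = pd.Series({design.columns[0]: 1.0})
    else:
        R = np.corrcoef(M, rowvar=False)
        det_r = np.linalg.det(R)
        vals = {}
        for c, sl in spans.items():
            idx = np.arange(M.shape[1])
            own = idx[sl]
            other = np.setdiff1d(idx, own)
            if len(other) == 0:
                vals[c] = 1.0
                continue
            d1 = np.linalg.det(R[np.ix_(own, own)])
            d2 = np.linalg.det(R[np.ix_(other, other)])
            vals[c] = float(d1 * d2 / det_r)
        gvif = pd.Series(vals)
    gvif_flags = [(c, float(v)) for c, v in gvif.items() if v >= gvif_threshold]
    return CollinearityReport(correlations=corr, gvif=gvif,
                              corr_flags=corr_flags, gvif_flags=gvif_flags)


# ---------------------------------------------------------------------------
# stepwise selection


def stepwise_select(
    data: pd.DataFrame,
    response: str,
    candidate_smooths=(),
    candidate_factors=(),
    family: str = "gaussian-identity",
    aic_drop: float = 2.0,
    basis_dim: int = 4,
):
    """Forward-then-backward stepwise term selection on AIC.

    A move is accepted only if it lowers AIC by more than ``aic_drop``;
    ties break toward the smaller model.  Returns ``(best_fit, trace)``
    where the trace lists every evaluated model with its AIC.
    """
    cands = [("s", t) for t in candidate_smooths] + \
            [("f", t) for t in candidate_factors]
    if not cands:
        raise ValueError("no candidate terms")

    def fit_with(included):
        sm = [t for kind, t in included if kind == "s"]
        fa = [t for kind, t in included if kind == "f"]
        return fit_additive_model(data, response, smooth_terms=sm,
                                  factor_terms=fa, family=family,
                                  basis_dim=basis_dim)

    trace = []
    included: list = []
    # intercept-only AIC baseline via a null fit on any single term? fit with
    # no terms: design is intercept only
    current = fit_with(included)
    trace.append(("start", tuple(included), current.aic))

    improved = True
    while improved:  # forward
        improved = False
        best_add, best_fit = None, None
        for cand in cands:
            if cand in included:
                continue
            try:
                f = fit_with(included + [cand])
            except Exception as err:  # rank deficiency etc.
                trace.append(("fail_add", cand, str(err)))
                continue
            trace.append(("try_add", cand, f.aic))
            if f.aic < current.aic - aic_drop and \
                    (best_fit is None or f.aic < best_fit.aic):
                best_add, best_fit = cand, f
        if best_add is not None:
            included.append(best_add)
            current = best_fit
            improved = True

    improved = True
    while improved and included:  # backward
        improved = False
        best_rm, best_fit = None, None
        for cand in list(included):
            f = fit_with([c for c in included if c != cand])
            trace.append(("try_drop", cand, f.aic))
            if f.aic < current.aic + aic_drop and \
                    (best_fit is None or f.aic < best_fit.aic):
                # dropping is accepted if AIC does not worsen by > aic_drop
                if f.aic <= current.aic:
                    best_rm, best_fit = cand, f
        if best_rm is not None:
            included.remove(best_rm)
            current = best_fit
            improved = True

    trace.append(("final", tuple(included), current.aic))
    return current, trace
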