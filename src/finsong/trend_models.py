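"""Seasonal trend models for INI and note spectral characteristics.

Two candidate generalized additive mixed models describe INI seasonality:

- **M1** ``INI ~ s(month) + s(song_year)`` — one global cyclic seasonal
  shape shared by all song years plus a smooth year effect;
- **M2** ``INI ~ song_year + s(month, by=song_year)`` — a categorical year
  effect with a separate cyclic seasonal shape per year.

Both use a Gamma family (INIs are positive, right-skewed interval data)
with a log link, and a per-singer random intercept to absorb repeated
measures within a singer.  The month smooth is a cyclic cubic P-spline
(periodic cardinal B-spline basis, cyclic second-difference penalty) with
basis dimension up to 12, so predictions join smoothly across the
December -> January boundary.  Model choice is by minimum AIC.

Spectral-characteristic models (center frequency, peak frequency, 90%
bandwidth of high-SNR notes) use the same machinery with a Gamma family,
identity link, month basis dimension up to 10, and a per-date random
intercept.

The engine is a penalized IRLS fit: random intercepts enter as
ridge-penalized dummy coefficients, smoothing parameters (including the
random-effect variance ratio) are chosen by minimizing a Laplace
approximation to the negative marginal likelihood — the mixed-model (ML)
treatment, under which a group effect with no real variance is shrunk
away — effective degrees of freedom come from the trace of the hat
matrix, and AIC uses the Gamma log-likelihood at the estimated dispersion
with ``edf + 1`` parameters, comparable across model forms fitted to the
same data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "Term",
    "TrendFit",
    "fit_ini_model",
    "fit_spectral_model",
    "select_model",
    "predict_monthly",
    "cyclic_spline_basis",
    "bspline_basis",
]

MAX_PIRLS_ITER = 200
PIRLS_TOL = 1e-8


# ---------------------------------------------------------------------------
# spline bases
# ---------------------------------------------------------------------------

def _cardinal_cubic(u: np.ndarray) -> np.ndarray:
    """Cardinal cubic B-spline kernel, support [-2, 2], unit knot spacing."""
    a = np.abs(u)
    out = np.zeros_like(a)
    m1 = a < 1
    m2 = (a >= 1) & (a < 2)
    out[m1] = (4 - 6 * a[m1] ** 2 + 3 * a[m1] ** 3) / 6.0
    out[m2] = (2 - a[m2]) ** 3 / 6.0
    return out


def cyclic_spline_basis(x: np.ndarray, k: int = 12, period: float = 12.0,
                        origin: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Periodic cubic P-spline basis and cyclic difference penalty.

    ``k`` equally spaced knots over one period (placed at month midpoints
    for the default month smooth).  Returns ``(B, S)`` with ``B`` the
    n x k design matrix and ``S`` the cyclic second-order difference
    penalty ``D'D`` (circulant).  The basis is periodic by construction:
    value and derivatives match across the period boundary.
    """
    x = np.asarray(x, dtype=float)
    delta = period / k
    knots = origin + delta * np.arange(k)
    # wrapped distance in knot units
    d = (x[:, None] - knots[None, :]) / delta
    d = (d + k / 2) % k - k / 2
    B = _cardinal_cubic(d)
    idx = np.arange(k)
    D = (np.eye(k)[(idx + 1) % k] - 2 * np.eye(k)
         + np.eye(k)[(idx - 1) % k])
    S = D.T @ D
    return B, S


def bspline_basis(x: np.ndarray, k: int, degree: int = 3
                  ) -> tuple[np.ndarray, np.ndarray, Callable]:
    """Open (non-cyclic) B-spline basis with second-difference penalty.

    Returns ``(B, S, builder)`` where ``builder(new_x)`` evaluates the
    same basis on new data.
    """
    from scipy.interpolate import BSpline

    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("cannot build a spline basis on a constant variable")
    n_inner = max(k - degree - 1, 0)
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    t = np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)]

    def builder(new_x: np.ndarray) -> np.ndarray:
        xx = np.clip(np.asarray(new_x, dtype=float), lo, hi)
        return BSpline.design_matrix(xx, t, degree).toarray()

    B = builder(x)
    m = B.shape[1]
    D = np.diff(np.eye(m), n=2, axis=0)
    return B, D.T @ D, builder


def _sum_to_zero(B: np.ndarray, S: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absorb the sum-to-zero identifiability constraint 1'B beta = 0.

    Returns the reparameterized basis/penalty and the k x (k-1) transform
    ``Z`` (needed to rebuild the constrained basis at prediction time).
    """
    c = B.sum(axis=0)[:, None]
    q, _ = np.linalg.qr(c, mode="complete")
    Z = q[:, 1:]
    return B @ Z, Z.T @ S @ Z, Z


# ---------------------------------------------------------------------------
# model terms
# ---------------------------------------------------------------------------

@dataclass
class Term:
    """One block of the model design matrix."""

    name: str
    kind: str                       # parametric | smooth | random
    build: Callable[[pd.DataFrame], np.ndarray]
    penalty: np.ndarray | None      # None => unpenalized
    n_cols: int
    basis_dim: int = 0              # pre-constraint basis size, for EDF bound


def _intercept_term() -> Term:
    return Term("Intercept", "parametric",
                lambda df: np.ones((len(df), 1)), None, 1)


def _factor_term(name: str, col: str, levels: list) -> Term:
    ref, others = levels[0], levels[1:]

    def build(df: pd.DataFrame) -> np.ndarray:
        v = df[col].to_numpy()
        return np.column_stack([(v == lev).astype(float) for lev in others])

    return Term(name, "parametric", build, None, len(others))


def _cyclic_term(name: str, col: str, k: int, period: float,
                 mask_col: str | None = None,
                 mask_level=None) -> Term:
    def raw(df):
        B, S = cyclic_spline_basis(df[col].to_numpy(float), k=k, period=period)
        return B, S

    # constraint transform computed once on the fitting data via closure
    state: dict = {}

    def build(df: pd.DataFrame) -> np.ndarray:
        B, S = raw(df)
        if "Z" not in state:
            Bc, Sc, Z = _sum_to_zero(B, S)
            state["Z"], state["S"] = Z, Sc
        else:
            Bc = B @ state["Z"]
        if mask_col is not None:
            Bc = Bc * (df[mask_col].to_numpy() == mask_level)[:, None]
        return Bc

    term = Term(name, "smooth", build, None, k - 1, basis_dim=k)
    term._state = state  # type: ignore[attr-defined]
    return term


def _year_smooth_term(name: str, col: str, k: int) -> Term:
    state: dict = {}

    def build(df: pd.DataFrame) -> np.ndarray:
        x = df[col].to_numpy(float)
        if "builder" not in state:
            B, S, builder = bspline_basis(x, k=k)
            Bc, Sc, Z = _sum_to_zero(B, S)
            state.update(builder=builder, Z=Z, S=Sc)
            return Bc
        return state["builder"](x) @ state["Z"]

    term = Term(name, "smooth", build, None, 0, basis_dim=k)
    term._state = state  # type: ignore[attr-defined]
    return term


def _random_term(name: str, col: str, levels: list) -> Term:
    def build(df: pd.DataFrame) -> np.ndarray:
        v = df[col].to_numpy()
        return np.column_stack([(v == lev).astype(float) for lev in levels])

    t = Term(name, "random", build, np.eye(len(levels)), len(levels),
             basis_dim=len(levels))
    return t


# ---------------------------------------------------------------------------
# penalized IRLS engine
# ---------------------------------------------------------------------------

def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


def _pirls(y: np.ndarray, X: np.ndarray, S_blocks: list[tuple[slice, np.ndarray]],
           lambdas: np.ndarray, link: str) -> dict:
    """Penalized IRLS for a Gamma GLM; returns fit state."""
    n, p = X.shape
    S = np.zeros((p, p))
    for lam, (sl, Sj) in zip(lambdas, S_blocks):
        S[sl, sl] += lam * Sj
    mu = np.full(n, y.mean())
    eta = np.log(mu) if link == "log" else mu.copy()
    dev = _gamma_deviance(y, mu)
    beta = np.zeros(p)
    for it in range(MAX_PIRLS_ITER):
        if link == "log":
            w = np.ones(n)
            z = eta + (y - mu) / mu
        else:  # identity
            w = 1.0 / np.maximum(mu, 1e-8) ** 2
            z = y
        XtW = X.T * w
        A = XtW @ X
        beta_new = np.linalg.solve(A + S + 1e-10 * np.eye(p), XtW @ z)
        eta = X @ beta_new
        if link == "log":
            eta = np.clip(eta, -30, 30)
            mu = np.exp(eta)
        else:
            mu = eta
            if np.any(mu <= 0):
                warnings.warn("identity-link Gamma fit produced non-positive "
                              "fitted values; clamping", RuntimeWarning)
                mu = np.maximum(mu, 1e-6)
        dev_new = _gamma_deviance(y, mu)
        beta = beta_new
        if abs(dev_new - dev) < PIRLS_TOL * (abs(dev_new) + 0.1):
            dev = dev_new
            break
        dev = dev_new
    else:
        warnings.warn("PIRLS did not converge within "
                      f"{MAX_PIRLS_ITER} iterations", RuntimeWarning)
    # hat/EDF and covariance at convergence
    if link == "log":
        w = np.ones(n)
    else:
        w = 1.0 / np.maximum(mu, 1e-8) ** 2
    XtW = X.T * w
    A = XtW @ X
    Ainv = np.linalg.inv(A + S + 1e-10 * np.eye(p))
    F = Ainv @ A
    edf_total = float(np.trace(F))
    return dict(beta=beta, mu=mu, eta=eta, dev=dev, F=F, Ainv=Ainv,
                edf=edf_total, n=n, converged=it < MAX_PIRLS_ITER - 1)


def _gcv(y: np.ndarray, X: np.ndarray, S_blocks, log_lam: np.ndarray,
         link: str) -> float:
    fit = _pirls(y, X, S_blocks, 10.0 ** log_lam, link)
    n, edf = fit["n"], fit["edf"]
    denom = max(n - edf, 1.0)
    return n * fit["dev"] / denom ** 2


def _laml(y: np.ndarray, X: np.ndarray, S_blocks, ranks: list[int],
          log_lam: np.ndarray, link: str, phi: float) -> float:
    """Negative Laplace-approximate marginal likelihood (up to constants).

    ``dev/phi + beta'S beta/phi + log|X'WX + S| - log|S|_+``; the
    pseudo-determinant term reduces to ``sum(rank_j * log lambda_j)`` plus
    a lambda-independent constant.  Behaves like (RE)ML for the
    ridge-penalized random-intercept blocks: with no real between-group
    variance the criterion drives their lambda up and the effective
    degrees of freedom toward zero.
    """
    lam = 10.0 ** log_lam
    fit = _pirls(y, X, S_blocks, lam, link)
    beta, mu = fit["beta"], fit["mu"]
    p = X.shape[1]
    S = np.zeros((p, p))
    rank_term = 0.0
    for l, r, (sl, Sj) in zip(lam, ranks, S_blocks):
        S[sl, sl] += l * Sj
        rank_term += r * np.log(l)
    w = (np.ones(len(y)) if link == "log"
         else 1.0 / np.maximum(mu, 1e-8) ** 2)
    A = (X.T * w) @ X
    pen = float(beta @ S @ beta)
    _, logdet = np.linalg.slogdet(A + S + 1e-10 * np.eye(p))
    return (fit["dev"] + pen) / phi + logdet - rank_term


@dataclass
class TrendFit:
    """A fitted seasonal model with its summaries and prediction machinery."""

    form: str
    terms: list[Term]
    beta: np.ndarray
    cov: np.ndarray                # Bayesian posterior covariance of beta
    slices: dict[str, slice]
    lambdas: dict[str, float]
    edf_by_term: dict[str, float]
    edf: float
    aic: float
    r2: float                      # adjusted deviance-explained
    scale: float
    deviance: float
    null_deviance: float
    n: int
    link: str
    fitted: np.ndarray
    response: np.ndarray
    converged: bool
    fitted_years: tuple[int, ...] = ()
    data_fingerprint: float = 0.0
    param_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    smooth_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def design(self, df: pd.DataFrame, population: bool = True) -> np.ndarray:
        cols = []
        for t in self.terms:
            Xt = t.build(df)
            if population and t.kind == "random":
                Xt = np.zeros_like(Xt)
            cols.append(Xt)
        return np.hstack(cols)

    def predict(self, df: pd.DataFrame, se: bool = False,
                population: bool = True):
        """Response-scale predictions (population level by default)."""
        X = self.design(df, population=population)
        eta = X @ self.beta
        mu = np.exp(eta) if self.link == "log" else eta
        if not se:
            return mu
        se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X),
                                    0.0))
        return mu, eta, se_eta

    def diagnostics(self) -> pd.DataFrame:
        """Residual table: fitted values, deviance residuals, Q-Q quantiles."""
        y, mu = self.response, self.fitted
        d = 2.0 * ((y - mu) / mu - np.log(y / mu))
        r = np.sign(y - mu) * np.sqrt(np.maximum(d, 0.0))
        order = np.argsort(r)
        theo = stats.norm.ppf((np.arange(1, len(r) + 1) - 0.5) / len(r))
        out = pd.DataFrame({"fitted": mu, "deviance_resid": r})
        out["qq_theoretical"] = np.empty(len(r))
        out.iloc[order, out.columns.get_loc("qq_theoretical")] = theo
        return out

    def summary_table(self) -> pd.DataFrame:
        """Parametric and smooth term summaries in one long table."""
        a = self.param_table.assign(part="parametric")
        b = self.smooth_table.assign(part="smooth")
        return pd.concat([a, b], ignore_index=True)


def _assemble_and_fit(df: pd.DataFrame, y: np.ndarray, terms: list[Term],
                      link: str, form: str,
                      optimize_lambda: bool = True,
                      maxiter: int = 60,
                      criterion: str = "laml") -> TrendFit:
    # build design blocks on the fitting data (fixes constraint transforms)
    blocks = [t.build(df) for t in terms]
    for t, B in zip(terms, blocks):
        t.n_cols = B.shape[1]
        if t.kind == "smooth" and t.penalty is None:
            t.penalty = t._state["S"]  # type: ignore[attr-defined]
    X = np.hstack(blocks)
    slices, S_blocks, pen_names = {}, [], []
    start = 0
    for t in terms:
        sl = slice(start, start + t.n_cols)
        slices[t.name] = sl
        if t.penalty is not None:
            S_blocks.append((sl, t.penalty))
            pen_names.append(t.name)
        start += t.n_cols

    x0 = np.zeros(len(S_blocks))
    if S_blocks and optimize_lambda:
        if criterion == "laml":
            fit0 = _pirls(y, X, S_blocks, np.ones(len(S_blocks)), link)
            phi0 = float(np.sum((y - fit0["mu"]) ** 2 / fit0["mu"] ** 2)
                         / max(len(y) - fit0["edf"], 1.0))
            ranks = [int(np.linalg.matrix_rank(Sj)) for _, Sj in S_blocks]
            objective = lambda ll: _laml(y, X, S_blocks, ranks, ll, link,
                                         phi0)
        else:
            objective = lambda ll: _gcv(y, X, S_blocks, ll, link)
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options=dict(maxiter=maxiter, xatol=0.05, fatol=1e-10))
        log_lam = res.x
    else:
        log_lam = x0
    lam = 10.0 ** log_lam
    fit = _pirls(y, X, S_blocks, lam, link)

    n, p = X.shape
    mu, beta, F = fit["mu"], fit["beta"], fit["F"]
    edf = fit["edf"]
    scale = float(np.sum((y - mu) ** 2 / mu ** 2) / max(n - edf, 1.0))
    dev = fit["dev"]
    null_mu = np.full(n, y.mean())
    null_dev = _gamma_deviance(y, null_mu)
    # Gamma log-likelihood at alpha = 1/scale
    alpha = 1.0 / max(scale, 1e-12)
    ll = float(np.sum(alpha * np.log(alpha * y / mu) - alpha * y / mu
                      - np.log(y) - special.gammaln(alpha)))
    aic = -2.0 * ll + 2.0 * (edf + 1.0)
    r2 = 1.0 - (dev / max(n - edf, 1.0)) / (null_dev / (n - 1))
    cov = fit["Ainv"] * scale

    edf_by_term = {t.name: float(np.trace(F[slices[t.name], slices[t.name]]))
                   for t in terms}
    lambdas = dict(zip(pen_names, lam))

    # per-term inference tables
    prows, srows = [], []
    df_resid = max(n - edf, 1.0)
    for t in terms:
        sl = slices[t.name]
        if t.kind == "parametric":
            for j in range(sl.start, sl.stop):
                se = float(np.sqrt(max(cov[j, j], 0.0)))
                tval = beta[j] / se if se > 0 else np.inf
                prows.append(dict(
                    term=t.name if t.n_cols == 1 else f"{t.name}[{j - sl.start}]",
                    estimate=float(beta[j]), se=se, t=float(tval),
                    p=float(2 * stats.t.sf(abs(tval), df_resid))))
        elif t.kind == "smooth":
            b = beta[sl]
            Vb = cov[sl, sl]
            e = edf_by_term[t.name]
            r = max(1, int(round(e)))
            T = float(b @ np.linalg.pinv(Vb, rcond=1e-10) @ b)
            fstat = T / r
            srows.append(dict(term=t.name, edf=e, ref_df=t.basis_dim - 1,
                              F=fstat,
                              p=float(stats.f.sf(fstat, r, df_resid))))
    tf = TrendFit(
        form=form, terms=terms, beta=beta, cov=cov, slices=slices,
        lambdas=lambdas, edf_by_term=edf_by_term, edf=edf, aic=aic, r2=r2,
        scale=scale, deviance=dev, null_deviance=null_dev, n=n, link=link,
        fitted=mu, response=y, converged=fit["converged"],
        data_fingerprint=float(np.sum(np.sort(y))),
        param_table=pd.DataFrame(prows), smooth_table=pd.DataFrame(srows))
    return tf


# ---------------------------------------------------------------------------
# public model fits
# ---------------------------------------------------------------------------

def _check_ini_frame(df: pd.DataFrame, response: str) -> None:
    if (df[response] <= 0).any():
        raise ValueError(f"{response} must be strictly positive for a "
                         "Gamma/log model")
    if df["month"].nunique() < 2:
        raise ValueError("singular design: only one month present")


def fit_ini_model(df: pd.DataFrame, form: str = "m1",
                  month_k: int = 12, year_k: int = 5,
                  maxiter: int = 60) -> TrendFit:
    """Fit one of the two candidate INI seasonality GAMMs.

    ``df`` needs columns ``ini`` (s), ``month`` (1..12), ``song_year``
    (int) and ``singer`` (id).  ``form='m1'`` fits the shared-seasonality
    model, ``'m2'`` the per-year seasonality model; both are Gamma with a
    log link and a per-singer random intercept.  AIC values are
    comparable across the two forms on identical data.
    """
    form = form.lower()
    if form not in ("m1", "m2"):
        raise ValueError(f"form must be 'm1' or 'm2', got {form!r}")
    _check_ini_frame(df, "ini")
    df = df.reset_index(drop=True)
    y = df["ini"].to_numpy(float)
    years = sorted(df["song_year"].unique())
    singers = sorted(df["singer"].unique())

    terms: list[Term] = [_intercept_term()]
    if form == "m1":
        terms.append(_cyclic_term("s(Month)", "month", k=month_k, period=12))
        if len(years) >= 3:
            terms.append(_year_smooth_term("s(SongYear)", "song_year",
                                           k=min(year_k, len(years))))
        else:
            # too few distinct years for a smooth: centered linear year term
            mean_year = float(np.mean(years))
            terms.append(Term(
                "SongYear(linear)", "parametric",
                lambda d, m=mean_year: (d["song_year"].to_numpy(float)[:, None]
                                        - m),
                None, 1))
    else:
        terms.append(_factor_term("SongYear", "song_year", years))
        for yr in years:
            terms.append(_cyclic_term(f"s(Month):SY{yr}", "month", k=month_k,
                                      period=12, mask_col="song_year",
                                      mask_level=yr))
    terms.append(_random_term("re(Singer)", "singer", singers))
    fit = _assemble_and_fit(df, y, terms, link="log", form=form,
                            maxiter=maxiter)
    fit.fitted_years = tuple(years)
    return fit


def fit_spectral_model(df: pd.DataFrame, response: str,
                       month_k: int = 10, year_k: int = 5,
                       maxiter: int = 60) -> TrendFit:
    """GAM for a spectral characteristic of high-SNR notes.

    ``response`` is a column of ``df`` (center/peak frequency or 90%
    bandwidth, Hz); predictors are ``month`` and ``song_year``, with a
    per-``date`` random intercept.  Gamma family, identity link (fitted
    means can in principle go non-positive on pathological data; the fit
    warns and clamps rather than failing silently).
    """
    _check_ini_frame(df, response)
    df = df.reset_index(drop=True)
    y = df[response].to_numpy(float)
    years = sorted(df["song_year"].unique())
    dates = sorted(df["date"].unique())
    terms: list[Term] = [_intercept_term(),
                         _cyclic_term("s(Month)", "month", k=month_k,
                                      period=12)]
    if len(years) >= 3:
        terms.append(_year_smooth_term("s(SongYear)", "song_year",
                                       k=min(year_k, len(years))))
    elif len(years) == 2:
        mean_year = float(np.mean(years))
        terms.append(Term("SongYear(linear)", "parametric",
                          lambda d, m=mean_year:
                          (d["song_year"].to_numpy(float)[:, None] - m),
                          None, 1))
    terms.append(_random_term("re(Date)", "date", dates))
    fit = _assemble_and_fit(df, y, terms, link="identity",
                            form=f"gam({response})", maxiter=maxiter)
    fit.fitted_years = tuple(years)
    return fit


def select_model(fits: list[TrendFit]) -> TrendFit:
    """Minimum-AIC selection among fits of the same data.

    Ties go to the simpler model (smaller EDF).  Fits on different data
    (different n or response values) raise.
    """
    if not fits:
        raise ValueError("no fits to select from")
    if len(fits) == 1:
        return fits[0]
    f0 = fits[0]
    for f in fits[1:]:
        if f.n != f0.n or not np.isclose(f.data_fingerprint,
                                         f0.data_fingerprint):
            raise ValueError("fits were computed on different data; AICs are "
                             "not comparable")
    return min(fits, key=lambda f: (round(f.aic, 6), f.edf))


def predict_monthly(fit: TrendFit, song_year: int,
                    months: np.ndarray | None = None,
                    singer: str | None = None) -> pd.DataFrame:
    """Monthly expected response with a 95% interval, population level.

    The prediction is periodic: month 13 wraps onto month 1.  Unknown song
    years (outside the fitted data) raise.
    """
    if fit.fitted_years and song_year not in fit.fitted_years:
        raise ValueError(f"song year {song_year} was not in the fitted data "
                         f"(fitted years: {sorted(fit.fitted_years)})")
    if months is None:
        months = np.arange(1, 13, dtype=float)
    months = np.asarray(months, dtype=float)
    wrapped = (months - 1) % 12 + 1
    newdf = pd.DataFrame({
        "month": wrapped,
        "song_year": song_year,
        "singer": singer if singer is not None else "__population__",
        "date": "__population__",
    })
    mu, eta, se = fit.predict(newdf, se=True)
    z = stats.norm.ppf(0.975)
    if fit.link == "log":
        lo, hi = np.exp(eta - z * se), np.exp(eta + z * se)
    else:
        lo, hi = eta - z * se, eta + z * se
    return pd.DataFrame({"month": months, "predicted": mu,
                         "ci_low": lo, "ci_high": hi})
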