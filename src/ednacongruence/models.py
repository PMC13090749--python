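"""Explanatory models for assignment congruence.

Three model stages:

* a negative-binomial random-intercept GLMM (log link) relating reanalyzed
  to original per-site species richness, dataset identity as the random
  factor;
* beta GLMs (logit mean link, mean-precision parameterization) for the
  dataset-level overlap proportions ``p_sp`` and ``p_read`` on log median
  fish reads, sampling year, reanalyzed richness and reference-database
  type;
* beta random-intercept mixed models for the per-species relative-abundance
  indices, testing whether species unique to the reanalysis carry fewer
  reads than shared species.

The mixed models are fitted by a Laplace approximation with a scalar
per-dataset random intercept: an inner Newton solve for the posterior modes
(vectorized over datasets) nested in an outer quasi-Newton optimization of
the approximate marginal likelihood.  Fixed-effects beta GLMs are delegated
to :class:`statsmodels.othermod.betareg.BetaModel`.

Proportion responses are smoothed off the boundary with
``y' = (y (n-1) + 0.5) / n`` before any beta fit, since observed overlaps
span the full 0%-100% range.

Also here: the median-fish-reads sensitivity filter and the grouped
nonparametric test suite (Kruskal-Wallis + Dunn post hoc with a compact
letter display, rank-sum, and an exact 2xk contingency test).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from statsmodels.othermod.betareg import BetaModel
from statsmodels.tools.numdiff import approx_hess


# ---------------------------------------------------------------------------
# fit container


@dataclass
class ModelFit:
    """Coefficients and variance components of one fitted model."""

    family: str
    link: str
    params: pd.DataFrame            # index: term; estimate, se, z, p
    dispersion: float | None        # NB theta or beta precision phi
    sigma2_u: float | None          # random-intercept variance (mixed only)
    r2_marginal: float | None
    r2_conditional: float | None
    n_obs: int
    converged: bool
    loglik: float | None = None
    message: str = ""

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.params.loc[term, "p"])

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        est, se = self.params.loc[term, ["estimate", "se"]]
        return float(est - z * se), float(est + z * se)

    def as_dict(self) -> dict:
        return {
            "family": self.family, "link": self.link,
            "coefficients": self.params.reset_index()
                                       .rename(columns={"index": "term"})
                                       .to_dict(orient="records"),
            "dispersion": self.dispersion, "sigma2_u": self.sigma2_u,
            "r2_marginal": self.r2_marginal, "r2_conditional": self.r2_conditional,
            "n_obs": self.n_obs, "converged": self.converged,
            "loglik": self.loglik, "message": self.message,
        }


def smooth_proportions(y: np.ndarray) -> np.ndarray:
    """Smithson-Verkuilen boundary smoothing y' = (y(n-1) + 0.5)/n."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


# ---------------------------------------------------------------------------
# exponential-family pieces for the Laplace machinery
# each family exposes log-likelihood and first two derivatives w.r.t. the
# linear predictor eta, at dispersion exp(log_aux)


class _NB2Family:
    """Negative binomial (NB2), log link: mu = exp(eta), Var = mu + mu^2/theta."""

    name = "negative_binomial"
    link = "log"

    @staticmethod
    def loglik(y, eta, theta):
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        return (special.gammaln(y + theta) - special.gammaln(theta)
                - special.gammaln(y + 1) + theta * np.log(theta)
                + y * eta - (y + theta) * np.log(mu + theta))

    @staticmethod
    def d1(y, eta, theta):
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        return y - (y + theta) * mu / (mu + theta)

    @staticmethod
    def d2(y, eta, theta):
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        return -(y + theta) * theta * mu / (mu + theta) ** 2


class _BetaFamily:
    """Beta, logit link, mean-precision parameterization (precision phi)."""

    name = "beta"
    link = "logit"

    @staticmethod
    def loglik(y, eta, phi):
        mu = special.expit(eta)
        a, b = mu * phi, (1 - mu) * phi
        return (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
                + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y))

    @staticmethod
    def d1(y, eta, phi):
        mu = special.expit(eta)
        ystar = np.log(y) - np.log1p(-y)
        mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
        return phi * (ystar - mustar) * mu * (1 - mu)

    @staticmethod
    def d2(y, eta, phi):
        mu = special.expit(eta)
        dmu = mu * (1 - mu)
        ystar = np.log(y) - np.log1p(-y)
        mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
        dmustar = special.polygamma(1, mu * phi) + special.polygamma(1, (1 - mu) * phi)
        # d/deta [ phi (ystar - mustar) dmu ]
        return (phi * (ystar - mustar) * (1 - 2 * mu) * dmu
                - phi ** 2 * dmustar * dmu ** 2)


# ---------------------------------------------------------------------------
# Laplace-approximated random-intercept fitter


class LaplaceMixedModel:
    """GLMM with one scalar random intercept per group, Laplace-fitted.

    Parameters are packed as [beta..., log_sigma, log_aux] where sigma is the
    random-intercept SD and aux is the family dispersion (theta or phi).
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, group_idx: np.ndarray,
                 family) -> None:
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        order = np.argsort(group_idx, kind="stable")
        self.y, self.x = self.y[order], self.x[order]
        self.groups = np.asarray(group_idx)[order]
        _, self.gidx = np.unique(self.groups, return_inverse=True)
        self.n_groups = self.gidx.max() + 1
        self.family = family
        self._u = np.zeros(self.n_groups)  # warm-started posterior modes

    def _group_objective(self, u: np.ndarray, eta0: np.ndarray, sigma2: float,
                         aux: float) -> np.ndarray:
        ll = np.bincount(self.gidx,
                         self.family.loglik(self.y, eta0 + u[self.gidx], aux),
                         minlength=self.n_groups)
        return ll - 0.5 * u ** 2 / sigma2

    def _inner_modes(self, eta0: np.ndarray, sigma2: float, aux: float,
                     max_iter: int = 60, tol: float = 1e-10):
        """Damped Newton solve for the per-group posterior modes (vectorized).

        The per-group curvature is clamped negative (the beta log-density is
        not globally concave in eta) and any step that decreases a group's
        objective is halved for that group only.
        """
        u = self._u.copy()
        fam, g = self.family, self.gidx
        h = self._group_objective(u, eta0, sigma2, aux)
        if not np.all(np.isfinite(h)):
            u = np.where(np.isfinite(h), u, 0.0)
            h = self._group_objective(u, eta0, sigma2, aux)
        for _ in range(max_iter):
            eta = eta0 + u[g]
            grad = np.bincount(g, fam.d1(self.y, eta, aux),
                               minlength=self.n_groups) - u / sigma2
            hess = np.bincount(g, fam.d2(self.y, eta, aux),
                               minlength=self.n_groups) - 1.0 / sigma2
            step = np.clip(grad / np.minimum(hess, -1e-8), -4.0, 4.0)
            u_new = u - step
            h_new = self._group_objective(u_new, eta0, sigma2, aux)
            for _ in range(25):
                worse = ~np.isfinite(h_new) | (h_new < h - 1e-12)
                if not worse.any():
                    break
                step = np.where(worse, 0.5 * step, step)
                u_new = u - step
                h_new = self._group_objective(u_new, eta0, sigma2, aux)
            ok = np.isfinite(h_new) & (h_new >= h - 1e-12)
            u = np.where(ok, u_new, u)
            h = np.where(ok, h_new, h)
            if np.max(np.abs(np.where(ok, step, 0.0))) < tol:
                break
        self._u = u
        eta = eta0 + u[g]
        curv = np.bincount(g, fam.d2(self.y, eta, aux),
                           minlength=self.n_groups) - 1.0 / sigma2
        curv = np.minimum(curv, -1e-10)
        return u, curv

    def nll(self, params: np.ndarray) -> float:
        p = self.x.shape[1]
        beta = params[:p]
        sigma2 = np.exp(2 * params[p])
        aux = np.exp(params[p + 1])
        eta0 = self.x @ beta
        u, curv = self._inner_modes(eta0, sigma2, aux)
        eta = eta0 + u[self.gidx]
        ll_data = self.family.loglik(self.y, eta, aux).sum()
        ll = (ll_data - 0.5 * (u ** 2).sum() / sigma2
              - 0.5 * self.n_groups * np.log(sigma2)
              - 0.5 * np.log(-curv).sum())
        if not np.isfinite(ll):
            return 1e10
        return -ll

    def fit(self, start_beta: np.ndarray, start_log_sigma: float = -1.0,
            start_log_aux: float = 0.0, term_names: Sequence[str] | None = None,
            fix_log_sigma: float | None = None) -> ModelFit:
        """Maximize the Laplace marginal likelihood.

        ``fix_log_sigma`` pins the random-intercept SD (on the log scale),
        giving the fixed-effects limit when set very low.
        """
        p = self.x.shape[1]
        if fix_log_sigma is not None:
            start_log_sigma = fix_log_sigma
            sig_bounds = (fix_log_sigma, fix_log_sigma)
        else:
            sig_bounds = (-7.0, 3.0)
        x0 = np.concatenate([start_beta, [start_log_sigma, start_log_aux]])
        bounds = [(None, None)] * p + [sig_bounds, (-5.0, 12.0)]
        res = optimize.minimize(self.nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12})
        # simplex polish: the surface can be very flat in the dispersion
        # direction and finite-difference gradients stall short of the optimum
        polish = optimize.minimize(
            self.nll, res.x, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000,
                     "maxfev": 3000})
        # the simplex stage only ever refines the quasi-Newton optimum, so
        # convergence is judged from whichever solution is kept
        converged_opt = bool(res.success) or bool(polish.success)
        if polish.fun <= res.fun:
            res = polish
        params = res.x
        beta = params[:p]
        sigma2 = float(np.exp(2 * params[p]))
        aux = float(np.exp(params[p + 1]))
        # Wald SEs from the numerical Hessian of the Laplace deviance,
        # over the free parameters only (sigma may be pinned)
        free = [i for i in range(p + 2)
                if not (fix_log_sigma is not None and i == p)]

        def nll_free(v: np.ndarray) -> float:
            full = params.copy()
            full[free] = v
            return self.nll(full)

        se = np.full(p, np.nan)
        converged = converged_opt
        try:
            hess = approx_hess(params[free], nll_free)
            cov = np.linalg.inv(hess)
            d = np.diag(cov)[:p]
            if np.all(d > 0):
                se = np.sqrt(d)
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
        z = beta / se
        pvals = 2 * stats.norm.sf(np.abs(z))
        names = list(term_names) if term_names is not None else (
            [f"x{i}" for i in range(p)])
        table = pd.DataFrame({"estimate": beta, "se": se, "z": z, "p": pvals},
                             index=names)
        r2m, r2c = self._nakagawa_r2(beta, sigma2, aux)
        return ModelFit(
            family=self.family.name, link=self.family.link, params=table,
            dispersion=aux, sigma2_u=sigma2, r2_marginal=r2m,
            r2_conditional=r2c, n_obs=self.y.size, converged=converged,
            loglik=-float(res.fun), message=str(res.message))

    def _nakagawa_r2(self, beta, sigma2, aux) -> tuple[float, float]:
        """Marginal / conditional R² with a lognormal observation-variance term.

        For the NB family the observation-level variance on the link scale is
        approximated by ln(1 + 1/nu_bar + 1/theta) with nu_bar the mean
        predicted count; for the beta family the delta-method analogue
        1 / ((1 + phi) * mu_bar * (1 - mu_bar)) is used.
        """
        eta_f = self.x @ beta
        var_f = float(np.var(eta_f))
        if self.family.name == "negative_binomial":
            nu_bar = float(np.exp(eta_f.mean() + sigma2 / 2))
            var_eps = math.log1p(1.0 / nu_bar + 1.0 / aux)
        else:
            mu_bar = float(special.expit(eta_f.mean()))
            var_eps = 1.0 / ((1.0 + aux) * mu_bar * (1.0 - mu_bar))
        denom = var_f + sigma2 + var_eps
        return var_f / denom, (var_f + sigma2) / denom


# ---------------------------------------------------------------------------
# model-stage front ends


def fit_nb_glmm_richness(original_richness, reanalyzed_richness, dataset_ids,
                         fix_sigma_zero: bool = False) -> ModelFit:
    """NB random-intercept GLMM: reanalyzed ~ original richness + (1 | dataset).

    ``fix_sigma_zero`` pins the random-intercept variance at (numerically)
    zero, reducing the model to a plain NB GLM.
    """
    y = np.asarray(reanalyzed_richness, dtype=float)
    x_orig = np.asarray(original_richness, dtype=float)
    ids = np.asarray(dataset_ids)
    if np.unique(ids).size < 2:
        raise ValueError("at least two datasets are required for a mixed fit")
    x = np.column_stack([np.ones_like(x_orig), x_orig])
    model = LaplaceMixedModel(y, x, ids, _NB2Family)
    b0 = math.log(max(y.mean(), 0.5))
    return model.fit(np.array([b0, 0.0]),
                     term_names=["intercept", "original_richness"],
                     fix_log_sigma=-7.0 if fix_sigma_zero else None)


def fit_beta_glm(data: pd.DataFrame, response: str,
                 predictors: Sequence[str] = ("log_median_fish_reads", "year",
                                              "reanalyzed_richness", "refdb_custom"),
                 center: bool = True) -> ModelFit:
    """Beta GLM (logit mean link) for a dataset-level overlap proportion.

    Predictors are centered by default so the intercept sits at the predictor
    means.  The response is boundary-smoothed before fitting.
    """
    df = data.dropna(subset=[response, *predictors])
    if len(df) < 10:
        raise ValueError("at least 10 observations are required")
    y = smooth_proportions(df[response].to_numpy())
    exog = df.loc[:, list(predictors)].astype(float).copy()
    if center:
        exog = exog - exog.mean()
    exog.insert(0, "intercept", 1.0)
    try:
        res = BetaModel(y, exog).fit(disp=False)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # separation / non-convergence
        table = pd.DataFrame(np.nan, index=list(exog.columns),
                             columns=["estimate", "se", "z", "p"])
        return ModelFit("beta", "logit", table, None, None, None, None,
                        len(df), False, message=f"fit failed: {exc}")
    k = exog.shape[1]
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    tv, pv = np.asarray(res.tvalues), np.asarray(res.pvalues)
    table = pd.DataFrame({"estimate": params[:k], "se": bse[:k],
                          "z": tv[:k], "p": pv[:k]}, index=list(exog.columns))
    # precision parameter is fitted on the log scale (default Log link)
    phi = float(np.exp(params[-1]))
    return ModelFit("beta", "logit", table, phi, None, None, None,
                    len(df), converged, loglik=float(res.llf))


def fit_abundance_mixed(records: pd.DataFrame, index: str = "a",
                        year_ref: float | None = None) -> ModelFit:
    """Beta mixed model of a relative-abundance index on species category.

    ``records`` is the tidy per-species table from
    :func:`ednacongruence.congruence.abundance_table`.  The model is
    ``index ~ unique_flag + refdb_custom + year + (1 | dataset)`` with a beta
    likelihood and logit link; a negative ``unique`` coefficient means species
    unique to the reanalysis carry lower relative read abundance.
    """
    df = records.dropna(subset=[index]).copy()
    if df["dataset_id"].nunique() < 2:
        raise ValueError("at least two datasets are required")
    y = smooth_proportions(df[index].to_numpy())
    year = df["year"].to_numpy(dtype=float)
    year = year - (year_ref if year_ref is not None else year.min())
    x = np.column_stack([
        np.ones(len(df)),
        (~df["shared"].to_numpy(dtype=bool)).astype(float),   # unique flag
        (df["refdb_type"].to_numpy() == "custom").astype(float),
        year,
    ])
    model = LaplaceMixedModel(y, x, df["dataset_id"].to_numpy(), _BetaFamily)
    ybar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    b0 = math.log(ybar / (1 - ybar))
    return model.fit(np.array([b0, 0.0, 0.0, 0.0]), start_log_aux=1.0,
                     term_names=["intercept", "unique", "refdb_custom", "year"])


def fit_beta_glm_fixed(y: np.ndarray, x: np.ndarray,
                       term_names: Sequence[str] | None = None) -> ModelFit:
    """Plain beta GLM on a raw design matrix (no smoothing, no centering).

    Thin wrapper used as the sigma² -> 0 reference point for the mixed fits.
    """
    res = BetaModel(np.asarray(y, float), np.asarray(x, float)).fit(disp=False)
    k = x.shape[1]
    names = list(term_names) if term_names else [f"x{i}" for i in range(k)]
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    table = pd.DataFrame({"estimate": params[:k], "se": bse[:k],
                          "z": np.asarray(res.tvalues)[:k],
                          "p": np.asarray(res.pvalues)[:k]}, index=names)
    return ModelFit("beta", "logit", table, float(np.exp(params[-1])),
                    None, None, None, len(y), True, loglik=float(res.llf))


# ---------------------------------------------------------------------------
# sensitivity filter


def sensitivity_filter(collection, min_median_fish_reads: float):
    """Drop datasets whose median per-site fish reads fall below a threshold.

    Returns ``(filtered_collection, report)`` where the report lists every
    removal.  Removing everything is an error.
    """
    if min_median_fish_reads < 0:
        raise ValueError("threshold must be >= 0")
    keep, removed = [], []
    for ds in collection.datasets:
        if ds.metadata.median_fish_reads < min_median_fish_reads:
            removed.append({"dataset_id": ds.dataset_id,
                            "median_fish_reads": ds.metadata.median_fish_reads})
        else:
            keep.append(ds)
    if not keep:
        raise ValueError("sensitivity filter removed every dataset")
    report = pd.DataFrame(removed, columns=["dataset_id", "median_fish_reads"])
    return collection.replace_datasets(keep), report


# ---------------------------------------------------------------------------
# grouped nonparametric tests


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None      # group1, group2, z, p
    letters: dict[str, str] | None = None


def dunn_test(values, groups, adjust: str | None = None) -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests on joint ranks, with tie correction.

    ``adjust='holm'`` applies a stepwise (Holm) adjustment; default is the
    unadjusted test.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = list(pd.unique(g))
    n = v.size
    ranks = stats.rankdata(v)
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n - 1))
    var_base = n * (n + 1) / 12 - tie_term
    rows = []
    for a, b in itertools.combinations(labels, 2):
        ra, rb = ranks[g == a], ranks[g == b]
        z = (ra.mean() - rb.mean()) / math.sqrt(
            var_base * (1 / ra.size + 1 / rb.size))
        rows.append({"group1": a, "group2": b, "z": z,
                     "p": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p"] = adj
    return out


def compact_letter_display(pairwise: pd.DataFrame, groups: Sequence,
                           alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise p-values.

    Groups sharing a letter are not significantly different at ``alpha``.
    """
    groups = list(groups)
    letters: list[set] = [set(groups)]
    for _, row in pairwise.iterrows():
        if row["p"] >= alpha:
            continue
        a, b = row["group1"], row["group2"]
        new = []
        for s in letters:
            if a in s and b in s:
                new.extend([s - {a}, s - {b}])
            else:
                new.append(s)
        # absorb: drop sets contained in another
        letters = [s for s in new
                   if s and not any(s < t for t in new if s is not t)]
        # deduplicate
        uniq = []
        for s in letters:
            if s not in uniq:
                uniq.append(s)
        letters = uniq
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letters):
        for g in groups:
            if g in s:
                out[g] += alphabet[i % len(alphabet)]
    return out


def group_tests(values, groups, alpha: float = 0.05,
                adjust: str | None = None) -> GroupTestResult:
    """Kruskal-Wallis across groups with Dunn post hoc and letter display."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("at least two groups are required")
    samples = [v[g == lab] for lab in labels]
    if any(s.size == 0 for s in samples):
        raise ValueError("empty group")
    if np.ptp(v) == 0:  # all values identical
        h, p = 0.0, 1.0
        pairwise = pd.DataFrame(
            [{"group1": a, "group2": b, "z": 0.0, "p": 1.0}
             for a, b in itertools.combinations(labels, 2)])
    else:
        h, p = stats.kruskal(*samples)
        pairwise = dunn_test(v, g, adjust=adjust)
    letters = compact_letter_display(pairwise, labels, alpha=alpha)
    return GroupTestResult("kruskal-wallis", float(h), float(p),
                           pairwise, letters)


def rank_sum_test(x, y, alternative: str = "two-sided") -> GroupTestResult:
    """Wilcoxon rank-sum (Mann-Whitney U), exact when sample sizes allow."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if (x.size <= 25 and y.size <= 25
                         and np.unique(np.concatenate([x, y])).size == x.size + y.size
                         ) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return GroupTestResult("rank-sum", float(res.statistic), float(res.pvalue))


def exact_contingency_2xk(table: np.ndarray, max_tables: int = 2_000_000,
                          n_mc: int = 20000, seed: int = 0) -> GroupTestResult:
    """Exact conditional test for a 2 x k contingency table (Freeman-Halton).

    Enumerates all tables with the observed margins and sums the
    multivariate-hypergeometric probabilities of tables no more probable than
    the observed one.  Falls back to Monte-Carlo sampling of tables from the
    conditional null when the enumeration would exceed ``max_tables``.
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    row0 = int(t[0].sum())
    cols = t.sum(axis=0)
    n = int(t.sum())

    def log_prob(first_row: np.ndarray) -> float:
        # P(table | margins) under the hypergeometric null
        return (sum(math.lgamma(c + 1) - math.lgamma(a + 1) - math.lgamma(c - a + 1)
                    for a, c in zip(first_row, cols))
                + math.lgamma(row0 + 1) + math.lgamma(n - row0 + 1)
                - math.lgamma(n + 1)
                + 0.0)

    lp_obs = log_prob(t[0])
    n_comb = 1
    for c in cols:
        n_comb *= (min(int(c), row0) + 1)
        if n_comb > max_tables:
            break
    if n_comb <= max_tables:
        k = len(cols)

        def rec(j: int, remaining: int, row: list) -> float:
            if j == k - 1:
                if remaining > cols[j]:
                    return 0.0
                lp = log_prob(np.array(row + [remaining]))
                return math.exp(lp) if lp <= lp_obs + 1e-9 else 0.0
            tail = cols[j + 1:].sum()
            lo = max(0, remaining - int(tail))
            hi = min(int(cols[j]), remaining)
            return sum(rec(j + 1, remaining - a, row + [a])
                       for a in range(lo, hi + 1))

        p = min(1.0, rec(0, row0, []))
    else:
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(len(cols)), cols)
        hits = 0
        for _ in range(n_mc):
            chosen = rng.choice(labels, size=row0, replace=False)
            first = np.bincount(chosen, minlength=len(cols))
            if log_prob(first) <= lp_obs + 1e-9:
                hits += 1
        p = (1 + hits) / (1 + n_mc)
    return GroupTestResult("exact-2xk", float(math.exp(lp_obs)), float(p))
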