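"""Penalized-spline generalized additive mixed models.

The outbreak, infestation and insecticide analyses all share one model
class: a GLM (negative binomial, binomial or Poisson) whose linear
predictor combines

* low-rank cubic regression spline smooths (basis dimension capped at 3,
  i.e. two effective columns each after the sum-to-zero constraint),
* ordinary linear terms, and
* random intercepts for survey year, farm, region, observer and cultivar,
  represented as ridge-penalized blocks of dummy coefficients (variance of
  factor j is ``scale / lambda_j``).

Estimation is penalized IRLS.  All smoothing parameters — one per smooth
and one per random-effect factor — are selected by REML on the working
Gaussian model, via the Fellner-Schall fixed-point update

    lambda_j  <-  phi * (rank(S_j) - lambda_j tr((X'WX + S)^-1 S_j))
                  / (beta' S_j beta),

interleaved with the IRLS steps.  The negative binomial shape ``theta`` is
profiled by an outer one-dimensional likelihood optimisation.  Reported
summaries follow common GAM practice: effective degrees of freedom
``tr((X'WX+S)^-1 X'WX)``, AIC ``-2 loglik + 2 edf``, deviance explained
``1 - D/D_null``, Wald-type chi-square p-values per term on the penalized
coefficient covariance, and prediction curves conditioned on covariate
medians with random effects set to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from scipy.optimize import minimize_scalar

from .splines import SplineBasis, build_spline_basis

__all__ = [
    "GAMMSpec",
    "GAMMFit",
    "MoranResult",
    "fit_gamm",
    "deviance_explained",
    "predict_curve",
    "morans_i",
    "compare_decay_rates",
    "threshold_response_models",
]

_LAM_MIN, _LAM_MAX = 1e-7, 1e9


# ---------------------------------------------------------------------------
# families


class _Family:
    name = ""

    def link(self, mu):  # pragma: no cover - interface
        raise NotImplementedError

    def inv_link(self, eta):
        raise NotImplementedError

    def mu_eta(self, eta):
        """d mu / d eta."""
        raise NotImplementedError

    def variance(self, mu):
        raise NotImplementedError

    def deviance(self, y, mu, w):
        raise NotImplementedError

    def loglik(self, y, mu, w):
        raise NotImplementedError

    def init_mu(self, y, w):
        raise NotImplementedError


class _Poisson(_Family):
    name = "poisson"

    def link(self, mu):
        return np.log(mu)

    def inv_link(self, eta):
        return np.exp(np.clip(eta, -30, 30))

    def mu_eta(self, eta):
        return np.exp(np.clip(eta, -30, 30))

    def variance(self, mu):
        return mu

    def deviance(self, y, mu, w):
        ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        return float(2.0 * np.sum(w * (ylogy - (y - mu))))

    def loglik(self, y, mu, w):
        return float(
            np.sum(w * (y * np.log(mu) - mu - special.gammaln(y + 1.0)))
        )

    def init_mu(self, y, w):
        return np.maximum(y, 0.0) + 0.1


class _NegativeBinomial(_Poisson):
    name = "negative_binomial"

    def __init__(self, theta: float = 1.0):
        self.theta = float(theta)

    def variance(self, mu):
        return mu + mu**2 / self.theta

    def deviance(self, y, mu, w):
        th = self.theta
        ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        tail = (y + th) * np.log((y + th) / (mu + th))
        return float(2.0 * np.sum(w * (ylogy - tail)))

    def loglik(self, y, mu, w):
        th = self.theta
        ll = (
            special.gammaln(y + th)
            - special.gammaln(th)
            - special.gammaln(y + 1.0)
            + th * np.log(th / (th + mu))
            + y * np.log(mu / (th + mu))
        )
        return float(np.sum(w * ll))


class _Binomial(_Family):
    """Binomial on the proportion scale; trials enter as prior weights."""

    name = "binomial"

    def link(self, mu):
        return np.log(mu / (1.0 - mu))

    def inv_link(self, eta):
        return special.expit(eta)

    def mu_eta(self, eta):
        p = special.expit(eta)
        return p * (1.0 - p)

    def variance(self, mu):
        return mu * (1.0 - mu)

    def deviance(self, y, mu, w):
        a = np.where(y > 0, y * np.log(np.where(y > 0, y, 1) / mu), 0.0)
        b = np.where(
            y < 1,
            (1 - y) * np.log(np.where(y < 1, 1 - y, 1) / (1 - mu)),
            0.0,
        )
        return float(2.0 * np.sum(w * (a + b)))

    def loglik(self, y, mu, w):
        succ = w * y
        tot = w
        comb = (
            special.gammaln(tot + 1)
            - special.gammaln(succ + 1)
            - special.gammaln(tot - succ + 1)
        )
        return float(
            np.sum(comb + succ * np.log(mu) + (tot - succ) * np.log(1 - mu))
        )

    def init_mu(self, y, w):
        return (w * y + 0.5) / (w + 1.0)


def _make_family(name: str, theta: float | None = None) -> _Family:
    if name == "poisson":
        return _Poisson()
    if name == "binomial":
        return _Binomial()
    if name == "negative_binomial":
        return _NegativeBinomial(theta if theta is not None else 1.0)
    raise ValueError(f"unknown family {name!r}")


# ---------------------------------------------------------------------------
# specification and fit containers


@dataclass
class GAMMSpec:
    """What to fit: family, response, terms, random effects, weights.

    ``response`` is a column name for count families, or a
    ``(successes, trials)`` column pair for the binomial outbreak model.
    ``smooth_terms`` is a list of covariate names or ``(name, k)`` pairs
    (default basis dimension 3).  ``weights`` names a prior-weight column
    (typically the number of farm visits); the binomial model carries its
    sample size in the trials column instead.
    """

    family: str
    response: object
    smooth_terms: list = field(default_factory=list)
    linear_terms: list = field(default_factory=list)
    random_effects: list = field(default_factory=list)
    weights: str | None = None
    theta: float | None = None
    default_k: int = 3
    single_predictor_mode: bool = False
    include_management: bool = False

    def normalized_smooths(self) -> list[tuple[str, int]]:
        out = []
        for term in self.smooth_terms:
            if isinstance(term, (tuple, list)):
                out.append((term[0], int(term[1])))
            else:
                out.append((term, self.default_k))
        for name, k in out:
            if k < 2:
                raise ValueError(f"smooth {name!r}: basis dimension must be >= 2")
        return out


@dataclass
class _Block:
    name: str
    kind: str  # "smooth" | "random"
    sl: slice
    S: np.ndarray
    rank: int
    lam: float = 1.0


@dataclass
class GAMMFit:
    """A fitted penalized-spline mixed model."""

    spec: GAMMSpec
    beta: np.ndarray
    cov: np.ndarray  # Bayesian covariance (H + S)^-1 * phi
    blocks: list
    term_cols: dict
    bases: dict
    medians: dict
    re_levels: dict
    family: _Family
    n: int
    y: np.ndarray
    prior_weights: np.ndarray
    fitted: np.ndarray
    eta: np.ndarray
    deviance: float
    null_deviance: float
    loglik: float
    edf: float
    edf_by_term: dict
    aic: float
    lambdas: dict
    re_variance: dict
    theta: float | None
    p_values: dict
    converged: bool
    n_iter: int
    x_range: dict

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.deviance / self.null_deviance

    @property
    def deviance_residuals(self) -> np.ndarray:
        fam, y, mu, w = self.family, self.y, self.fitted, self.prior_weights
        d = np.array(
            [
                fam.deviance(y[i : i + 1], mu[i : i + 1], w[i : i + 1])
                for i in range(self.n)
            ]
        )
        return np.sign(y - mu) * np.sqrt(np.maximum(d, 0.0))

    def summary(self) -> dict:
        return {
            "family": self.family.name,
            "n": self.n,
            "edf": round(self.edf, 3),
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "deviance_explained": self.deviance_explained,
            "aic": self.aic,
            "theta": self.theta,
            "re_variance": self.re_variance,
            "p_values": self.p_values,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# design assembly


def _build_design(spec: GAMMSpec, data: pd.DataFrame):
    n = len(data)
    cols = [np.ones((n, 1))]
    blocks: list[_Block] = []
    term_cols: dict[str, slice] = {"intercept": slice(0, 1)}
    bases: dict[str, SplineBasis] = {}
    medians: dict[str, float] = {}
    x_range: dict[str, tuple] = {}
    pos = 1

    for name in spec.linear_terms:
        xv = data[name].to_numpy(dtype=float)
        if np.std(xv) <= 1e-12:
            raise ValueError(f"linear term {name!r} is constant")
        cols.append(xv[:, None])
        term_cols[name] = slice(pos, pos + 1)
        medians[name] = float(np.median(xv))
        x_range[name] = (float(xv.min()), float(xv.max()))
        pos += 1

    for name, k in spec.normalized_smooths():
        xv = data[name].to_numpy(dtype=float)
        basis = build_spline_basis(xv, k=k)
        X = basis.X
        S = basis.S.copy()
        norm = np.abs(S).max()
        if norm > 0:
            S = S / norm
        cols.append(X)
        sl = slice(pos, pos + X.shape[1])
        blocks.append(
            _Block(name=f"s({name})", kind="smooth", sl=sl, S=S,
                   rank=basis.penalty_rank)
        )
        term_cols[f"s({name})"] = sl
        bases[name] = basis
        medians[name] = float(np.median(xv))
        x_range[name] = (float(xv.min()), float(xv.max()))
        pos += X.shape[1]

    re_levels: dict[str, np.ndarray] = {}
    for name in spec.random_effects:
        codes, levels = pd.factorize(data[name], sort=True)
        m = len(levels)
        Z = np.zeros((n, m))
        Z[np.arange(n), codes] = 1.0
        cols.append(Z)
        sl = slice(pos, pos + m)
        blocks.append(
            _Block(name=name, kind="random", sl=sl, S=np.eye(m), rank=m)
        )
        term_cols[f"re({name})"] = sl
        re_levels[name] = np.asarray(levels)
        pos += m

    X = np.hstack(cols)
    return X, blocks, term_cols, bases, medians, re_levels, x_range


def _penalty_matrix(p: int, blocks: list[_Block]) -> np.ndarray:
    S = np.zeros((p, p))
    for b in blocks:
        S[b.sl, b.sl] += b.lam * b.S
    return S


def _reml_criterion(X, w, z, blocks, beta, phi=1.0):
    """Working-model REML score (up to a lambda-free constant); used to
    validate the Fellner-Schall fixed point against direct optimisation."""
    p = X.shape[1]
    S = _penalty_matrix(p, blocks)
    H = (X * w[:, None]).T @ X
    r = float(w @ (z - X @ beta) ** 2 + beta @ S @ beta)
    sign, logdet = np.linalg.slogdet(H + S)
    log_s = sum(b.rank * np.log(b.lam) for b in blocks)
    return r / phi + logdet - log_s


# ---------------------------------------------------------------------------
# the fitter


def _pirls(X, y, pw, family, blocks, beta0=None, max_iter=200, tol=1e-11,
           update_lambda=True):
    n, p = X.shape
    mu = family.init_mu(y, pw)
    eta = family.link(mu)
    beta = beta0
    if beta is not None:
        eta = X @ beta
        mu = family.inv_link(eta)
    dev = family.deviance(y, mu, pw)
    lam_stable = not update_lambda or not blocks
    lam_frozen = not update_lambda or not blocks
    ridge = 0.0
    A = None
    reml_prev = np.inf
    for it in range(1, max_iter + 1):
        dmu = family.mu_eta(eta)
        dmu = np.maximum(dmu, 1e-10)
        var = np.maximum(family.variance(mu), 1e-10)
        w = pw * dmu**2 / var
        z = eta + (y - mu) / dmu
        WX = X * w[:, None]
        H = WX.T @ X
        rhs = WX.T @ z
        S = _penalty_matrix(p, blocks)
        try:
            C = linalg.cho_factor(
                H + S + ridge * np.eye(p), lower=True, check_finite=False
            )
        except linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-8 * np.mean(np.diag(H)) + 1e-10)
            warnings.warn(
                "ill-conditioned penalized system; adding ridge floor",
                stacklevel=3,
            )
            C = linalg.cho_factor(
                H + S + ridge * np.eye(p), lower=True, check_finite=False
            )
        beta = linalg.cho_solve(C, rhs, check_finite=False)
        eta = X @ beta
        mu = family.inv_link(eta)
        if family.name == "binomial":
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
        dev_new = family.deviance(y, mu, pw)

        lam_change = 0.0
        if update_lambda and blocks and not lam_frozen:
            # working-model REML score at the current (lambda, beta); its
            # stabilisation is the secondary convergence signal, since
            # near-infinite lambdas on effectively linear smooths can cycle
            # harmlessly at the boundary
            r_pen = float(w @ (z - eta) ** 2 + beta @ (S @ beta))
            logdet = 2.0 * float(np.sum(np.log(np.diag(C[0]))))
            log_s = sum(bl.rank * np.log(bl.lam) for bl in blocks)
            reml = r_pen + logdet - log_s
            reml_change = abs(reml - reml_prev) / (abs(reml) + 1.0)
            reml_prev = reml

            A = linalg.cho_solve(C, np.eye(p), check_finite=False)
            for b in blocks:
                Ab = A[b.sl, b.sl]
                tr_AS = float(np.sum(Ab * b.S.T))
                bsb = float(beta[b.sl] @ b.S @ beta[b.sl])
                num = max(b.rank - b.lam * tr_AS, 1e-10)
                lam_new = num / max(bsb, 1e-12)
                ratio = np.clip(lam_new / b.lam, 1.0 / 30.0, 30.0)
                lam_new = float(np.clip(b.lam * ratio, _LAM_MIN, _LAM_MAX))
                lam_change = max(lam_change, abs(np.log(lam_new / b.lam)))
                b.lam = lam_new
            lam_stable = lam_change < 1e-3 or (
                it >= 15 and reml_change < 1e-6
            )

        dev_change = abs(dev_new - dev) / (abs(dev_new) + 0.1)
        dev = dev_new
        # phase 1: co-iterate beta and lambda until REML settles;
        # phase 2: freeze lambda and polish beta to full precision
        if not lam_frozen and dev_change < 1e-5 and lam_stable and it > 2:
            lam_frozen = True
        if dev_change < tol and lam_frozen and it > 2:
            break
    else:
        raise RuntimeError(
            f"penalized IRLS failed to converge in {max_iter} iterations "
            f"(last relative deviance change {dev_change:.2e})"
        )
    # final covariance pieces at converged lambdas
    S = _penalty_matrix(p, blocks)
    C = linalg.cho_factor(
        H + S + ridge * np.eye(p), lower=True, check_finite=False
    )
    A = linalg.cho_solve(C, np.eye(p), check_finite=False)
    return beta, mu, eta, dev, A, H, it


def _null_deviance(family, y, pw):
    if family.name == "binomial":
        p0 = np.clip(np.sum(pw * y) / np.sum(pw), 1e-10, 1 - 1e-10)
        mu0 = np.full_like(y, p0, dtype=float)
    else:
        mu0 = np.full_like(
            y, max(np.sum(pw * y) / np.sum(pw), 1e-10), dtype=float
        )
    return family.deviance(y, mu0, pw)


def _extract_response(spec: GAMMSpec, data: pd.DataFrame):
    if spec.family == "binomial":
        if not (isinstance(spec.response, (tuple, list)) and len(spec.response) == 2):
            raise ValueError(
                "binomial family needs a (successes, trials) response pair"
            )
        succ = data[spec.response[0]].to_numpy(dtype=float)
        trials = data[spec.response[1]].to_numpy(dtype=float)
        if np.any(succ > trials):
            raise ValueError("successes exceed trials")
        if np.any(trials <= 0):
            raise ValueError("binomial trials must be positive")
        y = succ / trials
        pw = trials
        if spec.weights is not None:
            pw = pw * data[spec.weights].to_numpy(dtype=float)
        return y, pw
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("count response must be non-negative")
    pw = (
        data[spec.weights].to_numpy(dtype=float)
        if spec.weights is not None
        else np.ones(len(y))
    )
    return y, pw


def fit_gamm(spec: GAMMSpec, data: pd.DataFrame) -> GAMMFit:
    """Fit the penalized-spline mixed model described by ``spec``.

    For the negative binomial family with ``spec.theta is None`` the shape
    parameter is profiled by an outer 1-D likelihood optimisation over
    ``log theta``, re-running the penalized IRLS (warm-started) per
    candidate.
    """
    data = data.reset_index(drop=True)
    y, pw = _extract_response(spec, data)
    if len(data) == 0:
        raise ValueError("empty data")
    X, blocks, term_cols, bases, medians, re_levels, x_range = _build_design(
        spec, data
    )
    if spec.family == "negative_binomial" and spec.theta is None:
        state = {"beta": None}

        def neg_profile(log_th):
            fam = _NegativeBinomial(float(np.exp(log_th)))
            for b in blocks:
                b.lam = 1.0
            try:
                beta, mu, *_ = _pirls(
                    X, y, pw, fam, blocks, beta0=state["beta"]
                )
            except RuntimeError:
                return 1e12
            state["beta"] = beta
            return -fam.loglik(y, mu, pw)

        res = minimize_scalar(
            neg_profile,
            bounds=(np.log(0.05), np.log(1e4)),
            method="bounded",
            options={"xatol": 0.02, "maxiter": 40},
        )
        theta = float(np.exp(res.x))
        family = _NegativeBinomial(theta)
    else:
        family = _make_family(spec.family, spec.theta)
        theta = getattr(family, "theta", None)

    for b in blocks:
        b.lam = 1.0
    if spec.family == "binomial":
        events = np.sum(pw * y)
        if events == 0 or events == np.sum(pw):
            warnings.warn(
                "degenerate binomial response (all zero or all one); "
                "estimates lie on the boundary",
                stacklevel=2,
            )
    if spec.family in ("poisson", "negative_binomial") and np.all(y == 0):
        raise ValueError("all-zero count response: intercept is -infinity")

    beta, mu, eta, dev, A, H, n_iter = _pirls(X, y, pw, family, blocks)
    phi = 1.0
    cov = A * phi
    edf_mat = A @ H
    edf = float(np.trace(edf_mat))
    edf_by_term = {
        name: float(np.trace(edf_mat[sl, sl]))
        for name, sl in term_cols.items()
    }
    loglik = family.loglik(y, mu, pw)
    null_dev = _null_deviance(family, y, pw)
    aic = -2.0 * loglik + 2.0 * edf

    lambdas = {b.name: b.lam for b in blocks}
    re_variance = {
        b.name: phi / b.lam for b in blocks if b.kind == "random"
    }

    # Wald-type term tests on the penalized coefficient covariance, with the
    # reference distribution's df tied to the term's effective degrees of
    # freedom (a shrunk-to-linear smooth is compared against chi^2_1, not
    # chi^2_k), following standard practice for penalized smooth tests
    p_values = {}
    for name, sl in term_cols.items():
        if name == "intercept" or name.startswith("re("):
            continue
        bb = beta[sl]
        Vb = cov[sl, sl]
        try:
            stat = float(bb @ np.linalg.solve(Vb, bb))
        except np.linalg.LinAlgError:
            stat = float(bb @ np.linalg.pinv(Vb) @ bb)
        ncol = sl.stop - sl.start
        df = min(ncol, max(1, int(round(edf_by_term[name]))))
        p_values[name] = float(stats.chi2.sf(stat, df))

    return GAMMFit(
        spec=spec,
        beta=beta,
        cov=cov,
        blocks=blocks,
        term_cols=term_cols,
        bases=bases,
        medians=medians,
        re_levels=re_levels,
        family=family,
        n=len(data),
        y=y,
        prior_weights=pw,
        fitted=mu,
        eta=eta,
        deviance=dev,
        null_deviance=null_dev,
        loglik=loglik,
        edf=edf,
        edf_by_term=edf_by_term,
        aic=aic,
        lambdas=lambdas,
        re_variance=re_variance,
        theta=theta,
        p_values=p_values,
        converged=True,
        n_iter=n_iter,
        x_range=x_range,
    )


def strip_random_effects(spec: GAMMSpec) -> GAMMSpec:
    """The same model without its random intercepts (for refits)."""
    return GAMMSpec(
        family=spec.family,
        response=spec.response,
        smooth_terms=list(spec.smooth_terms),
        linear_terms=list(spec.linear_terms),
        random_effects=[],
        weights=spec.weights,
        theta=spec.theta,
        default_k=spec.default_k,
    )


def deviance_explained(fit_with: GAMMFit, fit_without: GAMMFit):
    """(proportion with REs, proportion without), both vs the null model.

    The two fits must be on identical data and family; the second is the
    refit of the same fixed-effect structure without random intercepts.
    """
    if fit_with.n != fit_without.n or fit_with.family.name != fit_without.family.name:
        raise ValueError("fits are not on identical data/family")
    if abs(fit_with.null_deviance - fit_without.null_deviance) > 1e-6 * (
        abs(fit_with.null_deviance) + 1.0
    ):
        raise ValueError("null deviances differ; fits not on the same data")
    return fit_with.deviance_explained, fit_without.deviance_explained


def predict_curve(
    fit: GAMMFit, covariate: str, grid=None, n_grid: int = 100,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Predicted response across a covariate grid with a Wald CI band.

    Other continuous covariates are held at their sample medians and random
    effects at zero; the band is the inverse link of the linear predictor
    plus/minus ``z * SE`` from the penalized coefficient covariance.
    """
    smooth_names = [n for n, _ in fit.spec.normalized_smooths()]
    if covariate not in smooth_names and covariate not in fit.spec.linear_terms:
        raise ValueError(f"covariate {covariate!r} not in the fitted model")
    lo, hi = fit.x_range[covariate]
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
        warnings.warn(
            f"prediction grid extends beyond the observed range of "
            f"{covariate!r}; extrapolating",
            stacklevel=2,
        )
    p = len(fit.beta)
    Xg = np.zeros((len(grid), p))
    Xg[:, fit.term_cols["intercept"]] = 1.0
    for name in fit.spec.linear_terms:
        sl = fit.term_cols[name]
        Xg[:, sl] = grid[:, None] if name == covariate else fit.medians[name]
    for name in smooth_names:
        sl = fit.term_cols[f"s({name})"]
        at = grid if name == covariate else np.full(1, fit.medians[name])
        B = fit.bases[name].matrix(at)
        Xg[:, sl] = B if name == covariate else B[0][None, :]
    eta = Xg @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, fit.cov, Xg), 0.0))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    inv = fit.family.inv_link
    return pd.DataFrame(
        {
            covariate: grid,
            "fit": inv(eta),
            "lower": inv(eta - z * se),
            "upper": inv(eta + z * se),
            "eta": eta,
            "se": se,
        }
    )


# ---------------------------------------------------------------------------
# spatial autocorrelation


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    weight_scheme: str


def morans_i(
    values, coords, weight_scheme: str = "inverse_distance"
) -> MoranResult:
    """Moran's I with a normal-approximation two-sided p-value.

    Weights are inverse pairwise distances (zero diagonal, unnormalised) by
    default; ``"binary_knn4"`` connects each site to its 4 nearest
    neighbours instead.  Residuals from each fitted model are screened this
    way to confirm the region/farm random effects absorb the spatial
    structure.
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 sites")
    if np.std(x) <= 1e-15:
        raise ValueError("zero-variance values")
    d = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    )
    if np.any((d == 0) & ~np.eye(n, dtype=bool)):
        raise ValueError("duplicate coordinates")
    if weight_scheme == "inverse_distance":
        with np.errstate(divide="ignore"):
            W = 1.0 / d
        np.fill_diagonal(W, 0.0)
    elif weight_scheme == "binary_knn4":
        W = np.zeros((n, n))
        for i in range(n):
            idx = np.argsort(d[i])[1:5]
            W[i, idx] = 1.0
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")

    zc = x - x.mean()
    S0 = W.sum()
    I = (n / S0) * float(zc @ W @ zc) / float(zc @ zc)
    EI = -1.0 / (n - 1)
    S1 = 0.5 * np.sum((W + W.T) ** 2)
    S2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    varI = (n**2 * S1 - n * S2 + 3 * S0**2) / (S0**2 * (n**2 - 1)) - EI**2
    zstat = (I - EI) / np.sqrt(varI)
    p = 2.0 * stats.norm.sf(abs(zstat))
    return MoranResult(
        I=float(I),
        expected=EI,
        variance=float(varI),
        z=float(zstat),
        p_value=float(p),
        weight_scheme=weight_scheme,
    )


# ---------------------------------------------------------------------------
# model comparison and the spray-response analyses


def compare_decay_rates(fits: dict) -> pd.DataFrame:
    """AIC table across decay rates; the winner has minimum AIC (smallest
    delta on ties)."""
    ns = {d: f.n for d, f in fits.items()}
    if len(set(ns.values())) > 1:
        raise ValueError(f"fits use differing sample sizes: {ns}")
    rows = sorted(
        ((d, f.aic) for d, f in fits.items()), key=lambda t: (t[1], t[0])
    )
    best_aic = rows[0][1]
    table = pd.DataFrame(
        [(d, a, a - best_aic) for d, a in sorted(rows)],
        columns=["delta", "aic", "delta_aic"],
    )
    table.attrs["winner"] = rows[0][0]
    return table


def threshold_response_models(
    season_responses: pd.DataFrame,
    never_sprayer_set: set,
    random_effects=("year", "farm", "region", "observer", "cultivar"),
    weights: str | None = "n_visits",
) -> dict:
    """The three farmer-response fits linking outbreaks to spray counts.

    (a) Poisson sprays ~ ever-exceeded indicator (linear);
    (b) Poisson sprays ~ smooth(fraction of visits above threshold, k=3);
    (c) model (b) refit after dropping farms that never applied any
        insecticide.
    """
    if season_responses["spray_count"].sum() == 0:
        raise ValueError(
            "no insecticide applications anywhere: spray models degenerate"
        )
    re = [r for r in random_effects if r in season_responses.columns]
    spec_a = GAMMSpec(
        family="poisson",
        response="spray_count",
        linear_terms=["ever_exceeded"],
        random_effects=re,
        weights=weights,
    )
    spec_b = GAMMSpec(
        family="poisson",
        response="spray_count",
        smooth_terms=[("fraction_exceeded", 3)],
        random_effects=re,
        weights=weights,
    )
    fit_a = fit_gamm(spec_a, season_responses)
    fit_b = fit_gamm(spec_b, season_responses)
    kept = season_responses[
        ~season_responses["farm_id"].isin(never_sprayer_set)
    ]
    if len(kept) == 0:
        raise ValueError("excluding never-sprayers removed every row")
    fit_c = fit_gamm(spec_b, kept)
    return {"ever_exceeded": fit_a, "fraction": fit_b,
            "fraction_sprayers_only": fit_c}
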