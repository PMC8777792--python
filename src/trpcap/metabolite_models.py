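"""Per-metabolite Bayesian logistic regression over genus composition and host habitat.

For each bioactive metabolite M the capability database supplies a binary
response — does model (strain) i produce M? — and the design holds an
intercept, one 0/1 indicator per *dominant* genus (genera with at least
``n_min`` strains in the database; all others pool into the baseline), and a
host-habitat indicator.  The fitted probability

    P(M, G) = logistic(beta_0 + beta_G + beta_host)

is the production potential of genus G for metabolite M in the given host,
the quantity that downstream sample prediction multiplies by genus abundance.

Inference is MAP with a Laplace (inverse-Hessian) covariance and Gaussian
posterior draws.  Slope priors are independent Normal(0, 2.5^2) on the
natural 0/1 indicator scale (every design column is a binary indicator, so
2.5 is a weakly-informative bound on a log-odds difference); the intercept
gets Normal(0, 10^2).  The proper prior keeps fits finite under complete
separation and single-class responses.  Odds ratios are exp(beta) with Wald
tests from the Laplace standard errors; model families across taxonomy
levels are compared by AIC computed from the *unpenalized* log-likelihood at
the MAP; predictive quality is assessed by Pareto-smoothed importance
sampling leave-one-out cross-validation (PSIS-LOO) over the posterior draws.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .reference_network import TrpcapError
from .capability_analysis import CapabilityMatrix

__all__ = [
    "PriorSpec",
    "DesignMatrix",
    "MetaboliteModel",
    "LooResult",
    "ConvergenceError",
    "dominant_taxa",
    "build_design",
    "fit_bayes_logit",
    "predict_proba",
    "wald_tests",
    "significance_band",
    "aic_rank",
    "psis_loo",
    "roc_holdout",
    "or_table",
    "pvalue_table",
    "save_models",
    "load_models",
]

INTERCEPT = "(Intercept)"


class ConvergenceError(TrpcapError):
    """MAP optimisation failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors: sd ``slope_scale`` on slopes, ``intercept_scale`` on the intercept."""

    slope_scale: float = 2.5
    intercept_scale: float = 10.0

    def precisions(self, columns: list[str]) -> np.ndarray:
        scales = np.array(
            [self.intercept_scale if c == INTERCEPT else self.slope_scale for c in columns]
        )
        return 1.0 / scales**2


@dataclass
class DesignMatrix:
    """0/1 design (intercept, taxon indicators, host indicator) plus binary response."""

    X: pd.DataFrame
    y: np.ndarray
    metabolite: str
    host_family: str
    rank: str = "genus"

    def __post_init__(self) -> None:
        vals = self.X.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("design entries must be 0/1")
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def dominant_taxa(
    cap: CapabilityMatrix, n_min: int = 10, rank: str = "genus", host: str = "all"
) -> list[str]:
    """Taxa with at least ``n_min`` models in the (host-filtered) database.

    Ordered by descending model count, then name; taxa below the cutoff pool
    into the regression baseline.
    """
    mask = cap.host_mask(host)
    counts = cap.meta.loc[mask, rank].replace("", np.nan).dropna().value_counts()
    keep = counts[counts >= n_min]
    return sorted(keep.index, key=lambda t: (-keep[t], t))


def build_design(
    cap: CapabilityMatrix,
    metabolite: str,
    host_family: str,
    dominant: list[str],
    rank: str = "genus",
    include_host: bool = True,
) -> DesignMatrix:
    """Indicator design for one metabolite: intercept + dominant taxa + host flag."""
    if metabolite not in cap.values.columns:
        raise KeyError(f"metabolite {metabolite!r} not a capability column")
    if not dominant:
        raise ValueError("dominant taxon list must be non-empty")
    if host_family not in ("human", "mouse"):
        raise ValueError(f"host_family must be 'human' or 'mouse', got {host_family!r}")
    known = cap.meta[rank] != ""
    meta = cap.meta.loc[known]
    X = pd.DataFrame(index=meta.index)
    X[INTERCEPT] = 1
    for taxon in dominant:
        X[taxon] = (meta[rank] == taxon).astype(int)
    if include_host:
        X[f"{host_family}_gut"] = meta[f"{host_family}_gut"].astype(int)
    y = cap.values.loc[known, metabolite].to_numpy(dtype=float)
    return DesignMatrix(X=X, y=y, metabolite=metabolite, host_family=host_family, rank=rank)


@dataclass
class MetaboliteModel:
    """A fitted per-metabolite model (MAP, Laplace covariance, posterior draws)."""

    metabolite: str
    host_family: str
    columns: list[str]
    beta: np.ndarray
    cov: np.ndarray
    prior: PriorSpec
    log_lik: float
    n_obs: int
    seed: int = 0
    draws: np.ndarray | None = None
    X: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.columns)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.log_lik

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def odds_ratios(self) -> pd.Series:
        return pd.Series(np.exp(self.beta), index=self.columns, name=self.metabolite)

    def posterior_draws(self, n_draws: int = 2000, seed: int | None = None) -> np.ndarray:
        rng = np.random.default_rng(self.seed if seed is None else seed)
        return rng.multivariate_normal(self.beta, self.cov, size=n_draws, method="cholesky")


def _log_posterior_parts(beta, X, y, prec):
    eta = X @ beta
    # log p(y|eta) summed, numerically stable
    ll = -(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)).sum()
    lp = ll - 0.5 * (prec * beta**2).sum()
    return ll, lp, eta


def fit_bayes_logit(
    design: DesignMatrix,
    prior: PriorSpec = PriorSpec(),
    tol: float = 1e-8,
    max_iter: int = 200,
    seed: int = 0,
    n_draws: int = 2000,
) -> MetaboliteModel:
    """MAP fit of the Bernoulli-logit model with independent normal priors.

    Damped Newton iterations on the log posterior; convergence when the
    gradient's max norm falls below ``tol``.  The Laplace covariance is the
    inverse Hessian at the MAP and ``n_draws`` Gaussian posterior draws are
    generated from it (seeded, so odds-ratio tables and LOO results
    regenerate deterministically).  An all-one or all-zero response fits
    under the prior with a warning.
    """
    X = design.X.to_numpy(dtype=float)
    y = design.y
    if len(y) < 2:
        raise ValueError("need at least two observations")
    classes = np.unique(y)
    if len(classes) < 2:
        warnings.warn(
            f"{design.metabolite}: response is all {int(classes[0])}; fit is prior-dominated"
        )
    prec = prior.precisions(design.columns)
    beta = np.zeros(X.shape[1])
    _, lp, eta = _log_posterior_parts(beta, X, y, prec)
    converged = False
    grad_norm = np.inf
    for _ in range(max_iter):
        p = expit(eta)
        grad = X.T @ (y - p) - prec * beta
        grad_norm = np.abs(grad).max()
        if grad_norm < tol:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X + np.diag(prec)
        step = np.linalg.solve(H, grad)
        # backtracking line search on the log posterior; near the optimum the
        # objective change underflows double precision, so once the gradient
        # is small the full Newton step is taken unconditionally (quadratic zone)
        if grad_norm < 1e-5:
            beta = beta + step
            _, lp, eta = _log_posterior_parts(beta, X, y, prec)
            continue
        t = 1.0
        for _ in range(60):
            cand = beta + t * step
            _, lp_new, eta_new = _log_posterior_parts(cand, X, y, prec)
            if lp_new >= lp - 1e-14:
                beta, lp, eta = cand, lp_new, eta_new
                break
            t /= 2
        else:
            break
    if not converged:
        raise ConvergenceError(
            f"{design.metabolite}: no convergence after {max_iter} iterations "
            f"(|grad|_inf = {grad_norm:.3g}, log posterior = {lp:.6g})"
        )
    p = expit(eta)
    w = np.clip(p * (1 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X + np.diag(prec)
    cov = np.linalg.inv(H)
    cov = (cov + cov.T) / 2
    log_lik, _, _ = _log_posterior_parts(beta, X, y, np.zeros_like(prec))
    model = MetaboliteModel(
        metabolite=design.metabolite,
        host_family=design.host_family,
        columns=design.columns,
        beta=beta,
        cov=cov,
        prior=prior,
        log_lik=float(log_lik),
        n_obs=len(y),
        seed=seed,
        X=X,
        y=y,
    )
    model.draws = model.posterior_draws(n_draws)
    return model


def predict_proba(model: MetaboliteModel, X) -> np.ndarray:
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    return expit(X @ model.beta)


def significance_band(p: float) -> str:
    for cut, label in ((0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05"), (0.1, "<0.1")):
        if p < cut:
            return label
    return "ns"


def wald_tests(model: MetaboliteModel) -> pd.DataFrame:
    """Per-coefficient z statistics and two-sided normal p-values.

    Standard errors come from the Laplace covariance, which must be positive
    definite.  Bands mirror the conventional {0.001, 0.01, 0.05, 0.1} cuts.
    """
    try:
        np.linalg.cholesky(model.cov)
    except np.linalg.LinAlgError as exc:
        raise TrpcapError("covariance matrix is not positive definite") from exc
    se = model.se
    z = model.beta / se
    p = 2 * (1 - norm.cdf(np.abs(z)))
    return pd.DataFrame(
        {
            "beta": model.beta,
            "se": se,
            "odds_ratio": np.exp(model.beta),
            "z": z,
            "p": p,
            "band": [significance_band(x) for x in p],
        },
        index=model.columns,
    )


def aic_rank(fits: list[MetaboliteModel]) -> list[MetaboliteModel]:
    """Rank candidate models (different taxonomy levels / feature sets) by AIC.

    All fits must be on the same observations; ties prefer fewer parameters.
    """
    if not fits:
        return []
    ref = fits[0]
    for f in fits[1:]:
        if f.n_obs != ref.n_obs or f.y is None or ref.y is None or not np.array_equal(f.y, ref.y):
            raise ValueError("aic_rank requires fits on identical observations")
    return sorted(fits, key=lambda f: (f.aic, f.k))


@dataclass
class LooResult:
    elpd_loo: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    in_sample_lpd: float


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # eta: (n, S); y: (n,) -> pointwise log-likelihood per draw
    return -(
        np.logaddexp(0.0, -eta) * y[:, None] + np.logaddexp(0.0, eta) * (1 - y)[:, None]
    )


def psis_loo(model: MetaboliteModel, X=None, y=None) -> LooResult:
    """PSIS leave-one-out expected log predictive density.

    Importance ratios 1/p(y_i | theta_s) are tail-smoothed per observation by
    a fitted generalised Pareto (tail size min(0.2 S, 3 sqrt(S))), giving
    per-observation Pareto-k diagnostics; the smoothed weights then average
    the pointwise predictive density.  Requires at least 100 posterior draws.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        import arviz as az  # deferred: slow import

    if model.draws is None or len(model.draws) < 100:
        raise ValueError("psis_loo needs at least 100 posterior draws")
    Xm = model.X if X is None else (X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float))
    ym = model.y if y is None else np.asarray(y, float)
    if Xm is None or ym is None:
        raise ValueError("design and response required (fit-time copies missing)")
    eta = Xm @ model.draws.T  # (n, S)
    ll = _bernoulli_loglik(eta, ym)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(-ll)
    lw = np.asarray(lw)
    pointwise = logsumexp(lw + ll, axis=1)  # lw already normalised per row
    in_sample = float((logsumexp(ll, axis=1) - np.log(ll.shape[1])).sum())
    return LooResult(
        elpd_loo=float(pointwise.sum()),
        pointwise=pointwise,
        pareto_k=np.asarray(k),
        in_sample_lpd=in_sample,
    )


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    seed_used: int

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds})


def roc_holdout(
    cap: CapabilityMatrix,
    metabolite: str,
    host_family: str = "human",
    dominant: list[str] | None = None,
    split: float = 0.8,
    seed: int = 0,
    prior: PriorSpec = PriorSpec(),
    rank: str = "genus",
    n_min: int = 10,
) -> RocResult:
    """Train/test validation of one metabolite model at an 80/20 (default) split.

    Fits on the training fraction and scores the held-out strains; AUC is the
    rank statistic with tie correction.  If the test split lacks one of the
    two classes the split is re-drawn (up to 10 reseeds, with a warning).
    """
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve

    if dominant is None:
        dominant = dominant_taxa(cap, n_min=n_min, rank=rank)
    design = build_design(cap, metabolite, host_family, dominant, rank=rank)
    n = len(design.y)
    for attempt in range(10):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(n)
        n_train = int(round(split * n))
        train, test = perm[:n_train], perm[n_train:]
        if len(np.unique(design.y[test])) == 2 and len(test) > 0:
            if attempt:
                warnings.warn(f"test split degenerate; reseeded to {seed + attempt}")
            break
    else:
        raise TrpcapError("single-class test split after 10 reseeds")
    sub = DesignMatrix(
        X=design.X.iloc[train],
        y=design.y[train],
        metabolite=metabolite,
        host_family=host_family,
        rank=rank,
    )
    model = fit_bayes_logit(sub, prior=prior, seed=seed)
    scores = predict_proba(model, design.X.iloc[test])
    fpr, tpr, thr = roc_curve(design.y[test], scores)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(sk_auc(fpr, tpr)),
                     seed_used=seed + attempt)


# ---------------------------------------------------------------------------
# Reporting and persistence
# ---------------------------------------------------------------------------

def or_table(models: dict[str, MetaboliteModel], abbrev: dict[str, str] | None = None) -> pd.DataFrame:
    """Predictors x metabolites table of odds ratios (intercept omitted)."""
    cols = {}
    for met, m in models.items():
        name = (abbrev or {}).get(met, met)
        cols[name] = m.odds_ratios.drop(INTERCEPT, errors="ignore")
    return pd.DataFrame(cols)


def pvalue_table(models: dict[str, MetaboliteModel], abbrev: dict[str, str] | None = None) -> pd.DataFrame:
    cols = {}
    for met, m in models.items():
        name = (abbrev or {}).get(met, met)
        cols[name] = wald_tests(m)["p"].drop(INTERCEPT, errors="ignore")
    return pd.DataFrame(cols)


def save_models(models: dict[str, MetaboliteModel], path) -> None:
    """JSON bundle (coefficients, covariance, prior, seed) for reuse in prediction."""
    if not models:
        raise ValueError("empty model bundle")
    host = {m.host_family for m in models.values()}
    if len(host) > 1:
        raise ValueError(f"bundle mixes host families {sorted(host)}")
    any_model = next(iter(models.values()))
    payload = {
        "format": "trpcap-models v1",
        "host_family": any_model.host_family,
        "prior": {"slope_scale": any_model.prior.slope_scale,
                  "intercept_scale": any_model.prior.intercept_scale},
        "metabolites": {
            met: {
                "columns": m.columns,
                "beta": m.beta.tolist(),
                "cov": m.cov.tolist(),
                "log_lik": m.log_lik,
                "n_obs": m.n_obs,
                "seed": m.seed,
            }
            for met, m in models.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_models(path) -> dict[str, MetaboliteModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "trpcap-models v1":
        raise TrpcapError(f"{path}: not a trpcap model bundle")
    prior = PriorSpec(**payload["prior"])
    out = {}
    for met, spec in payload["metabolites"].items():
        out[met] = MetaboliteModel(
            metabolite=met,
            host_family=payload["host_family"],
            columns=list(spec["columns"]),
            beta=np.array(spec["beta"]),
            cov=np.array(spec["cov"]),
            prior=prior,
            log_lik=spec["log_lik"],
            n_obs=spec["n_obs"],
            seed=spec["seed"],
        )
    return out
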