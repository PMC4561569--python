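"""Binomial and Poisson GLMMs with crossed random intercepts, plus
AICc-based multimodel inference.

Models are fitted by maximum likelihood with the random effects
integrated out by a Laplace approximation: for fixed variance components
the joint penalized likelihood is maximized over fixed effects and random
intercepts by penalized IRLS, and the profiled Laplace log-likelihood

    ll(theta) = ll_y(eta_hat) - u_hat' D^-1 u_hat / 2 - log|I + Z'WZ D| / 2

is maximized over the random-effect standard deviations by a
derivative-free outer optimizer.  With all variances at zero the fit
collapses exactly to the ordinary GLM.

Multimodel inference follows the information-theoretic recipe common in
behavioural ecology: every marginality-respecting submodel is fitted on
the same complete-case rows, ranked by AICc, and coefficients are
averaged over the Delta-AICc < 2 confidence set (conditional "natural"
averaging by default), with per-term relative importance and
weighted-unconditional-SE confidence intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ModelSpec",
    "FitResult",
    "AveragedModel",
    "standardize",
    "design_matrix",
    "fit_glmm",
    "aicc",
    "build_candidate_set",
    "behaviour_candidate_terms",
    "ars_candidate_terms",
    "model_average",
    "average_fits",
]

#: predictors that are standardized; age2 is built from standardized age
_NUMERIC_PREDICTORS = ("age", "f", "tarsus")


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect structure for one candidate model.

    ``terms`` are main effects drawn from {age, age2, behaviour, f,
    tarsus}; ``interactions`` are pairs of mains.  The intercept is
    always present.  Marginality is enforced: age2 requires age, and an
    interaction requires both its mains.
    """

    response: str
    terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    random: tuple[str, ...] = ("year", "individual")
    family: str = "binomial"

    def __post_init__(self):
        if self.family not in ("binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if "age2" in self.terms and "age" not in self.terms:
            raise ValueError("age2 requires age (marginality)")
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ValueError(f"interaction {a}:{b} requires both main effects")

    @property
    def label(self) -> str:
        parts = list(self.terms) + [f"{a}:{b}" for a, b in self.interactions]
        return " + ".join(parts) if parts else "intercept-only"

    def all_terms(self) -> tuple[str, ...]:
        return tuple(self.terms) + tuple(f"{a}:{b}" for a, b in self.interactions)


@dataclass
class FitResult:
    spec: ModelSpec
    beta: dict[str, float]
    se: dict[str, float]
    varcomps: dict[str, float]
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    grad_norm: float
    messages: list[str] = field(default_factory=list)


@dataclass
class AveragedModel:
    response: str
    table: pd.DataFrame                # per-model: label, k, loglik, AICc, delta, weight, in_set
    confidence_set: list[FitResult]
    weights: dict[str, float]          # renormalized over the confidence set
    averaged_beta: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    relative_importance: dict[str, float]
    delta_threshold: float
    method: str

    def coef_table(self) -> pd.DataFrame:
        terms = list(self.averaged_beta)
        return pd.DataFrame(
            {
                "term": terms,
                "estimate": [self.averaged_beta[t] for t in terms],
                "ci_low": [self.ci_low[t] for t in terms],
                "ci_high": [self.ci_high[t] for t in terms],
                "relative_importance": [self.relative_importance[t] for t in terms],
            }
        )


# ---------------------------------------------------------------------------
# standardization and design


def standardize(
    table: pd.DataFrame, predictors: tuple[str, ...] = _NUMERIC_PREDICTORS
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Standardize predictors to mean 0, variance 1 (population sd).

    Adds ``<name>_s`` columns; for ``age`` additionally builds ``age2_s``
    as the standardized square of standardized age.  Returns the new
    frame and the (mean, sd) scaling per column for back-transformation.
    A constant predictor raises ``ValueError`` naming the column.
    """
    out = table.copy()
    scaling: dict[str, tuple[float, float]] = {}

    def _std(x: np.ndarray, name: str) -> np.ndarray:
        # sample (n-1) standard deviation: the usual scale() convention
        m, s = float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if s == 0.0:
            raise ValueError(f"predictor {name!r} is constant; cannot standardize")
        scaling[name] = (m, s)
        return (x - m) / s

    for p in predictors:
        if p not in out.columns:
            continue
        x = out[p].to_numpy(dtype=float)
        out[p + "_s"] = _std(x, p)
        if p == "age":
            out["age2_s"] = _std(out["age_s"].to_numpy() ** 2, "age2")
    if "status" in out.columns and out["status"].dtype == object:
        out["behaviour"] = (out["status"] == "territorial").astype(float)
    return out, scaling


def design_matrix(spec: ModelSpec, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Columns: intercept, standardized mains, products for interactions."""
    colmap = {
        "age": "age_s", "age2": "age2_s", "f": "f_s",
        "tarsus": "tarsus_s", "behaviour": "behaviour",
    }
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for t in spec.terms:
        cols.append(table[colmap[t]].to_numpy(dtype=float))
        names.append(t)
    for a, b in spec.interactions:
        cols.append(
            table[colmap[a]].to_numpy(dtype=float) * table[colmap[b]].to_numpy(dtype=float)
        )
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def _response_vector(spec: ModelSpec, table: pd.DataFrame) -> np.ndarray:
    if spec.response == "status":
        if table["status"].dtype == object:
            y = (table["status"] == "territorial").to_numpy(dtype=float)
        else:
            y = table["status"].to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binomial response must be binary")
        return y
    y = table[spec.response].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("Poisson response must be a non-negative integer count")
    return y


def _random_codes(spec: ModelSpec, table: pd.DataFrame) -> list[tuple[str, np.ndarray, int]]:
    colmap = {"year": "year", "individual": "male_id"}
    out = []
    for r in spec.random:
        codes, uniq = pd.factorize(table[colmap[r]])
        if len(uniq) < 2:
            raise ValueError(f"random factor {r!r} needs >= 2 levels")
        out.append((r, codes.astype(np.int64), len(uniq)))
    return out


# ---------------------------------------------------------------------------
# likelihood machinery


def _family_funcs(family: str):
    if family == "binomial":
        def mu_w(eta):
            mu = 1.0 / (1.0 + np.exp(-eta))
            return mu, mu * (1.0 - mu)
        def ll(y, eta):
            # logistic log-likelihood, stable form
            return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    else:
        def mu_w(eta):
            mu = np.exp(np.clip(eta, -30, 30))
            return mu, mu
        def ll(y, eta):
            mu = np.exp(np.clip(eta, -30, 30))
            return float(np.sum(y * eta - mu - _lgamma_cache(y)))
    return mu_w, ll


def _lgamma_cache(y: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln
    return gammaln(y + 1.0)


def _combined_design(X: np.ndarray, blocks) -> np.ndarray:
    """Dense combined design [Z1 | Z2 ... | X].

    The random-effect columns lead so that one Cholesky of the joint
    Hessian yields log|H_uu| from its leading diagonal entries.
    """
    n, p = X.shape
    qtot = int(sum(q for _, _, q in blocks))
    C = np.zeros((n, p + qtot))
    off = 0
    for (_, codes, q) in blocks:
        C[np.arange(n), off + codes] = 1.0
        off += q
    C[:, qtot:] = X
    return C


def _pirls(y, X, blocks, sig2s, family, *, tol=1e-10, max_iter=200, start=None, C=None):
    """Penalized IRLS for the joint mode over (beta, u).

    ``blocks`` is [(name, codes, q)] for the active random factors with
    variances ``sig2s``.  Returns the Laplace profile log-likelihood and
    the pieces needed for SEs.
    """
    from scipy.linalg import cho_factor, cho_solve

    n, p = X.shape
    qs = [q for _, _, q in blocks]
    qtot = int(sum(qs))
    if C is None:
        C = _combined_design(X, blocks)
    pen = np.zeros(p + qtot)
    off = 0
    for s2, q in zip(sig2s, qs):
        pen[off:off + q] = 1.0 / s2
        off += q
    mu_w, ll = _family_funcs(family)
    didx = np.arange(p + qtot)

    if start is not None and start.shape == (p + qtot,):
        delta = start.copy()
    else:
        delta = np.zeros(p + qtot)
        # crude start for the intercept keeps IRLS away from flat regions
        if family == "poisson":
            delta[qtot] = math.log(max(float(np.mean(y)), 1e-3))
        else:
            pbar = min(max(float(np.mean(y)), 1e-3), 1 - 1e-3)
            delta[qtot] = math.log(pbar / (1 - pbar))
    obj_old = -np.inf
    cf = None
    for _ in range(max_iter):
        eta = C @ delta
        mu, w = mu_w(eta)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        CtW = C.T * w
        H = CtW @ C
        H[didx, didx] += pen
        rhs = CtW @ z
        try:
            cf = cho_factor(H, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            H[didx, didx] += 1e-8
            cf = cho_factor(H, lower=True, check_finite=False)
        delta_new = cho_solve(cf, rhs, check_finite=False)
        # step-halving on the penalized objective
        step = 1.0
        for _ in range(30):
            cand = delta + step * (delta_new - delta)
            obj = ll(y, C @ cand) - 0.5 * float(np.sum(pen * cand**2))
            if obj >= obj_old - 1e-12 or step < 1e-6:
                break
            step *= 0.5
        delta = cand
        if abs(obj - obj_old) < tol * (1.0 + abs(obj)):
            obj_old = obj
            break
        obj_old = obj
    eta = C @ delta
    mu, w = mu_w(eta)
    w = np.maximum(w, 1e-10)
    CtW = C.T * w
    H = CtW @ C
    H[didx, didx] += pen
    cf = cho_factor(H, lower=True, check_finite=False)
    ll_y = ll(y, eta)
    u_pen = 0.5 * float(np.sum(pen[:qtot] * delta[:qtot] ** 2))
    # log|I + Z'WZ D| = log|H_uu| + sum q log sig2; with the random-effect
    # columns leading, |H_uu| is the leading principal minor of the
    # Cholesky factor of H
    if qtot:
        logdet_Huu = 2.0 * float(np.sum(np.log(np.diag(cf[0])[:qtot])))
        logdet = logdet_Huu + sum(q * math.log(s2) for s2, q in zip(sig2s, qs))
    else:
        logdet = 0.0
    lap = ll_y - u_pen - 0.5 * logdet
    grad = C.T @ (y - mu) - pen * delta  # score of penalized ll (canonical link)
    # conditional covariance of the fixed effects (trailing block of H^-1)
    eye_p = np.zeros((p + qtot, p))
    eye_p[qtot:, :] = np.eye(p)
    cov_beta = cho_solve(cf, eye_p, check_finite=False)[qtot:, :]
    return {
        "delta": delta, "qtot": qtot, "p": p, "laplace": lap,
        "grad_norm": float(np.linalg.norm(grad)),
        "eta": eta, "cov_beta": cov_beta,
    }


def fit_glmm(
    spec: ModelSpec,
    table: pd.DataFrame,
    *,
    forced_varcomps: dict[str, float] | None = None,
    sigma_start: dict[str, float] | None = None,
) -> FitResult:
    """Fit one GLMM by Laplace-approximated maximum likelihood.

    ``forced_varcomps`` pins random-effect variances (e.g. to 0, which
    reproduces the ordinary GLM).  The parameter count ``k`` is the
    number of fixed coefficients plus the number of free random-effect
    variances, matching how information criteria are reported for such
    models.
    """
    y = _response_vector(spec, table)
    X, names = design_matrix(spec, table)
    blocks_all = _random_codes(spec, table)
    n = len(y)
    messages: list[str] = []

    if forced_varcomps is not None:
        sigmas = np.sqrt([max(forced_varcomps.get(r, 0.0), 0.0) for r, _, _ in blocks_all])
        res, sig_opt = _profile_fit(y, X, blocks_all, sigmas, spec.family, optimize_sigmas=False)
        n_var_free = 0
    else:
        x0 = np.array(
            [max(sigma_start.get(r, 0.4), 0.05) if sigma_start else 0.4 for r, _, _ in blocks_all]
        )
        res, sig_opt = _profile_fit(y, X, blocks_all, x0, spec.family, optimize_sigmas=True)
        n_var_free = len(blocks_all)

    delta, p, qtot = res["delta"], res["p"], res["qtot"]
    beta_hat = delta[qtot:]
    se = np.sqrt(np.maximum(np.diag(res["cov_beta"]), 0.0))
    if spec.family == "binomial" and np.max(np.abs(res["eta"])) > 15:
        messages.append("possible separation: |linear predictor| > 15")
    converged = res["grad_norm"] < 1e-4 * (1 + abs(res["laplace"]))
    if not converged:
        messages.append(f"gradient norm {res['grad_norm']:.2e} at solution")

    k = p + n_var_free
    return FitResult(
        spec=spec,
        beta=dict(zip(names, (float(b) for b in beta_hat))),
        se=dict(zip(names, (float(s) for s in se))),
        varcomps={r: float(s**2) for (r, _, _), s in zip(blocks_all, sig_opt)},
        loglik=float(res["laplace"]),
        k=k,
        n=n,
        aicc=aicc(res["laplace"], k, n),
        converged=bool(converged),
        grad_norm=res["grad_norm"],
        messages=messages,
    )


def _profile_fit(y, X, blocks_all, sigmas, family, *, optimize_sigmas):
    """Inner/outer loop: PIRLS inside, Powell over sigmas outside.

    The PIRLS mode is warm-started from the previous outer evaluation,
    which makes the inner solve nearly free once the outer search is in
    the right neighbourhood.
    """
    warm: dict = {"delta": None}
    C_cache: dict[tuple, np.ndarray] = {}

    def run(sig_vec):
        active = [(b, s) for b, s in zip(blocks_all, sig_vec) if s > 1e-6]
        blocks = [b for b, _ in active]
        sig2s = [s**2 for _, s in active]
        key = tuple(name for name, _, _ in blocks)
        if key not in C_cache:
            C_cache[key] = _combined_design(X, blocks)
        full = len(blocks) == len(blocks_all)
        res = _pirls(
            y, X, blocks, sig2s, family,
            start=warm["delta"] if full else None, C=C_cache[key],
        )
        if full:
            warm["delta"] = res["delta"]
        return res

    if not optimize_sigmas or not blocks_all:
        return run(sigmas), sigmas

    def neg(sig_vec):
        return -run(np.abs(sig_vec))["laplace"]

    x0 = np.asarray(sigmas, dtype=float)
    opt = optimize.minimize(
        neg, x0, method="L-BFGS-B",
        bounds=[(0.0, 10.0)] * len(x0),
        options={"ftol": 1e-10, "gtol": 1e-5, "eps": 2e-4, "maxfun": 120},
    )
    sig_opt = np.abs(opt.x)
    sig_opt[sig_opt <= 1e-4] = 0.0
    return run(sig_opt), sig_opt


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 ll + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# ---------------------------------------------------------------------------
# candidate sets and model averaging


def build_candidate_set(
    response: str,
    terms: tuple[str, ...],
    interactions: tuple[tuple[str, str], ...] = (),
    *,
    family: str = "binomial",
    random: tuple[str, ...] = ("year", "individual"),
) -> list[ModelSpec]:
    """All marginality-respecting submodels of the declared structure.

    Every subset of the mains with age2-requires-age, crossed with every
    subset of the interactions whose mains are present.
    """
    specs = []
    for r in range(len(terms) + 1):
        for mains in itertools.combinations(terms, r):
            if "age2" in mains and "age" not in mains:
                continue
            avail = [ix for ix in interactions if ix[0] in mains and ix[1] in mains]
            for s in range(len(avail) + 1):
                for ints in itertools.combinations(avail, s):
                    specs.append(
                        ModelSpec(
                            response=response, terms=mains, interactions=ints,
                            random=random, family=family,
                        )
                    )
    return specs


def behaviour_candidate_terms() -> tuple[tuple[str, ...], tuple[tuple[str, str], ...]]:
    """Model set 1: mains age + age2, f, tarsus; inbreeding-by-quality and
    quality-by-quality interactions."""
    return ("age", "age2", "f", "tarsus"), (("age2", "f"), ("tarsus", "f"), ("age2", "tarsus"))


def ars_candidate_terms() -> tuple[tuple[str, ...], tuple[tuple[str, str], ...]]:
    """Model set 3: adds mating behaviour and its interactions with male
    quality measures."""
    terms = ("behaviour", "age", "age2", "f", "tarsus")
    inters = (("behaviour", "f"), ("behaviour", "age"), ("behaviour", "tarsus"))
    return terms, inters


def model_average(
    candidates: list[ModelSpec],
    table: pd.DataFrame,
    *,
    delta_threshold: float = 2.0,
    method: str = "conditional",
) -> AveragedModel:
    """Fit candidates on common rows, rank by AICc, average the top set.

    Confidence set: Delta-AICc strictly below ``delta_threshold``.
    ``method="conditional"`` averages each coefficient over the models
    that contain it (natural averaging); ``method="full"`` substitutes 0
    where a term is absent.  CIs are Normal intervals from the weighted
    unconditional SE (which folds between-model spread into the SE).
    """
    if not candidates:
        raise ValueError("empty candidate set")
    if method not in ("conditional", "full"):
        raise ValueError(f"unknown averaging method {method!r}")
    responses = {c.response for c in candidates}
    if len(responses) > 1:
        raise ValueError("candidates mix responses")

    # complete-case intersection over every column any candidate uses
    used_terms = set().union(*(set(c.terms) for c in candidates))
    needed = tuple(t for t in ("age", "f", "tarsus") if t in used_terms)
    cols = list(needed) + [candidates[0].response]
    rows = table.dropna(subset=[c for c in cols if c in table.columns])
    rows, _ = standardize(rows, predictors=needed)

    # fit the richest model first; its variance estimates warm-start the rest
    order = sorted(range(len(candidates)), key=lambda i: -len(candidates[i].all_terms()))
    fits_by_idx: dict[int, FitResult] = {}
    sigma_start: dict[str, float] | None = None
    for i in order:
        fr = fit_glmm(candidates[i], rows, sigma_start=sigma_start)
        if sigma_start is None:
            sigma_start = {r: math.sqrt(v) for r, v in fr.varcomps.items()}
        fits_by_idx[i] = fr
    fits = [fits_by_idx[i] for i in range(len(candidates))]
    return average_fits(fits, delta_threshold=delta_threshold, method=method)


def average_fits(
    fits: list[FitResult],
    *,
    delta_threshold: float = 2.0,
    method: str = "conditional",
) -> AveragedModel:
    """Model-average already-fitted candidates (see :func:`model_average`)."""
    if not fits:
        raise ValueError("empty fit list")
    if method not in ("conditional", "full"):
        raise ValueError(f"unknown averaging method {method!r}")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    rel = np.exp(-0.5 * delta)
    w_all = rel / rel.sum()
    in_set = delta < delta_threshold

    conf = [f for f, keep in zip(fits, in_set) if keep]
    w_set = np.exp(-0.5 * delta[in_set])
    w_set = w_set / w_set.sum()
    weights = {f.spec.label: float(w) for f, w in zip(conf, w_set)}

    all_terms: list[str] = []
    for f in conf:
        for t in ("intercept",) + f.spec.all_terms():
            if t not in all_terms:
                all_terms.append(t)

    avg, lo, hi, imp = {}, {}, {}, {}
    for t in all_terms:
        has = np.array([t in ("intercept",) + f.spec.all_terms() for f in conf])
        imp[t] = float(w_set[has].sum()) if t != "intercept" else 1.0
        betas = np.array([f.beta.get(t, 0.0) for f in conf])
        ses = np.array([f.se.get(t, 0.0) for f in conf])
        if method == "conditional":
            w = np.where(has, w_set, 0.0)
            w = w / w.sum()
        else:
            w = w_set
        b = float(np.sum(w * betas))
        se_u = float(np.sum(w * np.sqrt(ses**2 + (betas - b) ** 2)))
        avg[t], lo[t], hi[t] = b, b - 1.959963984540054 * se_u, b + 1.959963984540054 * se_u

    tab = pd.DataFrame(
        {
            "model": [f.spec.label for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "AICc": aiccs,
            "delta_AICc": delta,
            "weight": w_all,
            "in_confidence_set": in_set,
        }
    ).sort_values("AICc", kind="stable").reset_index(drop=True)

    return AveragedModel(
        response=fits[0].spec.response,
        table=tab,
        confidence_set=conf,
        weights=weights,
        averaged_beta=avg,
        ci_low=lo,
        ci_high=hi,
        relative_importance=imp,
        delta_threshold=delta_threshold,
        method=method,
    )
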