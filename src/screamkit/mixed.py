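"""Mixed-effects inference on acoustic correlates.

Gaussian linear mixed models (REML) with two crossed random intercepts
(caller identity and event) relate each retained acoustic parameter to the
signaller's social role, conflict severity and their interaction; a binomial
logit mixed model (Laplace approximation) relates third-party support to the
same fixed effects with caller and recording-context intercepts.  The 36
fixed-effect p-values (12 responses x 3 effects) are adjusted jointly with
the Benjamini-Hochberg step-up procedure.  Marginal/conditional R² follow the
variance-partition formulation (fixed-effect variance over total; plus random
components for the conditional value; logit residual variance π²/3).

The Gaussian REML fitter is implemented directly (dense covariance, profiled
error variance, Nelder-Mead over the two variance ratios) and is validated
against statsmodels' MixedLM in the test suite; statsmodels has no Laplace
binomial GLMM with crossed random effects, so that fitter is implemented here
as well (penalized IRLS for the joint mode, Laplace objective in the variance
parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "LinearMixedModel",
    "BinomialMixedModel",
    "EffectResult",
    "KappaResult",
    "PrunePolicy",
    "bh_adjust",
    "cohen_kappa",
    "quantize_for_kappa",
    "fit_effect_model",
    "run_all_models",
    "support_model",
    "diagnose_and_prune",
    "CALL_RESPONSES",
    "BOUT_RESPONSES",
]

#: The retained response set: eight call-level and four bout-level parameters
#: (coefficient of frequency variation, bout duration and scream intervals are
#: excluded a priori for collinearity/asymmetry).
CALL_RESPONSES = [
    "duration",
    "peak_freq",
    "coef_mod",
    "trans_onset",
    "trans_offset",
    "q50",
    "iqr",
    "entropy",
]
BOUT_RESPONSES = ["n_screams", "avg_scream_duration", "scream_rate", "pct_nlp"]


def _codes(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(pd.Series(values).astype(str))
    return codes, len(uniques)


class LinearMixedModel:
    """Gaussian LMM with independent random intercepts, fitted by REML.

    Covariance: ``V = sigma2 * (I + sum_j gamma_j Z_j Z_j')`` where each
    ``Z_j`` is the indicator matrix of one grouping factor (factors may be
    crossed).  The error variance is profiled out and the variance ratios
    ``gamma_j`` are optimized by Nelder-Mead on the log scale.

    Fitted attributes: ``beta_``, ``se_``, ``sigma2_``, ``varcomps_`` (dict of
    random-intercept variances), ``loglik_`` (restricted), ``converged_``,
    ``singular_``, ``resid_`` (conditional), ``r2_marginal_``,
    ``r2_conditional_``.
    """

    def __init__(self, max_iter: int = 300):
        self.max_iter = max_iter

    def fit(self, y, X, groups: dict[str, np.ndarray]) -> "LinearMixedModel":
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if np.std(y) == 0:
            raise ValueError("response is degenerate (zero variance)")
        names = list(groups)
        Zs = []
        for name in names:
            codes, q = _codes(groups[name])
            Z = np.zeros((n, q))
            Z[np.arange(n), codes] = 1.0
            Zs.append(Z)
        grams = [Z @ Z.T for Z in Zs]

        def reml_neg(log_gamma: np.ndarray) -> float:
            gam = np.exp(np.clip(log_gamma, -12, 12))
            V = np.eye(n)
            for g, G in zip(gam, grams):
                V += g * G
            try:
                c, low = linalg.cho_factor(V, lower=True)
            except linalg.LinAlgError:
                return 1e12
            logdetV = 2.0 * np.log(np.diag(c)).sum()
            ViX = linalg.cho_solve((c, low), X)
            Viy = linalg.cho_solve((c, low), y)
            XtViX = X.T @ ViX
            try:
                beta = linalg.solve(XtViX, X.T @ Viy, assume_a="pos")
            except linalg.LinAlgError:
                return 1e12
            r = y - X @ beta
            quad = float(r @ linalg.cho_solve((c, low), r))
            if quad <= 0:
                return 1e12
            sigma2 = quad / (n - p)
            sign, logdetXtViX = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return 1e12
            return 0.5 * ((n - p) * math.log(sigma2) + logdetV + logdetXtViX + (n - p))

        x0 = np.zeros(len(Zs)) + math.log(0.5)
        res = optimize.minimize(
            reml_neg, x0, method="Nelder-Mead",
            options={"maxiter": self.max_iter, "xatol": 1e-4, "fatol": 1e-7},
        )
        self.converged_ = bool(res.success)
        gam = np.exp(np.clip(res.x, -12, 12))

        V = np.eye(n)
        for g, G in zip(gam, grams):
            V += g * G
        c, low = linalg.cho_factor(V, lower=True)
        ViX = linalg.cho_solve((c, low), X)
        Viy = linalg.cho_solve((c, low), y)
        XtViX = X.T @ ViX
        beta = linalg.solve(XtViX, X.T @ Viy, assume_a="pos")
        r = y - X @ beta
        sigma2 = float(r @ linalg.cho_solve((c, low), r)) / (n - p)
        cov_beta = sigma2 * linalg.inv(XtViX)

        self.names_ = names
        self.beta_ = beta
        self.se_ = np.sqrt(np.diag(cov_beta))
        self.cov_beta_ = cov_beta
        self.sigma2_ = sigma2
        self.varcomps_ = {name: float(sigma2 * g) for name, g in zip(names, gam)}
        self.singular_ = any(v < 1e-8 * sigma2 for v in self.varcomps_.values())
        self.loglik_ = -res.fun
        self.n_, self.p_ = n, p

        # BLUPs and conditional residuals for diagnostics
        Vir = linalg.cho_solve((c, low), r)
        self.ranef_ = {}
        cond = r.copy()
        for name, Z, g in zip(names, Zs, gam):
            u = g * (Z.T @ Vir)  # BLUP: tau2 Z' (sigma2 V)^-1 r = gamma Z' V^-1 r
            self.ranef_[name] = u
            cond -= Z @ u
        self.resid_ = cond
        self.fitted_ = y - cond

        var_fixed = float(np.var(X @ beta))
        var_rand = float(sum(self.varcomps_.values()))
        total = var_fixed + var_rand + sigma2
        self.r2_marginal_ = var_fixed / total
        self.r2_conditional_ = (var_fixed + var_rand) / total
        return self

    def wald(self, alpha: float = 0.05) -> pd.DataFrame:
        zq = stats.norm.ppf(1 - alpha / 2)
        stat = self.beta_ / self.se_
        p = 2 * stats.norm.sf(np.abs(stat))
        return pd.DataFrame(
            {
                "estimate": self.beta_,
                "se": self.se_,
                "stat": stat,
                "ci_low": self.beta_ - zq * self.se_,
                "ci_high": self.beta_ + zq * self.se_,
                "p": p,
            }
        )


class BinomialMixedModel:
    """Binomial-logit GLMM with independent random intercepts (Laplace).

    For fixed variance parameters the joint mode of (fixed effects, random
    effects) is found by penalized IRLS; the Laplace-approximate marginal
    likelihood is then maximized over the log random-intercept standard
    deviations by Nelder-Mead.  Wald standard errors come from the fixed-
    effect block of the inverse joint Hessian at the optimum.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def _pirls(self, y, X, Zs, tau2, beta0=None, u0=None):
        n, p = X.shape
        qs = [Z.shape[1] for Z in Zs]
        Z = np.hstack(Zs) if Zs else np.zeros((n, 0))
        q = Z.shape[1]
        pen = np.concatenate([np.full(k, 1.0 / t2) for k, t2 in zip(qs, tau2)]) if q else np.zeros(0)
        A = np.hstack([X, Z])
        coef = np.zeros(p + q)
        if beta0 is not None:
            coef[:p] = beta0
        if u0 is not None:
            coef[p:] = u0
        P = np.concatenate([np.zeros(p), pen])
        for _ in range(100):
            eta = A @ coef
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            W = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / W
            H = (A * W[:, None]).T @ A + np.diag(P)
            b = (A * W[:, None]).T @ z
            try:
                new = linalg.solve(H, b, assume_a="pos")
            except linalg.LinAlgError:
                new = linalg.lstsq(H, b)[0]
            if np.max(np.abs(new - coef)) < self.tol * (1 + np.max(np.abs(coef))):
                coef = new
                break
            coef = new
        eta = A @ coef
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        W = np.clip(mu * (1 - mu), 1e-10, None)
        return coef, mu, W, A, P

    def fit(self, y, X, groups: dict[str, np.ndarray]) -> "BinomialMixedModel":
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        names = list(groups)
        Zs = []
        for name in names:
            codes, qk = _codes(groups[name])
            Z = np.zeros((n, qk))
            Z[np.arange(n), codes] = 1.0
            Zs.append(Z)
        qs = [Z.shape[1] for Z in Zs]

        def neg_laplace(log_sd: np.ndarray) -> float:
            tau2 = np.exp(2 * np.clip(log_sd, -6, 4))
            coef, mu, W, A, P = self._pirls(y, X, Zs, tau2)
            u = coef[p:]
            ll = float(np.sum(y * np.log(np.clip(mu, 1e-12, None)) + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None))))
            pen = 0.5 * float(u @ (P[p:] * u))
            logdetD = float(sum(k * math.log(t2) for k, t2 in zip(qs, tau2)))
            Zmat = A[:, p:]
            H = (Zmat * W[:, None]).T @ Zmat + np.diag(P[p:])
            sign, logdetH = np.linalg.slogdet(H)
            if sign <= 0:
                return 1e12
            return -(ll - pen - 0.5 * logdetD - 0.5 * logdetH)

        x0 = np.full(len(Zs), math.log(0.5))
        res = optimize.minimize(
            neg_laplace, x0, method="Nelder-Mead",
            options={"maxiter": self.max_iter, "xatol": 1e-3, "fatol": 1e-6},
        )
        self.converged_ = bool(res.success)
        sd = np.exp(np.clip(res.x, -6, 4))
        tau2 = sd**2
        coef, mu, W, A, P = self._pirls(y, X, Zs, tau2)
        H = (A * W[:, None]).T @ A + np.diag(P)
        try:
            cov = linalg.inv(H)
        except linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        self.names_ = names
        self.beta_ = coef[:p]
        self.se_ = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        self.varcomps_ = {name: float(t2) for name, t2 in zip(names, tau2)}
        self.singular_ = any(t2 < 1e-6 for t2 in tau2)
        self.loglik_ = -res.fun
        self.mu_ = mu
        self.n_, self.p_ = n, p

        var_fixed = float(np.var(X @ self.beta_))
        var_rand = float(sum(tau2))
        total = var_fixed + var_rand + math.pi**2 / 3.0
        self.r2_marginal_ = var_fixed / total
        self.r2_conditional_ = (var_fixed + var_rand) / total
        return self

    def wald(self, alpha: float = 0.05) -> pd.DataFrame:
        zq = stats.norm.ppf(1 - alpha / 2)
        stat = self.beta_ / self.se_
        p = 2 * stats.norm.sf(np.abs(stat))
        return pd.DataFrame(
            {
                "estimate": self.beta_,
                "se": self.se_,
                "stat": stat,
                "ci_low": self.beta_ - zq * self.se_,
                "ci_high": self.beta_ + zq * self.se_,
                "p": p,
            }
        )


# ---------------------------------------------------------------------------
# Multiple testing, kappa


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


def quantize_for_kappa(values, tol: float) -> np.ndarray:
    """Bin continuous measurements into tolerance-wide categories.

    Reliability protocols count two coders' continuous measurements (event
    duration, scream duration) as agreeing when they differ by less than a
    tolerance; rounding to multiples of ``tol`` turns such measurements into
    the categorical sequences :func:`cohen_kappa` expects.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    return np.round(np.asarray(values, dtype=float) / tol).astype(int)


@dataclass
class KappaResult:
    kappa: float
    n_items: int
    observed_agreement: float
    expected_agreement: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.kappa)


def cohen_kappa(coder_a, coder_b) -> KappaResult:
    """Cohen's kappa for two equal-length categorical sequences.

    kappa = (po - pe) / (1 - pe).  When both coders use a single identical
    category, chance agreement is 1 and kappa is undefined (NaN).
    """
    a = pd.Series(coder_a).astype(str)
    b = pd.Series(coder_b).astype(str)
    if len(a) != len(b):
        raise ValueError("coder sequences must have equal length")
    if len(a) == 0:
        raise ValueError("empty sequences")
    n = len(a)
    po = float((a.values == b.values).mean())
    cats = sorted(set(a) | set(b))
    pa = a.value_counts().reindex(cats, fill_value=0) / n
    pb = b.value_counts().reindex(cats, fill_value=0) / n
    pe = float((pa * pb).sum())
    kappa = (po - pe) / (1 - pe) if pe < 1.0 else float("nan")
    return KappaResult(kappa=kappa, n_items=n, observed_agreement=po, expected_agreement=pe)


# ---------------------------------------------------------------------------
# Effect models over the feature tables


@dataclass
class EffectResult:
    """One fixed-effect row of the inference ledger."""

    response: str
    effect: str
    estimate: float
    se: float
    stat: float
    ci_low: float
    ci_high: float
    p: float
    p_adjusted: float | None
    r2_marginal: float
    r2_conditional: float
    n_individuals: int
    n_units: int
    outliers_removed: int = 0
    transform: str = "identity"
    singular: bool = False
    converged: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


_EFFECTS = ["role[victim]", "severity[severe]", "role[victim]:severity[severe]"]


def _design_matrix(data: pd.DataFrame) -> np.ndarray:
    role = (data["role"].astype(str) == "victim").astype(float).to_numpy()
    sev = (data["severity"].astype(str) == "severe").astype(float).to_numpy()
    return np.column_stack([np.ones(len(data)), role, sev, role * sev])


def _symmetrize(y: np.ndarray) -> tuple[np.ndarray, str]:
    """Transform toward symmetry (identity/sqrt/log by |skewness|), then scale."""
    from .dfa import SymmetrizingScaler

    sc = SymmetrizingScaler().fit(y[:, None])
    return sc.transform(y[:, None])[:, 0], sc.transforms_[0]


def fit_effect_model(
    data: pd.DataFrame,
    response: str,
    random_factors: tuple[str, str] = ("caller_id", "event_id"),
    family: str = "gaussian",
    transform: bool = True,
) -> tuple[list[EffectResult], object]:
    """Fit one mixed model and return its three fixed-effect rows.

    Gaussian responses are symmetry-transformed and standardized before a
    REML fit with crossed random intercepts; the binomial family models a
    yes/no response on the logit scale (no transform).
    """
    need = [response, "role", "severity", *random_factors]
    work = data.dropna(subset=[c for c in need if c in data.columns]).copy()
    if work[response].nunique() < 2:
        raise ValueError(f"response {response!r} is degenerate")
    if work["caller_id"].nunique() < 2:
        raise ValueError("need at least 2 callers")
    X = _design_matrix(work)
    groups = {f: work[f].to_numpy() for f in random_factors}
    tname = "identity"
    if family == "gaussian":
        y = work[response].to_numpy(dtype=float)
        if transform:
            y, tname = _symmetrize(y)
        model = LinearMixedModel().fit(y, X, groups)
    elif family == "binomial":
        y = (work[response].astype(str) == "yes").astype(float).to_numpy()
        model = BinomialMixedModel().fit(y, X, groups)
    else:
        raise ValueError(f"unknown family {family!r}")
    wald = model.wald()
    rows = []
    for k, eff in enumerate(_EFFECTS, start=1):
        rows.append(
            EffectResult(
                response=response,
                effect=eff,
                estimate=float(wald["estimate"][k]),
                se=float(wald["se"][k]),
                stat=float(wald["stat"][k]),
                ci_low=float(wald["ci_low"][k]),
                ci_high=float(wald["ci_high"][k]),
                p=float(wald["p"][k]),
                p_adjusted=None,
                r2_marginal=model.r2_marginal_,
                r2_conditional=model.r2_conditional_,
                n_individuals=int(work["caller_id"].nunique()),
                n_units=len(work),
                transform=tname,
                singular=model.singular_,
                converged=model.converged_,
            )
        )
    return rows, model


def run_all_models(
    call_table: pd.DataFrame,
    bout_table: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Fit the 12 response models and BH-adjust the 36 p-values jointly.

    Model failures are recorded in the ledger (NaN statistics) without
    stopping the remaining fits; their p-values are excluded from the BH
    family.  Returns the ledger as a DataFrame with a ``significant`` column
    at FDR level ``q``.
    """
    rows: list[EffectResult] = []
    failures: list[dict] = []
    for table, responses in ((call_table, CALL_RESPONSES), (bout_table, BOUT_RESPONSES)):
        for resp in responses:
            try:
                fits, _ = fit_effect_model(table, resp)
                rows.extend(fits)
            except Exception as exc:  # recorded, not raised
                for eff in _EFFECTS:
                    failures.append({"response": resp, "effect": eff, "error": str(exc)})
    ledger = pd.DataFrame([r.as_dict() for r in rows])
    if not ledger.empty:
        ledger["p_adjusted"] = bh_adjust(ledger["p"].to_numpy())
        ledger["significant"] = ledger["p_adjusted"] <= q
    for f in failures:
        ledger = pd.concat([ledger, pd.DataFrame([f])], ignore_index=True)
    return ledger


def support_model(bout_table: pd.DataFrame) -> tuple[list[EffectResult], BinomialMixedModel]:
    """Binomial GLMM of third-party support at the bout level.

    Random intercepts: caller identity and the 4-level recording context
    (falls back to the binary context column when the detailed one is
    absent).
    """
    ctx = "context4" if "context4" in bout_table.columns else "context"
    return fit_effect_model(
        bout_table, "support", random_factors=("caller_id", ctx), family="binomial"
    )


# ---------------------------------------------------------------------------
# Diagnostics


@dataclass
class PrunePolicy:
    """What diagnose_and_prune is allowed to remove (flags are always set)."""

    remove_outliers: bool = False
    remove_influential: bool = False
    resid_threshold: float = 3.0
    influence_se_factor: float = 1.0


def diagnose_and_prune(
    data: pd.DataFrame,
    response: str,
    policy: PrunePolicy | None = None,
    random_factors: tuple[str, str] = ("caller_id", "event_id"),
) -> tuple[pd.DataFrame, dict]:
    """Residual outlier and influential-caller screening for one model.

    Rows whose |standardized conditional residual| exceeds the policy
    threshold are flagged; callers whose removal moves any fixed-effect
    estimate by more than ``influence_se_factor`` standard errors are flagged.
    Removals happen only under the explicit policy and are logged with
    before/after estimates.
    """
    policy = policy or PrunePolicy()
    work = data.dropna(subset=[response]).reset_index(drop=True)
    rows, model = fit_effect_model(work, response, random_factors=random_factors)
    sd = math.sqrt(model.sigma2_)
    std_resid = model.resid_ / sd
    outlier_mask = np.abs(std_resid) > policy.resid_threshold
    before = np.array([r.estimate for r in rows])

    influential = []
    for caller in work["caller_id"].unique():
        sub = work[work["caller_id"] != caller]
        if sub["caller_id"].nunique() < 2 or sub[response].nunique() < 2:
            continue
        try:
            rows_i, _ = fit_effect_model(sub, response, random_factors=random_factors)
        except Exception:
            continue
        delta = np.array([r.estimate for r in rows_i]) - before
        ses = np.array([r.se for r in rows])
        if np.any(np.abs(delta) > policy.influence_se_factor * ses):
            influential.append(str(caller))

    log = {
        "n_outliers_flagged": int(outlier_mask.sum()),
        "outlier_rows": work.index[outlier_mask].tolist(),
        "influential_callers": influential,
        "estimates_before": before.tolist(),
        "removed_outliers": 0,
        "removed_callers": [],
    }
    cleaned = work
    if policy.remove_outliers and outlier_mask.any():
        cleaned = cleaned[~outlier_mask]
        log["removed_outliers"] = int(outlier_mask.sum())
    if policy.remove_influential and influential:
        cleaned = cleaned[~cleaned["caller_id"].isin(influential)]
        log["removed_callers"] = influential
    if log["removed_outliers"] or log["removed_callers"]:
        rows_after, _ = fit_effect_model(cleaned, response, random_factors=random_factors)
        log["estimates_after"] = [r.estimate for r in rows_after]
    return cleaned.reset_index(drop=True), log
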