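"""Angling-survival models and standardized selection gradients.

The survival component of fitness is binary: a fish first captured within the
horizon is scored 0 ("theoretically dead"), otherwise 1.  Candidate logistic
models over the z-standardized traits (BP, TL, G, SB, SH, SP and the
quadratic terms G², BP²) are ranked by small-sample AICc and Akaike weights;
the coefficients of the final model are linearized (average-gradient
transformation: ``beta_SD = alpha * mean(W(1-W)) / Wbar``) and converted to
mean-standardized gradients ``beta_mu = beta_SD * mu / sigma`` — the relative
fitness change from doubling the trait, unit free and comparable across
traits.

Pond replication enters as a pond-level intercept: ``pond_mode="random"``
(default) fits a Laplace-approximated random intercept, ``"fixed"`` uses pond
dummies, ``"none"`` pools.  The parameter count ``k`` used by AICc counts
fixed effects including the intercept only, matching how the candidate-set
parameter column is conventionally reported (NULL model: k = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = [
    "TraitMatrix",
    "FitResult",
    "PondLogisticRegression",
    "growth_residuals",
    "zstandardize",
    "assign_fitness",
    "fit_logistic",
    "aicc",
    "akaike_weights",
    "MODEL_SETS",
    "run_model_set",
    "select_final_model",
    "janzen_stern",
    "mean_standardized_gradients",
    "nagelkerke_r2",
    "selection_gradients",
    "trait_descriptives",
]

BASE_TRAITS = ("BP", "TL", "G", "SB", "SH", "SP")
DERIVED_TRAITS = ("G2", "BP2")


# ---------------------------------------------------------------------------
# trait preparation


def growth_residuals(increment, bp) -> np.ndarray:
    """Growth increment with its boldness-correlated part regressed out (OLS)."""
    increment = np.asarray(increment, dtype=float).ravel()
    bp = np.asarray(bp, dtype=float).ravel()
    if increment.shape != bp.shape:
        raise ValueError("increment and BP must be paired")
    if len(increment) < 3:
        raise ValueError("growth residuals need n >= 3")
    if np.ptp(bp) == 0:
        raise ValueError("BP is constant; residual regression undefined")
    design = np.column_stack([np.ones_like(bp), bp])
    coef, *_ = np.linalg.lstsq(design, increment, rcond=None)
    return increment - design @ coef


@dataclass
class TraitMatrix:
    """z-standardized predictors with their original means and SDs."""

    z: pd.DataFrame  # columns BP, TL, G, SB, SH, SP, G2, BP2
    means: pd.Series
    sds: pd.Series
    pond: pd.Series
    fish_id: pd.Series
    raw: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.z)


def zstandardize(raw: pd.DataFrame, mean_overrides: dict | None = None) -> TraitMatrix:
    """Standardize the six analysis traits to mean 0, SD 1 (sample SD, n-1).

    ``raw`` needs columns fish_id, pond, and the six traits (case-insensitive
    BP, TL, G, SB, SH, SP).  Quadratic terms G² and BP² are squares of the
    z-scores.  A zero-variance trait raises, naming it.

    ``mean_overrides`` replaces the stored original mean of a trait for the
    purpose of later mean-standardization.  The growth trait enters the model
    as a boldness-decorrelated residual whose mean is 0 by construction; its
    biologically meaningful mean is that of the raw growth increment, so the
    pipeline overrides it (doubling "growth" refers to the increment in mm,
    not to a residual).
    """
    cols = {c.upper(): c for c in raw.columns}
    missing = [t for t in BASE_TRAITS if t not in cols]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    z = pd.DataFrame(index=raw.index)
    means, sds = {}, {}
    for t in BASE_TRAITS:
        x = raw[cols[t]].to_numpy(dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0:
            raise ValueError(f"trait {t} has zero variance; cannot z-standardize")
        z[t] = (x - mu) / sd
        if mean_overrides and t in mean_overrides:
            mu = float(mean_overrides[t])
        means[t], sds[t] = mu, sd
    z["G2"] = z["G"] ** 2
    z["BP2"] = z["BP"] ** 2
    return TraitMatrix(
        z=z,
        means=pd.Series(means),
        sds=pd.Series(sds),
        pond=raw[cols.get("POND", "pond")].reset_index(drop=True),
        fish_id=raw[cols.get("FISH_ID", "fish_id")].astype(str).reset_index(drop=True),
        raw=raw.reset_index(drop=True),
    )


def assign_fitness(captures: pd.DataFrame, horizon_days: int, roster) -> pd.Series:
    """Binary survival: 0 if first capture day <= horizon, else 1 (recaptures ignored)."""
    roster_ids = (
        roster["fish_id"].astype(str) if isinstance(roster, pd.DataFrame) else pd.Series(list(roster), dtype=str)
    )
    s = pd.Series(1, index=roster_ids.to_numpy(), dtype=int, name="s")
    if len(captures):
        unknown = set(captures["fish_id"].astype(str)) - set(s.index)
        if unknown:
            raise ValueError(f"capture log contains fish not in roster: {sorted(unknown)}")
        first = captures.groupby("fish_id")["day"].min()
        dead = first.index[first <= horizon_days]
        s.loc[dead] = 0
    return s


# ---------------------------------------------------------------------------
# logistic fitting


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable sum of y*log(p) + (1-y)*log(1-p)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Plain maximum-likelihood logit via iteratively reweighted least squares."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        d = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        aliased = np.nonzero(d < 1e-8 * d.max())[0].tolist()
        raise np.linalg.LinAlgError(f"design matrix rank deficient (aliased columns {aliased})")
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        if np.max(np.abs(eta)) > 30:
            raise RuntimeError(
                "logistic fit diverged (|linear predictor| > 30): likely complete separation"
            )
        XtW = X.T * w
        try:
            beta = beta + np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError as e:
            raise RuntimeError(f"IRLS step failed: {e}") from e
        ll = _bernoulli_ll(y, X @ beta)
        if abs(ll - ll_old) < tol:
            cov = np.linalg.inv((X.T * (expit(X @ beta) * (1 - expit(X @ beta)))) @ X)
            return beta, ll, cov
        ll_old = ll
    raise RuntimeError("logistic fit did not converge in max_iter IRLS steps")


def _solve_pond_modes(y, eta_fixed, pond_idx, n_ponds, tau2):
    """Conditional modes of the pond random intercepts (1-D Newton per pond)."""
    u = np.zeros(n_ponds)
    for j in range(n_ponds):
        sel = pond_idx == j
        yj, ej = y[sel], eta_fixed[sel]
        uj = 0.0
        for _ in range(50):
            p = expit(ej + uj)
            g = np.sum(yj - p) - uj / tau2
            h = -np.sum(p * (1 - p)) - 1.0 / tau2
            step = g / h
            uj -= step
            if abs(step) < 1e-12:
                break
        u[j] = uj
    return u


def _laplace_marginal_ll(beta, log_tau, X, y, pond_idx, n_ponds):
    """Laplace-approximated marginal log-likelihood of a random-intercept logit."""
    tau2 = np.exp(2.0 * log_tau)
    eta_fixed = X @ beta
    u = _solve_pond_modes(y, eta_fixed, pond_idx, n_ponds, tau2)
    ll = 0.0
    for j in range(n_ponds):
        sel = pond_idx == j
        eta = eta_fixed[sel] + u[j]
        w = expit(eta) * (1 - expit(eta))
        ll += (
            _bernoulli_ll(y[sel], eta)
            - u[j] ** 2 / (2.0 * tau2)
            - 0.5 * np.log1p(tau2 * np.sum(w))
        )
    return ll, u


@dataclass
class FitResult:
    """One fitted survival model."""

    terms: tuple
    coef: pd.Series  # fixed effects incl. intercept (and pond dummies if fixed mode)
    se: pd.Series
    p_values: pd.Series
    loglik: float
    k: int
    n: int
    fitted: np.ndarray  # survival probabilities W_i
    mean_fitness: float  # Wbar = mean of observed s
    pond_mode: str
    tau: float | None = None  # random-intercept SD (random mode)
    pond_effects: dict = field(default_factory=dict)
    model_no: int | None = None

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


class PondLogisticRegression(BaseEstimator):
    """Logistic survival model with optional pond-level intercepts.

    scikit-learn-style estimator: ``fit(X, y)`` where ``X`` is a DataFrame
    holding the term columns plus a ``pond`` column; ``y`` is the 0/1
    survival vector.  Fitted attributes: ``coef_``, ``se_``, ``loglik_``,
    ``k_``, ``fitted_``, ``tau_`` (random mode), ``result_``.
    """

    def __init__(self, terms=(), pond_mode: str = "random",
                 tol: float = 1e-8, max_iter: int = 100):
        self.terms = terms
        self.pond_mode = pond_mode
        self.tol = tol
        self.max_iter = max_iter

    def _design(self, X: pd.DataFrame) -> tuple[np.ndarray, list]:
        terms = list(self.terms)
        cols = [np.ones(len(X))] + [X[t].to_numpy(dtype=float) for t in terms]
        names = ["(Intercept)"] + terms
        return np.column_stack(cols), names

    def fit(self, X: pd.DataFrame, y):
        if self.pond_mode not in ("random", "fixed", "none"):
            raise ValueError("pond_mode must be random, fixed or none")
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(y)) or not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("fitness vector must be binary (0/1) with no missing values")
        design, names = self._design(X)
        if not np.all(np.isfinite(design)):
            raise ValueError("design matrix contains non-finite values")
        k = design.shape[1]  # fixed effects incl. intercept
        if len(y) <= k + 1:
            raise ValueError(f"n={len(y)} too small for k={k} parameters")

        tau = None
        pond_effects: dict = {}
        if self.pond_mode == "none" or "pond" not in X.columns:
            beta, ll, cov = _irls(design, y, self.tol, self.max_iter)
            fitted = expit(design @ beta)
        elif self.pond_mode == "fixed":
            ponds = np.sort(X["pond"].unique())
            dummies = [(X["pond"] == p).to_numpy(dtype=float) for p in ponds[1:]]
            full = np.column_stack([design] + dummies)
            names = names + [f"pond[{p}]" for p in ponds[1:]]
            beta, ll, cov = _irls(full, y, self.tol, self.max_iter)
            fitted = expit(full @ beta)
            k = full.shape[1]
        else:  # random
            ponds = np.sort(X["pond"].unique())
            pond_idx = X["pond"].map({p: j for j, p in enumerate(ponds)}).to_numpy()
            beta0, _, _ = _irls(design, y, self.tol, self.max_iter)
            x0 = np.append(beta0, np.log(0.3))

            def nll(theta):
                ll_, _ = _laplace_marginal_ll(
                    theta[:-1], theta[-1], design, y, pond_idx, len(ponds)
                )
                return -ll_

            res = optimize.minimize(
                nll, x0, method="L-BFGS-B",
                bounds=[(None, None)] * k + [(-8.0, 3.0)],
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
            )
            if not res.success and res.fun > nll(x0):
                raise RuntimeError(f"random-intercept fit failed: {res.message}")
            beta, log_tau = res.x[:-1], res.x[-1]
            tau = float(np.exp(log_tau))
            ll, u = _laplace_marginal_ll(beta, log_tau, design, y, pond_idx, len(ponds))
            pond_effects = {int(p): float(u[j]) for j, p in enumerate(ponds)}
            fitted = expit(design @ beta + u[pond_idx])
            # Wald covariance from the observed information of the marginal
            # likelihood w.r.t. the fixed effects (tau held at its optimum)
            cov = _numeric_beta_cov(
                lambda b: _laplace_marginal_ll(b, log_tau, design, y, pond_idx, len(ponds))[0],
                beta,
            )

        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            zval = np.where(se > 0, beta / se, np.nan)
        pvals = 2.0 * stats.norm.sf(np.abs(zval))
        self.coef_ = pd.Series(beta, index=names)
        self.se_ = pd.Series(se, index=names)
        self.p_values_ = pd.Series(pvals, index=names)
        self.loglik_ = float(ll)
        self.k_ = int(k)
        self.fitted_ = fitted
        self.tau_ = tau
        self.result_ = FitResult(
            terms=tuple(self.terms),
            coef=self.coef_,
            se=self.se_,
            p_values=self.p_values_,
            loglik=self.loglik_,
            k=self.k_,
            n=len(y),
            fitted=fitted,
            mean_fitness=float(np.mean(y)),
            pond_mode=self.pond_mode,
            tau=tau,
            pond_effects=pond_effects,
        )
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design, _ = self._design(X)
        p1 = expit(design @ self.coef_.to_numpy()[: design.shape[1]])
        return np.column_stack([1 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _numeric_beta_cov(ll_fun, beta: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Inverse observed information by central finite differences."""
    p = len(beta)
    H = np.empty((p, p))
    f0 = ll_fun(beta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = step
            ej = np.zeros(p); ej[j] = step
            if i == j:
                H[i, i] = (ll_fun(beta + ei) - 2 * f0 + ll_fun(beta - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    ll_fun(beta + ei + ej) - ll_fun(beta + ei - ej)
                    - ll_fun(beta - ei + ej) + ll_fun(beta - ei - ej)
                ) / (4 * step**2)
    return np.linalg.inv(-H)


def fit_logistic(terms, traits: TraitMatrix, fitness, pond_mode: str = "random") -> FitResult:
    """Fit one candidate model on a TraitMatrix (thin wrapper over the estimator)."""
    X = traits.z.copy()
    X["pond"] = traits.pond.to_numpy()
    y = fitness.to_numpy() if isinstance(fitness, pd.Series) else np.asarray(fitness)
    est = PondLogisticRegression(terms=tuple(terms), pond_mode=pond_mode)
    est.fit(X, y)
    return est.result_


# ---------------------------------------------------------------------------
# information criteria


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: ``-2 ll + 2k + 2k(k+1)/(n-k-1)``."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights: ``exp(-delta/2)`` over the candidate set, normalized."""
    v = np.asarray(aicc_values, dtype=float)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("aicc values must be finite and nonempty")
    delta = v - v.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


#: Candidate model sets (model number -> terms), short = 7-day and
#: long = 20-day fitness horizon.  Model 9 is the intercept-only NULL.
MODEL_SETS = {
    "short": {
        1: ("BP", "TL", "G", "SB", "SH", "SP", "BP2", "G2"),
        2: ("BP", "TL", "SB", "SH", "G", "SP", "G2"),
        3: ("BP", "TL", "SB", "SH", "SP", "G"),
        4: ("BP", "TL", "SB", "SH", "G"),
        5: ("BP", "TL", "SB", "G"),
        6: ("BP", "TL", "G"),
        7: ("TL", "G"),
        8: ("G",),
        9: (),
    },
    "long": {
        1: ("BP", "TL", "SB", "SH", "G", "SP", "BP2", "G2"),
        2: ("BP", "TL", "SB", "SH", "G", "SP", "G2"),
        3: ("BP", "TL", "SB", "SH", "G", "SP"),
        4: ("BP", "TL", "SB", "SH", "G"),
        5: ("BP", "SB", "SH", "G"),
        6: ("BP", "SB", "G"),
        7: ("BP", "G"),
        8: ("G",),
        9: (),
    },
}


def run_model_set(
    traits: TraitMatrix,
    fitness,
    horizon: str | int = "short",
    pond_mode: str = "random",
) -> tuple[pd.DataFrame, dict]:
    """Fit the nine-candidate set, rank by AICc and attach Akaike weights.

    ``horizon`` may be "short"/"long" or the day count (7 -> short, else
    long).  Individual fit failures are recorded (aicc = NaN) and the
    comparison continues over the models that converged.  Returns the
    comparison table and a dict model_no -> FitResult.
    """
    if isinstance(horizon, (int, np.integer)):
        horizon = "short" if horizon <= 7 else "long"
    spec_set = MODEL_SETS[horizon]
    fits: dict[int, FitResult] = {}
    rows = []
    for no, terms in spec_set.items():
        row = {"model_no": no, "terms": " + ".join(terms) if terms else "NULL"}
        try:
            fr = fit_logistic(terms, traits, fitness, pond_mode=pond_mode)
            fr.model_no = no
            fits[no] = fr
            row.update(k=fr.k, loglik=fr.loglik, aicc=fr.aicc, error="")
        except Exception as e:  # propagate per-model, keep comparing
            row.update(k=len(terms) + 1, loglik=np.nan, aicc=np.nan, error=str(e))
        rows.append(row)
    comp = pd.DataFrame(rows)
    ok = comp["aicc"].notna()
    comp["delta_aicc"] = np.nan
    comp["weight"] = np.nan
    if ok.any():
        comp.loc[ok, "delta_aicc"] = comp.loc[ok, "aicc"] - comp.loc[ok, "aicc"].min()
        comp.loc[ok, "weight"] = akaike_weights(comp.loc[ok, "aicc"].to_numpy())
    comp["best"] = ok & (comp["delta_aicc"] < 1.0)
    return comp, fits


def select_final_model(comparison: pd.DataFrame, fits: dict) -> FitResult:
    """The richest model within delta-AICc < 1 of the minimum.

    Ties in richness break toward the smaller model number (the set is ordered
    from richest to NULL, so this is deterministic).
    """
    cand = comparison[comparison["best"]]
    if not len(cand):
        raise ValueError("no converged models within delta-AICc < 1")
    cand = cand.sort_values(["k", "model_no"], ascending=[False, True], kind="mergesort")
    return fits[int(cand.iloc[0]["model_no"])]


# ---------------------------------------------------------------------------
# gradients and fit statistics


def janzen_stern(fit: FitResult) -> pd.Series:
    """Linearized (SD-standardized) gradients from logistic coefficients.

    ``beta_SD,j = alpha_j * mean_i[W_i (1 - W_i)] / Wbar`` — the
    average-gradient transformation; because predictors are z-scored this is
    already the SD-standardized selection gradient.
    """
    if fit.mean_fitness == 0:
        raise ValueError("mean fitness is zero; gradients undefined")
    factor = float(np.mean(fit.fitted * (1.0 - fit.fitted))) / fit.mean_fitness
    alphas = fit.coef.drop("(Intercept)")
    alphas = alphas[[i for i in alphas.index if not i.startswith("pond[")]]
    return alphas * factor


def mean_standardized_gradients(beta_sd: pd.Series, means: pd.Series, sds: pd.Series) -> pd.Series:
    """``beta_mu = beta_SD * mu / sigma`` per trait (NaN for quadratic terms)."""
    out = {}
    for t, b in beta_sd.items():
        if t in means.index:
            out[t] = b * means[t] / sds[t]
        else:
            out[t] = np.nan
    return pd.Series(out)


def nagelkerke_r2(fit: FitResult, null_fit: FitResult) -> float:
    """Nagelkerke pseudo-R²: Cox-Snell rescaled to a [0, 1] maximum."""
    if fit.n != null_fit.n:
        raise ValueError("fits must share the same n")
    l1, l0, n = fit.loglik, null_fit.loglik, fit.n
    if l1 < l0 - 1e-6:
        raise ValueError(f"model log-likelihood {l1:.4f} below null {l0:.4f}")
    r2_cs = 1.0 - np.exp(2.0 * (l0 - min(l1, 0.0)) / n) if l1 > l0 else 0.0
    denom = 1.0 - np.exp(2.0 * l0 / n)
    return float(min(max(r2_cs / denom, 0.0), 1.0)) if denom > 0 else 0.0


def selection_gradients(fit: FitResult, traits: TraitMatrix, null_fit: FitResult | None = None) -> pd.DataFrame:
    """Per-trait gradient table for a final model (alpha, SE, p, beta_SD, beta_mu)."""
    beta_sd = janzen_stern(fit)
    beta_mu = mean_standardized_gradients(beta_sd, traits.means, traits.sds)
    rows = []
    for t in beta_sd.index:
        rows.append(
            {
                "trait": t,
                "alpha": fit.coef[t],
                "se": fit.se[t],
                "p": fit.p_values[t],
                "beta_sd": beta_sd[t],
                "beta_mu": beta_mu[t],
            }
        )
    out = pd.DataFrame(rows)
    out["r2_nagelkerke"] = nagelkerke_r2(fit, null_fit) if null_fit is not None else np.nan
    return out


def trait_descriptives(raw: pd.DataFrame, fitness: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Captured-vs-uncaptured group means (+/- SD) and the trait correlation matrix."""
    cols = {c.upper(): c for c in raw.columns}
    rows = []
    cap_mask = (fitness.to_numpy() == 0)
    for t in BASE_TRAITS:
        x = raw[cols[t]].to_numpy(dtype=float)
        for label, m in [("captured", cap_mask), ("not_captured", ~cap_mask)]:
            sel = x[m]
            rows.append(
                {
                    "trait": t,
                    "group": label,
                    "n": int(m.sum()),
                    "mean": float(np.mean(sel)) if sel.size else np.nan,
                    "sd": float(np.std(sel, ddof=1)) if sel.size > 1 else np.nan,
                }
            )
    desc = pd.DataFrame(rows)
    zcols = [cols[t] for t in BASE_TRAITS]
    corr = raw[zcols].astype(float).corr(method="pearson")
    corr.index = corr.columns = list(BASE_TRAITS)
    return desc, corr
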