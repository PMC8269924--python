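"""Discrete-time survival model on the person-period dataset.

The event indicator (1 = did not progress to the next level on time) is
modelled with a Bernoulli likelihood and logit link.  The linear predictor
contains one dummy per period — the five time dummies *are* the intercepts,
there is no global constant — plus person-level covariates (and optional
pairwise interactions), so a covariate shifts the per-period log-odds by the
same amount at every time: the proportional-odds structure holds by
construction.

Per-period hazards for a covariate pattern are h_t = expit(beta_t + x'beta)
and the cumulative survival (probability of still progressing on time through
period t) is S_t = prod_{j<=t} (1 - h_j).

The fit is a damped Newton (equivalently IRLS) maximiser of the exact
log-likelihood; convergence when the largest score component falls below
1e-8 (a relative -2LL stagnation guard stops runs that can no longer
improve numerically), with an iteration cap of 100.
The coefficient covariance is the inverse observed information at the
optimum.  Rows missing any requested covariate are dropped per model
(complete case) and the dropped count is reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, xlogy

from .records import CODING, N_TRANSITIONS

__all__ = [
    "HazardFit",
    "SurvivalCurve",
    "EffectEstimate",
    "InteractionDecision",
    "FitError",
    "RankDeficiencyError",
    "fit",
    "baseline_hazards",
    "pattern_curve",
    "effect_estimates",
    "recode_reference",
    "lr_test",
    "pseudo_r2",
    "interaction_rule",
    "interaction_decision",
    "survival_from_hazards",
]

GRAD_TOL = 1e-8
LL_TOL = 1e-14   # relative -2LL stagnation guard; the score criterion decides
MAX_ITER = 100


class FitError(RuntimeError):
    """Raised when a model cannot be fitted as requested."""


class RankDeficiencyError(FitError):
    """Raised when the design matrix is rank deficient, naming the columns."""


@dataclass(frozen=True)
class HazardFit:
    """A fitted discrete-time hazard model."""

    time_coefficients: np.ndarray          # beta_t, t = 1..max_time
    covariate_coefficients: dict[str, float]
    covariance: pd.DataFrame               # over all coefficients, time first
    minus2LL: float
    null_minus2LL: float                   # time-dummies-only fit, same rows
    n_rows: int
    n_persons: int
    converged: bool
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    contrasts: dict[str, tuple[str, str]] = field(default_factory=dict)
    n_dropped_rows: int = 0
    n_dropped_persons: int = 0
    separation_suspected: bool = False
    max_time: int = N_TRANSITIONS

    @property
    def param_names(self) -> list[str]:
        return list(self.covariance.index)

    def coef(self) -> pd.Series:
        vals = list(self.time_coefficients) + [
            self.covariate_coefficients[k] for k in self.param_names[self.max_time:]
        ]
        return pd.Series(vals, index=self.param_names, name="coef")

    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.covariance.to_numpy())),
            index=self.param_names,
            name="se",
        )


@dataclass(frozen=True)
class SurvivalCurve:
    """Per-period hazard and cumulative survival for one covariate pattern."""

    covariate_pattern: dict[str, object]
    hazards: np.ndarray   # h_t
    survival: np.ndarray  # S_t = prod_{j<=t} (1 - h_j)


@dataclass(frozen=True)
class EffectEstimate:
    """A covariate's effect on the odds of the event (not progressing)."""

    name: str
    contrast: str         # "coded vs reference"
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class InteractionDecision:
    include: bool
    p_value: float
    delta_minus2LL: float
    rationale: str


def survival_from_hazards(hazards: np.ndarray) -> np.ndarray:
    return np.cumprod(1.0 - np.asarray(hazards, dtype=float))


# ---------------------------------------------------------------------------
# design matrix


def _encode_column(pp: pd.DataFrame, name: str) -> np.ndarray:
    """Encode a covariate column as a 0/1 indicator of its coded category."""
    col = pp[name]
    if name in CODING:
        one, zero = CODING[name]
        vals = col.to_numpy(dtype=object)
        known = pd.isna(vals) | (vals == one) | (vals == zero)
        if not known.all():
            # allow numeric 0/1 input as well
            numeric = pd.to_numeric(col, errors="coerce")
            if numeric.dropna().isin([0, 1]).all():
                return numeric.to_numpy(dtype=float)
            bad = sorted(set(np.asarray(vals)[~known].tolist()))
            raise FitError(f"covariate '{name}': unexpected values {bad}")
        out = np.where(pd.isna(vals), np.nan, (vals == one).astype(float))
        return out.astype(float)
    numeric = pd.to_numeric(col, errors="coerce")
    return numeric.to_numpy(dtype=float)


def _design(
    pp: pd.DataFrame,
    covariates: tuple[str, ...],
    interactions: tuple[tuple[str, str], ...],
    max_time: int,
):
    """Complete-case rows, design matrix, response and parameter names."""
    cols = {}
    for name in covariates:
        if name not in pp.columns:
            raise FitError(f"unknown covariate '{name}'")
        cols[name] = _encode_column(pp, name)
    keep = np.ones(len(pp), dtype=bool)
    for v in cols.values():
        keep &= ~np.isnan(v)
    used = pp.loc[keep]
    n_dropped_rows = int((~keep).sum())
    n_dropped_persons = pp["person_id"].nunique() - used["person_id"].nunique()

    t = used["time"].to_numpy()
    if (t < 1).any() or (t > max_time).any():
        raise FitError(f"person-period times outside 1..{max_time}")
    for j in range(1, max_time + 1):
        if not (t == j).any():
            raise RankDeficiencyError(
                f"time dummy 'time_{j}' has no person-period rows"
            )
    X_time = np.equal.outer(t, np.arange(1, max_time + 1)).astype(float)
    names = [f"time_{j}" for j in range(1, max_time + 1)]
    X_parts = [X_time]
    for name in covariates:
        X_parts.append(cols[name][keep][:, None])
        names.append(name)
    for a, b in interactions:
        if a not in covariates or b not in covariates:
            raise FitError(f"interaction ({a}, {b}) references unfitted covariates")
        X_parts.append((cols[a][keep] * cols[b][keep])[:, None])
        names.append(f"{a}:{b}")
    X = np.hstack(X_parts)
    y = used["event"].to_numpy(dtype=float)
    return used, X, y, names, n_dropped_rows, n_dropped_persons


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    p = X.shape[1]
    # cheap named diagnoses first: constant columns, duplicated columns
    const = [names[j] for j in range(p) if np.ptp(X[:, j]) == 0]
    if const:
        raise RankDeficiencyError(f"constant (degenerate) columns: {const}")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[-1] < 1e-8 * s[0]:
        involved = [names[j] for j in np.nonzero(np.abs(vt[-1]) > 1e-6)[0]]
        raise RankDeficiencyError(f"collinear columns: {involved}")


def _newton(X: np.ndarray, y: np.ndarray):
    """Damped Newton maximisation of the Bernoulli log-likelihood."""
    n, p = X.shape
    beta = np.zeros(p)

    def m2ll(b):
        mu = expit(X @ b)
        return -2.0 * float(np.sum(xlogy(y, mu) + xlogy(1 - y, 1 - mu)))

    cur = m2ll(beta)
    converged = False
    for _ in range(MAX_ITER):
        mu = expit(X @ beta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        lam = 1.0
        new = m2ll(beta + lam * step)
        halvings = 0
        while new > cur + 1e-12 and halvings < 30:
            lam *= 0.5
            new = m2ll(beta + lam * step)
            halvings += 1
        beta = beta + lam * step
        if cur - new < LL_TOL * max(1.0, abs(cur)):
            # -2LL has stagnated; accept only if the score is already small,
            # otherwise this is a failure to make progress, not convergence
            cur = new
            mu = expit(X @ beta)
            grad = X.T @ (y - mu)
            converged = bool(np.max(np.abs(grad)) < 1e-6)
            break
        cur = new
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-300, None)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, m2ll(beta), converged


def fit(
    person_periods: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = (),
    interactions: tuple[tuple[str, str], ...] | list[tuple[str, str]] = (),
    *,
    global_intercept: bool = False,
    max_time: int = N_TRANSITIONS,
) -> HazardFit:
    """Fit the discrete-time logistic hazard model by maximum likelihood.

    The design always contains exactly ``max_time`` time dummies and no
    global constant; requesting a global intercept is refused rather than
    silently reparameterised.  Complete-case per model: rows with a missing
    value on any requested covariate are dropped and counted.
    """
    if global_intercept:
        raise FitError(
            "a global intercept would alias the time dummies; the model is "
            "parameterised with exactly one intercept per period"
        )
    covariates = tuple(covariates)
    interactions = tuple(tuple(pair) for pair in interactions)
    used, X, y, names, ndr, ndp = _design(
        person_periods, covariates, interactions, max_time
    )
    n = len(used)
    if n == 0:
        raise FitError("no complete-case rows to fit")
    if not (0 < y.sum() < n):
        raise FitError("need at least one event and one non-event")
    _check_rank(X, names)

    beta, cov, m2, converged = _newton(X, y)
    separation = bool(np.max(np.abs(beta)) > 15.0)
    if separation:
        warnings.warn(
            "complete or quasi-complete separation suspected: some "
            "coefficients diverged; estimates are unreliable",
            stacklevel=2,
        )
    if not converged and not separation:
        warnings.warn("Newton iteration cap reached without convergence", stacklevel=2)

    if covariates or interactions:
        b0, _, m2_null, _ = _newton(X[:, :max_time], y)
        null_m2 = m2_null
    else:
        null_m2 = m2

    cov_df = pd.DataFrame(cov, index=names, columns=names)
    return HazardFit(
        time_coefficients=beta[:max_time].copy(),
        covariate_coefficients={
            name: float(b) for name, b in zip(names[max_time:], beta[max_time:])
        },
        covariance=cov_df,
        minus2LL=float(m2),
        null_minus2LL=float(null_m2),
        n_rows=n,
        n_persons=int(used["person_id"].nunique()),
        converged=converged,
        covariates=covariates,
        interactions=interactions,
        contrasts={
            name: CODING[name] for name in covariates if name in CODING
        },
        n_dropped_rows=ndr,
        n_dropped_persons=int(ndp),
        separation_suspected=separation,
        max_time=max_time,
    )


# ---------------------------------------------------------------------------
# derived quantities


def baseline_hazards(fit_result: HazardFit) -> SurvivalCurve:
    """Hazards and survival for the reference covariate pattern (all zeros)."""
    h = expit(fit_result.time_coefficients)
    return SurvivalCurve(
        covariate_pattern={name: 0 for name in fit_result.covariates},
        hazards=h,
        survival=survival_from_hazards(h),
    )


def _pattern_value(fit_result: HazardFit, name: str, value) -> float:
    if isinstance(value, str):
        if name not in CODING:
            raise FitError(f"covariate '{name}' has no category coding")
        one, zero = CODING[name]
        if value == one:
            return 1.0
        if value == zero:
            return 0.0
        raise FitError(f"covariate '{name}': unknown category '{value}'")
    return float(value)


def pattern_curve(fit_result: HazardFit, pattern: dict[str, object]) -> SurvivalCurve:
    """Hazards/survival for a covariate pattern, e.g. {"gender": "female"}.

    Every fitted covariate must be assigned (as its category label or as a
    0/1 value); interaction terms are evaluated from the assigned values.
    """
    unknown = set(pattern) - set(fit_result.covariates)
    if unknown:
        raise FitError(f"pattern assigns unknown covariates: {sorted(unknown)}")
    missing = set(fit_result.covariates) - set(pattern)
    if missing:
        raise FitError(f"pattern must assign every fitted covariate; missing {sorted(missing)}")
    x = {k: _pattern_value(fit_result, k, v) for k, v in pattern.items()}
    shift = sum(fit_result.covariate_coefficients[k] * x[k] for k in fit_result.covariates)
    for a, b in fit_result.interactions:
        shift += fit_result.covariate_coefficients[f"{a}:{b}"] * x[a] * x[b]
    h = expit(fit_result.time_coefficients + shift)
    return SurvivalCurve(
        covariate_pattern=dict(pattern),
        hazards=h,
        survival=survival_from_hazards(h),
    )


def effect_estimates(fit_result: HazardFit, z: float = 1.96) -> list[EffectEstimate]:
    """Wald odds ratios (event scale: odds of not progressing), 95% CIs, p."""
    se = fit_result.se()
    out = []
    for name in fit_result.param_names[fit_result.max_time:]:
        b = fit_result.covariate_coefficients[name]
        s = float(se[name])
        if ":" in name:
            a_, b_ = name.split(":")
            contrast = f"{a_} x {b_} interaction"
        else:
            one, zero = fit_result.contrasts.get(name, ("1", "0"))
            contrast = f"{one} vs {zero}"
        wald_p = 2.0 * stats.norm.sf(abs(b) / s) if s > 0 else float("nan")
        out.append(
            EffectEstimate(
                name=name,
                contrast=contrast,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - z * s)),
                ci_high=float(np.exp(b + z * s)),
                p_value=float(wald_p),
            )
        )
    return out


def recode_reference(estimate: EffectEstimate) -> EffectEstimate:
    """Swap a binary covariate's reference category.

    Flipping the 0/1 coding negates the coefficient, so the odds ratio maps
    to its reciprocal and the confidence limits swap and invert; the Wald p
    is unchanged.
    """
    parts = estimate.contrast.split(" vs ")
    contrast = f"{parts[1]} vs {parts[0]}" if len(parts) == 2 else estimate.contrast
    return EffectEstimate(
        name=estimate.name,
        contrast=contrast,
        odds_ratio=1.0 / estimate.odds_ratio,
        ci_low=1.0 / estimate.ci_high,
        ci_high=1.0 / estimate.ci_low,
        p_value=estimate.p_value,
    )


def lr_test(full: HazardFit, reduced: HazardFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits on the same rows."""
    if not set(reduced.param_names) <= set(full.param_names):
        raise FitError("models are not nested (reduced terms not in full model)")
    if reduced.n_rows != full.n_rows:
        raise FitError("models were fitted on different row sets")
    df = len(full.param_names) - len(reduced.param_names)
    chi2 = max(0.0, reduced.minus2LL - full.minus2LL)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df == 0:
        p = 1.0
    return chi2, df, p


def pseudo_r2(fit_result: HazardFit) -> tuple[float, float]:
    """(Cox-Snell, Nagelkerke) pseudo R-squared against the time-only null."""
    n = fit_result.n_rows
    cox_snell = 1.0 - np.exp((fit_result.minus2LL - fit_result.null_minus2LL) / n)
    max_cs = 1.0 - np.exp(-fit_result.null_minus2LL / n)
    nagelkerke = cox_snell / max_cs if max_cs > 0 else 0.0
    return float(cox_snell), float(nagelkerke)


def interaction_rule(
    p_value: float,
    delta_minus2LL: float,
    alpha: float = 0.05,
    delta_threshold: float = 4.0,
) -> bool:
    """Keep an interaction if it is significant OR improves -2LL by >= 4.

    The -2LL threshold is inclusive: an improvement of exactly the threshold
    counts as substantial.
    """
    return (p_value < alpha) or (delta_minus2LL >= delta_threshold)


def interaction_decision(
    fit_with: HazardFit,
    fit_without: HazardFit,
    alpha: float = 0.05,
    delta_threshold: float = 4.0,
) -> InteractionDecision:
    """Decide whether the interaction term(s) enter the final model.

    ``fit_with`` must extend ``fit_without`` by interaction terms only.  The
    significance arm uses the (smallest) Wald p of the added terms; the other
    arm the -2LL improvement.
    """
    extra = set(fit_with.param_names) - set(fit_without.param_names)
    if not set(fit_without.param_names) <= set(fit_with.param_names) or not extra:
        raise FitError("fit_with must nest fit_without plus interaction term(s)")
    if any(":" not in name for name in extra):
        raise FitError(f"added terms are not all interactions: {sorted(extra)}")
    if fit_with.n_rows != fit_without.n_rows:
        raise FitError("models were fitted on different row sets")
    ps = [e.p_value for e in effect_estimates(fit_with) if e.name in extra]
    p = min(ps)
    delta = fit_without.minus2LL - fit_with.minus2LL
    include = interaction_rule(p, delta, alpha, delta_threshold)
    why = []
    why.append(
        f"Wald p = {p:.3g} ({'<' if p < alpha else '>='} alpha = {alpha})"
    )
    why.append(
        f"delta -2LL = {delta:.3g} "
        f"({'>=' if delta >= delta_threshold else '<'} threshold = {delta_threshold})"
    )
    return InteractionDecision(
        include=include,
        p_value=float(p),
        delta_minus2LL=float(delta),
        rationale="; ".join(why),
    )
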