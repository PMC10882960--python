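"""Negative-binomial GLMM for alien-species counts, fitted by Laplace
approximation.

The model links the number of species relocations AS between an exporter and
an importer in a decade to the cumulative transported mass (TR), the pair
distance (D) and the species richness of both countries:

    AS ~ NB(mean = exp(eta), dispersion = theta)
    eta = b0 + b_TR * z(log(1 + TR)) + b_D * D
             + b_Se * log(S_e) + b_Si * log(S_i)
             + u_{importer:period} + u_{exporter:period}

with independent Gaussian random intercepts for importer-within-period and
exporter-within-period (each with its own variance), absorbing unmeasured
country- and era-specific drivers such as surveillance effort or invasion
control.  Log-trade is z-scored (the coefficient is "per SD of log trade");
the richness terms enter as raw logs and distance in km, so their
coefficients are per log-unit and per km.  The scaling constants are stored
in the fit and re-applied at prediction time.

No maintained Python library fits a negative-binomial GLMM, so the marginal
likelihood is maximised here directly: for trial values of (theta, sigma) the
joint mode over (beta, u) is found by damped Newton iterations on the
penalised log-likelihood (the observed-information weight matrix for the NB
log link is positive, so the inner problem is well behaved), and the Laplace
correction -0.5 log|Z'WZ + Sigma^-1| turns the joint maximum into an
approximate marginal log-likelihood.  A derivative-free Nelder--Mead search
over (log theta, log sigma_1, log sigma_2) completes the fit.  Starting
values are fixed (beta = 0, theta = 1, random-effect variances 0.1), so the
fit is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

FIXED_EFFECTS: tuple[str, ...] = ("logTR", "D", "logS_e", "logS_i")
RANDOM_EFFECTS: tuple[str, ...] = ("importer_period", "exporter_period")

_ETA_CLIP = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect subset and transform choices for one candidate model.

    The intercept is always included and the random-effect structure is the
    same for every candidate.  ``standardize`` lists the (transformed)
    covariates that are z-scored; by default only log-trade.
    """

    fixed_effects: tuple[str, ...] = FIXED_EFFECTS
    standardize: tuple[str, ...] = ("logTR",)
    random_effects: tuple[str, ...] = RANDOM_EFFECTS

    def __post_init__(self) -> None:
        unknown = set(self.fixed_effects) - set(FIXED_EFFECTS)
        if unknown:
            raise ValueError(f"unknown fixed effects: {sorted(unknown)}")
        unknown_re = set(self.random_effects) - set(RANDOM_EFFECTS)
        if unknown_re:
            raise ValueError(f"unknown random effects: {sorted(unknown_re)}")


@dataclass
class GLMMFit:
    """Result of one GLMM (or random-effect-free GLM) fit."""

    spec: ModelSpec
    beta: dict[str, float]
    beta_se: dict[str, float]
    theta: float
    re_sd: dict[str, float]
    loglik: float
    aicc: float
    n_obs: int
    k_params: int
    scaling: dict[str, tuple[float, float]]
    converged: bool
    boundary: bool
    re_modes: dict[str, dict[str, float]] = field(default_factory=dict)
    message: str = ""

    @property
    def re_variances(self) -> dict[str, float]:
        return {k: v**2 for k, v in self.re_sd.items()}


def transform_covariates(panel: pd.DataFrame) -> pd.DataFrame:
    """Log transforms shared by fitting, prediction and simulation.

    TR uses log(1 + x) because pre-trade decades contain zeros; S_e and S_i
    are always >= 1 and use plain log; distance stays in km.
    """
    out = pd.DataFrame(index=panel.index)
    out["logTR"] = np.log1p(panel["TR"].to_numpy(dtype=float))
    out["D"] = panel["D"].to_numpy(dtype=float)
    out["logS_e"] = np.log(panel["S_e"].to_numpy(dtype=float))
    out["logS_i"] = np.log(panel["S_i"].to_numpy(dtype=float))
    return out


def compute_scaling(
    covariates: pd.DataFrame, spec: ModelSpec
) -> dict[str, tuple[float, float]]:
    """Per-variable (mean, sd) used for standardization; identity elsewhere.

    The sd uses the population convention (ddof=0).  A constant column gets
    sd 1 so standardization is a pure centering.
    """
    scaling: dict[str, tuple[float, float]] = {}
    for name in spec.fixed_effects:
        if name in spec.standardize:
            x = covariates[name].to_numpy(dtype=float)
            sd = float(np.std(x))
            scaling[name] = (float(np.mean(x)), sd if sd > 0 else 1.0)
        else:
            scaling[name] = (0.0, 1.0)
    return scaling


def build_design(
    panel: pd.DataFrame,
    spec: ModelSpec,
    scaling: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, tuple[float, float]]]:
    """Response, fixed-effect design (with intercept) and scaling constants."""
    cov = transform_covariates(panel)
    if scaling is None:
        scaling = compute_scaling(cov, spec)
    cols = [np.ones(len(panel))]
    names = ["intercept"]
    for name in spec.fixed_effects:
        m, s = scaling[name]
        cols.append((cov[name].to_numpy(dtype=float) - m) / s)
        names.append(name)
    X = np.column_stack(cols)
    y = panel["AS"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("AS must be nonnegative integer counts")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in design matrix")
    return y, X, names, dict(scaling)


def random_effect_labels(panel: pd.DataFrame, factor: str) -> np.ndarray:
    """Group label per row for one random-effect factor."""
    period = panel["decade_end"].astype(int).astype(str)
    if factor == "importer_period":
        return (panel["i"].astype(str) + ":" + period).to_numpy()
    if factor == "exporter_period":
        return (panel["e"].astype(str) + ":" + period).to_numpy()
    raise ValueError(f"unknown random-effect factor {factor!r}")


# ---------------------------------------------------------------------------
# negative-binomial log-likelihood pieces (log link, dispersion theta)

def nb_loglik(y: np.ndarray, eta: np.ndarray, theta: float) -> float:
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * (eta - np.log(theta + mu))
        )
    )


def _nb_grad_weight(
    y: np.ndarray, eta: np.ndarray, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """d loglik / d eta and the (positive) observed information per row."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    grad = y - (y + theta) * mu / (theta + mu)
    weight = (y + theta) * theta * mu / (theta + mu) ** 2
    return grad, weight


class _LaplaceMachine:
    """Inner solver for one data set and model spec; reused across outer
    parameter trials with warm starts."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: list[np.ndarray]):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.group_codes: list[np.ndarray] = []
        self.group_levels: list[np.ndarray] = []
        offset = 0
        self.offsets: list[int] = []
        for labels in groups:
            levels, codes = np.unique(labels, return_inverse=True)
            self.group_codes.append(codes)
            self.group_levels.append(levels)
            self.offsets.append(offset)
            offset += len(levels)
        self.q = offset
        self.v = np.zeros(self.p + self.q)  # [beta, u] warm start

    def _eta(self, v: np.ndarray) -> np.ndarray:
        eta = self.X @ v[: self.p]
        for codes, off in zip(self.group_codes, self.offsets):
            eta = eta + v[self.p + off + codes]
        return eta

    def _penalty_diag(self, sigmas: Sequence[float]) -> np.ndarray:
        d = np.zeros(self.p + self.q)
        for (off, levels), sd in zip(
            zip(self.offsets, self.group_levels), sigmas, strict=True
        ):
            d[self.p + off : self.p + off + len(levels)] = 1.0 / sd**2
        return d

    def _objective(self, v: np.ndarray, theta: float, pen: np.ndarray) -> float:
        return nb_loglik(self.y, self._eta(v), theta) - 0.5 * float(
            np.sum(pen * v**2)
        )

    def _hessian(self, weight: np.ndarray, pen: np.ndarray) -> np.ndarray:
        """Dense (p+q)x(p+q) negative Hessian of the penalised loglik."""
        m = self.p + self.q
        H = np.zeros((m, m))
        Xw = self.X * weight[:, None]
        H[: self.p, : self.p] = self.X.T @ Xw
        # X' W Z blocks, accumulated columnwise per group level
        for codes, off in zip(self.group_codes, self.offsets):
            for j in range(self.p):
                np.add.at(H[j, self.p + off :], codes, Xw[:, j])
        # symmetric copy of X'WZ
        H[self.p :, : self.p] = H[: self.p, self.p :].T
        # Z' W Z blocks (within and across factors)
        for a, (codes_a, off_a) in enumerate(zip(self.group_codes, self.offsets)):
            diag = np.zeros(len(self.group_levels[a]))
            np.add.at(diag, codes_a, weight)
            idx = self.p + off_a + np.arange(len(diag))
            H[idx, idx] += diag
            for b in range(a + 1, len(self.group_codes)):
                codes_b, off_b = self.group_codes[b], self.offsets[b]
                cross = np.zeros((len(self.group_levels[a]), len(self.group_levels[b])))
                np.add.at(cross, (codes_a, codes_b), weight)
                H[
                    self.p + off_a : self.p + off_a + cross.shape[0],
                    self.p + off_b : self.p + off_b + cross.shape[1],
                ] += cross
                H[
                    self.p + off_b : self.p + off_b + cross.shape[1],
                    self.p + off_a : self.p + off_a + cross.shape[0],
                ] += cross.T
        H[np.arange(m), np.arange(m)] += pen
        return H

    def group_levels_len(self, offset: int) -> int:
        for off, levels in zip(self.offsets, self.group_levels):
            if off == offset:
                return len(levels)
        raise KeyError(offset)

    def joint_mode(
        self, theta: float, sigmas: Sequence[float], tol: float = 1e-10, max_iter: int = 100
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Damped Newton ascent to the joint (beta, u) mode.

        Returns the mode, the per-row observed-information weights there, and
        the penalised log-likelihood value.  The stopping rule uses the
        Newton decrement (the predicted remaining improvement), which bounds
        the parameter error much more tightly than the realised objective
        change on flat likelihood surfaces.
        """
        pen = self._penalty_diag(sigmas)
        v = self.v.copy()
        obj = self._objective(v, theta, pen)
        for _ in range(max_iter):
            eta = self._eta(v)
            grad_eta, weight = _nb_grad_weight(self.y, eta, theta)
            grad = np.concatenate(
                [self.X.T @ grad_eta, np.zeros(self.q)]
            )
            for codes, off in zip(self.group_codes, self.offsets):
                g = np.zeros(self.group_levels_len(off))
                np.add.at(g, codes, grad_eta)
                grad[self.p + off : self.p + off + len(g)] = g
            grad -= pen * v
            H = self._hessian(weight, pen)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            decrement = float(grad @ step)  # predicted 2x improvement
            # backtracking line search on the penalised log-likelihood
            t = 1.0
            for _ls in range(30):
                candidate = v + t * step
                cand_obj = self._objective(candidate, theta, pen)
                if cand_obj >= obj - 1e-12:
                    break
                t *= 0.5
            v = candidate
            obj = cand_obj
            if decrement < tol * (1 + abs(obj)) or decrement < 1e-12:
                break
        self.v = v.copy()
        _, weight = _nb_grad_weight(self.y, self._eta(v), theta)
        return v, weight, obj

    def mode_u(
        self,
        beta: np.ndarray,
        theta: float,
        sigmas: Sequence[float],
        tol: float = 1e-11,
        max_iter: int = 100,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Newton ascent over the random effects only, beta held fixed."""
        pen_u = self._penalty_diag(sigmas)[self.p :]
        u = getattr(self, "_u_warm", np.zeros(self.q)).copy()
        offset = self.X @ beta

        def eta_of(u_vec: np.ndarray) -> np.ndarray:
            eta = offset.copy()
            for codes, off in zip(self.group_codes, self.offsets):
                eta += u_vec[off + codes]
            return eta

        def obj_of(u_vec: np.ndarray) -> float:
            return nb_loglik(self.y, eta_of(u_vec), theta) - 0.5 * float(
                np.sum(pen_u * u_vec**2)
            )

        obj = obj_of(u)
        for _ in range(max_iter):
            eta = eta_of(u)
            grad_eta, weight = _nb_grad_weight(self.y, eta, theta)
            grad = np.zeros(self.q)
            for codes, off in zip(self.group_codes, self.offsets):
                g = np.zeros(self.group_levels_len(off))
                np.add.at(g, codes, grad_eta)
                grad[off : off + len(g)] = g
            grad -= pen_u * u
            Huu = self._hessian(weight, np.concatenate([np.zeros(self.p), pen_u]))[
                self.p :, self.p :
            ]
            step = np.linalg.solve(Huu, grad)
            decrement = float(grad @ step)
            t = 1.0
            for _ls in range(30):
                candidate = u + t * step
                cand_obj = obj_of(candidate)
                if cand_obj >= obj - 1e-12:
                    break
                t *= 0.5
            u = candidate
            obj = cand_obj
            if decrement < tol * (1 + abs(obj)) or decrement < 1e-13:
                break
        self._u_warm = u.copy()
        _, weight = _nb_grad_weight(self.y, eta_of(u), theta)
        return u, weight

    def laplace_full(
        self, beta: np.ndarray, theta: float, sigmas: Sequence[float]
    ) -> float:
        """Laplace marginal log-likelihood at explicit (beta, theta, sigmas).

        Unlike the profiled version, beta enters the curvature term, so
        maximising this objective over beta removes the small attenuation
        the profile shortcut leaves on group-level covariates.
        """
        u, weight = self.mode_u(beta, theta, sigmas)
        pen = self._penalty_diag(sigmas)
        pen_u = pen[self.p :]
        eta = self.X @ beta
        for codes, off in zip(self.group_codes, self.offsets):
            eta = eta + u[off + codes]
        ll = nb_loglik(self.y, eta, theta)
        quad = float(np.sum(pen_u * u**2))
        log_det_sigma = -float(np.sum(np.log(pen_u)))
        Huu = self._hessian(weight, pen)[self.p :, self.p :]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return -np.inf
        return ll - 0.5 * quad - 0.5 * log_det_sigma - 0.5 * logdet

    def laplace_loglik(self, theta: float, sigmas: Sequence[float]) -> float:
        """Laplace-approximate marginal log-likelihood, profiled over beta."""
        v, weight, _ = self.joint_mode(theta, sigmas)
        pen = self._penalty_diag(sigmas)
        eta = self._eta(v)
        ll = nb_loglik(self.y, eta, theta)
        u = v[self.p :]
        pen_u = pen[self.p :]
        quad = float(np.sum(pen_u * u**2))
        log_det_sigma = -float(np.sum(np.log(pen_u)))  # log|Sigma|
        H = self._hessian(weight, pen)
        Huu = H[self.p :, self.p :]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return -np.inf
        return ll - 0.5 * quad - 0.5 * log_det_sigma - 0.5 * logdet

    def glm_loglik_and_mode(self, theta: float) -> tuple[np.ndarray, float]:
        """Random-effect-free limit: plain NB GLM profiled over beta.

        The random intercepts are pinned to zero (an unpenalised u would act
        as free per-group fixed effects instead), so the result is the true
        sigma -> 0 limit of the marginal likelihood.
        """
        if self.q > 0:
            if not hasattr(self, "_glm_machine"):
                self._glm_machine = _LaplaceMachine(self.y, self.X, [])
            sub = self._glm_machine
            v_beta, _, _ = sub.joint_mode(theta, [])
            v = np.concatenate([v_beta, np.zeros(self.q)])
            return v, nb_loglik(self.y, sub._eta(v_beta), theta)
        v, _, _ = self.joint_mode(theta, [])
        return v, nb_loglik(self.y, self._eta(v), theta)


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.nan
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    value = _aicc(loglik, k, n)
    if math.isnan(value):
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return value


def fit(
    panel: pd.DataFrame,
    spec: ModelSpec | None = None,
    include_random: bool = True,
    scaling: Mapping[str, tuple[float, float]] | None = None,
    max_outer_iter: int = 400,
) -> GLMMFit:
    """Fit the NB GLMM (or, with ``include_random=False``, the NB GLM).

    The outer search runs Nelder--Mead over (log theta, log sigma_1, log
    sigma_2) from the fixed starting values theta=1, sigma^2=0.1; beta and
    the random-effect modes are profiled out by inner Newton iterations.
    Random-effect standard deviations pinned near the lower box edge are
    reported as boundary fits.
    """
    spec = spec or ModelSpec()
    y, X, names, scaling_used = build_design(panel, spec, scaling)
    n, p = X.shape

    # internal centering/scaling of all covariate columns: the reported
    # coefficients keep their natural units (per km, per log unit), but the
    # optimiser works on a well-conditioned parametrisation
    col_m = np.zeros(p)
    col_s = np.ones(p)
    for j in range(1, p):
        col_m[j] = float(np.mean(X[:, j]))
        sd = float(np.std(X[:, j]))
        col_s[j] = sd if sd > 0 else 1.0
    X_int = X.copy()
    X_int[:, 1:] = (X[:, 1:] - col_m[1:]) / col_s[1:]
    # beta_natural = A @ beta_internal
    A = np.eye(p)
    for j in range(1, p):
        A[j, j] = 1.0 / col_s[j]
        A[0, j] = -col_m[j] / col_s[j]

    groups = (
        [random_effect_labels(panel, f) for f in spec.random_effects]
        if include_random
        else []
    )
    machine = _LaplaceMachine(y, X_int, groups)

    n_re = len(groups)
    k = p + 1 + n_re  # fixed effects (incl. intercept) + theta + RE variances

    log_sigma_lo, log_sigma_hi = -6.0, 3.0
    log_theta_lo, log_theta_hi = -6.0, 8.0

    if include_random:

        def negll(params: np.ndarray) -> float:
            lt = float(np.clip(params[0], log_theta_lo, log_theta_hi))
            ls = np.clip(params[1:], log_sigma_lo, log_sigma_hi)
            value = machine.laplace_loglik(math.exp(lt), list(np.exp(ls)))
            if not np.isfinite(value):
                return 1e12
            return -value

        x0 = np.array([0.0] + [0.5 * math.log(0.1)] * n_re)
        res = optimize.minimize(
            negll,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": max_outer_iter,
                "xatol": 1e-3,
                "fatol": 1e-6,
                "adaptive": True,
            },
        )
        lt = float(np.clip(res.x[0], log_theta_lo, log_theta_hi))
        ls = np.clip(res.x[1:], log_sigma_lo, log_sigma_hi)
        v_profile, _, _ = machine.joint_mode(math.exp(lt), list(np.exp(ls)))

        # polish: the profile stage holds beta at the joint mode, which
        # ignores how beta moves the Laplace curvature term and leaves a
        # small attenuation on group-level covariates; re-optimise all
        # parameters in the full Laplace objective from the profile solution
        def neg_full(params: np.ndarray) -> float:
            b = params[:p]
            lt_ = float(np.clip(params[p], log_theta_lo, log_theta_hi))
            ls_ = np.clip(params[p + 1 :], log_sigma_lo, log_sigma_hi)
            value = machine.laplace_full(b, math.exp(lt_), list(np.exp(ls_)))
            if not np.isfinite(value):
                return 1e12
            return -value

        x1 = np.concatenate([v_profile[:p], [lt], ls])
        res2 = optimize.minimize(
            neg_full,
            x1,
            method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-7, "eps": 1e-6},
        )
        beta_hat = res2.x[:p]
        lt = float(np.clip(res2.x[p], log_theta_lo, log_theta_hi))
        ls = np.clip(res2.x[p + 1 :], log_sigma_lo, log_sigma_hi)
        theta = math.exp(lt)
        sigmas = [float(s) for s in np.exp(ls)]
        loglik = machine.laplace_full(beta_hat, theta, sigmas)
        u_hat, weight = machine.mode_u(beta_hat, theta, sigmas)
        v = np.concatenate([beta_hat, u_hat])
        pen = machine._penalty_diag(sigmas)
        boundary = bool(np.any(ls <= log_sigma_lo + 0.5))
        converged = bool(res2.success) and (bool(res.success) or res.fun < 1e11)
        message = f"{res.message}; polish: {res2.message}"
    else:

        def negll_glm(params: np.ndarray) -> float:
            lt = float(np.clip(params[0], log_theta_lo, log_theta_hi))
            _, value = machine.glm_loglik_and_mode(math.exp(lt))
            return -value

        res = optimize.minimize_scalar(
            lambda lt: negll_glm(np.array([lt])),
            bounds=(log_theta_lo, log_theta_hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        theta = math.exp(float(res.x))
        sigmas = []
        v, loglik = machine.glm_loglik_and_mode(theta)
        _, weight = _nb_grad_weight(y, machine._eta(v), theta)
        pen = np.zeros(p)
        boundary = False
        converged = bool(res.success)
        message = str(getattr(res, "message", ""))

    if not converged:
        logger.warning("GLMM fit did not converge cleanly: %s", message)

    # standard errors from the beta block of the inverse joint observed
    # information (conditional on theta and the RE variances)
    H = machine._hessian(weight, pen if include_random else np.zeros(p + machine.q))
    try:
        H_inv = np.linalg.inv(H)
        cov_nat = A @ H_inv[:p, :p] @ A.T
        beta_se = np.sqrt(np.clip(np.diag(cov_nat), 0, None))
    except np.linalg.LinAlgError:
        beta_se = np.full(p, np.nan)

    beta_nat = A @ v[:p]
    beta = {name: float(b) for name, b in zip(names, beta_nat)}
    se = {name: float(s) for name, s in zip(names, beta_se)}
    re_sd = {f: float(s) for f, s in zip(spec.random_effects, sigmas)}
    re_modes: dict[str, dict[str, float]] = {}
    for f, levels, off in zip(
        spec.random_effects, machine.group_levels, machine.offsets
    ):
        u = v[p + off : p + off + len(levels)]
        re_modes[f] = {str(lvl): float(val) for lvl, val in zip(levels, u)}

    return GLMMFit(
        spec=spec,
        beta=beta,
        beta_se=se,
        theta=float(theta),
        re_sd=re_sd,
        loglik=float(loglik),
        aicc=_aicc(loglik, k, n),
        n_obs=n,
        k_params=k,
        scaling=scaling_used,
        converged=converged,
        boundary=boundary,
        re_modes=re_modes,
        message=str(message),
    )


def candidate_specs(
    variables: Sequence[str] = FIXED_EFFECTS,
) -> list[ModelSpec]:
    """All fixed-effect subsets (including intercept-only), largest first."""
    specs = []
    for r in range(len(variables), -1, -1):
        for combo in combinations(variables, r):
            specs.append(ModelSpec(fixed_effects=combo))
    return specs


def select_model(
    panel: pd.DataFrame,
    candidates: Iterable[ModelSpec] | None = None,
    include_random: bool = True,
) -> list[GLMMFit]:
    """Fit candidate models and rank them by AICc (ties: fewer parameters).

    Candidates whose AICc is undefined (n <= k+1) are excluded with a log
    note.  The best-supported model is first.
    """
    candidates = list(candidates) if candidates is not None else candidate_specs()
    if not candidates:
        raise ValueError("no candidate specifications supplied")
    fits = []
    for spec in candidates:
        result = fit(panel, spec, include_random=include_random)
        if math.isnan(result.aicc):
            logger.warning(
                "candidate %s excluded: AICc undefined (n=%d, k=%d)",
                spec.fixed_effects,
                result.n_obs,
                result.k_params,
            )
            continue
        fits.append(result)
    fits.sort(key=lambda f: (f.aicc, f.k_params))
    return fits


def predict_mean(
    fit_result: GLMMFit,
    TR: float | np.ndarray,
    D: float | np.ndarray,
    S_e: float | np.ndarray,
    S_i: float | np.ndarray,
    mode: str = "population",
    importer: str | None = None,
    exporter: str | None = None,
    period: int | None = None,
) -> float | np.ndarray:
    """Expected AS count for given covariates.

    ``population`` mode sets the random effects to zero (predictions for a
    generic route); ``conditional`` mode adds the estimated random-intercept
    modes for the given importer/exporter/period levels.
    """
    TR, D, S_e, S_i = (np.asarray(v, dtype=float) for v in (TR, D, S_e, S_i))
    scalar = TR.ndim == 0 and D.ndim == 0 and S_e.ndim == 0 and S_i.ndim == 0
    TR, D, S_e, S_i = np.broadcast_arrays(
        np.atleast_1d(TR), np.atleast_1d(D), np.atleast_1d(S_e), np.atleast_1d(S_i)
    )
    frame = pd.DataFrame({"TR": TR, "D": D, "S_e": S_e, "S_i": S_i})
    cov = transform_covariates(frame)
    eta = np.full(len(frame), fit_result.beta["intercept"])
    for name in fit_result.spec.fixed_effects:
        m, s = fit_result.scaling[name]
        eta = eta + fit_result.beta[name] * (cov[name].to_numpy() - m) / s
    if mode == "conditional":
        if period is None or importer is None or exporter is None:
            raise ValueError("conditional mode needs importer, exporter and period")
        for factor, level in (
            ("importer_period", f"{importer}:{period}"),
            ("exporter_period", f"{exporter}:{period}"),
        ):
            modes = fit_result.re_modes.get(factor, {})
            if level not in modes:
                raise KeyError(f"unknown {factor} level {level!r}")
            eta = eta + modes[level]
    elif mode != "population":
        raise ValueError(f"unknown prediction mode {mode!r}")
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    return float(mu[0]) if scalar else mu


def spearman_screen(
    panel: pd.DataFrame, variables: Sequence[str] = FIXED_EFFECTS
) -> tuple[pd.DataFrame, bool]:
    """Spearman rank correlations among (transformed) covariates.

    Returns the correlation matrix and a pass flag that is False when any
    off-diagonal |rho| >= 0.5.  Constant variables yield NaN entries, which
    do not trigger a failure but are visible in the matrix.
    """
    if len(panel) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    cov = transform_covariates(panel)
    k = len(variables)
    mat = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            xa = cov[variables[a]].to_numpy()
            xb = cov[variables[b]].to_numpy()
            if np.std(xa) == 0 or np.std(xb) == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(xa, xb).statistic
            mat[a, b] = mat[b, a] = rho
    frame = pd.DataFrame(mat, index=list(variables), columns=list(variables))
    off = mat[~np.eye(k, dtype=bool)]
    passed = not np.any(np.abs(off[~np.isnan(off)]) >= 0.5)
    return frame, passed


def r2_nakagawa(fit_result: GLMMFit, panel: pd.DataFrame) -> tuple[float, float]:
    """Marginal and conditional R2 for the log-link NB mixed model.

    Variance decomposition on the latent (log) scale: the fixed-effect
    variance is the variance of the fitted fixed linear predictor across
    rows, the random-effect variance is the sum of the fitted intercept
    variances, and the distribution-specific variance uses the lognormal
    approximation ln(1 + 1/lambda + 1/theta) with lambda the typical mean
    count exp(mean eta + total latent variance / 2).
    """
    y, X, names, _ = build_design(panel, fit_result.spec, fit_result.scaling)
    beta_vec = np.array([fit_result.beta[n] for n in names])
    eta_fixed = X @ beta_vec
    var_f = float(np.var(eta_fixed))
    var_re = float(sum(sd**2 for sd in fit_result.re_sd.values()))
    lam = float(np.exp(np.mean(eta_fixed) + 0.5 * (var_f + var_re)))
    var_d = math.log(1.0 + 1.0 / lam + 1.0 / fit_result.theta)
    total = var_f + var_re + var_d
    marginal = var_f / total
    conditional = (var_f + var_re) / total
    if fit_result.boundary:
        logger.warning("R2 computed from a boundary fit; interpret with caution")
    return marginal, conditional
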