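"""Random-coefficient trajectory model with heteroscedastic residuals.

Implements, from scratch, the linear mixed model used to analyse
response-to-target ratios across sustained wakefulness:

    y_ij = x_ij' beta + z_ij' b_i + e_ij

with a 15-term fixed-effects design (task, stimulus, constant-routine
factors; a saturating homeostatic exponential exp(-t/18.2); 24-h sine and
cosine circadian terms; and their two-way interactions), an unstructured
3x3 random-effect covariance for subject-specific intercepts and task and
stimulus slopes, and residual variances that differ by task x stimulus
cell (a base variance sigma^2 times one positive multiplier per cell, the
reference cell fixed at 1).

Estimation maximises the profiled Gaussian marginal (ML) or restricted
(REML) likelihood: at each value of the variance parameters, beta is the
generalised-least-squares solution and sigma^2 has a closed form, so the
optimiser works on the scaled random-effect covariance (log-Cholesky
parameterisation, guaranteeing positive-definiteness) and the log variance
multipliers only.  Per-subject covariance inverses use the Woodbury
identity, so a likelihood evaluation is linear in the number of
observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "LmmFit",
    "FIXED_TERMS",
    "build_design",
    "fit",
    "fit_occasions",
    "wald_table",
    "amplitude_phase",
    "predict",
]

#: Canonical fixed-effect term order of the full trajectory model.
FIXED_TERMS = (
    "Intercept",
    "TASK",
    "STIM",
    "CR",
    "exp",
    "sin",
    "cos",
    "TASK:STIM",
    "TASK:CR",
    "TASK:exp",
    "TASK:sin",
    "TASK:cos",
    "STIM:exp",
    "STIM:sin",
    "STIM:cos",
)

# Treatment (0/1) coding.  Production is the TASK reference level: under
# this coding the published coefficient pattern reproduces the observed
# trajectories (estimation rising from under-estimation toward veridical,
# production falling from over-production).
TASK_CODES = {"production": 0.0, "estimation": 1.0}
CR_CODES = {"CR1": 0.0, "CR2": 1.0}
STIM_REFERENCE = 10.0


class DesignError(ValueError):
    """Unknown factor level or malformed design input."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the fixed, random and variance structure.

    ``fixed_terms`` must be a subset of :data:`FIXED_TERMS` (order is
    normalised to the canonical order).  ``random_terms`` selects columns of
    the per-subject random design from ``("Intercept", "TASK", "STIM")``.
    ``variance_groups`` is ``"cell"`` (one residual-variance multiplier per
    task x stimulus cell), ``"task-stim"`` (multiplicative task and stimulus
    factors) or ``"none"`` (homoscedastic).
    """

    fixed_terms: tuple[str, ...] = FIXED_TERMS
    random_terms: tuple[str, ...] = ("Intercept", "TASK", "STIM")
    variance_groups: str = "cell"
    tau_h: float = 18.2
    period: float = 24.0

    def __post_init__(self) -> None:
        unknown = set(self.fixed_terms) - set(FIXED_TERMS)
        if unknown:
            raise DesignError(f"unknown fixed terms: {sorted(unknown)}")
        # normalise order so nesting comparisons are order-free
        ordered = tuple(t for t in FIXED_TERMS if t in self.fixed_terms)
        object.__setattr__(self, "fixed_terms", ordered)
        if self.variance_groups not in ("cell", "task-stim", "none"):
            raise DesignError(f"unknown variance_groups: {self.variance_groups}")

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.fixed_terms) <= set(other.fixed_terms)


def _code_factors(occasions: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        task = occasions["task"].map(TASK_CODES).to_numpy(dtype=float)
        cr = occasions["cr"].map(CR_CODES).to_numpy(dtype=float)
    except Exception as exc:  # pragma: no cover - defensive
        raise DesignError(str(exc)) from exc
    if np.any(~np.isfinite(task)):
        bad = sorted(set(occasions["task"]) - set(TASK_CODES))
        raise DesignError(f"unknown task level(s): {bad}")
    if np.any(~np.isfinite(cr)):
        bad = sorted(set(occasions["cr"]) - set(CR_CODES))
        raise DesignError(f"unknown cr level(s): {bad}")
    stim_raw = occasions["stimulus_s"].to_numpy(dtype=float)
    stim = (stim_raw != STIM_REFERENCE).astype(float)
    return task, stim, cr


def build_design(occasions: pd.DataFrame, spec: ModelSpec = ModelSpec()):
    """Build fixed (X) and random (Z) design matrices from an occasion table.

    ``occasions`` needs columns ``subject_id``, ``cr``, ``task``,
    ``stimulus_s`` and ``t_dlmo_h`` (time from that epoch's DLMO, hours).

    Returns ``(X, Z, subjects, var_groups)`` where ``X`` has one column per
    ``spec.fixed_terms`` entry in canonical order, ``Z`` has columns
    ``(1, TASK, STIM)`` restricted to ``spec.random_terms``, ``subjects``
    are per-row subject labels and ``var_groups`` per-row residual-variance
    group labels.
    """
    task, stim, cr = _code_factors(occasions)
    t = occasions["t_dlmo_h"].to_numpy(dtype=float)
    w = 2.0 * np.pi / spec.period
    basis = {
        "Intercept": np.ones_like(t),
        "TASK": task,
        "STIM": stim,
        "CR": cr,
        "exp": np.exp(-t / spec.tau_h),
        "sin": np.sin(w * t),
        "cos": np.cos(w * t),
    }
    cols = []
    for term in spec.fixed_terms:
        if ":" in term:
            a, b = term.split(":")
            cols.append(basis[a] * basis[b])
        else:
            cols.append(basis[term])
    X = np.column_stack(cols)

    z_cols = {"Intercept": np.ones_like(t), "TASK": task, "STIM": stim}
    Z = np.column_stack([z_cols[t_] for t_ in spec.random_terms])

    subjects = occasions["subject_id"].to_numpy()
    if spec.variance_groups == "none":
        var_groups = np.full(len(occasions), "all", dtype=object)
    else:
        var_groups = (
            occasions["task"].astype(str) + ":" + occasions["stimulus_s"].astype(str)
        ).to_numpy(dtype=object)
    return X, Z, subjects, var_groups


@dataclass
class LmmFit:
    """A fitted random-coefficient model."""

    beta: np.ndarray
    se: np.ndarray
    term_names: tuple[str, ...]
    re_cov: np.ndarray  # Psi, on the response scale
    sigma: float  # base residual SD (reference variance group)
    var_multipliers: dict[str, float]  # SD multipliers, reference == 1
    loglik: float
    method: str
    n_obs: int
    n_subjects: int
    converged: bool
    cov_beta: np.ndarray
    df: int
    theta: np.ndarray
    spec: ModelSpec | None = None
    blups: dict = field(default_factory=dict)
    n_params: int = 0
    optimizer_message: str = ""
    group_names: tuple[str, ...] = ()

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _group_log_design(group_names: tuple[str, ...], structure: str) -> np.ndarray:
    """Map free log-SD parameters to per-group log multipliers.

    Returns D (n_groups x k) with log w_g = D_g . theta_w.  ``"free"``
    gives one parameter per non-reference group; ``"factorial"`` parses
    "task:stim" labels into multiplicative task and stimulus factors
    (reference level of each = the alphabetically first)."""
    n = len(group_names)
    if structure == "free":
        D = np.zeros((n, max(n - 1, 0)))
        for i in range(1, n):
            D[i, i - 1] = 1.0
        return D
    if structure == "factorial":
        tasks = sorted({g.split(":")[0] for g in group_names})
        stims = sorted({g.split(":")[1] for g in group_names})
        cols = [t for t in tasks[1:]] + [s for s in stims[1:]]
        D = np.zeros((n, len(cols)))
        for i, g in enumerate(group_names):
            task, stim = g.split(":")
            if task != tasks[0]:
                D[i, cols.index(task)] = 1.0
            if stim != stims[0]:
                D[i, len(tasks) - 1 + stims[1:].index(stim)] = 1.0
        return D
    raise ValueError(f"unknown variance structure {structure!r}")


def _unpack_theta(theta: np.ndarray, q: int, group_design: np.ndarray):
    """theta -> (L, w2) with G = L L' the scaled RE covariance and w2 the
    per-group variance multipliers (reference fixed at 1)."""
    theta = np.clip(theta, -40.0, 40.0)  # keep exp() finite on wild iterates
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[k])
            else:
                L[i, j] = theta[k]
            k += 1
    n_free = group_design.shape[1]
    if n_free:
        w2 = np.exp(2.0 * (group_design @ theta[k : k + n_free]))
    else:
        w2 = np.ones(group_design.shape[0])
    return L, w2


def _pack_start(q: int, n_free_groups: int, diag: float = -0.5) -> np.ndarray:
    theta = []
    for i in range(q):
        for j in range(i + 1):
            theta.append(diag if i == j else 0.0)
    theta.extend([0.0] * n_free_groups)
    return np.asarray(theta)


class _ProfiledDeviance:
    """Profiled -2 log-likelihood of the marginal Gaussian model.

    Data are pre-sorted into per-subject blocks once; each call assembles
    X' V0^-1 X, X' V0^-1 y, y' V0^-1 y and log|V0| via the Woodbury
    identity with V0_i = Z_i G Z_i' + diag(w2), then profiles out beta
    (GLS) and sigma^2 (closed form).
    """

    def __init__(self, X, Z, y, subjects, var_groups, method="ML", structure="free"):
        X = np.asarray(X, dtype=float)
        Z = np.asarray(Z, dtype=float)
        y = np.asarray(y, dtype=float)
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        if np.linalg.matrix_rank(X) < self.p:
            raise DesignError("fixed-effects design matrix is rank deficient")
        self.group_names = tuple(sorted(set(map(str, var_groups))))
        gcode = {g: i for i, g in enumerate(self.group_names)}
        gidx = np.asarray([gcode[str(g)] for g in var_groups])
        self.n_groups = len(self.group_names)
        order = np.argsort(np.asarray(subjects, dtype=object), kind="stable")
        self.subject_labels = []
        self.blocks = []  # (X_i, Z_i, y_i, gidx_i)
        subj_sorted = np.asarray(subjects, dtype=object)[order]
        bounds = np.flatnonzero(np.r_[True, subj_sorted[1:] != subj_sorted[:-1], True])
        for a, b in zip(bounds[:-1], bounds[1:]):
            idx = order[a:b]
            self.subject_labels.append(subj_sorted[a])
            self.blocks.append((X[idx], Z[idx], y[idx], gidx[idx]))
        self.n_subjects = len(self.blocks)
        self.method = method
        self.group_design = _group_log_design(self.group_names, structure)

    def components(self, theta):
        L, w2 = _unpack_theta(theta, self.q, self.group_design)
        p, q = self.p, self.q
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdet = 0.0
        per_subject = []
        for Xi, Zi, yi, gi in self.blocks:
            wi = w2[gi]
            A = Zi @ L
            Aw = A / wi[:, None]
            M = np.eye(q) + A.T @ Aw
            cM = np.linalg.cholesky(M)
            U = A.T @ (Xi / wi[:, None])  # q x p
            v = A.T @ (yi / wi)
            MiU = np.linalg.solve(M, U)
            Miv = np.linalg.solve(M, v)
            XtVX += Xi.T @ (Xi / wi[:, None]) - U.T @ MiU
            XtVy += Xi.T @ (yi / wi) - U.T @ Miv
            ytVy += yi @ (yi / wi) - v @ Miv
            logdet += 2.0 * np.sum(np.log(np.diag(cM))) + np.sum(np.log(wi))
            per_subject.append((M, L))
        return L, w2, XtVX, XtVy, ytVy, logdet, per_subject

    def deviance(self, theta):
        try:
            _, _, XtVX, XtVy, ytVy, logdet, _ = self.components(theta)
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return 1e12
        qform = max(ytVy - beta @ XtVy, 1e-300)
        n, p = self.n, self.p
        if self.method == "REML":
            sig2 = qform / (n - p)
            sign, ld_xvx = np.linalg.slogdet(XtVX)
            if sign <= 0:
                return 1e12
            dev = (n - p) * np.log(2.0 * np.pi * sig2) + logdet + ld_xvx + (n - p)
        else:
            sig2 = qform / n
            dev = n * np.log(2.0 * np.pi * sig2) + logdet + n
        if not np.isfinite(dev):
            return 1e12
        return dev

    def finalize(self, theta, converged, message, spec=None):
        L, w2, XtVX, XtVy, ytVy, logdet, _ = self.components(theta)
        beta = np.linalg.solve(XtVX, XtVy)
        qform = max(ytVy - beta @ XtVy, 1e-300)
        n, p = self.n, self.p
        denom = (n - p) if self.method == "REML" else n
        sig2 = qform / denom
        loglik = -0.5 * self.deviance(theta)
        cov_beta = sig2 * np.linalg.inv(XtVX)
        re_cov = sig2 * (L @ L.T)
        mult = {g: float(np.sqrt(w2[i])) for i, g in enumerate(self.group_names)}
        # empirical BLUPs: b_i = L M_i^{-1} A_i' W_i^{-1} (y_i - X_i beta)
        blups = {}
        for label, (Xi, Zi, yi, gi) in zip(self.subject_labels, self.blocks):
            wi = w2[gi]
            A = Zi @ L
            M = np.eye(self.q) + A.T @ (A / wi[:, None])
            u = A.T @ ((yi - Xi @ beta) / wi)
            blups[label] = L @ np.linalg.solve(M, u)
        df = self._containment_df()
        n_params = p + len(theta) + 1  # beta + variance params + sigma^2
        return LmmFit(
            beta=beta,
            se=np.sqrt(np.maximum(np.diag(cov_beta), 0.0)),
            term_names=spec.fixed_terms if spec is not None else tuple(
                f"x{i}" for i in range(p)
            ),
            re_cov=re_cov,
            sigma=float(np.sqrt(sig2)),
            var_multipliers=mult,
            loglik=float(loglik),
            method=self.method,
            n_obs=n,
            n_subjects=self.n_subjects,
            converged=converged,
            cov_beta=cov_beta,
            df=df,
            theta=np.asarray(theta, dtype=float),
            spec=spec,
            blups=blups,
            n_params=n_params,
            optimizer_message=message,
            group_names=self.group_names,
        )

    def _containment_df(self) -> int:
        """Denominator df by the containment rule.

        Every fixed-effect column that varies within at least one subject
        counts against the within-subject stratum; the intercept is counted
        there by convention.  df = n_obs - n_subjects - p_within.
        """
        p_within = 0
        for j in range(self.p):
            varies = any(
                np.ptp(Xi[:, j]) > 0 for Xi, _, _, _ in self.blocks if len(Xi) > 1
            )
            col_is_intercept = all(
                np.allclose(Xi[:, j], Xi[0, j]) and Xi[0, j] == 1.0
                for Xi, _, _, _ in self.blocks
            )
            if varies or col_is_intercept:
                p_within += 1
        return self.n - self.n_subjects - p_within


def fit(
    X,
    Z,
    y,
    subjects,
    var_groups=None,
    method: str = "ML",
    spec: ModelSpec | None = None,
    extra_starts: int = 1,
    variance_structure: str = "free",
) -> LmmFit:
    """Maximise the (restricted) marginal likelihood of the mixed model.

    Parameters
    ----------
    X, Z, y : arrays
        Fixed design (n x p), random design (n x q), response (n,).
    subjects : array
        Per-row subject labels grouping the random effects.
    var_groups : array, optional
        Per-row residual-variance group labels; ``None`` for homoscedastic.
    method : {"ML", "REML"}
        ML for likelihood-ratio comparison of fixed effects; REML for final
        variance reporting.
    extra_starts : int
        Number of additional dispersed starting points beyond the default.
    variance_structure : {"free", "factorial"}
        How the per-group variance multipliers are parameterised: one free
        multiplier per non-reference group, or multiplicative task and
        stimulus factors parsed from "task:stim" group labels.
    """
    if method not in ("ML", "REML"):
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    y = np.asarray(y, dtype=float)
    if var_groups is None:
        var_groups = np.full(len(y), "all", dtype=object)
    prof = _ProfiledDeviance(
        X, Z, y, subjects, var_groups, method=method, structure=variance_structure
    )
    if prof.n_subjects < 2:
        raise DesignError("at least 2 subjects are required")

    n_free = prof.group_design.shape[1]
    starts = [_pack_start(prof.q, n_free, diag=-0.5)]
    for k in range(extra_starts):
        starts.append(_pack_start(prof.q, n_free, diag=0.5 * (k + 1)))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            prof.deviance,
            x0,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) or best.fun < 1e11
    if not best.success:
        # polish with a derivative-free pass; never fail silently
        res2 = optimize.minimize(
            prof.deviance, best.x, method="Nelder-Mead",
            options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
        )
        if res2.fun <= best.fun:
            best = res2
        converged = bool(best.fun < 1e11)
    return prof.finalize(best.x, converged, str(best.message), spec=spec)


def fit_occasions(
    occasions: pd.DataFrame, spec: ModelSpec = ModelSpec(), method: str = "ML"
) -> LmmFit:
    """Convenience wrapper: build the design from an occasion table and fit."""
    X, Z, subjects, var_groups = build_design(occasions, spec)
    structure = "factorial" if spec.variance_groups == "task-stim" else "free"
    return fit(X, Z, occasions["ratio"].to_numpy(dtype=float), subjects,
               var_groups, method=method, spec=spec, variance_structure=structure)


def wald_table(fit_: LmmFit) -> pd.DataFrame:
    """Per-term Wald tests: value, SE, denominator df, t and two-sided p."""
    t_stat = fit_.beta / fit_.se
    df = fit_.df
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    return pd.DataFrame(
        {
            "term": list(fit_.term_names),
            "value": fit_.beta,
            "se": fit_.se,
            "df": df,
            "t": t_stat,
            "p": p,
        }
    )


def amplitude_phase(s_coef: float, c_coef: float, period: float = 24.0):
    """Convert sine/cosine coefficients to (amplitude, acrophase hours).

    Uses A*cos(w*t - P) = s*sin(w*t) + c*cos(w*t): amplitude
    sqrt(s^2 + c^2), acrophase (period/2pi)*atan2(s, c) reduced to
    [0, period).
    """
    amp = float(np.hypot(s_coef, c_coef))
    acro = float((period / (2.0 * np.pi)) * np.arctan2(s_coef, c_coef) % period)
    return amp, acro


def predict(fit_: LmmFit, newdata: pd.DataFrame, level: str = "population"):
    """Predicted ratios for new occasions.

    ``level="population"`` returns X @ beta; ``level="subject"`` adds each
    row's subject BLUP contribution Z @ b_i (the subject must have been in
    the fitted data).
    """
    if fit_.spec is None:
        raise ValueError("fit carries no ModelSpec; cannot build a design")
    X, Z, subjects, _ = build_design(newdata, fit_.spec)
    yhat = X @ fit_.beta
    if level == "population":
        return yhat
    if level != "subject":
        raise ValueError(f"unknown level {level!r}")
    out = yhat.copy()
    for i, s in enumerate(subjects):
        if s not in fit_.blups:
            raise KeyError(f"subject {s!r} not present in the fitted data")
        out[i] += Z[i] @ fit_.blups[s]
    return out
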