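"""Latent-variable structural equation model for trait-efficiency associations.

Model
-----
Measurement part: expressive suppression (ES) is a latent factor indicated by
the four ES questionnaire items, cognitive reappraisal (CR) by the six CR
items (congeneric indicators, uncorrelated unique variances).  Structural
part: one network-efficiency outcome is regressed on latent ES, latent CR and
the observed covariates age, gender and the summed negative-affect (NA)
score.  All exogenous variables (two latents plus the covariates) covary
freely.  All observed variables are z-standardized internally before fitting
and the standardized solution is reported.

Estimation is normal-theory maximum likelihood: the discrepancy

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

is minimized with analytic gradients (L-BFGS-B).  Factor scale is set by
marker indicators (es1, cr1); the exogenous covariance matrix is
parameterized through its Cholesky factor so it stays positive definite.
Standard errors come from the inverse observed information of F (delta method
for the standardized solution); an optional first-order sandwich correction
("robust" standard errors) is available — point estimates are unaffected.
Fit is summarized by chi-square, CFI, TLI, RMSEA and SRMR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .behavior import CR_ITEMS, ES_ITEMS
from .errors import DegenerateInputError, ValidationError

ITEMS = ES_ITEMS + CR_ITEMS
_MIN_VAR = 1e-6


# --------------------------------------------------------------------------
# model structure
# --------------------------------------------------------------------------

class _ModelStructure:
    """Index bookkeeping for the fixed model, for a given covariate list."""

    def __init__(self, covariates: Sequence[str]):
        self.covariates = list(covariates)
        self.observed = ITEMS + self.covariates + ["efficiency"]
        self.p = len(self.observed)
        self.n_items = len(ITEMS)
        self.factors = ["ES", "CR"] + self.covariates          # exogenous
        self.n_xi = len(self.factors)
        self.n_f = self.n_xi + 1                               # + disturbance
        self.eff_row = self.p - 1
        # free loading entries (row, factor col); markers es1, cr1 fixed at 1
        self.free_loadings = [(i, 0) for i in range(1, 4)] + [
            (4 + j, 1) for j in range(1, 6)
        ]
        # parameter vector layout
        self.n_lam = len(self.free_loadings)
        self.n_beta = self.n_xi
        self.n_chol = self.n_xi * (self.n_xi + 1) // 2
        self.n_theta = self.n_items
        self.q = self.n_lam + self.n_beta + self.n_chol + self.n_theta + 1
        self.tril = np.tril_indices(self.n_xi)

    def unpack(self, theta: np.ndarray):
        s = self
        i0 = 0
        lam = theta[i0:i0 + s.n_lam]; i0 += s.n_lam
        beta = theta[i0:i0 + s.n_beta]; i0 += s.n_beta
        lvec = theta[i0:i0 + s.n_chol]; i0 += s.n_chol
        thet = theta[i0:i0 + s.n_theta]; i0 += s.n_theta
        psi = theta[i0]
        L = np.zeros((s.n_xi, s.n_xi))
        L[s.tril] = lvec
        return lam, beta, L, thet, psi

    def matrices(self, theta: np.ndarray):
        """(G, Psi_f, Theta_diag, Phi) for a parameter vector."""
        s = self
        lam, beta, L, thet, psi = self.unpack(theta)
        G = np.zeros((s.p, s.n_f))
        G[0, 0] = 1.0
        G[4, 1] = 1.0
        for (row, col), v in zip(s.free_loadings, lam):
            G[row, col] = v
        for j, _ in enumerate(s.covariates):
            G[s.n_items + j, 2 + j] = 1.0
        G[s.eff_row, :s.n_xi] = beta
        G[s.eff_row, s.n_xi] = 1.0
        Phi = L @ L.T
        Psi_f = np.zeros((s.n_f, s.n_f))
        Psi_f[:s.n_xi, :s.n_xi] = Phi
        Psi_f[s.n_xi, s.n_xi] = psi
        Theta = np.zeros(s.p)
        Theta[:s.n_items] = thet
        return G, Psi_f, Theta, Phi

    def implied(self, theta: np.ndarray) -> np.ndarray:
        G, Psi_f, Theta, _ = self.matrices(theta)
        return G @ Psi_f @ G.T + np.diag(Theta)

    def dsigma(self, theta: np.ndarray) -> list[np.ndarray]:
        """Dense derivative matrices dSigma/dtheta_k (used for sandwich SEs)."""
        s = self
        G, Psi_f, Theta, Phi = self.matrices(theta)
        _, _, L, _, _ = self.unpack(theta)
        GP = G @ Psi_f
        Gxi = G[:, :s.n_xi]
        out = []
        for (row, col) in s.free_loadings:
            d = np.zeros((s.p, s.p))
            d[row, :] += GP[:, col]
            d[:, row] += GP[:, col]
            out.append(d)
        for k in range(s.n_xi):
            d = np.zeros((s.p, s.p))
            d[s.eff_row, :] += GP[:, k]
            d[:, s.eff_row] += GP[:, k]
            out.append(d)
        for a, b in zip(*s.tril):
            E = np.zeros((s.n_xi, s.n_xi))
            E[a, b] = 1.0
            dPhi = E @ L.T + L @ E.T
            out.append(Gxi @ dPhi @ Gxi.T)
        for i in range(s.n_items):
            d = np.zeros((s.p, s.p))
            d[i, i] = 1.0
            out.append(d)
        d = np.zeros((s.p, s.p))
        gpsi = G[:, s.n_xi]
        out.append(np.outer(gpsi, gpsi))
        return out


def _discrepancy_and_grad(theta: np.ndarray, S: np.ndarray, struct: _ModelStructure,
                          logdet_S: float):
    G, Psi_f, Theta, _ = struct.matrices(theta)
    _, _, L, _, _ = struct.unpack(theta)
    Sigma = G @ Psi_f @ G.T + np.diag(Theta)
    try:
        chol = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(theta)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    Sinv = np.linalg.inv(Sigma)
    F = logdet + np.trace(S @ Sinv) - logdet_S - struct.p
    W = Sinv @ (Sigma - S) @ Sinv          # dF = tr(W dSigma)
    A = W @ G @ Psi_f                      # p x n_f
    grad = np.empty(struct.q)
    i0 = 0
    for (row, col) in struct.free_loadings:
        grad[i0] = 2.0 * A[row, col]; i0 += 1
    for k in range(struct.n_xi):
        grad[i0] = 2.0 * A[struct.eff_row, k]; i0 += 1
    Gxi = G[:, :struct.n_xi]
    M = Gxi.T @ W @ Gxi
    ML = 2.0 * (M @ L)
    for a, b in zip(*struct.tril):
        grad[i0] = ML[a, b]; i0 += 1
    for i in range(struct.n_items):
        grad[i0] = W[i, i]; i0 += 1
    gpsi = G[:, struct.n_xi]
    grad[i0] = float(gpsi @ W @ gpsi)
    return F, grad


# --------------------------------------------------------------------------
# results container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SEMResult:
    """Standardized solution, fit indices and diagnostics of one model fit."""

    loadings: Mapping[str, float]
    loadings_se: Mapping[str, float]
    beta: Mapping[str, float]
    beta_se: Mapping[str, float]
    beta_pvalues: Mapping[str, float]
    fit: Mapping[str, float]
    converged: bool
    n_obs: int
    n_iter: int = 0

    def summary(self) -> str:
        lines = ["Standardized loadings:"]
        for k, v in self.loadings.items():
            lines.append(f"  {k:<4s} {v:+.3f} (SE {self.loadings_se[k]:.3f})")
        lines.append("Structural coefficients (efficiency on ...):")
        for k, v in self.beta.items():
            lines.append(
                f"  {k:<8s} {v:+.3f} (SE {self.beta_se[k]:.3f}, p = {self.beta_pvalues[k]:.4f})"
            )
        f = self.fit
        lines.append(
            f"Fit: chi2({f['df']:.0f}) = {f['chi2']:.2f}, CFI = {f['CFI']:.3f}, "
            f"TLI = {f['TLI']:.3f}, RMSEA = {f['RMSEA']:.3f}, SRMR = {f['SRMR']:.3f}"
        )
        return "\n".join(lines)


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class StructuralEquationModel(BaseEstimator):
    """sklearn-style estimator for the fixed efficiency model.

    Parameters
    ----------
    include_na : bool
        Model the summed NA score as an observed covariate (the main
        analysis); ``False`` reproduces the supplementary variant without it.
    robust_se : bool
        Apply a first-order sandwich correction to the standard errors.
        Point estimates are identical either way.
    max_iter : int
        L-BFGS-B iteration cap.

    ``fit`` expects a DataFrame with columns es1..es4, cr1..cr6, age, gender,
    na_score (when ``include_na``) and ``efficiency``.
    """

    def __init__(self, include_na: bool = True, robust_se: bool = False,
                 max_iter: int = 500):
        self.include_na = include_na
        self.robust_se = robust_se
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------

    def _structure(self) -> _ModelStructure:
        covs = ["age", "gender"] + (["na_score"] if self.include_na else [])
        return _ModelStructure(covs)

    def _start(self, S: np.ndarray, struct: _ModelStructure) -> np.ndarray:
        s = struct
        theta = np.zeros(s.q)
        lam = []
        phi0 = {}
        for fac, idx in (("ES", range(0, 4)), ("CR", range(4, 10))):
            block = S[np.ix_(list(idx), list(idx))]
            off = block[np.triu_indices(len(block), k=1)]
            phi0[fac] = float(np.clip(np.mean(off), 0.1, 0.9))
        for (row, col) in s.free_loadings:
            marker = 0 if col == 0 else 4
            phi = phi0["ES" if col == 0 else "CR"]
            lam.append(float(np.clip(S[row, marker] / phi, 0.2, 2.0)))
        Phi0 = np.eye(s.n_xi) * 0.5
        Phi0[0, 0] = phi0["ES"]
        Phi0[1, 1] = phi0["CR"]
        ncov = len(s.covariates)
        if ncov:
            Phi0[2:, 2:] = S[np.ix_(range(s.n_items, s.n_items + ncov),
                                    range(s.n_items, s.n_items + ncov))]
        L0 = np.linalg.cholesky(Phi0 + 1e-6 * np.eye(s.n_xi))
        i0 = 0
        theta[i0:i0 + s.n_lam] = lam; i0 += s.n_lam
        theta[i0:i0 + s.n_beta] = 0.0; i0 += s.n_beta
        theta[i0:i0 + s.n_chol] = L0[s.tril]; i0 += s.n_chol
        theta[i0:i0 + s.n_theta] = 0.5; i0 += s.n_theta
        theta[i0] = max(float(S[s.eff_row, s.eff_row]) * 0.9, 0.1)
        return theta

    def _bounds(self, struct: _ModelStructure):
        s = struct
        bounds: list[tuple[float | None, float | None]] = []
        bounds += [(None, None)] * s.n_lam
        bounds += [(None, None)] * s.n_beta
        for a, b in zip(*s.tril):
            bounds.append((_MIN_VAR, None) if a == b else (None, None))
        bounds += [(_MIN_VAR, None)] * s.n_theta
        bounds.append((_MIN_VAR, None))
        return bounds

    @staticmethod
    def _standardized(theta, struct):
        """Vector of standardized loadings (10) then betas (n_xi)."""
        G, Psi_f, Theta, Phi = struct.matrices(theta)
        Sigma = G @ Psi_f @ G.T + np.diag(Theta)
        sd = np.sqrt(np.diag(Sigma))
        out = []
        all_loadings = [(i, 0) for i in range(4)] + [(4 + j, 1) for j in range(6)]
        for (row, col) in all_loadings:
            out.append(G[row, col] * np.sqrt(Phi[col, col]) / sd[row])
        lam, beta, L, thet, psi = struct.unpack(theta)
        sd_eff = sd[struct.eff_row]
        for k in range(struct.n_xi):
            out.append(beta[k] * np.sqrt(Phi[k, k]) / sd_eff)
        return np.array(out)

    # -- public API --------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "StructuralEquationModel":
        struct = self._structure()
        missing = [c for c in struct.observed if c not in X.columns]
        if missing:
            raise ValidationError(f"SEM input missing columns {missing}")
        n = len(X)
        if n < struct.p + 1:
            raise ValidationError(f"need more observations than variables ({n} <= {struct.p})")
        if n < 30:
            warnings.warn(f"SEM fit on n = {n} < 30 participants; estimates will be unstable")
        raw = X[struct.observed].to_numpy(dtype=float)
        sd = raw.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = struct.observed[int(np.argmax(sd == 0))]
            raise DegenerateInputError(f"observed variable {bad!r} has zero variance")
        Z = (raw - raw.mean(axis=0)) / sd           # z-transform all observed
        S = np.cov(Z, rowvar=False, ddof=1)
        eig_min = float(np.linalg.eigvalsh(S).min())
        if eig_min <= 0:
            raise DegenerateInputError(
                f"sample covariance is not positive definite (min eigenvalue {eig_min:.3g})"
            )
        logdet_S = float(np.linalg.slogdet(S)[1])
        theta0 = self._start(S, struct)
        res = optimize.minimize(
            _discrepancy_and_grad, theta0, args=(S, struct, logdet_S),
            jac=True, method="L-BFGS-B", bounds=self._bounds(struct),
            options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x
        self.converged_ = bool(res.success) and np.isfinite(res.fun)
        self.n_iter_ = int(res.nit)
        self.theta_ = theta
        self.struct_ = struct
        self.n_obs_ = n
        self.discrepancy_ = float(res.fun)
        self.sigma_implied_ = struct.implied(theta)
        self.sample_cov_ = S

        acov = self._acov(theta, S, struct, logdet_S, Z)
        std = self._standardized(theta, struct)
        jac = self._std_jacobian(theta, struct)
        std_se = np.sqrt(np.clip(np.diag(jac @ acov @ jac.T), 0, None))
        item_names = ITEMS
        pred_names = struct.factors
        self.loadings_ = dict(zip(item_names, std[:10]))
        self.loadings_se_ = dict(zip(item_names, std_se[:10]))
        self.beta_ = dict(zip(pred_names, std[10:]))
        self.beta_se_ = dict(zip(pred_names, std_se[10:]))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(std_se[10:] > 0, std[10:] / std_se[10:], np.inf)
        self.beta_pvalues_ = dict(zip(pred_names, 2 * stats.norm.sf(np.abs(z))))
        self.fit_indices_ = self._fit_indices(S, n, struct)
        return self

    def _acov(self, theta, S, struct, logdet_S, Z):
        n = self.n_obs_
        H = self._hessian(theta, S, struct, logdet_S)
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.pinv(H)
            self.converged_ = False
        acov = (2.0 / (n - 1)) * Hinv
        if self.robust_se:
            dS = struct.dsigma(theta)
            Sigma = struct.implied(theta)
            Sinv = np.linalg.inv(Sigma)
            U = Z @ Sinv                                   # n x p
            trs = np.array([np.trace(Sinv @ d) for d in dS])
            q = np.einsum("ip,kpq,iq->ik", U, np.array(dS), U, optimize=True)
            scores = 0.5 * (q - trs[None, :])              # n x q
            B = scores.T @ scores
            A_inv = acov  # (A = ((n-1)/2) H, acov = A^{-1})
            acov = A_inv @ B @ A_inv
        return acov

    def _hessian(self, theta, S, struct, logdet_S, eps=1e-5):
        q = struct.q
        H = np.empty((q, q))
        for k in range(q):
            tp = theta.copy(); tp[k] += eps
            tm = theta.copy(); tm[k] -= eps
            _, gp = _discrepancy_and_grad(tp, S, struct, logdet_S)
            _, gm = _discrepancy_and_grad(tm, S, struct, logdet_S)
            H[k] = (gp - gm) / (2 * eps)
        return (H + H.T) / 2.0

    def _std_jacobian(self, theta, struct, eps=1e-6):
        base = self._standardized(theta, struct)
        J = np.empty((base.size, theta.size))
        for k in range(theta.size):
            tp = theta.copy(); tp[k] += eps
            J[:, k] = (self._standardized(tp, struct) - base) / eps
        return J

    def _fit_indices(self, S, n, struct):
        p = struct.p
        df = p * (p + 1) // 2 - struct.q
        T = (n - 1) * self.discrepancy_
        D = np.diag(S)
        R = S / np.sqrt(np.outer(D, D))
        F_b = -float(np.linalg.slogdet(R)[1])
        T_b = (n - 1) * F_b
        df_b = p * (p - 1) // 2
        cfi = 1.0 - max(T - df, 0.0) / max(T_b - df_b, T - df, 1e-12)
        denom = T_b / df_b - 1.0
        tli = (T_b / df_b - T / df) / denom if denom > 0 else 1.0
        rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
        resid = (S - self.sigma_implied_) / np.sqrt(np.outer(D, D))
        iu = np.triu_indices(p)
        srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
        return {
            "chi2": float(T), "df": float(df),
            "pvalue": float(stats.chi2.sf(T, df)) if df > 0 else float("nan"),
            "CFI": float(cfi), "TLI": float(tli), "RMSEA": rmsea, "SRMR": srmr,
        }

    def result(self) -> SEMResult:
        return SEMResult(
            loadings=self.loadings_, loadings_se=self.loadings_se_,
            beta=self.beta_, beta_se=self.beta_se_, beta_pvalues=self.beta_pvalues_,
            fit=self.fit_indices_, converged=self.converged_,
            n_obs=self.n_obs_, n_iter=self.n_iter_,
        )


def fit_sem(
    behavior_frame: pd.DataFrame,
    efficiency: Sequence[float] | np.ndarray,
    include_na: bool = True,
    robust_se: bool = False,
) -> SEMResult:
    """Fit the fixed model with one efficiency outcome vector swapped in.

    ``behavior_frame`` is :meth:`CohortBehavior.sem_frame` output (or any
    frame with the item, age, gender and na_score columns); ``efficiency``
    must be aligned to its rows.
    """
    efficiency = np.asarray(efficiency, dtype=float)
    if len(efficiency) != len(behavior_frame):
        raise ValidationError("efficiency vector not aligned to behavior rows")
    X = behavior_frame.copy()
    X["efficiency"] = efficiency
    model = StructuralEquationModel(include_na=include_na, robust_se=robust_se)
    model.fit(X)
    return model.result()


# --------------------------------------------------------------------------
# derived reporting helpers
# --------------------------------------------------------------------------

#: Conventional fit-index cutoffs (Hu-Bentler style).
FIT_CUTOFFS = {"CFI": 0.90, "TLI": 0.90, "RMSEA": 0.08, "SRMR": 0.08}


def fit_acceptable(result: SEMResult) -> tuple[bool, dict[str, bool]]:
    """Conjunction of CFI >= .90, TLI >= .90, RMSEA <= .08, SRMR <= .08."""
    f = result.fit
    verdicts = {
        "CFI": f["CFI"] >= FIT_CUTOFFS["CFI"],
        "TLI": f["TLI"] >= FIT_CUTOFFS["TLI"],
        "RMSEA": f["RMSEA"] <= FIT_CUTOFFS["RMSEA"],
        "SRMR": f["SRMR"] <= FIT_CUTOFFS["SRMR"],
    }
    return all(verdicts.values()), verdicts


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if m < 1:
        raise ValidationError("comparison count m must be >= 1")
    return min(1.0, m * p)


@dataclass(frozen=True)
class AssociationReport:
    """Grid of standardized coefficients and corrected p-values per strategy."""

    strategy: str
    grid: pd.DataFrame           # display grid: beta row + p row per threshold
    tidy: pd.DataFrame           # long format with flags
    m: int


def association_report(
    results: Mapping[tuple[str, float], SEMResult],
    strategy: str,
    networks: Sequence[str],
    thresholds: Sequence[float],
    m: int = 10,
    spec=None,
) -> AssociationReport:
    """Build a Table-2/3-style report for one strategy ('ES' or 'CR').

    Rows are thresholds (a coefficient row and a corrected-p row each),
    columns networks; cells without a fitted model print ``N\\A``.  Corrected
    p < 0.05 is flagged significant, [0.05, 0.10) marginally significant.
    """
    if strategy not in ("ES", "CR"):
        raise ValidationError("strategy must be 'ES' or 'CR'")
    tidy_rows = []
    display: dict[str, list[str]] = {}
    for net in networks:
        size = None
        if spec is not None:
            size = spec.n_nodes if net == "WBN" else spec.network_size(net)
        header = f"{net} ({size})" if size else net
        col = []
        for t in thresholds:
            res = results.get((net, round(float(t), 2)))
            if res is None:
                col += ["N\\A", "N\\A"]
                continue
            beta = res.beta[strategy]
            p_raw = res.beta_pvalues[strategy]
            p_corr = bonferroni(p_raw, m)
            tidy_rows.append({
                "network": net, "threshold": round(float(t), 2), "beta": beta,
                "p_raw": p_raw, "p_corrected": p_corr,
                "significant": p_corr < 0.05,
                "marginal": 0.05 <= p_corr < 0.10,
                "converged": res.converged,
            })
            col += [f"{beta:+.3f}", f"{p_corr:.3f}"]
        display[header] = col
    index = []
    for t in thresholds:
        index += [f"{t:.2f}", f"{t:.2f} (p)"]
    missing = [
        (net, t) for net in networks for t in thresholds
        if (net, round(float(t), 2)) not in results
    ]
    grid = pd.DataFrame(display, index=index)
    grid.index.name = "threshold"
    tidy = pd.DataFrame(
        tidy_rows,
        columns=["network", "threshold", "beta", "p_raw", "p_corrected",
                 "significant", "marginal", "converged"],
    )
    return AssociationReport(strategy=strategy, grid=grid, tidy=tidy, m=m)


# --------------------------------------------------------------------------
# model-implied simulation (for parameter-recovery and calibration studies)
# --------------------------------------------------------------------------

def simulate_sem_dataset(
    n: int,
    loading: float = 0.8,
    beta: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a dataset directly from the model in its standardized metric.

    Latents and covariates are independent standard normals; each item is
    ``loading * factor + sqrt(1 - loading^2) * noise`` (continuous); the
    outcome is the structural regression with disturbance variance chosen so
    every observed variable has unit variance.  Returns the frame
    :func:`fit_sem` expects.
    """
    beta = dict(beta or {})
    preds = ["ES", "CR", "age", "gender", "na_score"]
    b = np.array([beta.get(k, 0.0) for k in preds])
    if (b ** 2).sum() >= 1.0:
        raise ValidationError("sum of squared betas must be < 1 in the standardized metric")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal((n, 5))
    eff = xi @ b + np.sqrt(1.0 - (b ** 2).sum()) * rng.standard_normal(n)
    resid_sd = np.sqrt(1.0 - loading ** 2)
    cols = {}
    for i, name in enumerate(ES_ITEMS):
        cols[name] = loading * xi[:, 0] + resid_sd * rng.standard_normal(n)
    for i, name in enumerate(CR_ITEMS):
        cols[name] = loading * xi[:, 1] + resid_sd * rng.standard_normal(n)
    cols["age"], cols["gender"], cols["na_score"] = xi[:, 2], xi[:, 3], xi[:, 4]
    cols["efficiency"] = eff
    return pd.DataFrame(cols)
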