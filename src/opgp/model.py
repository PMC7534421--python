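"""Linear mixed models for genetic evaluation (REML + BLUP).

The model is

    y = 1*mu + sum_i Z_i u_i + e,     u_i ~ N(0, K_i * sigma2_i),
                                      e   ~ N(0, I * sigma2_e),

with an intercept as the only fixed effect (phenotypes are pre-adjusted)
and one or two random genetic terms, each with an arbitrary positive
semi-definite covariance matrix K_i (A, G, Ga, H, D or HD).  Individuals
present in K_i but without phenotypes receive predictions and PEV through
the same equations.

Variance components are estimated by average-information REML with
EM-REML fallback steps when the AI update leaves the parameter space;
single-random-term models use an exact spectral profile of the restricted
likelihood instead (one eigendecomposition, then a 1-D optimisation).

`BLUPModel.fit()` returns a `BLUPResults` object carrying the variance
components with standard errors, the REML log-likelihood and AIC,
random-effect predictions (EBV/MBV/GEBV, dominance deviations, MGV),
prediction error variances and heritability ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .kinship import RelationshipMatrix

ADDITIVE = "additive"
DOMINANCE = "dominance"
RESIDUAL = "residual"

#: display name of the additive prediction by covariance kind
PREDICTION_NAME = {"A": "EBV", "G": "MBV", "Ga": "MBV", "H": "GEBV", "HD": "GEBV"}


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trajectory."""

    def __init__(self, message: str, trajectory: list):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class HeritabilityEstimates:
    """Variance ratios h2 = s2g/T, d2 = s2d/T, H2 = (s2g+s2d)/T with T the
    total of genetic plus residual variance; SEs by first-order delta method."""

    h2: float
    d2: float
    H2: float
    se_h2: float
    se_d2: float
    se_H2: float

    def __str__(self) -> str:
        return (f"h2={self.h2:.3f} ({self.se_h2:.3f})  "
                f"d2={self.d2:.3f} ({self.se_d2:.3f})  "
                f"H2={self.H2:.3f} ({self.se_H2:.3f})")


class BLUPModel:
    """Mixed model for one trait with genetic covariance structures.

    Parameters
    ----------
    y : array-like
        Phenotypes (adjusted), one per observation.
    ids : sequence of str
        Individual id per observation; must appear in every term's matrix.
    terms : sequence of (label, RelationshipMatrix)
        Random genetic terms; labels 'additive' and/or 'dominance'.
    """

    def __init__(self, y, ids, terms):
        self.y = np.asarray(y, dtype=float)
        self.ids = np.asarray(ids, dtype=object)
        if self.y.ndim != 1 or len(self.y) != len(self.ids):
            raise ValueError("y and ids must be 1-D and equally long")
        if np.isnan(self.y).any():
            raise ValueError("y contains missing values; drop them before fitting")
        if len(self.y) < 3:
            raise ValueError("need at least 3 observations")
        labels = [lab for lab, _ in terms]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate random-term labels")
        self.terms: list[tuple[str, RelationshipMatrix]] = list(terms)
        self.n = len(self.y)
        self._obs_index = {}   # label -> obs position within K ids
        self._kfull = []       # label-ordered n x n covariance of observations
        for label, K in self.terms:
            idx = K.index_of(self.ids)
            self._obs_index[label] = idx
            self._kfull.append(K.values[np.ix_(idx, idx)])

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, terms,
                       id_col: str = "individual_id") -> "BLUPModel":
        sub = data[[id_col, trait]].dropna(subset=[trait])
        return cls(sub[trait].to_numpy(), sub[id_col].to_numpy(), terms)

    # ------------------------------------------------------------------
    # restricted likelihood machinery (observation space)
    # ------------------------------------------------------------------

    def _build_V(self, theta: np.ndarray) -> np.ndarray:
        V = theta[-1] * np.eye(self.n)
        for t, K in zip(theta[:-1], self._kfull):
            V += t * K
        return V

    def _logl_only(self, theta: np.ndarray) -> float:
        """Restricted log-likelihood without score/AI (no full inverse)."""
        n = self.n
        try:
            cho = linalg.cho_factor(self._build_V(theta), lower=True)
        except linalg.LinAlgError:
            return -np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
        sol = linalg.cho_solve(cho, np.column_stack([self.y, np.ones(n)]))
        vy, vx = sol[:, 0], sol[:, 1]
        xvx = vx.sum()
        ypy = self.y @ vy - (self.y @ vx) ** 2 / xvx
        return -0.5 * (logdet_v + np.log(xvx) + ypy)

    def _reml_pieces(self, theta: np.ndarray):
        """Return (logl, score, AI, P, Py) at variance components theta.

        theta orders the genetic terms first, residual last.
        """
        n = self.n
        cho = linalg.cho_factor(self._build_V(theta), lower=True)
        logdet_v = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Vinv = linalg.cho_solve(cho, np.eye(n))
        vx = Vinv.sum(axis=1)              # V^-1 X with X = 1
        xvx = vx.sum()
        P = Vinv - np.outer(vx, vx) / xvx
        Py = P @ self.y
        ypy = self.y @ Py
        logl = -0.5 * (logdet_v + np.log(xvx) + ypy)
        ws, trs = [], []
        for K in self._kfull:
            ws.append(K @ Py)
            trs.append(np.sum(P * K))
        ws.append(Py)
        trs.append(np.trace(P))
        score = np.array([0.5 * (Py @ w - tr) for w, tr in zip(ws, trs)])
        W = np.column_stack(ws)
        AI = 0.5 * (W.T @ P @ W)
        return logl, score, AI, P, Py

    def fit(self, start=None, maxiter: int = 200, tol_logl: float = 1e-8,
            tol_param: float = 1e-6) -> "BLUPResults":
        """Estimate variance components by REML and return results."""
        if not self.terms:
            return self._fit_null()
        if len(self.terms) == 1 and start is None:
            return self._fit_spectral(tol_param=tol_param)
        return self._fit_ai(start, maxiter, tol_logl, tol_param)

    def _fit_null(self) -> "BLUPResults":
        s2 = float(np.var(self.y, ddof=1))
        n = self.n
        logl = -0.5 * ((n - 1) * np.log(s2) + np.log(n) + (n - 1))
        cov = np.array([[2.0 * s2**2 / (n - 1)]])
        return BLUPResults(self, np.array([s2]), cov, logl, True, 0, [],
                           method="closed-form")

    def _fit_ai(self, start, maxiter, tol_logl, tol_param) -> "BLUPResults":
        vary = float(np.var(self.y, ddof=1))
        floor = 1e-10 * vary
        k = len(self.terms)
        theta = (np.asarray(start, dtype=float) if start is not None
                 else np.full(k + 1, vary / (k + 1)))
        trajectory = []
        prev_logl = -np.inf
        logl = AI = None
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            logl, score, AI, _, _Py = self._reml_pieces(theta)
            trajectory.append((theta.copy(), logl))
            if it > 1 and abs(logl - prev_logl) < tol_logl and d_par < tol_param:
                converged = True
                break
            prev_logl = logl
            # active set: components at the floor whose score points outward
            # stay frozen there, so the rest converges at AI speed
            free = ~((theta <= 1.001 * floor) & (score < 0))
            if not free.any():
                converged = True
                break
            d_ai = np.zeros_like(theta)
            sub_ai = AI[np.ix_(free, free)]
            try:
                d_ai[free] = np.linalg.solve(sub_ai, score[free])
            except np.linalg.LinAlgError:
                d_ai[free] = np.linalg.pinv(sub_ai) @ score[free]
            # EM-REML update s2_new = s2 + s2^2 (y'PKPy - tr(PK)) / n: slower
            # but monotone; used when a (step-halved) AI step cannot ascend
            d_em = np.where(free, theta**2 * (2.0 * score) / self.n, 0.0)
            new_theta = None
            for direction in (d_ai, d_em):
                if not np.all(np.isfinite(direction)):
                    continue
                step = 1.0
                for _ in range(12):
                    trial = np.maximum(theta + step * direction, floor)
                    if self._logl_only(trial) >= logl - 1e-12:
                        new_theta = trial
                        break
                    step *= 0.5
                if new_theta is not None:
                    break
            if new_theta is None:  # ascent impossible: at a (local) maximum
                converged = True
                d_par = 0.0
                break
            d_par = np.max(np.abs(new_theta - theta) / (np.abs(theta) + 1e-12))
            theta = new_theta
        if not converged:
            raise ConvergenceError(
                f"AI-REML did not converge in {maxiter} iterations", trajectory)
        cov = np.linalg.pinv(AI)
        return BLUPResults(self, theta, cov, logl, converged, it, trajectory,
                           method="ai-reml")

    def _fit_spectral(self, tol_param: float = 1e-6) -> "BLUPResults":
        """Exact 1-D profile REML for a single genetic term plus residual."""
        n = self.n
        K = self._kfull[0]
        lam_eigs, U = linalg.eigh(K)
        lam_eigs = np.maximum(lam_eigs, 0.0)
        yt = U.T @ self.y
        xt = U.T @ np.ones(n)

        def profile(log_ratio: float):
            r = np.exp(log_ratio)
            d = r * lam_eigs + 1.0
            xvx0 = np.sum(xt**2 / d)
            beta = np.sum(xt * yt / d) / xvx0
            resid = yt - beta * xt
            ypy0 = np.sum(resid**2 / d)
            s2e = ypy0 / (n - 1)
            logl = -0.5 * ((n - 1) * np.log(s2e) + np.sum(np.log(d))
                           + np.log(xvx0) + (n - 1))
            return logl, s2e

        res = optimize.minimize_scalar(lambda t: -profile(t)[0],
                                       bounds=(-30.0, 30.0), method="bounded",
                                       options={"xatol": 1e-10})
        log_ratio = float(res.x)
        logl, s2e = profile(log_ratio)
        theta = np.array([np.exp(log_ratio) * s2e, s2e])
        vary = float(np.var(self.y, ddof=1))
        theta = np.maximum(theta, 1e-10 * vary)
        _, _, AI, _, _ = self._reml_pieces(theta)
        cov = np.linalg.pinv(AI)
        return BLUPResults(self, theta, cov, logl, True, int(res.nfev), [],
                           method="spectral-reml")

    def evaluate(self, params: dict[str, float]) -> "BLUPResults":
        """Results at fixed variance components (no estimation).

        ``params`` maps each term label plus 'residual' to a variance.
        """
        theta = np.array([params[lab] for lab, _ in self.terms]
                         + [params[RESIDUAL]], dtype=float)
        logl, _, AI, _, _ = self._reml_pieces(theta)
        return BLUPResults(self, theta, np.linalg.pinv(AI), logl, True, 0, [],
                           method="fixed")


class BLUPResults:
    """REML estimates, BLUP predictions and derived genetic parameters."""

    def __init__(self, model: BLUPModel, theta: np.ndarray, cov_params,
                 loglike: float, converged: bool, n_iter: int, trajectory,
                 method: str):
        self.model = model
        self.labels = [lab for lab, _ in model.terms] + [RESIDUAL]
        self.params = dict(zip(self.labels, np.asarray(theta, dtype=float)))
        self.cov_params = np.asarray(cov_params, dtype=float)
        self.loglike = float(loglike)
        self.converged = converged
        self.n_iter = n_iter
        self.trajectory = trajectory
        self.method = method
        self._theta = np.asarray(theta, dtype=float)
        self._P = None
        self._Py = None
        self._mu = None
        self._pev_cache: dict[str, pd.Series] = {}

    # -- fit statistics -------------------------------------------------

    @property
    def bse(self) -> dict[str, float]:
        se = np.sqrt(np.maximum(np.diag(self.cov_params), 0.0))
        return dict(zip(self.labels, se))

    @property
    def aic(self) -> float:
        """AIC on the convention used by the study software: -2*logL + 2."""
        return -2.0 * self.loglike + 2.0

    @property
    def aic_conventional(self) -> float:
        """-2*logL + 2k with k the number of variance parameters."""
        return -2.0 * self.loglike + 2.0 * len(self.labels)

    # -- internals ------------------------------------------------------

    def _projection(self):
        if self._P is None:
            _, _, _, P, Py = self.model._reml_pieces(self._theta)
            self._P, self._Py = P, Py
            # GLS intercept mu_hat = (1'V^-1 1)^-1 1'V^-1 y
            n = self.model.n
            V = self._theta[-1] * np.eye(n)
            for t, K in zip(self._theta[:-1], self.model._kfull):
                V += t * K
            cho = linalg.cho_factor(V, lower=True)
            vy = linalg.cho_solve(cho, self.model.y)
            vx = linalg.cho_solve(cho, np.ones(n))
            self._mu = float(np.sum(vy) / np.sum(vx))
        return self._P, self._Py

    @property
    def mu(self) -> float:
        self._projection()
        return self._mu

    # -- predictions ----------------------------------------------------

    def ranef(self, label: str) -> pd.Series:
        """BLUP of random term ``label`` for every id in its covariance matrix.

        u_hat = sigma2 * K Z' P y  (equals the Henderson MME solution).
        """
        _, Py = self._projection()
        K = dict(self.model.terms)[label]
        idx = self.model._obs_index[label]
        zpy = np.zeros(K.n)
        np.add.at(zpy, idx, Py)
        u = self.params[label] * (K.values @ zpy)
        return pd.Series(u, index=K.ids, name=label)

    def pev(self, label: str) -> pd.Series:
        """Prediction error variance per individual for term ``label``.

        PEV = diag( sigma2 K - sigma2^2 K Z' P Z K ), the corresponding
        diagonal block of the inverted MME coefficient matrix.
        """
        if label in self._pev_cache:
            return self._pev_cache[label]
        P, _ = self._projection()
        K = dict(self.model.terms)[label]
        idx = self.model._obs_index[label]
        s2 = self.params[label]
        S = np.zeros((K.n, K.n))
        S[np.ix_(idx, idx)] = P
        M = K.values @ S
        pev = s2 * np.diag(K.values) - s2**2 * np.einsum("ij,ji->i", M, K.values)
        out = pd.Series(np.maximum(pev, 0.0), index=K.ids, name=f"PEV_{label}")
        self._pev_cache[label] = out
        return out

    @property
    def additive_name(self) -> str:
        K = dict(self.model.terms).get(ADDITIVE)
        return PREDICTION_NAME.get(K.kind, "EBV") if K is not None else "EBV"

    @property
    def mgv(self) -> pd.Series:
        """Molecular genetic value MGV = additive + dominance prediction."""
        if DOMINANCE not in self.labels:
            raise ValueError("MGV requires a dominance term in the model")
        g = self.ranef(ADDITIVE)
        d = self.ranef(DOMINANCE)
        common = d.index.intersection(g.index)
        return (g.loc[common] + d.loc[common]).rename("MGV")

    def predictions_frame(self) -> pd.DataFrame:
        """Per-individual predictions and PEV for every random term."""
        frames = {}
        for lab, _K in self.model.terms:
            name = self.additive_name if lab == ADDITIVE else "dominance"
            frames[name] = self.ranef(lab)
            frames[f"PEV_{name}"] = self.pev(lab)
        df = pd.DataFrame(frames)
        if DOMINANCE in self.labels:
            df["MGV"] = self.mgv
        df.index.name = "individual_id"
        return df

    # -- genetic parameters --------------------------------------------

    def heritability(self) -> HeritabilityEstimates:
        s2g = self.params.get(ADDITIVE, 0.0)
        s2d = self.params.get(DOMINANCE, 0.0)
        s2e = self.params[RESIDUAL]
        total = s2g + s2d + s2e
        if total <= 0:
            raise ValueError("total variance is zero")
        h2, d2 = s2g / total, s2d / total
        H2 = h2 + d2

        # delta method on the fitted parameter vector
        grads = {"h2": [], "d2": [], "H2": []}
        for lab in self.labels:
            is_g = lab == ADDITIVE
            is_d = lab == DOMINANCE
            grads["h2"].append((total * is_g - s2g) / total**2)
            grads["d2"].append((total * is_d - s2d) / total**2)
            grads["H2"].append((total * (is_g or is_d) - (s2g + s2d)) / total**2)
        ses = {}
        for key, grad in grads.items():
            grad = np.array(grad)
            ses[key] = float(np.sqrt(max(grad @ self.cov_params @ grad, 0.0)))
        return HeritabilityEstimates(h2, d2, H2, ses["h2"], ses["d2"], ses["H2"])

    def theoretical_accuracy(self, label: str = ADDITIVE) -> pd.Series:
        """r_i = sqrt(1 - PEV_i / (sigma2_a (1 + F_i))) per individual."""
        from .validation import theoretical_accuracy  # local to avoid cycle
        K = dict(self.model.terms)[label]
        F = pd.Series(np.diag(K.values) - 1.0, index=K.ids)
        return theoretical_accuracy(self.pev(label), self.params[label], F)

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "BLUP mixed model (REML)",
            f"  method: {self.method}   converged: {self.converged} "
            f"({self.n_iter} iterations)",
            f"  n obs: {self.model.n}",
            "  variance components:",
        ]
        bse = self.bse
        for lab in self.labels:
            lines.append(f"    {lab:<10} {self.params[lab]:12.6g}  "
                         f"(SE {bse[lab]:.4g})")
        lines.append(f"  logL: {self.loglike:.4f}   AIC: {self.aic:.4f}")
        try:
            lines.append("  ratios: " + str(self.heritability()))
        except ValueError:
            pass
        return "\n".join(lines)
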