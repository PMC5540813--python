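"""Pedigree-based variance-component estimation.

Univariate model for a quantitative trait y in a set of pedigrees:

    y = X b + g + e,   g ~ N(0, sigma_g^2 * K),   e ~ N(0, sigma_e^2 * I)

where K = 2*Phi is the expected additive relationship matrix from the
pedigree (1 on the diagonal for non-inbred individuals, 0.5 for
parent-offspring and full sibs). Narrow-sense heritability is
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2). The likelihood is maximized by
one eigendecomposition of K followed by a 1-d profile search over h^2, with
the fixed effects solved by GLS and the total variance profiled analytically
at every candidate h^2. The test of h^2 = 0 is a likelihood-ratio test
against the boundary null, using the 1/2 chi2_0 + 1/2 chi2_1 mixture.

Bivariate model for traits (y1, y2) on the same individuals:

    cov = G (x) K + E (x) I,   G, E 2x2 PSD

from which the genetic correlation rho_g = G12 / sqrt(G11 G22), the
environmental correlation rho_e likewise from E, and the model-implied
phenotypic correlation from G + E. After rotating both traits by the
eigenvectors of K the 2n-dimensional likelihood factorizes into n
independent 2x2 problems, so each objective evaluation is O(n). Tests:
rho_g = 0 by a 1-df LRT; rho_g = 1 against the boundary with the 1/2 chi2
mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "validate_pedigree",
    "kinship_from_pedigree",
    "VarianceComponentModel",
    "BivariateVarianceComponentModel",
    "fit_univariate_vc",
    "fit_bivariate_vc",
    "cross_ai_correlations",
]


# ---------------------------------------------------------------------------
# Pedigree / kinship


def _parent_arrays(ped: pd.DataFrame):
    ids = ped["individual_id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in pedigree")
    pos = {v: i for i, v in enumerate(ids)}

    def resolve(col):
        out = []
        for v in ped[col]:
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "0" or v == 0:
                out.append(-1)
            elif v in pos:
                out.append(pos[v])
            else:
                raise ValueError(f"{col} {v!r} not present in pedigree")
        return np.array(out)

    father, mother = resolve("father_id"), resolve("mother_id")
    if np.any((father == -1) != (mother == -1)):
        bad = ped["individual_id"][(father == -1) != (mother == -1)].tolist()
        raise ValueError(f"individuals with exactly one known parent: {bad}")
    return father, mother


def validate_pedigree(ped: pd.DataFrame) -> np.ndarray:
    """Check pedigree consistency and return a topological order
    (parents before offspring). Raises on cycles or half-specified
    parents."""
    father, mother = _parent_arrays(ped)
    n = len(ped)
    order, placed = [], np.zeros(n, dtype=bool)
    remaining = set(range(n))
    while remaining:
        ready = [i for i in remaining
                 if (father[i] == -1 or placed[father[i]])
                 and (mother[i] == -1 or placed[mother[i]])]
        if not ready:
            raise ValueError("pedigree contains a cycle")
        for i in ready:
            order.append(i)
            placed[i] = True
            remaining.discard(i)
    return np.array(order)


def kinship_from_pedigree(ped: pd.DataFrame) -> np.ndarray:
    """Expected additive relationship matrix K = 2*Phi by the recursive
    tabular method, in the row order of ``ped``.

    K[i,i] = 1 + F_i with inbreeding F_i = Phi(father_i, mother_i); for i
    with known parents and any j processed earlier,
    K[i,j] = (K[father_i, j] + K[mother_i, j]) / 2.
    """
    father, mother = _parent_arrays(ped)
    order = validate_pedigree(ped)
    n = len(ped)
    K = np.zeros((n, n))
    for i in order:
        f, m = father[i], mother[i]
        if f == -1:
            K[i, i] = 1.0
        else:
            row = 0.5 * (K[f, :] + K[m, :])
            K[i, :] = row
            K[:, i] = row
            K[i, i] = 1.0 + 0.5 * K[f, m]
    return K


# ---------------------------------------------------------------------------
# Univariate fit


@dataclass
class VCFit:
    """Variance-component fit summary (one or two traits)."""
    h2: float
    h2_se: float
    p_h2: float
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    loglik: float
    h2_trait2: float | None = None
    rho_g: float | None = None
    rho_g_se: float | None = None
    p_rho0: float | None = None
    p_rho1: float | None = None
    rho_e: float | None = None
    rho_phen: float | None = None
    extras: dict = field(default_factory=dict)


def _prepare(y, X, K):
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1)) if X is None else np.column_stack(
        [np.ones(n), np.asarray(X, dtype=float)]
    )
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship matrix shape does not match phenotypes")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kinship matrix must be symmetric")
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-8:
        raise ValueError("kinship matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    return y, X, lam, U


class VarianceComponentModel(BaseEstimator):
    """Univariate pedigree variance-component model (ML).

    ``fit(y, X=None, kinship=K)`` maximizes the multivariate-normal
    likelihood with covariance ``sigma_g^2 K + sigma_e^2 I``; covariates X
    (an intercept is always prepended) are profiled out by GLS at each
    candidate heritability.

    Attributes after fitting: ``h2_``, ``h2_se_``, ``p_``,
    ``sigma2_g_``, ``sigma2_e_``, ``beta_``, ``loglik_``, ``loglik_null_``,
    ``at_boundary_``.
    """

    def __init__(self, tol: float = 1e-8):
        self.tol = tol

    # profile negative log-likelihood at heritability h
    @staticmethod
    def _nll(h, ytil, Xtil, lam):
        n = len(ytil)
        d = h * lam + (1.0 - h)
        d = np.clip(d, 1e-12, None)
        Xi = Xtil / d[:, None]
        beta = np.linalg.solve(Xtil.T @ Xi, Xi.T @ ytil)
        r = ytil - Xtil @ beta
        sigma2 = float(np.sum(r**2 / d) / n)
        nll = 0.5 * (n * math.log(2.0 * math.pi * sigma2)
                     + float(np.sum(np.log(d))) + n)
        return nll, beta, sigma2

    def fit(self, y, X=None, *, kinship):
        y, X, lam, U = _prepare(y, X, kinship)
        ytil, Xtil = U.T @ y, U.T @ X

        def f(h):
            return self._nll(h, ytil, Xtil, lam)[0]

        res = optimize.minimize_scalar(f, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": self.tol})
        # the bounded minimizer never lands exactly on a bound; check both
        candidates = [(f(0.0), 0.0), (res.fun, float(res.x)), (f(1.0), 1.0)]
        nll_opt, h_opt = min(candidates, key=lambda c: c[0])
        _, beta, sigma2 = self._nll(h_opt, ytil, Xtil, lam)
        self.h2_ = h_opt
        self.sigma2_ = sigma2
        self.sigma2_g_ = h_opt * sigma2
        self.sigma2_e_ = (1.0 - h_opt) * sigma2
        self.beta_ = beta
        self.loglik_ = -nll_opt
        self.loglik_null_ = -f(0.0)
        lr = max(0.0, 2.0 * (self.loglik_ - self.loglik_null_))
        # boundary null: 1/2 chi2_0 + 1/2 chi2_1 mixture
        self.p_ = float(0.5 * stats.chi2.sf(lr, 1)) if lr > 0 else 0.5
        self.lrt_ = lr
        self.at_boundary_ = h_opt in (0.0, 1.0)
        self.h2_se_ = self._profile_se(f, h_opt, nll_opt)
        return self

    @staticmethod
    def _profile_se(f, h, nll, step=1e-3):
        if h - step < 0.0 or h + step > 1.0:
            return float("nan")
        d2 = (f(h + step) - 2.0 * nll + f(h - step)) / step**2
        return 1.0 / math.sqrt(d2) if d2 > 0 else float("nan")

    def result_(self) -> VCFit:
        return VCFit(h2=self.h2_, h2_se=self.h2_se_, p_h2=self.p_,
                     sigma2_g=self.sigma2_g_, sigma2_e=self.sigma2_e_,
                     beta=self.beta_, loglik=self.loglik_)


def fit_univariate_vc(y, X, K) -> VCFit:
    """Functional wrapper around :class:`VarianceComponentModel`."""
    return VarianceComponentModel().fit(y, X, kinship=K).result_()


# ---------------------------------------------------------------------------
# Bivariate fit


def _bi_nll(theta, ytil, Xtil, lam, rho_g_fixed=None):
    """Negative log-likelihood of the rotated bivariate model.

    theta = (log G11, log G22, z_g, log E11, log E22, z_e); z terms map to
    correlations via tanh. When ``rho_g_fixed`` is given, z_g is dropped
    from theta and the genetic correlation is held at that value.
    """
    if rho_g_fixed is None:
        lg1, lg2, zg, le1, le2, ze = theta
        rg = math.tanh(zg)
    else:
        lg1, lg2, le1, le2, ze = theta
        rg = rho_g_fixed
    re = math.tanh(ze)
    g1, g2, e1, e2 = (math.exp(v) for v in (lg1, lg2, le1, le2))
    g12 = rg * math.sqrt(g1 * g2)
    e12 = re * math.sqrt(e1 * e2)

    n = len(lam)
    a = lam * g1 + e1
    b = lam * g12 + e12
    c = lam * g2 + e2
    det = a * c - b * b
    if np.any(det <= 0) or np.any(a <= 0):
        return 1e12, None
    w11, w12, w22 = c / det, -b / det, a / det

    y1, y2 = ytil
    p = Xtil.shape[1]
    A = np.zeros((2 * p, 2 * p))
    A[:p, :p] = Xtil.T @ (Xtil * w11[:, None])
    A[:p, p:] = Xtil.T @ (Xtil * w12[:, None])
    A[p:, :p] = A[:p, p:].T
    A[p:, p:] = Xtil.T @ (Xtil * w22[:, None])
    rhs = np.concatenate([
        Xtil.T @ (w11 * y1 + w12 * y2),
        Xtil.T @ (w12 * y1 + w22 * y2),
    ])
    beta = np.linalg.solve(A, rhs)
    r1 = y1 - Xtil @ beta[:p]
    r2 = y2 - Xtil @ beta[p:]
    quad = float(np.sum(w11 * r1**2 + 2.0 * w12 * r1 * r2 + w22 * r2**2))
    nll = 0.5 * (float(np.sum(np.log(det))) + quad + 2 * n * math.log(2.0 * math.pi))
    params = dict(G=np.array([[g1, g12], [g12, g2]]),
                  E=np.array([[e1, e12], [e12, e2]]), beta=beta)
    return nll, params


_ZBOUND = 8.0  # |rho| <= tanh(8) ~ 1 - 2e-7


class BivariateVarianceComponentModel(BaseEstimator):
    """Bivariate pedigree variance-component model (ML).

    ``fit(Y, X=None, kinship=K)`` with Y of shape (n, 2) estimates 2x2
    genetic and environmental covariance matrices G and E under
    cov(vec Y) = G (x) K + E (x) I, and reports the genetic, environmental
    and model-implied phenotypic correlations with boundary-aware tests of
    rho_g = 0 and rho_g = 1.

    Attributes after fitting: ``G_``, ``E_``, ``rho_g_``, ``rho_g_se_``,
    ``rho_e_``, ``rho_phen_``, ``h2_``, (per-trait, length 2), ``beta_``,
    ``loglik_``, ``p_rho0_``, ``p_rho1_``.
    """

    def __init__(self, n_restarts: int = 2):
        self.n_restarts = n_restarts

    def _optimize(self, x0, args, rho_g_fixed=None):
        nz = 6 if rho_g_fixed is None else 5
        bounds = [(-30, 30)] * nz
        zpos = [2, 5] if rho_g_fixed is None else [4]
        for i in zpos:
            bounds[i] = (-_ZBOUND, _ZBOUND)

        def f(theta):
            return _bi_nll(theta, *args, rho_g_fixed=rho_g_fixed)[0]

        best = None
        for start in x0:
            res = optimize.minimize(f, start, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        return best

    def fit(self, Y, X=None, *, kinship):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("Y must have shape (n, 2)")
        y1, X1, lam, U = _prepare(Y[:, 0], X, kinship)
        y2 = Y[:, 1]
        ytil = (U.T @ y1, U.T @ y2)
        Xtil = U.T @ X1
        args = (ytil, Xtil, lam)

        # univariate starts per trait
        uni = [VarianceComponentModel().fit(Y[:, j], X, kinship=kinship)
               for j in range(2)]
        rc = float(np.corrcoef(Y[:, 0], Y[:, 1])[0, 1])
        z0 = math.atanh(np.clip(rc, -0.95, 0.95))

        def logv(v):
            return math.log(max(v, 1e-8))

        starts = [
            [logv(uni[0].sigma2_g_), logv(uni[1].sigma2_g_), z0,
             logv(uni[0].sigma2_e_), logv(uni[1].sigma2_e_), z0],
            [logv(0.5 * uni[0].sigma2_), logv(0.5 * uni[1].sigma2_), 0.0,
             logv(0.5 * uni[0].sigma2_), logv(0.5 * uni[1].sigma2_), 0.0],
        ][: max(1, self.n_restarts)]
        best = self._optimize(starts, args)
        nll, params = _bi_nll(best.x, *args)
        G, E = params["G"], params["E"]
        self.G_, self.E_ = G, E
        self.beta_ = params["beta"]
        self.loglik_ = -nll
        self.rho_g_ = float(G[0, 1] / math.sqrt(G[0, 0] * G[1, 1]))
        self.rho_e_ = float(E[0, 1] / math.sqrt(E[0, 0] * E[1, 1]))
        P = G + E
        self.rho_phen_ = float(P[0, 1] / math.sqrt(P[0, 0] * P[1, 1]))
        self.h2_ = np.array([G[0, 0] / P[0, 0], G[1, 1] / P[1, 1]])
        self.theta_ = best.x

        # constrained fits for the correlation tests
        drop = [v for i, v in enumerate(best.x) if i != 2]
        fit0 = self._optimize([drop], args, rho_g_fixed=0.0)
        fit1 = self._optimize([drop], args, rho_g_fixed=1.0)
        lr0 = max(0.0, 2.0 * (-nll + fit0.fun))
        lr1 = max(0.0, 2.0 * (-nll + fit1.fun))
        self.p_rho0_ = float(stats.chi2.sf(lr0, 1))
        self.p_rho1_ = float(0.5 * stats.chi2.sf(lr1, 1)) if lr1 > 0 else 0.5
        self.rho_g_se_ = self._rho_se(best.x, args)
        return self

    @staticmethod
    def _rho_se(theta, args, step=1e-4):
        """Delta-method SE of rho_g from the observed information of the
        full parameter vector."""
        k = len(theta)

        def f(t):
            return _bi_nll(t, *args)[0]

        H = np.zeros((k, k))
        f0 = f(theta)
        for i in range(k):
            for j in range(i, k):
                ti = np.array(theta); tj = np.array(theta); tij = np.array(theta)
                ti[i] += step; tj[j] += step
                tij[i] += step; tij[j] += step
                H[i, j] = H[j, i] = (f(tij) - f(ti) - f(tj) + f0) / step**2
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float("nan")
        var_z = cov[2, 2]
        if var_z <= 0:
            return float("nan")
        rho = math.tanh(theta[2])
        return float((1.0 - rho**2) * math.sqrt(var_z))

    def result_(self) -> VCFit:
        return VCFit(
            h2=float(self.h2_[0]), h2_se=float("nan"), p_h2=float("nan"),
            sigma2_g=float(self.G_[0, 0]), sigma2_e=float(self.E_[0, 0]),
            beta=self.beta_, loglik=self.loglik_,
            h2_trait2=float(self.h2_[1]),
            rho_g=self.rho_g_, rho_g_se=self.rho_g_se_,
            p_rho0=self.p_rho0_, p_rho1=self.p_rho1_,
            rho_e=self.rho_e_, rho_phen=self.rho_phen_,
        )


def fit_bivariate_vc(y1, y2, X, K) -> VCFit:
    """Functional wrapper around :class:`BivariateVarianceComponentModel`."""
    Y = np.column_stack([y1, y2])
    return BivariateVarianceComponentModel().fit(Y, X, kinship=K).result_()


def cross_ai_correlations(traits: pd.DataFrame, X, K) -> pd.DataFrame:
    """All pairwise phenotypic and genetic correlations between traits.

    ``traits`` holds one column per trait (e.g. the seven structure AIs).
    The phenotypic correlation is the Pearson correlation of the
    covariate-residualised traits (with its test p-value); the genetic
    correlation comes from the pairwise bivariate variance-component fits,
    with uncorrected LRT p-values for rho_g = 0.
    """
    from .site import residualize

    cols = list(traits.columns)
    resid = {c: residualize(traits[c].to_numpy(), np.asarray(X, dtype=float).T)
             for c in cols}
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            r, p_phen = stats.pearsonr(resid[a], resid[b])
            fit = fit_bivariate_vc(traits[a], traits[b], X, K)
            rows.append({
                "trait_1": a, "trait_2": b,
                "rho_phen": float(r), "p_phen": float(p_phen),
                "rho_g": fit.rho_g, "rho_g_se": fit.rho_g_se,
                "p_rho0": fit.p_rho0, "rho_e": fit.rho_e,
            })
    return pd.DataFrame(rows)
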