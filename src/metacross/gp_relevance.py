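"""Multi-task sparse GP regression and Shapley attribution of metabolites.

Metabolite production activities (inputs) are regressed onto signaling
circuit activities (outputs) with a sparse variational Gaussian process.
The model follows the multi-output construction with one latent GP per
output mixed by the identity matrix, a kernel that is the sum of a squared
exponential and a linear component with hyperparameters shared across all
inputs and latent functions, a Gaussian likelihood with a learned
homoscedastic noise per task, and a common set of inducing points (default
50).  Because the likelihood is Gaussian, the optimal variational posterior
over the inducing values is analytic, so the evidence lower bound is
optimized in its collapsed form (the Titsias bound) over the shared kernel
hyperparameters and per-task noises; inducing locations are placed by
seeded k-means on the training inputs.

Model quality is scored with repeated k-fold cross-validation (task-wise
R^2 and MSE); metabolites are ranked per circuit by the mean absolute
Shapley value of their production on held-out samples, and a circuit only
contributes annotated (metabolite, circuit) pairs when its mean test R^2
exceeds the relevance threshold (default 0.5).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import comb
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

EXACT_SHAP_MAX_FEATURES = 12


@dataclass
class GPConfig:
    """Configuration of the sparse multi-task GP."""

    n_inducing: int = 50
    max_opt_iter: int = 200
    optimize: bool = True
    jitter: float = 1e-8
    seed: int = 0
    #: optional fixed hyperparameters {lengthscale, rbf_variance,
    #: linear_variance, noise}; used with optimize=False
    init_params: dict = field(default_factory=dict)
    #: codomain of the outputs; when set, predictive means are projected
    #: onto it before scoring (circuit activities live in [0, 1])
    clip_range: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------


def _kernel(X1: np.ndarray, X2: np.ndarray, ell: float, v_rbf: float,
            v_lin: float) -> np.ndarray:
    """Shared-hyperparameter sum kernel: RBF + linear."""
    sq = (np.sum(X1 ** 2, axis=1)[:, None] + np.sum(X2 ** 2, axis=1)[None, :]
          - 2.0 * X1 @ X2.T)
    np.maximum(sq, 0.0, out=sq)
    return v_rbf * np.exp(-0.5 * sq / ell ** 2) + v_lin * (X1 @ X2.T)


def _kernel_diag(X: np.ndarray, ell: float, v_rbf: float, v_lin: float) -> np.ndarray:
    return v_rbf + v_lin * np.sum(X ** 2, axis=1)


# ---------------------------------------------------------------------------
# Sparse multi-task GP (collapsed variational bound)
# ---------------------------------------------------------------------------


class MultiTaskSGPR:
    """Sparse variational GP regressor with shared kernel across tasks."""

    def __init__(self, config: GPConfig | None = None):
        self.config = config or GPConfig()
        self.fitted_ = False

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "MultiTaskSGPR":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("X and Y must be finite")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have aligned rows")
        n, d = X.shape
        self.n_tasks_ = Y.shape[1]
        self.X_ = X
        self.y_mean_ = Y.mean(axis=0)
        self.Yc_ = Y - self.y_mean_

        cfg = self.config
        n_i = cfg.n_inducing
        if n_i > n:
            logger.warning("n_inducing=%d exceeds n=%d; reduced to n", n_i, n)
            n_i = n
        self.Z_ = self._init_inducing(X, n_i, cfg.seed)

        theta0 = self._init_theta()
        if cfg.optimize:
            bounds = [(-8.0, 8.0)] * theta0.size
            res = optimize.minimize(
                self._neg_elbo, theta0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": cfg.max_opt_iter})
            if not np.isfinite(res.fun):
                raise RuntimeError(
                    f"non-finite ELBO during optimization (theta={res.x})")
            theta = res.x
        else:
            theta = theta0
        self.theta_ = theta
        self.elbo_ = -self._neg_elbo(theta)
        self._precompute(theta)
        self.fitted_ = True
        return self

    @staticmethod
    def _init_inducing(X: np.ndarray, n_i: int, seed: int) -> np.ndarray:
        if n_i >= X.shape[0]:
            return X.copy()
        km = KMeans(n_clusters=n_i, n_init=1, random_state=seed & 0x7FFFFFFF)
        km.fit(X)
        return km.cluster_centers_

    def _init_theta(self) -> np.ndarray:
        p = self.config.init_params
        X, Yc = self.X_, self.Yc_
        if "lengthscale" in p:
            ell0 = p["lengthscale"]
        else:
            # median-heuristic on a deterministic subsample
            sub = X[:: max(1, X.shape[0] // 200)]
            sq = (np.sum(sub ** 2, 1)[:, None] + np.sum(sub ** 2, 1)[None, :]
                  - 2 * sub @ sub.T)
            med = np.median(sq[sq > 0]) if np.any(sq > 0) else 1.0
            ell0 = math.sqrt(max(med, 1e-4))
        vy = max(float(Yc.var()), 1e-6)
        v_rbf0 = p.get("rbf_variance", vy)
        v_lin0 = p.get("linear_variance", 0.1 * vy)
        noise0 = p.get("noise", 0.1 * vy)
        return np.log(np.array([ell0, v_rbf0, v_lin0]
                               + [noise0] * self.n_tasks_))

    def _unpack(self, theta: np.ndarray):
        ell, v_rbf, v_lin = np.exp(theta[:3])
        noises = np.exp(theta[3:])
        return ell, v_rbf, v_lin, noises

    def _neg_elbo(self, theta: np.ndarray) -> float:
        try:
            return -self._elbo(theta)
        except np.linalg.LinAlgError:
            return 1e12

    def _elbo(self, theta: np.ndarray) -> float:
        """Collapsed (Titsias) bound, summed over tasks."""
        ell, v_rbf, v_lin, noises = self._unpack(theta)
        X, Z, Yc = self.X_, self.Z_, self.Yc_
        n, m = X.shape[0], Z.shape[0]
        Kmm = _kernel(Z, Z, ell, v_rbf, v_lin)
        Kmm[np.diag_indices_from(Kmm)] += self.config.jitter + 1e-10 * np.trace(Kmm) / m
        Lm = cholesky(Kmm, lower=True)
        Kmn = _kernel(Z, X, ell, v_rbf, v_lin)
        A = solve_triangular(Lm, Kmn, lower=True)        # m x n
        knn = _kernel_diag(X, ell, v_rbf, v_lin)
        qnn_tr = np.sum(A ** 2)
        total = 0.0
        for j in range(self.n_tasks_):
            s2 = noises[j]
            y = Yc[:, j]
            B = np.eye(m) + (A @ A.T) / s2
            LB = cholesky(B, lower=True)
            Ay = A @ y
            c = solve_triangular(LB, Ay, lower=True) / s2
            total += (-0.5 * n * math.log(2 * math.pi)
                      - np.sum(np.log(np.diag(LB)))
                      - 0.5 * n * math.log(s2)
                      - 0.5 * (y @ y) / s2
                      + 0.5 * (c @ c)
                      - 0.5 * (np.sum(knn) - qnn_tr) / s2)
        if not np.isfinite(total):
            raise np.linalg.LinAlgError("non-finite bound")
        return total

    def _precompute(self, theta: np.ndarray) -> None:
        ell, v_rbf, v_lin, noises = self._unpack(theta)
        X, Z, Yc = self.X_, self.Z_, self.Yc_
        m = Z.shape[0]
        Kmm = _kernel(Z, Z, ell, v_rbf, v_lin)
        Kmm[np.diag_indices_from(Kmm)] += self.config.jitter + 1e-10 * np.trace(Kmm) / m
        Lm = cholesky(Kmm, lower=True)
        Kmn = _kernel(Z, X, ell, v_rbf, v_lin)
        A = solve_triangular(Lm, Kmn, lower=True)
        self._alphas = np.empty((m, self.n_tasks_))
        self._LBs = []
        for j in range(self.n_tasks_):
            s2 = noises[j]
            B = np.eye(m) + (A @ A.T) / s2
            LB = cholesky(B, lower=True)
            c = solve_triangular(LB, A @ Yc[:, j], lower=True) / s2
            tmp = solve_triangular(LB.T, c, lower=False)
            self._alphas[:, j] = solve_triangular(Lm.T, tmp, lower=False)
            self._LBs.append(LB)
        self._Lm = Lm
        self._params = (ell, v_rbf, v_lin, noises)

    # -- prediction ---------------------------------------------------------

    def predict(self, Xs: np.ndarray, return_var: bool = False):
        """Predictive mean (and latent variance) per task."""
        if not self.fitted_:
            raise RuntimeError("model is not fitted")
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        ell, v_rbf, v_lin, noises = self._params
        Ksm = _kernel(Xs, self.Z_, ell, v_rbf, v_lin)
        mean = Ksm @ self._alphas + self.y_mean_
        if not return_var:
            return mean
        t1 = solve_triangular(self._Lm, Ksm.T, lower=True)   # m x ns
        kss = _kernel_diag(Xs, ell, v_rbf, v_lin)
        var = np.empty((Xs.shape[0], self.n_tasks_))
        for j in range(self.n_tasks_):
            t2 = solve_triangular(self._LBs[j], t1, lower=True)
            var[:, j] = kss - np.sum(t1 ** 2, axis=0) + np.sum(t2 ** 2, axis=0)
        return mean, np.maximum(var, 0.0)

    @property
    def hyperparameters(self) -> dict:
        ell, v_rbf, v_lin, noises = self._params
        return {"lengthscale": float(ell), "rbf_variance": float(v_rbf),
                "linear_variance": float(v_lin),
                "noise": [float(s) for s in noises]}


def fit_mtgp(X: np.ndarray, Y: np.ndarray, config: GPConfig | None = None) -> MultiTaskSGPR:
    """Fit the sparse multi-task GP (tumor samples only by convention)."""
    return MultiTaskSGPR(config).fit(X, Y)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def r2_score(s: np.ndarray, s_hat: np.ndarray) -> float:
    """Coefficient of determination; 0 is the mean predictor, constant
    observations give NaN."""
    s = np.asarray(s, dtype=float)
    s_hat = np.asarray(s_hat, dtype=float)
    if s.shape != s_hat.shape or s.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    sstot = np.sum((s - s.mean()) ** 2)
    if sstot == 0.0:
        return float("nan")
    return float(1.0 - np.sum((s - s_hat) ** 2) / sstot)


def mse(s: np.ndarray, s_hat: np.ndarray) -> float:
    s = np.asarray(s, dtype=float)
    s_hat = np.asarray(s_hat, dtype=float)
    if s.shape != s_hat.shape:
        raise ValueError("need equal-length vectors")
    return float(np.mean((s - s_hat) ** 2))


# ---------------------------------------------------------------------------
# Repeated k-fold cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-(circuit, repetition, fold) train/test R^2 and MSE."""

    table: pd.DataFrame  # columns: circuit, rep, fold, train_r2, test_r2, train_mse, test_mse

    def circuit_means(self) -> pd.DataFrame:
        return self.table.groupby("circuit")[
            ["train_r2", "test_r2", "train_mse", "test_mse"]].mean()


def repeated_kfold_cv(X: np.ndarray, Y: np.ndarray, k: int = 5,
                      reps: int = 100, config: GPConfig | None = None,
                      task_names: list[str] | None = None) -> CVReport:
    """Fresh shuffled k-fold partition per repetition, full refit per fold."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < 2 * k:
        raise ValueError(f"need n >= 2k samples for {k}-fold CV")
    config = config or GPConfig()
    names = task_names or [f"task{j}" for j in range(Y.shape[1])]
    rows = []
    for rep in range(reps):
        rng = np.random.default_rng((config.seed, rep))
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold_idx, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx)
            fold_cfg = GPConfig(
                n_inducing=config.n_inducing, max_opt_iter=config.max_opt_iter,
                optimize=config.optimize, jitter=config.jitter,
                seed=int(np.random.default_rng(
                    (config.seed, rep, fold_idx)).integers(2 ** 31)),
                init_params=dict(config.init_params),
                clip_range=config.clip_range)
            model = fit_mtgp(X[train_idx], Y[train_idx], fold_cfg)
            pred_tr = model.predict(X[train_idx])
            pred_te = model.predict(X[test_idx])
            if config.clip_range is not None:
                lo, hi = config.clip_range
                pred_tr = np.clip(pred_tr, lo, hi)
                pred_te = np.clip(pred_te, lo, hi)
            for j, name in enumerate(names):
                rows.append((name, rep, fold_idx,
                             r2_score(Y[train_idx, j], pred_tr[:, j]),
                             r2_score(Y[test_idx, j], pred_te[:, j]),
                             mse(Y[train_idx, j], pred_tr[:, j]),
                             mse(Y[test_idx, j], pred_te[:, j])))
    return CVReport(pd.DataFrame(
        rows, columns=["circuit", "rep", "fold",
                       "train_r2", "test_r2", "train_mse", "test_mse"]))


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------


def _as_task_function(model, task) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model) and not isinstance(model, MultiTaskSGPR):
        return lambda X: np.asarray(model(np.atleast_2d(X)), dtype=float).ravel()
    if isinstance(task, str):
        raise ValueError("task must be a column index for a fitted model")
    return lambda X: model.predict(np.atleast_2d(X))[:, task]


def _shapley_kernel_weight(p: int, size: int) -> float:
    return (p - 1) / (comb(p, size) * size * (p - size))


def kernel_shap(model, background: np.ndarray, explain: np.ndarray,
                n_coalitions: int = 0, task: int = 0,
                seed: int = 0) -> np.ndarray:
    """Kernel-SHAP attributions for each explained sample (one task).

    Missing features are imputed with the background mean; the Shapley-kernel
    weighted least squares is solved with the local-accuracy constraint
    (attributions plus the base value reproduce the prediction).  With
    ``n_coalitions`` large enough to enumerate all 2^p - 2 proper coalitions
    the solution is exact; the default budget is ``2 p + 2048``.
    """
    f = _as_task_function(model, task)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    explain = np.atleast_2d(np.asarray(explain, dtype=float))
    p = explain.shape[1]
    if n_coalitions <= 0:
        n_coalitions = 2 * p + 2048
    if n_coalitions < p + 2:
        raise ValueError(f"n_coalitions must be >= p + 2 = {p + 2}")
    bg_mean = background.mean(axis=0)
    base = float(f(bg_mean[None, :])[0])
    fx = f(explain)

    Z = _coalition_masks(p, n_coalitions, seed)
    weights = np.array([_shapley_kernel_weight(p, int(z.sum())) for z in Z])
    sw = np.sqrt(weights)

    phis = np.empty((explain.shape[0], p))
    for i, x in enumerate(explain):
        pts = np.where(Z.astype(bool), x, bg_mean)
        fz = f(pts)
        y = fz - base - Z[:, -1] * (fx[i] - base)
        M = Z[:, :-1] - Z[:, [-1]]
        sol, *_ = np.linalg.lstsq(M * sw[:, None], y * sw, rcond=None)
        phis[i, :-1] = sol
        phis[i, -1] = fx[i] - base - sol.sum()
    return phis


def _coalition_masks(p: int, budget: int, seed: int) -> np.ndarray:
    n_all = 2 ** p - 2
    if n_all <= budget:
        masks = np.zeros((n_all, p))
        for row, bits in enumerate(itertools.islice(itertools.product((0, 1), repeat=p), 1, 2 ** p - 1)):
            masks[row] = bits
        return masks
    rng = np.random.default_rng(seed)
    sizes = np.arange(1, p)
    size_w = (p - 1) / (sizes * (p - sizes))
    size_w = size_w / size_w.sum()
    masks = np.zeros((budget, p))
    # always include all singleton and all-but-one coalitions
    fixed = []
    for i in range(p):
        m1 = np.zeros(p); m1[i] = 1
        m2 = np.ones(p); m2[i] = 0
        fixed.extend([m1, m2])
    for row, m in enumerate(fixed[:budget]):
        masks[row] = m
    for row in range(len(fixed), budget):
        s = rng.choice(sizes, p=size_w)
        idx = rng.choice(p, size=s, replace=False)
        masks[row, idx] = 1
    return masks


def exact_shap_oracle(model, x: np.ndarray, background: np.ndarray,
                      task: int = 0) -> np.ndarray:
    """Exact Shapley values by enumeration over all 2^p coalitions.

    Background-mean imputation; refuses more than
    ``EXACT_SHAP_MAX_FEATURES`` features.
    """
    f = _as_task_function(model, task)
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    p = x.size
    if p > EXACT_SHAP_MAX_FEATURES:
        raise ValueError(f"exact enumeration limited to {EXACT_SHAP_MAX_FEATURES} features")
    bg_mean = background.mean(axis=0)
    masks = np.array(list(itertools.product((0, 1), repeat=p)), dtype=float)
    pts = np.where(masks.astype(bool), x, bg_mean)
    fvals = f(pts)
    lookup = {tuple(int(b) for b in m): v for m, v in zip(masks, fvals)}
    fact = math.factorial
    phi = np.zeros(p)
    others = list(range(p))
    for i in range(p):
        rest = [j for j in others if j != i]
        for r in range(p):
            for S in itertools.combinations(rest, r):
                w = fact(r) * fact(p - r - 1) / fact(p)
                key = [0] * p
                for j in S:
                    key[j] = 1
                without = lookup[tuple(key)]
                key[i] = 1
                with_i = lookup[tuple(key)]
                phi[i] += w * (with_i - without)
    return phi


# ---------------------------------------------------------------------------
# Relevance ranking
# ---------------------------------------------------------------------------


def relevance_ranking(cv: CVReport, shap_by_task: Mapping[str, np.ndarray],
                      metabolites: list[str],
                      r2_threshold: float = 0.5) -> pd.DataFrame:
    """Rank metabolites per circuit by mean |SHAP|; gate by test R^2.

    ``shap_by_task`` maps circuit name -> (explained samples x metabolites)
    attribution matrix.  A circuit is relevant iff its mean test R^2 exceeds
    ``r2_threshold`` (strictly); only relevant circuits yield annotated
    pairs.  Ties in mean |SHAP| are broken by metabolite id.
    """
    means = cv.circuit_means()["test_r2"]
    rows = []
    for circuit, attr in shap_by_task.items():
        attr = np.atleast_2d(np.asarray(attr, dtype=float))
        if attr.shape[1] != len(metabolites):
            raise ValueError("attribution width must equal metabolite count")
        mean_abs = np.abs(attr).mean(axis=0)
        r2 = float(means.loc[circuit])
        order = sorted(range(len(metabolites)),
                       key=lambda i: (-mean_abs[i], metabolites[i]))
        ranks = {metabolites[i]: r + 1 for r, i in enumerate(order)}
        for i, met in enumerate(metabolites):
            rows.append((met, circuit, float(mean_abs[i]), ranks[met], r2,
                         r2 > r2_threshold))
    return pd.DataFrame(rows, columns=["metabolite", "circuit", "mean_abs_shap",
                                       "rank", "circuit_test_r2", "relevant"])


def annotated_pairs(relevance: pd.DataFrame, top_k: int = 1) -> set[tuple[str, str]]:
    """(metabolite, circuit) pairs from relevant circuits' top-k metabolites."""
    sel = relevance[relevance["relevant"] & (relevance["rank"] <= top_k)]
    return set(zip(sel["metabolite"], sel["circuit"]))
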