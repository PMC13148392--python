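"""Truncation selection and RRBLUP genomic prediction.

RRBLUP fits y = 1*mu + Z u + e with i.i.d. marker effects u ~ N(0, sigma_u^2)
and e ~ N(0, sigma_e^2), Z being the column-mean-centred dosage matrix.  The
variance ratio lambda = sigma_e^2 / sigma_u^2 is estimated by restricted
maximum likelihood using one spectral decomposition of Z Z^T (the efficient
mixed-model trick: for any candidate lambda the REML criterion is then a
cheap function of the eigenvalues and rotated data), and marker effects are
recovered from the mixed-model equations at the optimum.  Training is fully
deterministic given the training set.

`RidgeBLUP` is the estimator class (fit/predict, sklearn-style parameter
handling); `train_rrblup`/`predict_gebv` are the thin functional wrappers the
breeding scheme uses, operating on `TrainingSet`/`GsModel` containers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

from .genome import Population
from .traits import SnpChip

__all__ = [
    "TrainingSet",
    "GsModel",
    "RidgeBLUP",
    "genotype_chip",
    "select_top",
    "train_rrblup",
    "predict_gebv",
    "accuracy",
    "rolling_training_set",
]


def genotype_chip(pop: Population, chip: SnpChip) -> np.ndarray:
    """Dosage matrix (individuals x chip markers) in {0,1,2}."""
    if chip.n_markers == 0:
        raise ValueError("chip has no markers")
    return pop.dosages(chip.marker_idx)


def select_top(values: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n largest values; ties broken by lowest index."""
    values = np.asarray(values, dtype=np.float64)
    if n > values.size:
        raise ValueError("cannot select more individuals than available")
    order = np.argsort(-values, kind="stable")
    return order[:n]


@dataclass
class TrainingSet:
    """Phenotype/genotype records for RRBLUP training."""

    dosages: np.ndarray  # (n, m)
    phenos: np.ndarray  # (n,)
    generations: np.ndarray  # (n,) generation label per record

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.phenos = np.asarray(self.phenos, dtype=np.float64)
        self.generations = np.asarray(self.generations, dtype=object)
        n = self.dosages.shape[0]
        if self.phenos.shape[0] != n or self.generations.shape[0] != n:
            raise ValueError("row counts of dosages/phenos/generations disagree")
        if not np.all(np.isfinite(self.phenos)):
            raise ValueError("phenotypes contain missing values")

    @property
    def n(self) -> int:
        return int(self.dosages.shape[0])


def rolling_training_set(history, window: int = 3) -> TrainingSet:
    """Merge the most recent ``window`` generations, oldest first.

    ``history`` is a sequence of (generation_label, dosages, phenotypes)
    triples in chronological order; phenotypes are pooled raw (no per-
    generation standardisation).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    recent = list(history)[-window:]
    if not recent:
        raise ValueError("history is empty")
    dosages = np.concatenate([np.asarray(d) for _, d, _ in recent], axis=0)
    phenos = np.concatenate([np.asarray(p, dtype=np.float64) for _, _, p in recent])
    gens = np.concatenate(
        [np.full(np.asarray(d).shape[0], g, dtype=object) for g, d, _ in recent]
    )
    return TrainingSet(dosages, phenos, gens)


@dataclass
class GsModel:
    """A trained RRBLUP model: intercept, marker effects, training metadata."""

    intercept: float
    marker_effects: np.ndarray  # (m,) float64
    col_means: np.ndarray  # (m,) float64 training-set centring means
    lambda_: float
    sigma_u2: float
    sigma_e2: float
    training_generations: tuple = ()
    map_factor_at_training: float = 1.0

    def __post_init__(self):
        self.marker_effects = np.asarray(self.marker_effects, dtype=np.float64)
        self.col_means = np.asarray(self.col_means, dtype=np.float64)
        if self.marker_effects.shape != self.col_means.shape:
            raise ValueError("effects and centring means must align")
        if not self.lambda_ >= 0:
            raise ValueError("lambda must be >= 0")


class RidgeBLUP:
    """Ridge-regression BLUP of marker effects with REML shrinkage.

    Parameters
    ----------
    shrinkage : "reml" or a float
        "reml" estimates lambda = sigma_e^2/sigma_u^2 by restricted maximum
        likelihood; a finite float fixes lambda; ``numpy.inf`` gives the
        infinite-shrinkage limit (zero effects, intercept = mean response).
    compute_dtype : numpy dtype
        Precision for the O(n^2 m) covariance build and eigendecomposition.

    Fitted attributes (trailing underscore): ``intercept_``, ``coef_``,
    ``col_means_``, ``lambda_``, ``sigma_u2_``, ``sigma_e2_``, ``n_train_``,
    ``converged_``.
    """

    _LOG10_GRID = np.linspace(-8.0, 8.0, 33)
    _PARAM_NAMES = ("shrinkage", "compute_dtype", "reml_subsample")

    def __init__(self, shrinkage="reml", compute_dtype=np.float32, reml_subsample=1500):
        self.shrinkage = shrinkage
        self.compute_dtype = compute_dtype
        # above this training size, lambda is REML-estimated on an evenly
        # spaced row subsample (the full system is still solved exactly at
        # that lambda); None disables subsampling
        self.reml_subsample = reml_subsample

    # -- sklearn-style parameter plumbing ---------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._PARAM_NAMES}

    def set_params(self, **params) -> "RidgeBLUP":
        for k, v in params.items():
            if k not in self._PARAM_NAMES:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------------
    def fit(self, X, y) -> "RidgeBLUP":
        X = np.asarray(X)
        y = np.asarray(y, dtype=np.float64)
        n, m = X.shape
        if n < 2:
            raise ValueError("need at least 2 training records")
        if m < 1:
            raise ValueError("need at least 1 marker")
        if y.shape[0] != n:
            raise ValueError("X and y disagree on n")
        self.col_means_ = X.mean(axis=0, dtype=np.float64)
        self.n_train_ = n
        self.converged_ = True

        if np.ptp(y) == 0.0:
            # degenerate response: zero effects, intercept at the common value
            self.intercept_ = float(y[0])
            self.coef_ = np.zeros(m)
            self.lambda_ = np.inf
            self.sigma_u2_ = 0.0
            self.sigma_e2_ = 0.0
            return self
        if isinstance(self.shrinkage, (int, float)) and np.isinf(self.shrinkage):
            self.intercept_ = float(y.mean())
            self.coef_ = np.zeros(m)
            self.lambda_ = np.inf
            self.sigma_u2_ = 0.0
            self.sigma_e2_ = float(y.var(ddof=1))
            return self

        Z = X.astype(self.compute_dtype)
        Z -= self.col_means_.astype(self.compute_dtype)

        K = None
        if self.shrinkage == "reml":
            sub = self.reml_subsample
            if sub is not None and n > sub:
                idx = np.unique(np.linspace(0, n - 1, sub).astype(np.int64))
                delta = self._reml_delta(Z[idx], y[idx])
            else:
                K = self._gram(Z)
                delta = self._reml_delta(Z, y, K=K)
        else:
            delta = float(self.shrinkage)
            if delta < 0:
                raise ValueError("fixed shrinkage must be >= 0")
        mu, coef, sigma_u2 = self._solve_at_delta(Z, y, delta, K=K)

        self.coef_ = coef
        self.intercept_ = float(mu)
        self.lambda_ = float(delta)
        self.sigma_u2_ = float(sigma_u2)
        self.sigma_e2_ = self.lambda_ * self.sigma_u2_ if np.isfinite(delta) else 0.0
        return self

    @staticmethod
    def _gram(Z: np.ndarray) -> np.ndarray:
        """Z Z^T via a rank-k update (half the flops of a full GEMM)."""
        if Z.dtype == np.float32:
            from scipy.linalg.blas import ssyrk

            return ssyrk(1.0, np.asfortranarray(Z.T), trans=1, lower=1)
        return Z @ Z.T

    def _reml_delta(self, Z: np.ndarray, y: np.ndarray, K: np.ndarray | None = None) -> float:
        """Restricted-maximum-likelihood lambda via one eigendecomposition."""
        n = Z.shape[0]
        if K is None:
            K = self._gram(Z)
        w, U = scipy.linalg.eigh(K, driver="evd", lower=True)
        w = np.maximum(w.astype(np.float64), 0.0)
        a = (U.T @ y.astype(U.dtype)).astype(np.float64)
        b = (U.T @ np.ones(n, dtype=U.dtype)).astype(np.float64)
        scale = max(w.mean(), 1e-12)

        def neg2_reml(log10_delta: float) -> float:
            delta = 10.0**log10_delta * scale
            v = w + delta
            sb = np.sum(b * b / v)
            sab = np.sum(a * b / v)
            mu = sab / sb
            q = np.sum(a * a / v) - 2.0 * mu * sab + mu * mu * sb
            q = max(q, 1e-300)
            return (n - 1) * np.log(q / (n - 1)) + np.sum(np.log(v)) + np.log(sb)

        crit = np.array([neg2_reml(t) for t in self._LOG10_GRID])
        if not np.all(np.isfinite(crit)):
            warnings.warn(
                "REML criterion not finite; falling back to plug-in lambda = m",
                RuntimeWarning,
            )
            self.converged_ = False
            return float(Z.shape[1])
        i = int(np.argmin(crit))
        lo = self._LOG10_GRID[max(i - 1, 0)]
        hi = self._LOG10_GRID[min(i + 1, len(self._LOG10_GRID) - 1)]
        res = minimize_scalar(
            neg2_reml, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
        )
        if res.success:
            return 10.0 ** float(res.x) * scale
        self.converged_ = False
        return 10.0 ** float(self._LOG10_GRID[i]) * scale

    def _solve_at_delta(self, Z: np.ndarray, y: np.ndarray, delta: float, K=None):
        """GLS intercept and marker effects from the mixed-model equations.

        Solves (Z Z^T + delta I) alpha = y - mu with the intercept profiled
        out, then u = Z^T alpha.
        """
        n = Z.shape[0]
        V = self._gram(Z) if K is None else K.copy()
        # jitter floor keeps the float32 Cholesky positive definite when the
        # REML optimum sits at the zero-shrinkage boundary (noiseless data)
        dmin = 100.0 * float(np.finfo(V.dtype).eps) * max(float(np.trace(V)), 1e-30)
        V[np.diag_indices(n)] += max(delta, dmin)
        c, low = scipy.linalg.cho_factor(V, lower=True, overwrite_a=True)
        ones = np.ones(n, dtype=V.dtype)
        x1 = scipy.linalg.cho_solve((c, low), ones)
        xy = scipy.linalg.cho_solve((c, low), y.astype(V.dtype))
        mu = float(ones @ xy) / float(ones @ x1)
        alpha = (xy - mu * x1).astype(np.float64)
        coef = (alpha.astype(Z.dtype) @ Z).astype(np.float64)
        sigma_u2 = float((y - mu) @ alpha) / (n - 1)
        return mu, coef, max(sigma_u2, 0.0)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X)
        return self.intercept_ + (X.astype(np.float64) - self.col_means_) @ self.coef_

    def to_model(self, training_generations=(), map_factor_at_training=1.0) -> GsModel:
        return GsModel(
            intercept=self.intercept_,
            marker_effects=self.coef_,
            col_means=self.col_means_,
            lambda_=self.lambda_,
            sigma_u2=self.sigma_u2_,
            sigma_e2=self.sigma_e2_,
            training_generations=tuple(training_generations),
            map_factor_at_training=float(map_factor_at_training),
        )


def train_rrblup(
    ts: TrainingSet,
    shrinkage="reml",
    map_factor_at_training: float = 1.0,
) -> GsModel:
    """Fit RRBLUP on a training set; deterministic given the data."""
    est = RidgeBLUP(shrinkage=shrinkage).fit(ts.dosages, ts.phenos)
    gens = tuple(dict.fromkeys(ts.generations))  # unique labels, order kept
    return est.to_model(gens, map_factor_at_training)


def predict_gebv(model: GsModel, dosages: np.ndarray) -> np.ndarray:
    """Genomic estimated breeding values for a dosage matrix."""
    X = np.asarray(dosages, dtype=np.float64)
    return model.intercept + (X - model.col_means) @ model.marker_effects


def accuracy(gebv: np.ndarray, true_values: np.ndarray) -> float:
    """Pearson correlation of GEBV with true genetic values (NaN if constant)."""
    gebv = np.asarray(gebv, dtype=np.float64)
    true_values = np.asarray(true_values, dtype=np.float64)
    if gebv.std() == 0.0 or true_values.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(gebv, true_values)[0, 1])
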