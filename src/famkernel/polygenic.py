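"""Null polygenic mixed model y = X a + u + e with cov(u) = sigma2_g R.

The variance structure V = sigma2_g R + sigma2_e I is profiled over the
heritability ratio h2 = sigma2_g / (sigma2_g + sigma2_e) after a one-time
rotation by the eigenvectors of R, so each (RE)ML evaluation is O(N C^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .data_io import SampleFrame
from .kinship import RelationshipMatrix, condition_psd

logger = logging.getLogger(__name__)

_H2_MAX = 1.0 - 1e-8  # keep V invertible when R is rank deficient
_BOUNDARY_TOL = 1e-4


@dataclass
class TransformedTrait:
    """A phenotype presentation for downstream kernel testing.

    ``transform`` is one of {"original", "env_residual", "grammar_plus",
    "grammar_gamma"}; ``fit`` is the PolygenicModel the vector came from and
    supplies the variance scale sigma2 used by the kernel test.
    """

    values: np.ndarray
    transform: str
    fit: "PolygenicModel"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("transformed trait contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


class PolygenicModel(BaseEstimator):
    """REML/ML fit of the polygenic null model for one quantitative trait.

    Parameters
    ----------
    method : {"reml", "ml"}
        Restricted (default) or full maximum likelihood.
    grid_points : int
        Size of the coarse h2 grid scanned before Brent refinement; guards
        against local optima of the profile likelihood.
    xtol : float
        Absolute tolerance of the h2 optimizer.

    Attributes (after ``fit``)
    --------------------------
    alpha_ : fixed-effect estimates (GLS at the optimum)
    sigma2_g_, sigma2_e_, sigma2_, h2_ : variance components
    loglik_ : profile (restricted) log-likelihood at the optimum
    boundary_ : True when h2 is estimated at 0 or 1
    eigvals_, eigvecs_ : cached eigendecomposition of the conditioned R
    """

    def __init__(self, method: str = "reml", grid_points: int = 33,
                 xtol: float = 1e-6):
        self.method = method
        self.grid_points = grid_points
        self.xtol = xtol

    # -- likelihood machinery ------------------------------------------------

    def _profile(self, h2: float):
        """GLS estimates and profiled variance at a fixed h2 (rotated space)."""
        d = h2 * self.eigvals_ + (1.0 - h2)
        w = 1.0 / d
        Xw = self._xrot * w[:, None]
        xtx = self._xrot.T @ Xw
        xty = Xw.T @ self._yrot
        alpha = np.linalg.solve(xtx, xty)
        r = self._yrot - self._xrot @ alpha
        rss = float(r @ (w * r))
        n, c = self._xrot.shape
        dof = n - c if self.method == "reml" else n
        s2 = rss / dof
        return d, alpha, r, s2, xtx

    def _negloglik(self, h2: float) -> float:
        d, _, _, s2, xtx = self._profile(h2)
        n, c = self._xrot.shape
        if not np.isfinite(s2) or s2 <= 0:
            raise FloatingPointError("non-finite profile likelihood")
        ll = -0.5 * (np.log(d).sum() + (n - c if self.method == "reml" else n)
                     * (np.log(s2) + 1.0))
        if self.method == "reml":
            sign, logdet = np.linalg.slogdet(xtx)
            ll -= 0.5 * logdet
        return -ll

    # -- sklearn-style API ---------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            relationship: RelationshipMatrix | np.ndarray = None):
        """Fit the model; X is the N x C fixed-effect design (with intercept)."""
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        n, c = X.shape
        if relationship is None:
            raise ValueError("a relationship matrix is required")
        if isinstance(relationship, np.ndarray):
            relationship = RelationshipMatrix(
                relationship, np.arange(n).astype(str), source="file")
        if n <= c + 2:
            raise ValueError(f"need N > C + 2 (N = {n}, C = {c})")
        relationship = condition_psd(relationship)
        self.relationship_ = relationship
        w, U = np.linalg.eigh(relationship.values)
        self.eigvals_ = np.clip(w, 0.0, None)
        self.eigvecs_ = U
        self._xrot = U.T @ X
        self._yrot = U.T @ y
        self.X_ = X
        self.y_ = y

        grid = np.linspace(0.0, _H2_MAX, self.grid_points)
        vals = [self._negloglik(h) for h in grid]
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if lo < hi:
            res = minimize_scalar(self._negloglik, bounds=(lo, hi),
                                  method="bounded",
                                  options={"xatol": self.xtol})
            h2, nll = float(res.x), float(res.fun)
            if vals[k] < nll:  # grid point beat the refinement (flat edge)
                h2, nll = float(grid[k]), float(vals[k])
        else:
            h2, nll = float(grid[k]), float(vals[k])

        _, alpha, r, s2, _ = self._profile(h2)
        self.h2_ = h2
        self.sigma2_ = float(s2)
        self.sigma2_g_ = h2 * self.sigma2_
        self.sigma2_e_ = (1.0 - h2) * self.sigma2_
        self.alpha_ = alpha
        self.loglik_ = -nll
        self.boundary_ = h2 <= _BOUNDARY_TOL or h2 >= 1.0 - _BOUNDARY_TOL
        if self.boundary_:
            logger.info("heritability estimated at the boundary (h2 = %.4g)", h2)
        self._rrot = r  # rotated centered trait U^T (y - X alpha)
        self.n_ = n
        return self

    @classmethod
    def from_components(cls, relationship: RelationshipMatrix | np.ndarray,
                        h2: float, sigma2: float,
                        X: np.ndarray | None = None,
                        y: np.ndarray | None = None) -> "PolygenicModel":
        """Build a 'fitted' model with known variance components.

        Used for oracles and for transforming a trait under externally
        supplied (e.g. true simulation) parameters. When ``y`` is given the
        fixed effects are estimated by GLS at the supplied h2.
        """
        self = cls()
        if isinstance(relationship, np.ndarray):
            relationship = RelationshipMatrix(
                relationship, np.arange(relationship.shape[0]).astype(str),
                source="file")
        relationship = condition_psd(relationship)
        self.relationship_ = relationship
        w, U = np.linalg.eigh(relationship.values)
        self.eigvals_ = np.clip(w, 0.0, None)
        self.eigvecs_ = U
        n = relationship.n
        if X is None:
            X = np.ones((n, 1))
        X = np.atleast_2d(np.asarray(X, float))
        self.X_ = X
        self._xrot = U.T @ X
        self.h2_ = float(h2)
        self.sigma2_ = float(sigma2)
        self.sigma2_g_ = self.h2_ * self.sigma2_
        self.sigma2_e_ = (1.0 - self.h2_) * self.sigma2_
        self.boundary_ = h2 in (0.0, 1.0)
        self.loglik_ = np.nan
        self.n_ = n
        if y is not None:
            self.y_ = np.asarray(y, float)
            self._yrot = U.T @ self.y_
            _, alpha, r, _, _ = self._profile(min(self.h2_, _H2_MAX))
            self.alpha_ = alpha
            self._rrot = r
        return self

    # -- linear algebra helpers (eigen-cache) ---------------------------------

    @property
    def v_eigvals_(self) -> np.ndarray:
        """Eigenvalues of V-hat = sigma2_g R + sigma2_e I."""
        return self.sigma2_g_ * self.eigvals_ + self.sigma2_e_

    def v_matrix(self) -> np.ndarray:
        """Dense V-hat (for oracles; O(N^2) memory)."""
        return (self.sigma2_g_ * self.relationship_.values
                + self.sigma2_e_ * np.eye(self.n_))

    def v_inv_dot(self, vec: np.ndarray) -> np.ndarray:
        """V-hat^{-1} @ vec through the eigen-cache."""
        return self.eigvecs_ @ ((self.eigvecs_.T @ vec) / self.v_eigvals_)

    def centered_trait(self) -> np.ndarray:
        """y - X alpha-hat in the original (unrotated) basis."""
        return self.eigvecs_ @ self._rrot

    # -- trait presentations ---------------------------------------------------

    def center_phenotype(self) -> TransformedTrait:
        """Covariate-centered trait y - X alpha-hat (presentation 'original')."""
        return TransformedTrait(self.centered_trait(), "original", self)

    def environmental_residuals(self) -> TransformedTrait:
        """Centered trait minus the BLUP of the polygenic component.

        e-hat = y~ - sigma2_g R V^{-1} y~, computed through the eigen-cache.
        """
        scaled = (self.sigma2_g_ * self.eigvals_ / self.v_eigvals_) * self._rrot
        resid = self.eigvecs_ @ (self._rrot - scaled)
        return TransformedTrait(resid, "env_residual", self)


def reml_fit(frame: SampleFrame, R: RelationshipMatrix,
             method: str = "reml") -> PolygenicModel:
    """Fit the polygenic null model for a SampleFrame (ids aligned to R)."""
    R = R.reorder(frame.ids) if not np.array_equal(R.ids, frame.ids) else R
    return PolygenicModel(method=method).fit(frame.covariates, frame.phenotype,
                                             relationship=R)


def environmental_residuals(fit: PolygenicModel,
                            frame: SampleFrame | None = None) -> TransformedTrait:
    return fit.environmental_residuals()


def center_phenotype(fit: PolygenicModel,
                     frame: SampleFrame | None = None) -> TransformedTrait:
    return fit.center_phenotype()
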