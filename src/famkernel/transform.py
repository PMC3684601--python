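"""GRAMMAR+ phenotype transformation and per-marker gamma factors.

Premultiplying the covariate-centered trait by V^{-1} (the inverse of the
fitted polygenic covariance) removes the family correlation that breaks
unrelated-sample score tests; the scalar prefactor sigma2 / sqrt(gamma_bar)
restores the scale so that simple-regression score statistics on the
transformed trait approximate the exact mixed-model statistics. The
marker-specific shrinkage factor

    gamma_m = sigma2 (g~' V^{-1} g~) / (g~' g~)

is approximately constant across markers under a polygenic architecture;
its analytic average gamma_bar = sigma2 tr(V^{-1} R) / N is what the
transformation divides out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeRegion, SampleFrame
from .polygenic import PolygenicModel, TransformedTrait

__all__ = [
    "GammaFactors", "TransformedTrait", "TraitTransformer",
    "gamma_per_marker", "gamma_bar", "grammar_plus", "grammar_gamma",
    "simple_score",
]


@dataclass
class GammaFactors:
    """Per-marker gamma factors with their analytic average.

    ``used`` flags the polymorphic markers gamma is defined for;
    monomorphic markers are excluded (gamma undefined when g~'g~ = 0).
    """

    gamma: np.ndarray
    used: np.ndarray
    gamma_bar: float

    @property
    def mean(self) -> float:
        return float(self.gamma.mean())

    @property
    def var(self) -> float:
        return float(self.gamma.var())


def _centered_polymorphic(region: GenotypeRegion):
    g = region.impute_missing().genotypes
    gc = g - g.mean(axis=0)
    ss = (gc ** 2).sum(axis=0)
    return gc, ss, ss > 0


def gamma_per_marker(fit: PolygenicModel, region: GenotypeRegion) -> GammaFactors:
    """gamma_m = sigma2 (g~' V^{-1} g~) / (g~' g~) for each polymorphic marker."""
    gc, ss, used = _centered_polymorphic(region)
    gcu = gc[:, used]
    rot = fit.eigvecs_.T @ gcu
    num = ((rot ** 2) / fit.v_eigvals_[:, None]).sum(axis=0)
    gamma = fit.sigma2_ * num / ss[used]
    return GammaFactors(gamma=gamma, used=used, gamma_bar=gamma_bar(fit))


def gamma_bar(fit: PolygenicModel) -> float:
    """Analytic average gamma factor, sigma2 * tr(V^{-1} R) / N.

    From the eigen-cache this is (1/N) sum_i sigma2 lambda_i /
    (sigma2_g lambda_i + sigma2_e). Equals 1 when R = I or h2 = 0, and lies
    in (0, 1] for any PSD R with unit mean diagonal.
    """
    return float(np.mean(fit.sigma2_ * fit.eigvals_ / fit.v_eigvals_))


def grammar_plus(fit: PolygenicModel,
                 frame: SampleFrame | None = None) -> TransformedTrait:
    """GRAMMAR+ transformed trait y+ = (sigma2 / sqrt(gamma_bar)) V^{-1} y~."""
    gb = gamma_bar(fit)
    if gb <= 0:
        raise ValueError("gamma_bar must be positive (degenerate R)")
    scaled = fit._rrot / fit.v_eigvals_
    y_plus = (fit.sigma2_ / np.sqrt(gb)) * (fit.eigvecs_ @ scaled)
    return TransformedTrait(y_plus, "grammar_plus", fit)


def grammar_gamma(fit: PolygenicModel,
                  frame: SampleFrame | None = None) -> TransformedTrait:
    """GRAMMAR-Gamma variant: y = (sigma2 / gamma_bar) V^{-1} y~.

    Divides by gamma_bar rather than its square root; appropriate for
    single-marker effect estimation rather than kernel testing.
    """
    gb = gamma_bar(fit)
    scaled = fit._rrot / fit.v_eigvals_
    return TransformedTrait((fit.sigma2_ / gb) * (fit.eigvecs_ @ scaled),
                            "grammar_gamma", fit)


@dataclass
class MarkerScores:
    """Per-marker simple-regression scores on a transformed trait."""

    beta: np.ndarray  # effect estimates for the used markers
    t_stat: np.ndarray  # score statistics T+_m
    used: np.ndarray  # polymorphic-marker mask over the region


def simple_score(y_t: TransformedTrait, region: GenotypeRegion,
                 sigma2: float | None = None) -> MarkerScores:
    """Simple-regression scores of each polymorphic marker against y_t.

    beta+_m = (g~' y) / (g~' g~);  T+_m = (g~' y)^2 / (sigma2 g~' g~),
    with sigma2 the total variance of the polygenic fit carried by y_t.
    """
    if y_t.n != region.n_samples:
        raise ValueError("trait and genotype region are not sample-aligned")
    if sigma2 is None:
        sigma2 = y_t.fit.sigma2_
    gc, ss, used = _centered_polymorphic(region)
    gty = gc[:, used].T @ y_t.values
    beta = gty / ss[used]
    t_stat = gty ** 2 / (sigma2 * ss[used])
    return MarkerScores(beta=beta, t_stat=t_stat, used=used)


class TraitTransformer(PolygenicModel):
    """Fit-and-transform estimator producing one phenotype presentation.

    A thin sklearn-style wrapper over :class:`PolygenicModel`: ``fit(X, y,
    relationship=R)`` fits the polygenic null model, ``transform()`` returns
    the requested presentation of the fitted trait as a plain vector.

    Parameters
    ----------
    mode : {"grammar_plus", "original", "env_residual", "grammar_gamma"}
    method, grid_points, xtol : passed through to PolygenicModel.
    """

    _MODES = ("grammar_plus", "original", "env_residual", "grammar_gamma")

    def __init__(self, mode: str = "grammar_plus", method: str = "reml",
                 grid_points: int = 33, xtol: float = 1e-6):
        super().__init__(method=method, grid_points=grid_points, xtol=xtol)
        self.mode = mode

    def transform(self, y: np.ndarray | None = None) -> np.ndarray:
        """Transformed values of the fitted trait.

        ``y`` may re-supply the fitted trait (checked for equality); the
        transformation is defined by the fitted covariance, not per-sample,
        so transforming unseen phenotype vectors is deliberately refused.
        """
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if y is not None and not np.allclose(y, self.y_):
            raise ValueError("transform is defined for the fitted trait only")
        return self.transformed_trait().values

    def transformed_trait(self) -> TransformedTrait:
        if self.mode == "original":
            return self.center_phenotype()
        if self.mode == "env_residual":
            return self.environmental_residuals()
        if self.mode == "grammar_gamma":
            return grammar_gamma(self)
        return grammar_plus(self)

    def fit_transform(self, X, y, relationship=None) -> np.ndarray:
        return self.fit(X, y, relationship=relationship).transform()
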