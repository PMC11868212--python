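"""Stationary latent Gaussian fields via random Fourier features.

Each field is a *deterministic function of location* once its spectral
sample is drawn, so sites and prediction-grid cells evaluated at the same
coordinates receive identical values — the property the shared-field
construction of the synthetic study relies on.

A field with ``n_features`` cosine features approximates a zero-mean,
unit-variance Gaussian process with squared-exponential covariance
``exp(-d^2 / (2 l^2))`` where ``l`` is the correlation length.
"""
from __future__ import annotations

import numpy as np


class LatentField:
    """One realisation of an approximately standard-normal random field."""

    def __init__(self, rng: np.random.Generator, corr_length_m: float,
                 n_features: int = 96):
        if corr_length_m <= 0:
            raise ValueError("correlation length must be positive")
        self._w = rng.normal(0.0, 1.0 / corr_length_m, size=(n_features, 2))
        self._b = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
        self._scale = np.sqrt(2.0 / n_features)

    def __call__(self, x, y):
        pts = np.column_stack([np.asarray(x, float).ravel(),
                               np.asarray(y, float).ravel()])
        z = self._scale * np.cos(pts @ self._w.T + self._b).sum(axis=1)
        return z


class CorrelatedFamily:
    """A family of latent fields sharing a common component.

    Member ``k`` is ``sqrt(rho) * base + sqrt(1 - rho) * jitter_k`` with
    independent jitters, giving pairwise latent (Pearson) correlation
    ``rho``.  For bivariate Gaussians Spearman's rho_S relates to the
    Pearson correlation by ``rho_S = (6/pi) * asin(rho/2)``; the mixing
    weight is chosen from the configured rank-correlation target plus a
    safety margin, so monotone transforms of the members keep their rank
    correlation above the target.
    """

    MARGIN = 0.07

    def __init__(self, rng: np.random.Generator, n_members: int,
                 corr_length_m: float, rank_corr_target: float,
                 n_features: int = 96):
        target = min(0.99, rank_corr_target + self.MARGIN)
        rho = 2.0 * np.sin(np.pi * target / 6.0)  # latent Pearson correlation
        self._a = np.sqrt(rho)
        self._b = np.sqrt(1.0 - rho)
        self.base = LatentField(rng, corr_length_m, n_features)
        self.jitters = [LatentField(rng, corr_length_m, n_features)
                        for _ in range(n_members)]

    def member(self, k: int, x, y):
        return self._a * self.base(x, y) + self._b * self.jitters[k](x, y)
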