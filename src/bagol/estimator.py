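"""scikit-learn style estimator facade over the grouping pipeline.

`BayesianGrouper` is a clusterer with a variable, inferred number of
components: fit() runs the reversible-jump sampler over a localization
table and exposes the MAPN emitters as fitted attributes; labels are the
allocation of each localization to its nearest inferred emitter.  It
follows the scikit-learn estimator contract (get_params/set_params,
trailing-underscore fitted attributes) and therefore composes with
sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .data import LocalizationSet
from .model import SamplerConfig
from .pipeline import analyze


def _as_localizations(X):
    if isinstance(X, LocalizationSet):
        return X
    try:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return LocalizationSet(
                X["x"].to_numpy(), X["y"].to_numpy(),
                X["sigma_x"].to_numpy(), X["sigma_y"].to_numpy(),
                X["frame"].to_numpy() if "frame" in X else None,
                X["photons"].to_numpy() if "photons" in X else None)
    except ImportError:  # pragma: no cover
        pass
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 4:
        raise ValueError(
            "X must be a LocalizationSet, a DataFrame with columns "
            "x,y,sigma_x,sigma_y[,frame,photons], or an array with at least "
            "4 columns (x, y, sigma_x, sigma_y)")
    frame = X[:, 4] if X.shape[1] > 4 else None
    photons = X[:, 5] if X.shape[1] > 5 else None
    return LocalizationSet(X[:, 0], X[:, 1], X[:, 2], X[:, 3], frame, photons)


class BayesianGrouper(ClusterMixin, BaseEstimator):
    """Group localizations into emitters by reversible-jump MCMC.

    Parameters
    ----------
    xi : float
        Mean localizations per emitter (fixed value, or the initial value
        when ``xi_mode='hierarchical'``).
    xi_mode : {'hierarchical', 'fixed'}
        Learn the mean blinking rate from the data or hold it fixed.
    xi_prior_eta, xi_prior_gamma : float
        Shape and mean of the gamma (hyper)prior on the blinking rate.
    count_model : {'poisson', 'gamma_poisson'}
        Localizations-per-emitter law; 'gamma_poisson' (negative binomial)
        suits dSTORM blinking.
    drift : bool
        Estimate per-emitter linear drift over the acquisition.
    n_samples, n_burnin : int
        Post-burn-in and burn-in chain lengths (burn-in defaults to
        ``n_samples``).
    subregion_size, overlap : float or None, nm
        Field tiling; None analyzes the data as a single region.
    random_state : int
        Seed for the sampler (and derived per-subregion seeds).

    Attributes
    ----------
    n_emitters_ : int
        MAPN emitter count.
    emitter_positions_ : (n_emitters_, 2) ndarray, nm
    emitter_precisions_ : (n_emitters_, 2) ndarray, nm
    emitter_drifts_ : (n_emitters_, 2) ndarray
    labels_ : (n_samples,) ndarray
        Nearest inferred emitter for each input localization (-1 if none).
    result_ : AnalysisResult
        Full pipeline output (chains, tiling plan, report).

    Examples
    --------
    >>> from bagol.simulate import sim_dimer, blinks_from_emitters
    >>> locs, _ = blinks_from_emitters(sim_dimer(10.0, lam=50), rng=1)
    >>> BayesianGrouper(xi=50, xi_mode="fixed", n_samples=500,
    ...                 random_state=1).fit(locs).n_emitters_
    2
    """

    def __init__(self, xi=50.0, xi_mode="hierarchical", xi_prior_eta=1.0,
                 xi_prior_gamma=5.0, count_model="poisson", drift=False,
                 n_samples=1000, n_burnin=None, subregion_size=None,
                 overlap=None, random_state=0):
        self.xi = xi
        self.xi_mode = xi_mode
        self.xi_prior_eta = xi_prior_eta
        self.xi_prior_gamma = xi_prior_gamma
        self.count_model = count_model
        self.drift = drift
        self.n_samples = n_samples
        self.n_burnin = n_burnin
        self.subregion_size = subregion_size
        self.overlap = overlap
        self.random_state = random_state

    def _config(self):
        return SamplerConfig(
            xi=self.xi, xi_mode=self.xi_mode,
            xi_prior_eta=self.xi_prior_eta,
            xi_prior_gamma=self.xi_prior_gamma,
            count_model=self.count_model, drift_enabled=self.drift,
            n_samples=self.n_samples, n_burnin=self.n_burnin,
            rng_seed=int(self.random_state))

    def fit(self, X, y=None):
        """Run the sampler on a localization table.

        X may be a LocalizationSet, a DataFrame with columns
        ``x, y, sigma_x, sigma_y[, frame, photons]``, or a plain array with
        those columns in order.
        """
        locs = _as_localizations(X)
        self.result_ = analyze(locs, self._config(),
                               subregion_size=self.subregion_size,
                               overlap=self.overlap)
        mapn = self.result_.mapn
        self.n_emitters_ = mapn.K_map
        self.emitter_positions_ = mapn.positions
        self.emitter_precisions_ = mapn.precisions
        self.emitter_drifts_ = mapn.drifts
        self.n_loc_ = mapn.n_loc
        self.labels_ = self._nearest(locs.positions)
        return self

    def _nearest(self, points):
        if self.n_emitters_ == 0 or points.shape[0] == 0:
            return np.full(points.shape[0], -1, dtype=int)
        from scipy.spatial import cKDTree

        tree = cKDTree(self.emitter_positions_)
        _, idx = tree.query(points, k=1)
        return idx.astype(int)

    def predict(self, X):
        """Nearest inferred emitter index for new localizations."""
        check_is_fitted(self, "n_emitters_")
        locs = _as_localizations(X)
        return self._nearest(locs.positions)

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_
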