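"""Scikit-learn style estimator for co-occurrence network inference.

:class:`CooccurrenceNetwork` wraps the full class-1 inference — tie-break
noise Monte Carlo, permutation-null threshold selection, per-replicate
thresholding and the consensus network — behind a ``fit`` interface, in the
spirit of structure estimators like ``sklearn.covariance.GraphicalLasso``:
``X`` has locations (samples) in rows and OTUs (features) in columns, and
the fitted object exposes the inferred graphs as trailing-underscore
attributes.
"""

from __future__ import annotations

from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._rng import child_seed, normalize_seed
from .abundance import AbundanceMatrix, filter_min_total
from .netstats import summarize_ensemble
from .networks import (
    component_sweep,
    consensus_network,
    default_grid,
    monte_carlo_ensemble,
    noise_transition_threshold,
)

__all__ = ["CooccurrenceNetwork"]


class CooccurrenceNetwork(BaseEstimator):
    """Infer a microbial co-occurrence network from an abundance matrix.

    Parameters
    ----------
    threshold : "auto" or float in [0, 1], default="auto"
        Correlation threshold τ. ``"auto"`` locates the permutation-null
        noise transition (largest component of the permuted treatment below
        ``cutoff`` of OTUs) and adds ``margin``.
    margin : float, default=0.05
        Safety margin above the noise transition in auto mode.
    cutoff : float, default=0.01
        Largest-component fraction defining the noise transition.
    grid_step : float, default=0.01
        Threshold grid resolution for the sweep in auto mode.
    n_replicates : int, default=2000
        Tie-break Monte-Carlo draws (the published protocol uses 2000).
    support : float, default=0.9
        Consensus support fraction: an edge is kept when present in at
        least this fraction of replicates.
    min_total : float, default=0
        Drop OTUs with fewer total sequences than this before inference
        (0 = keep all; the soil-survey protocol used 5).
    random_state : int or None
        Master seed for every stochastic step.

    Attributes
    ----------
    otu_ids_ : list of str
        Feature (OTU) identifiers retained after filtering.
    threshold_ : float
        The threshold actually applied.
    transition_ : float or None
        The noise transition located in auto mode.
    sweep_ : ThresholdSweep or None
        Largest-component curves (auto mode only).
    networks_ : list of networkx.Graph
        One thresholded network per tie-break replicate.
    consensus_ : networkx.Graph
        Edges present in at least ``support`` of the replicates.
    """

    def __init__(
        self,
        threshold: Union[str, float] = "auto",
        margin: float = 0.05,
        cutoff: float = 0.01,
        grid_step: float = 0.01,
        n_replicates: int = 2000,
        support: float = 0.9,
        min_total: float = 0,
        random_state: Optional[int] = None,
    ):
        self.threshold = threshold
        self.margin = margin
        self.cutoff = cutoff
        self.grid_step = grid_step
        self.n_replicates = n_replicates
        self.support = support
        self.min_total = min_total
        self.random_state = random_state

    def _as_abundance(self, X) -> AbundanceMatrix:
        if isinstance(X, AbundanceMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            loc = [str(i) for i in X.index]
            counts = X.to_numpy(dtype=float).T
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-D (locations × OTUs)")
            counts = X.T
            names = [f"OTU_{i:04d}" for i in range(counts.shape[0])]
            loc = [f"L{j:03d}" for j in range(counts.shape[1])]
        if (counts < 0).any():
            raise ValueError("abundances must be non-negative")
        return AbundanceMatrix(counts=counts, otu_ids=names, location_ids=loc)

    def fit(self, X, y=None) -> "CooccurrenceNetwork":
        """Infer the network ensemble and consensus from ``X``.

        ``X`` is (n_locations, n_otus): samples in rows, taxa in columns
        (a pandas DataFrame's column names become OTU ids). An
        :class:`AbundanceMatrix` (OTUs in rows) is also accepted directly.
        """
        m = self._as_abundance(X)
        self.n_features_in_ = m.n_otus
        if self.min_total > 0:
            m = filter_min_total(m, self.min_total)
        if m.n_otus < 2:
            raise ValueError("need at least 2 OTUs after filtering")
        self.otu_ids_ = list(m.otu_ids)
        seed = normalize_seed(self.random_state)

        self.sweep_ = None
        self.transition_ = None
        if self.threshold == "auto":
            self.sweep_ = component_sweep(
                m,
                treatments=("noise_added", "permuted"),
                grid=default_grid(self.grid_step),
                seed=child_seed(seed, 1),
            )
            self.transition_ = noise_transition_threshold(self.sweep_, cutoff=self.cutoff)
            if self.transition_ is None:
                raise ValueError(
                    "permuted-treatment curve never fell below the cutoff; "
                    "no noise transition on the grid"
                )
            self.threshold_ = min(1.0, self.transition_ + self.margin)
        else:
            tau = float(self.threshold)
            if not (0.0 <= tau <= 1.0):
                raise ValueError("threshold must lie in [0, 1] or be 'auto'")
            self.threshold_ = tau

        self.networks_ = monte_carlo_ensemble(
            m,
            tau=self.threshold_,
            replicates=self.n_replicates,
            master_seed=child_seed(seed, 2),
        )
        self.consensus_ = consensus_network(self.networks_, support=self.support)
        return self

    def ensemble_statistics(self, include_modularity: bool = True):
        """Per-replicate statistics table and {stat: {mean, sd, n}} summary."""
        self._check_fitted()
        return summarize_ensemble(self.networks_, include_modularity=include_modularity)

    def get_network(self, replicate: int = 0) -> nx.Graph:
        """The thresholded network of one tie-break replicate."""
        self._check_fitted()
        return self.networks_[replicate]

    def _check_fitted(self) -> None:
        if not hasattr(self, "networks_"):
            raise AttributeError("estimator is not fitted; call fit(X) first")
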