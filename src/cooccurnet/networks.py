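"""From correlation matrices to interaction networks.

An interaction network connects two OTUs when the absolute value of their
(tie-broken) Spearman coefficient exceeds a threshold τ; nodes left without
any edge (singletons) are dropped by convention. The working threshold is
anchored by the permutation null: sweeping τ on an element-wise permuted
matrix produces a sigmoidal largest-component curve whose collapse below 1%
of OTUs marks the *noise transition* — a lower bound on defensible
thresholds, since every edge in the permuted treatment is spurious.

Repeating the tie-break draw yields an ensemble of equally plausible
networks; the *consensus network* keeps the edges present in at least a
given fraction (90% by default) of the replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._rng import child_seed
from .abundance import AbundanceMatrix
from .correlation import (
    CorrelationMatrix,
    NoiseSpec,
    add_tiebreak_noise,
    min_distinct_gap,
    pairwise_correlations,
    permute_elements,
)

__all__ = [
    "ThresholdSweep",
    "threshold_network",
    "largest_component_fraction",
    "component_sweep",
    "noise_transition_threshold",
    "monte_carlo_ensemble",
    "consensus_network",
    "default_grid",
]

TREATMENTS = ("original", "noise_added", "permuted")


def default_grid(step: float = 0.01) -> np.ndarray:
    """Ascending threshold grid on [0, 1]; step 0.01 resolves the curves."""
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


@dataclass
class ThresholdSweep:
    """Largest-component fraction per threshold, per data treatment.

    Fractions use the full OTU count N (post-filter, pre-singleton-removal)
    as denominator and are non-increasing in τ for a fixed matrix.
    """

    grid: np.ndarray
    curves: Dict[str, np.ndarray]
    n_otus: int
    seed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        data = {"threshold": self.grid}
        data.update({t: c for t, c in self.curves.items()})
        return pd.DataFrame(data)


def threshold_network(
    c: CorrelationMatrix,
    tau: float,
    provenance: str = "original",
    seed: Optional[int] = None,
) -> nx.Graph:
    """Simple undirected graph with an edge wherever |ρ| > τ.

    The inequality is strict, self-pairs are excluded, and singletons are
    removed, so the node count n is at most the OTU count N. Each edge
    carries ``rho`` (signed), ``weight`` = |ρ| and ``sign``; strong
    mutual-exclusion pairs (large negative ρ) therefore become edges too.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    rho = c.rho
    n = c.n_otus
    iu, ju = np.triu_indices(n, k=1)
    mask = np.abs(rho[iu, ju]) > tau
    g = nx.Graph(threshold=float(tau), provenance=provenance, n_otus=n)
    if seed is not None:
        g.graph["seed"] = int(seed)
    ids = list(c.otu_ids)
    for i, j in zip(iu[mask], ju[mask]):
        r = float(rho[i, j])
        g.add_edge(ids[i], ids[j], rho=r, weight=abs(r), sign=1 if r >= 0 else -1)
    return g


def _largest_component_size(abs_rho: np.ndarray, tau: float) -> int:
    """Size of the largest component with >= 2 nodes (0 if no edges)."""
    n = abs_rho.shape[0]
    adj = np.triu(abs_rho > tau, k=1)
    if not adj.any():
        return 0
    sparse = csr_matrix(adj)
    n_comp, labels = connected_components(sparse, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    sizes = sizes[sizes >= 2]
    return int(sizes.max()) if sizes.size else 0


def largest_component_fraction(c: CorrelationMatrix, tau: float) -> float:
    """Fraction of *all* N OTUs inside the largest connected component.

    The denominator is the full OTU count, including OTUs discarded as
    singletons at this threshold, so the value at τ = 0 is 1 and at τ = 1
    is 0.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    abs_rho = np.abs(c.rho).copy()
    np.fill_diagonal(abs_rho, 0.0)
    return _largest_component_size(abs_rho, tau) / c.n_otus


def _fraction_curve(c: CorrelationMatrix, grid: np.ndarray) -> np.ndarray:
    abs_rho = np.abs(c.rho).copy()
    np.fill_diagonal(abs_rho, 0.0)
    return np.array(
        [_largest_component_size(abs_rho, t) / c.n_otus for t in grid]
    )


def component_sweep(
    m: AbundanceMatrix,
    treatments: Sequence[str] = TREATMENTS,
    grid: Optional[np.ndarray] = None,
    seed: int = 0,
) -> ThresholdSweep:
    """Largest-component curves for up to three data treatments.

    ``original``: standard Spearman with average ranks on the raw matrix
    (the uncorrected baseline). ``noise_added``: one tie-break draw.
    ``permuted``: element-wise permutation followed by a tie-break draw —
    the matrix-level null whose collapse locates the noise transition.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending")
    curves: Dict[str, np.ndarray] = {}
    for t in treatments:
        if t == "original":
            c = pairwise_correlations(m, on_ties="average")
        elif t == "noise_added":
            s = child_seed(seed, 0)
            c = pairwise_correlations(
                add_tiebreak_noise(m, NoiseSpec.for_matrix(m, seed=s)), seed=s
            )
        elif t == "permuted":
            perm = permute_elements(m, seed=child_seed(seed, 1))
            s = child_seed(seed, 2)
            c = pairwise_correlations(
                add_tiebreak_noise(perm, NoiseSpec.for_matrix(perm, seed=s)), seed=s
            )
        else:
            raise ValueError(f"unknown treatment {t!r}")
        curves[t] = _fraction_curve(c, grid)
    return ThresholdSweep(grid=grid, curves=curves, n_otus=m.n_otus, seed=seed)


def noise_transition_threshold(
    sweep: ThresholdSweep, cutoff: float = 0.01
) -> Optional[float]:
    """Smallest grid threshold with a permuted-treatment fraction below ``cutoff``.

    This is the noise transition: above it the all-spurious permuted network
    retains less than ``cutoff`` (1% by default) of OTUs in its largest
    component. A conservative working threshold sits slightly above this
    value. Returns ``None`` when the curve never drops below the cutoff on
    the grid.
    """
    if "permuted" not in sweep.curves:
        raise ValueError("sweep has no permuted-treatment curve")
    below = sweep.curves["permuted"] < cutoff
    if not below.any():
        return None
    return float(sweep.grid[int(np.argmax(below))])


def monte_carlo_ensemble(
    m: AbundanceMatrix,
    tau: float,
    replicates: int = 2000,
    master_seed: int = 0,
) -> List[nx.Graph]:
    """Ensemble of equally plausible networks, one per tie-break draw.

    Replicate ``r`` thresholds the correlation matrix of an independently
    noise-added copy of ``m``; Δ is computed once on the raw matrix. Node
    and edge counts vary across replicates whenever the raw matrix has ties.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    gap = min_distinct_gap(m)
    graphs: List[nx.Graph] = []
    for r in range(replicates):
        s = child_seed(master_seed, r)
        spec = NoiseSpec(gap=gap, amplitude=gap / 1000.0, seed=s)
        noisy = add_tiebreak_noise(m, spec)
        c = pairwise_correlations(noisy, seed=s)
        graphs.append(threshold_network(c, tau, provenance="noise_added", seed=s))
    return graphs


def consensus_network(
    ensemble: Iterable[nx.Graph], support: float = 0.9
) -> nx.Graph:
    """Edges present in at least a ``support`` fraction of the replicates.

    The comparison is inclusive ("at least"): an edge in exactly
    ``support * n_replicates`` replicates is retained. Nodes are the
    endpoints of retained edges; each edge records its support fraction, its
    mean |ρ| across the replicates that contain it, and its majority sign.
    """
    graphs = list(ensemble)
    if not graphs:
        raise ValueError("ensemble is empty")
    if not (0.0 < support <= 1.0):
        raise ValueError("support must lie in (0, 1]")
    n_rep = len(graphs)
    counts: Dict[tuple, int] = {}
    weight_sum: Dict[tuple, float] = {}
    sign_sum: Dict[tuple, int] = {}
    for g in graphs:
        for u, v, data in g.edges(data=True):
            key = (u, v) if u <= v else (v, u)
            counts[key] = counts.get(key, 0) + 1
            weight_sum[key] = weight_sum.get(key, 0.0) + data.get("weight", 1.0)
            sign_sum[key] = sign_sum.get(key, 0) + data.get("sign", 1)
    cons = nx.Graph(
        support=float(support),
        n_replicates=n_rep,
        threshold=graphs[0].graph.get("threshold"),
        n_otus=graphs[0].graph.get("n_otus"),
    )
    needed = support * n_rep - 1e-9
    for key in sorted(counts):
        k = counts[key]
        if k >= needed:
            cons.add_edge(
                key[0],
                key[1],
                support=k / n_rep,
                weight=weight_sum[key] / k,
                sign=1 if sign_sum[key] >= 0 else -1,
            )
    return cons
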