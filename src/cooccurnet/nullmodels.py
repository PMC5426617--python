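"""Class-2 null models: random-graph ensembles for the derived network.

Two standard simple-graph models control for connectivity when judging
whether a pattern in the derived network could arise by chance:

* Erdős–Rényi G(n, p): every pair of nodes is an edge independently with
  the same probability p, matching the derived network's average degree
  only.
* Chung-Lu: pair (i, j) is an edge with probability kᵢkⱼ/2m (capped at 1),
  matching the expected degree *sequence* of the derived network.

Sampling a large ensemble from either model yields an empirical null
distribution for any network statistic, from which empirical p-values and
z-scores for the observed network follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np

from ._rng import spawn_rng

__all__ = [
    "NullEnsembleSummary",
    "SignificanceResult",
    "er_probability",
    "sample_erdos_renyi",
    "sample_chung_lu",
    "null_distribution",
    "empirical_significance",
]


def er_probability(n: int, mean_degree: float, recipe: str = "matrix_cells") -> float:
    """Edge probability for an Erdős–Rényi null matched to a mean degree.

    Two published parameterizations exist for the same target ⟨k⟩ = 2m/n:

    * ``"matrix_cells"`` (default): p = 2m/n² = ⟨k⟩/n — derived by spreading
      2m edge stubs over the n² cells of the adjacency matrix. For the
      reference case n=300, ⟨k⟩=11.64 (m=1746) this gives p = 0.0388 and an
      expected edge count p·n(n−1)/2 ≈ 1740.2.
    * ``"pairs"``: p = ⟨k⟩/(n−1) — the exact G(n, p) moment match, giving
      p ≈ 0.03893 and expected edge count exactly m = 1746 for the same
      case.

    The default follows the matrix-cell recipe because the published
    reference distributions were generated with it; the difference is a
    factor (n−1)/n.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if mean_degree < 0:
        raise ValueError("mean degree must be >= 0")
    if recipe == "matrix_cells":
        return mean_degree / n
    if recipe == "pairs":
        return mean_degree / (n - 1)
    raise ValueError(f"unknown recipe {recipe!r}")


def _graph_from_pairs(
    n: int, iu: np.ndarray, ju: np.ndarray, mask: np.ndarray, keep_singletons: bool
) -> nx.Graph:
    g = nx.Graph()
    if keep_singletons:
        g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    return g


def sample_erdos_renyi(
    n: int,
    p: float,
    seed: Union[int, np.random.Generator] = 0,
    keep_singletons: bool = False,
) -> nx.Graph:
    """One draw from G(n, p): each of the n(n−1)/2 pairs is an edge w.p. p.

    Simple by construction (each unordered pair is handled once; no
    self-loops). Degree-zero nodes are dropped by default, mirroring the
    singleton-removal convention applied to derived networks before
    statistics.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    return _graph_from_pairs(n, iu, ju, mask, keep_singletons)


def sample_chung_lu(
    degrees: Sequence[float],
    seed: Union[int, np.random.Generator] = 0,
    keep_singletons: bool = False,
) -> nx.Graph:
    """One draw from the Chung-Lu model for an expected degree sequence.

    Pair (i, j), i < j, is an edge independently with probability
    min(1, kᵢkⱼ/2m) where 2m = Σkᵢ. The cap keeps probabilities valid for
    heavy-tailed sequences with kᵢkⱼ > 2m; the number of capped pairs is
    recorded in ``g.graph["n_capped_pairs"]``. A zero-total sequence yields
    an empty graph.
    """
    k = np.asarray(degrees, dtype=float)
    if (k < 0).any():
        raise ValueError("expected degrees must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed)
    n = k.size
    two_m = k.sum()
    g = nx.Graph(n_capped_pairs=0)
    if two_m == 0:
        if keep_singletons:
            g.add_nodes_from(range(n))
        return g
    iu, ju = np.triu_indices(n, k=1)
    p = k[iu] * k[ju] / two_m
    n_capped = int((p > 1.0).sum())
    p = np.minimum(p, 1.0)
    mask = rng.random(iu.size) < p
    g = _graph_from_pairs(n, iu, ju, mask, keep_singletons)
    g.graph["n_capped_pairs"] = n_capped
    return g


@dataclass
class NullEnsembleSummary:
    """Empirical null distributions of statistics over a graph ensemble."""

    model: str
    parameters: Dict[str, object]
    replicates: int
    samples: Dict[str, np.ndarray]
    skipped: Dict[str, int]
    seed: int

    def mean(self, stat: str) -> float:
        return float(np.mean(self.samples[stat]))

    def sd(self, stat: str) -> float:
        return float(np.std(self.samples[stat], ddof=1))

    def summary(self) -> Dict[str, Dict[str, float]]:
        return {
            s: {"mean": self.mean(s), "sd": self.sd(s), "n": int(self.samples[s].size)}
            for s in self.samples
        }


def null_distribution(
    sampler: Callable[[np.random.Generator], nx.Graph],
    statistic: Union[Callable[[nx.Graph], float], Mapping[str, Callable[[nx.Graph], float]]],
    replicates: int = 2000,
    seed: int = 0,
    model: str = "custom",
    parameters: Optional[Dict[str, object]] = None,
    allow_empty: bool = False,
) -> NullEnsembleSummary:
    """Empirical null distribution of one or more statistics.

    ``sampler`` maps a NumPy generator to a graph; ``statistic`` is a single
    callable or a name → callable mapping (all evaluated on each draw).
    Draws on which a statistic is undefined (degenerate graphs) are skipped
    for that statistic, with the skip count recorded; if every draw is
    degenerate for some statistic an error is raised unless
    ``allow_empty=True``, in which case the statistic is dropped from the
    summary (its skip count remains).
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    stats_map: Dict[str, Callable[[nx.Graph], float]]
    if callable(statistic):
        stats_map = {getattr(statistic, "__name__", "statistic"): statistic}
    else:
        stats_map = dict(statistic)
    samples: Dict[str, list] = {name: [] for name in stats_map}
    skipped: Dict[str, int] = {name: 0 for name in stats_map}
    for r in range(replicates):
        g = sampler(spawn_rng(seed, r))
        for name, fn in stats_map.items():
            try:
                samples[name].append(float(fn(g)))
            except (ValueError, ZeroDivisionError):
                skipped[name] += 1
    for name in list(samples):
        if not samples[name]:
            if allow_empty:
                del samples[name]
            else:
                raise ValueError(f"statistic {name!r} was undefined on every draw")
    return NullEnsembleSummary(
        model=model,
        parameters=dict(parameters or {}),
        replicates=replicates,
        samples={name: np.asarray(vals) for name, vals in samples.items()},
        skipped=skipped,
        seed=int(seed),
    )


@dataclass
class SignificanceResult:
    p_value: float
    z_score: float
    n_null: int
    tail: str


def empirical_significance(
    observed: float,
    null: Union[NullEnsembleSummary, np.ndarray, Sequence[float]],
    tail: str = "two_sided",
    stat: Optional[str] = None,
) -> SignificanceResult:
    """Empirical p-value and z-score of an observed statistic against a null.

    Uses the add-one estimator p = (1 + #{null at least as extreme}) /
    (1 + replicates), which is never exactly zero and is uniform under the
    null. ``tail="upper"`` counts null ≥ observed, ``"lower"`` counts
    null ≤ observed, ``"two_sided"`` doubles the smaller tail (capped at 1).
    The z-score is (observed − null mean) / null sd; a zero-sd null with a
    deviating observation reports signed infinity while the p-value still
    comes from the counts.
    """
    if isinstance(null, NullEnsembleSummary):
        if stat is None:
            if len(null.samples) != 1:
                raise ValueError("specify stat= for a multi-statistic summary")
            stat = next(iter(null.samples))
        samples = np.asarray(null.samples[stat], dtype=float)
    else:
        samples = np.asarray(null, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 null samples")
    r = samples.size
    p_upper = (1 + int((samples >= observed).sum())) / (1 + r)
    p_lower = (1 + int((samples <= observed).sum())) / (1 + r)
    if tail == "upper":
        p = p_upper
    elif tail == "lower":
        p = p_lower
    elif tail == "two_sided":
        p = min(1.0, 2.0 * min(p_upper, p_lower))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    mu = float(samples.mean())
    sd = float(samples.std(ddof=1))
    if sd == 0:
        z = 0.0 if observed == mu else float(np.sign(observed - mu)) * float("inf")
    else:
        z = (observed - mu) / sd
    return SignificanceResult(p_value=float(p), z_score=float(z), n_null=r, tail=tail)
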