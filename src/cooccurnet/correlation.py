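"""Class-1 null models: tie-broken Spearman correlation on sparse matrices.

Sparse OTU abundance matrices are dominated by zeros, so the Spearman rank
correlation — which assigns tied entries their average rank — systematically
inflates pairwise scores: two taxa absent from the same sites look strongly
correlated. The correction implemented here breaks ties by Monte Carlo: add
i.i.d. uniform noise on ``(-b, b)`` with ``b = Δ/1000``, where ``Δ`` is the
smallest difference between distinct matrix values, to every entry. The
perturbation is far below the data's resolution, so every strict ordering in
the raw matrix is preserved, while tied entries receive a uniformly random
relative order. Repeating the draw yields an ensemble of equally plausible
rank configurations (and, downstream, networks).

The element-wise permutation null lives here too: shuffling all N·L entries
preserves the abundance value distribution while destroying every between-OTU
dependence, giving a null distribution of correlation scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._rng import spawn_rng
from .abundance import AbundanceMatrix

__all__ = [
    "NoiseSpec",
    "CorrelationMatrix",
    "min_distinct_gap",
    "add_tiebreak_noise",
    "spearman_rho",
    "pairwise_correlations",
    "permute_elements",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitude and seed of one tie-breaking noise draw.

    ``gap`` is Δ, the minimum absolute difference between distinct matrix
    entries; ``amplitude`` is b, the half-width of the uniform perturbation.
    The invariant ``0 < b < Δ/2`` guarantees that no strict ordering between
    two entries can be reversed by the noise.
    """

    gap: float
    amplitude: float
    seed: int

    def __post_init__(self) -> None:
        if not (0 < self.amplitude < self.gap / 2):
            raise ValueError(
                f"noise amplitude {self.amplitude} must lie in (0, gap/2) "
                f"with gap={self.gap}; order preservation would not be guaranteed"
            )

    @classmethod
    def for_matrix(cls, m: AbundanceMatrix, seed: int, divisor: float = 1000.0) -> "NoiseSpec":
        """Build the standard spec b = Δ/divisor for matrix ``m``."""
        gap = min_distinct_gap(m)
        return cls(gap=gap, amplitude=gap / divisor, seed=int(seed))


@dataclass
class CorrelationMatrix:
    """Symmetric N×N matrix of Spearman coefficients from one tie-break draw."""

    rho: np.ndarray
    otu_ids: Sequence[str]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = self.rho.shape[0]
        if self.rho.shape != (n, n) or n != len(self.otu_ids):
            raise ValueError("rho must be square and match otu_ids")

    @property
    def n_otus(self) -> int:
        return self.rho.shape[0]

    def abs_offdiag(self) -> np.ndarray:
        """Upper-triangle |ρ| values (the diagonal is excluded throughout)."""
        iu = np.triu_indices(self.n_otus, k=1)
        return np.abs(self.rho[iu])


def min_distinct_gap(m: AbundanceMatrix) -> float:
    """Δ: smallest absolute difference between two distinct matrix values."""
    values = np.unique(m.counts)
    if values.size < 2:
        raise ValueError("matrix is constant; no ordering to preserve")
    return float(np.diff(values).min())


def add_tiebreak_noise(m: AbundanceMatrix, spec: NoiseSpec) -> AbundanceMatrix:
    """A′ = A + E with E i.i.d. uniform on (−b, +b).

    Strictly ordered pairs of entries keep their order (|E| < Δ/2); tied
    entries become distinct almost surely, so each draw samples one total
    order consistent with the raw matrix's partial order.
    """
    gap = min_distinct_gap(m)
    if spec.amplitude >= gap / 2:
        raise ValueError(
            f"amplitude {spec.amplitude} >= Δ/2 = {gap / 2} for this matrix"
        )
    rng = spawn_rng(spec.seed)
    noise = rng.uniform(-spec.amplitude, spec.amplitude, size=m.counts.shape)
    return AbundanceMatrix(
        counts=m.counts + noise,
        otu_ids=list(m.otu_ids),
        location_ids=list(m.location_ids),
        phylum=m.phylum,
    )


def _check_no_ties_rows(counts: np.ndarray) -> None:
    for i, row in enumerate(counts):
        if np.unique(row).size != row.size:
            raise ValueError(
                f"tied entries within OTU row {i}; add tie-breaking noise first"
            )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation ρ = 1 − 6 Σ rᵢ² / (L(L²−1)) for tie-free vectors.

    ``rᵢ`` is the difference between the ranks of ``x`` and ``y`` at
    location ``i``. Requires L ≥ 3 and no ties within either vector (the
    closed form is exact only for permutation ranks); callers must break
    ties with noise first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    L = x.size
    if L < 3:
        raise ValueError("need at least 3 locations")
    if np.unique(x).size != L or np.unique(y).size != L:
        raise ValueError("ties present; add tie-breaking noise first")
    rx = stats.rankdata(x, method="ordinal")
    ry = stats.rankdata(y, method="ordinal")
    d = rx.astype(float) - ry
    return float(1.0 - 6.0 * np.sum(d * d) / (L * (L * L - 1.0)))


def pairwise_correlations(
    m: AbundanceMatrix, seed: Optional[int] = None, on_ties: str = "raise"
) -> CorrelationMatrix:
    """All-pairs Spearman coefficients of the OTU rows.

    With ``on_ties="raise"`` (the corrected treatment) the input must be a
    noise-added matrix with no within-row ties; ranks are then permutations
    and the result equals the closed-form ρ for every pair. With
    ``on_ties="average"`` tied entries get their average rank — the standard,
    uncorrected Spearman whose pathologies on sparse data motivate the
    tie-breaking correction. Rows with zero rank variance (constant rows,
    possible only under ``"average"``) get ρ = 0 against every partner.
    """
    counts = m.counts
    if on_ties == "raise":
        _check_no_ties_rows(counts)
        ranks = stats.rankdata(counts, method="ordinal", axis=1).astype(float)
    elif on_ties == "average":
        ranks = stats.rankdata(counts, method="average", axis=1)
    else:
        raise ValueError(f"unknown on_ties policy {on_ties!r}")
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.where(np.isfinite(rho), rho, 0.0)
    if (sd == 0).any():  # constant rows: no monotone association definable
        rho[sd == 0, :] = 0.0
        rho[:, sd == 0] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    return CorrelationMatrix(rho=rho, otu_ids=list(m.otu_ids), seed=seed)


def permute_elements(m: AbundanceMatrix, seed: int) -> AbundanceMatrix:
    """Uniformly random element-wise permutation of all N·L entries.

    Preserves the multiset of abundance values (the background distribution)
    while destroying every between-OTU dependence; the basic matrix-level
    null model.
    """
    rng = spawn_rng(seed)
    flat = m.counts.ravel()
    shuffled = flat[rng.permutation(flat.size)]
    return AbundanceMatrix(
        counts=shuffled.reshape(m.counts.shape),
        otu_ids=list(m.otu_ids),
        location_ids=list(m.location_ids),
        phylum=m.phylum,
    )
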