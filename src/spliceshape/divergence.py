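"""Comparison metrics: Euclidean matrix distance and Kullback-Leibler divergence.

Two frequency summaries are compared in this pipeline: median frequency
matrices, by the Euclidean distance over their shared lower-triangular
cells, and frequency distributions, by the discrete Kullback-Leibler
divergence KLd(P||Q) = sum_i P(i) log(P(i)/Q(i)) — the information lost
when the model distribution Q is used to approximate the data distribution
P.  Natural logarithms are used throughout, so divergences are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import rel_entr

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .sites import MedianFrequencyMatrix


def matrix_distance(f1: "MedianFrequencyMatrix", f2: "MedianFrequencyMatrix") -> float:
    """Euclidean distance between two median frequency matrices.

    sqrt of the sum of squared differences over cells present in both
    matrices; symmetric, and zero iff the matrices agree on their shared
    cells.  Cells absent from either matrix (no supporting groups) are
    omitted from the sum rather than imputed.
    """
    if f1.values.shape != f2.values.shape:
        raise ValueError("matrices must share Kmax and Mmax")
    shared = f1.present & f2.present
    if not shared.any():
        raise ValueError("matrices share no present cells")
    diff = f1.values[shared] - f2.values[shared]
    return float(np.sqrt(np.sum(diff**2)))


@dataclass
class BinnedDistribution:
    """A discrete probability distribution over bins of [0, 1]."""

    edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.edges.ndim != 1 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.masses.shape != (self.edges.size - 1,):
            raise ValueError("need one mass per bin")
        if np.any(self.masses < 0) or not np.isclose(self.masses.sum(), 1.0):
            raise ValueError("masses must be nonnegative and sum to 1")


def kld(P: BinnedDistribution, Q: BinnedDistribution) -> float:
    """KLd(P||Q) in nats, with the convention 0 * log(0/q) = 0.

    Requires shared bin edges and Q mass wherever P has mass (guaranteed
    after pseudo-count smoothing).  Asymmetric by construction: it measures
    approximation of P by Q, not the reverse.
    """
    if P.edges.shape != Q.edges.shape or not np.allclose(P.edges, Q.edges):
        raise ValueError("distributions must share bin edges")
    terms = rel_entr(P.masses, Q.masses)  # p*log(p/q), 0 where p == 0
    if np.isinf(terms).any():
        raise ValueError("Q has zero mass where P has mass; smooth first")
    return float(terms.sum())


def kld_from_samples(
    p_samples,
    q_samples,
    n_bins: int = 50,
    pseudocount: float = 0.5,
) -> float:
    """KLd estimate between two samples of frequency values in [0, 1].

    Both samples are histogrammed on shared equal-width bins over [0, 1]; a
    pseudo-count is added to every bin of both histograms before
    normalisation so the divergence is finite for any finite sample.
    """
    p_samples = np.asarray(p_samples, dtype=float)
    q_samples = np.asarray(q_samples, dtype=float)
    if p_samples.size == 0 or q_samples.size == 0:
        raise ValueError("both sample sets must be nonempty")
    if (
        np.any(p_samples < 0) or np.any(p_samples > 1)
        or np.any(q_samples < 0) or np.any(q_samples > 1)
    ):
        raise ValueError("frequency samples must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    p_hist = np.histogram(p_samples, bins=edges)[0] + pseudocount
    q_hist = np.histogram(q_samples, bins=edges)[0] + pseudocount
    P = BinnedDistribution(edges, p_hist / p_hist.sum())
    Q = BinnedDistribution(edges, q_hist / q_hist.sum())
    return kld(P, Q)
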