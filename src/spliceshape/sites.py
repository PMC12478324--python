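"""Alternative splice-site groups and their frequency hierarchy.

An *alternative-site group* is one anchor site (a donor, say) together with
the M partner sites it splices to (its alternative acceptors) and their
pooled unique-read counts.  Ranking the partner counts and normalising by
the group total gives the frequency hierarchy f(1,M) >= f(2,M) >= ... >=
f(M,M), which sums to 1; the median of f(k,M) over all groups with exactly
M partners is the entry mf(k,M) of the median frequency matrix summarising
a whole dataset.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .junctions import ACCEPTOR, DONOR, Junction, SpliceSite, junction_sites

DEFAULT_KMAX = 6
DEFAULT_MMAX = 15


@dataclass
class AltSiteGroup:
    """An anchor splice site with its ranked alternative partner sites.

    Partners are sorted by descending read count, ties broken by ascending
    genomic position so ranks are reproducible.
    """

    anchor: SpliceSite
    partners: list[tuple[SpliceSite, int]]

    def __post_init__(self) -> None:
        if not self.partners:
            raise ValueError("a group needs at least one partner site")
        for site, count in self.partners:
            if count <= 0:
                raise ValueError("partner counts must be positive")
            if site.chrom != self.anchor.chrom or site.strand != self.anchor.strand:
                raise ValueError("partners must share the anchor's chromosome and strand")

    @property
    def M(self) -> int:
        return len(self.partners)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.partners], dtype=float)


@dataclass
class FrequencyVector:
    """Ranked frequencies f(1,M) ... f(M,M) of one group; sums to 1."""

    M: int
    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (self.M,):
            raise ValueError("frequency vector length must equal M")
        if not np.isclose(self.f.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        if np.any(np.diff(self.f) > 1e-12) or self.f[-1] < -1e-12:
            raise ValueError("frequencies must be nonincreasing and nonnegative")


@dataclass
class MedianFrequencyMatrix:
    """Lower-triangular matrix of median ranked frequencies mf(k,M).

    ``values[k-1, M-1]`` is the median over all groups with multiplicity M of
    the k-th ranked frequency, for k <= min(Kmax, M); cells with no
    supporting groups (and the upper triangle k > M) are NaN.
    ``group_counts[M-1]`` records how many groups back column M.
    """

    values: np.ndarray
    group_counts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_counts = np.asarray(self.group_counts, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a Kmax x Mmax matrix")
        if self.group_counts.shape != (self.values.shape[1],):
            raise ValueError("group_counts must have one entry per M column")

    @property
    def Kmax(self) -> int:
        return self.values.shape[0]

    @property
    def Mmax(self) -> int:
        return self.values.shape[1]

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of cells backed by at least one group."""
        return ~np.isnan(self.values)

    def cell(self, k: int, M: int) -> float:
        """mf(k,M) with 1-based k and M."""
        return float(self.values[k - 1, M - 1])

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write as TSV, one row per k, absent cells as ``NA``."""
        path = Path(path)
        with path.open("w") as fh:
            header = ["k"] + [f"M{M}" for M in range(1, self.Mmax + 1)]
            fh.write("\t".join(header) + "\n")
            fh.write(
                "\t".join(["n_groups"] + [str(c) for c in self.group_counts]) + "\n"
            )
            for ki in range(self.Kmax):
                row = [str(ki + 1)]
                for Mi in range(self.Mmax):
                    v = self.values[ki, Mi]
                    row.append("NA" if np.isnan(v) else f"{v:.6g}")
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "MedianFrequencyMatrix":
        lines = Path(path).read_text().strip().split("\n")
        n_groups = np.array([int(x) for x in lines[1].split("\t")[1:]])
        rows = []
        for line in lines[2:]:
            cells = line.split("\t")[1:]
            rows.append([np.nan if c == "NA" else float(c) for c in cells])
        return cls(np.array(rows), n_groups)


def group_by_anchor(
    junctions: Iterable[Junction], anchor_role: str
) -> list[AltSiteGroup]:
    """Group strand-resolved junctions by a shared anchor site.

    With ``anchor_role='donor'`` each group is one donor site with its
    alternative acceptor partners (and vice versa).  Junctions with zero
    unique reads carry no expression evidence and are ignored.  Output is
    sorted by anchor coordinates, so it is invariant to input order.
    """
    if anchor_role not in (DONOR, ACCEPTOR):
        raise ValueError("anchor_role must be 'donor' or 'acceptor'")
    buckets: dict[SpliceSite, dict[SpliceSite, int]] = defaultdict(dict)
    for j in junctions:
        if j.unique_reads <= 0:
            continue
        donor, acceptor = junction_sites(j)
        anchor, partner = (donor, acceptor) if anchor_role == DONOR else (acceptor, donor)
        buckets[anchor][partner] = buckets[anchor].get(partner, 0) + j.unique_reads
    groups = []
    for anchor in sorted(buckets, key=lambda s: (s.chrom, s.position, s.strand)):
        partners = sorted(
            buckets[anchor].items(), key=lambda it: (-it[1], it[0].position)
        )
        groups.append(AltSiteGroup(anchor=anchor, partners=list(partners)))
    return groups


def frequencies(group: AltSiteGroup) -> FrequencyVector:
    """Ranked frequencies of a group: each partner count over the group total."""
    counts = group.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("group total count must be positive")
    return FrequencyVector(M=group.M, f=counts / total)


def scaled_expression(group: AltSiteGroup) -> np.ndarray:
    """Partner counts scaled by the group mean; the output mean is exactly 1.

    This is the normalisation used to pool expression levels of groups with
    different absolute expression onto one density curve.
    """
    counts = group.counts
    if counts.sum() <= 0:
        raise ValueError("group total count must be positive")
    return counts / counts.mean()


def multiplicity_histogram(
    groups: Iterable[AltSiteGroup], Mmax: int = DEFAULT_MMAX
) -> dict[int, int]:
    """Count groups per multiplicity M; M > Mmax pooled in an overflow bin.

    Keys are 1..Mmax plus ``Mmax + 1`` for the overflow bin; all keys are
    present, zero-count bins included.
    """
    hist = {M: 0 for M in range(1, Mmax + 2)}
    for g in groups:
        hist[min(g.M, Mmax + 1)] += 1
    return hist


def junction_multiplicity_heatmap(
    junctions: Iterable[Junction], Mmax: int = DEFAULT_MMAX
) -> np.ndarray:
    """Joint (numA, numD) table: one count per junction.

    ``numA`` is the number of alternative acceptors of the junction's donor
    site and ``numD`` the number of alternative donors of its acceptor site;
    cell ``[numA-1, numD-1]`` accumulates one unit per junction.  Values
    above Mmax fall in the last row/column.
    """
    junctions = [j for j in junctions if j.unique_reads > 0]
    donor_groups = group_by_anchor(junctions, DONOR)
    acceptor_groups = group_by_anchor(junctions, ACCEPTOR)
    num_a = {g.anchor: g.M for g in donor_groups}
    num_d = {g.anchor: g.M for g in acceptor_groups}
    table = np.zeros((Mmax, Mmax), dtype=int)
    for j in junctions:
        donor, acceptor = junction_sites(j)
        a = min(num_a[donor], Mmax)
        d = min(num_d[acceptor], Mmax)
        table[a - 1, d - 1] += 1
    return table


def median_frequency_matrix(
    groups: Iterable[AltSiteGroup],
    Kmax: int = DEFAULT_KMAX,
    Mmax: int = DEFAULT_MMAX,
) -> MedianFrequencyMatrix:
    """Median ranked frequencies over groups, stratified by multiplicity.

    Groups with M > Mmax are excluded outright (not truncated).  Cells with
    no supporting groups stay NaN; ranks that were never detected in any
    group of a stratum are genuine zeros and are kept as such.
    """
    by_m: dict[int, list[np.ndarray]] = defaultdict(list)
    for g in groups:
        if g.M > Mmax:
            continue
        by_m[g.M].append(frequencies(g).f)
    values = np.full((Kmax, Mmax), np.nan)
    counts = np.zeros(Mmax, dtype=int)
    for M, vecs in by_m.items():
        arr = np.vstack(vecs)
        counts[M - 1] = arr.shape[0]
        med = np.median(arr, axis=0)
        kmax_here = min(Kmax, M)
        values[:kmax_here, M - 1] = med[:kmax_here]
    return MedianFrequencyMatrix(values=values, group_counts=counts)


def frequency_samples(
    groups: Iterable[AltSiteGroup], Mmax: int = DEFAULT_MMAX
) -> dict[tuple[int, int], np.ndarray]:
    """Observed f(k,M) values pooled per (k, M) stratum.

    Used to compare empirical frequency distributions with model draws
    stratum by stratum (e.g. by Kullback-Leibler divergence).
    """
    pools: dict[tuple[int, int], list[float]] = defaultdict(list)
    for g in groups:
        if g.M > Mmax:
            continue
        f = frequencies(g).f
        for k in range(1, g.M + 1):
            pools[(k, g.M)].append(f[k - 1])
    return {km: np.array(v) for km, v in pools.items()}


def pooled_scaled_expression(groups: Iterable[AltSiteGroup]) -> np.ndarray:
    """All scaled expression values of all groups, pooled into one array."""
    vals = [scaled_expression(g) for g in groups]
    if not vals:
        return np.empty(0)
    return np.concatenate(vals)
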