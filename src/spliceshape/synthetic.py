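"""Synthetic multi-sample splice-junction datasets with known ground truth.

Emulates what the pipeline consumes from a real RNA-seq study — one STAR
``SJ.out.tab`` per sample plus a gene annotation — from a generative model
matching the Weibull analysis: each gene carries one alternative-site group
whose M partner-site intensities are drawn from W(a_true, 1), and each
sample's junction reads are allocated to the partners multinomially with a
Poisson total.  Because the ground-truth shape parameter is known, every
pipeline stage (parsing, merging, the >= 3-sample filter, strand
assignment, grouping, matrix building, fitting) can be tested end to end
for parameter recovery without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import junctions as jio
from . import sites as asites
from . import weibull as wb

#: Multiplicity distribution approximating the empirical decay of group
#: sizes in bulk RNA-seq: geometric with ratio ~0.55, truncated at M = 15.
def geometric_m_distribution(ratio: float = 0.55, Mmax: int = 15) -> dict[int, float]:
    w = np.array([ratio ** (M - 1) for M in range(1, Mmax + 1)])
    w /= w.sum()
    return {M: float(w[M - 1]) for M in range(1, Mmax + 1)}


@dataclass
class SyntheticConfig:
    """Ground-truth model and sampling settings for one synthetic dataset.

    ``depth`` is the mean number of junction reads per group per sample
    (Poisson-distributed per sample); ``strand_fraction`` is the fraction of
    genes placed on the + strand; ``acceptor_anchor_fraction`` the fraction
    of genes whose group is anchored on an acceptor site (partners are then
    alternative donors); ``dropout`` is a per-sample probability that a
    detected junction line is omitted from the written table, to exercise
    the multi-sample detection filter.
    """

    a_true: float = 0.14
    n_genes: int = 2000
    strand_fraction: float = 0.5
    acceptor_anchor_fraction: float = 0.5
    M_distribution: Optional[Mapping[int, float]] = None
    depth: float = 5000.0
    n_samples: int = 6
    seed: int = 0
    dropout: float = 0.0
    overhang: int = 30

    def __post_init__(self) -> None:
        if not self.a_true > 0:
            raise ValueError("a_true must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.M_distribution is None:
            self.M_distribution = geometric_m_distribution()
        total = sum(self.M_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError("M_distribution masses must sum to 1")


@dataclass
class SyntheticDataset:
    """Paths of one generated dataset."""

    sj_paths: list[Path]
    gtf_path: Path
    truth_path: Path
    config: SyntheticConfig


_GENE_PAD = 500          # bp between the gene boundary and the outermost site
_SITE_SPACING = 50       # bp between adjacent alternative sites
_GENE_GAP = 2000         # bp between consecutive genes


def generate(config: SyntheticConfig, out_dir: Union[str, Path]) -> SyntheticDataset:
    """Write ``n_samples`` SJ.out.tab files, a GTF and a ground-truth table.

    Genes are laid out without overlap on a single synthetic chromosome;
    each holds one anchor site with M partner sites, all inside the gene
    span, with strand orientation honoured (on the - strand the donor is
    the right intron end).  Output is byte-identical for identical configs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    m_vals = np.array(sorted(config.M_distribution))
    m_probs = np.array([config.M_distribution[m] for m in m_vals], dtype=float)
    m_probs /= m_probs.sum()

    sample_rows: list[list[tuple]] = [[] for _ in range(config.n_samples)]
    gtf_lines: list[str] = []
    truth_lines: list[str] = [
        "gene_id\tchrom\tstrand\tanchor_role\tanchor_pos\tM\ta_true\tintensities"
    ]
    chrom = "chrS1"
    cursor = 1

    for gi in range(config.n_genes):
        M = int(rng.choice(m_vals, p=m_probs))
        strand = "+" if rng.random() < config.strand_fraction else "-"
        anchor_role = (
            jio.ACCEPTOR if rng.random() < config.acceptor_anchor_fraction else jio.DONOR
        )
        intensities = rng.weibull(config.a_true, size=M)
        # guard against exact zeros from extreme shapes
        intensities = np.maximum(intensities, 1e-300)
        probs = intensities / intensities.sum()

        gene_start = cursor
        span = 2 * _GENE_PAD + (M + 1) * _SITE_SPACING
        gene_end = gene_start + span
        anchor_left = (anchor_role == jio.DONOR) == (strand == "+")
        # intron coordinates: one shared end (the anchor) and M distinct
        # partner ends, all within the gene span
        if anchor_left:
            start = gene_start + _GENE_PAD
            ends = [start + _SITE_SPACING * (i + 1) for i in range(M)]
            coords = [(start, e) for e in ends]
            anchor_pos = start
        else:
            end = gene_start + _GENE_PAD + _SITE_SPACING * (M + 1)
            starts = [gene_start + _GENE_PAD + _SITE_SPACING * i for i in range(M)]
            coords = [(s, end) for s in starts]
            anchor_pos = end

        counts = rng.multinomial(
            rng.poisson(config.depth, size=config.n_samples), probs
        )  # (n_samples, M)
        strand_code = jio.STRAND_TO_CODE[strand]
        for si in range(config.n_samples):
            for pi, (s, e) in enumerate(coords):
                c = int(counts[si, pi])
                if c == 0:
                    continue
                if config.dropout > 0 and rng.random() < config.dropout:
                    continue
                sample_rows[si].append(
                    (chrom, s, e, strand_code, 0, 0, c, 0, config.overhang)
                )

        gene_id = f"SYNG{gi:06d}"
        gtf_lines.append(
            "\t".join(
                [
                    chrom,
                    "spliceshape",
                    "gene",
                    str(gene_start),
                    str(gene_end),
                    ".",
                    strand,
                    ".",
                    f'gene_id "{gene_id}"; gene_name "{gene_id}"; gene_biotype "protein_coding";',
                ]
            )
        )
        truth_lines.append(
            "\t".join(
                [
                    gene_id,
                    chrom,
                    strand,
                    anchor_role,
                    str(anchor_pos),
                    str(M),
                    f"{config.a_true:g}",
                    ",".join(f"{v:.8g}" for v in intensities),
                ]
            )
        )
        cursor = gene_end + _GENE_GAP

    sj_paths = []
    for si in range(config.n_samples):
        p = out_dir / f"sample{si + 1:02d}.SJ.out.tab"
        with p.open("w") as fh:
            for row in sorted(sample_rows[si], key=lambda r: (r[0], r[1], r[2])):
                fh.write("\t".join(str(v) for v in row) + "\n")
        sj_paths.append(p)

    gtf_path = out_dir / "genes.gtf"
    gtf_path.write_text("\n".join(gtf_lines) + ("\n" if gtf_lines else ""))
    truth_path = out_dir / "truth.tsv"
    truth_path.write_text("\n".join(truth_lines) + "\n")
    return SyntheticDataset(
        sj_paths=sj_paths, gtf_path=gtf_path, truth_path=truth_path, config=config
    )


@dataclass
class RecoveryReport:
    """Outcome of a full generate -> parse -> fit round trip."""

    a_true: float
    fits: dict[str, wb.ShapeFit]          # per anchor role
    matrices: dict[str, asites.MedianFrequencyMatrix]
    n_junctions: int
    strand_report: jio.StrandReport

    def error(self, role: str) -> float:
        return abs(self.fits[role].a_hat - self.a_true)


def end_to_end_recovery(
    config: SyntheticConfig,
    out_dir: Union[str, Path],
    min_samples: int = 3,
    grid: Optional[Sequence[float]] = None,
    reps: int = 5000,
    fit_seed: int = 1,
    Kmax: int = asites.DEFAULT_KMAX,
    Mmax: int = asites.DEFAULT_MMAX,
) -> RecoveryReport:
    """Generate a dataset and run the full pipeline to re-estimate the shape.

    Runs generate -> parse -> merge -> multi-sample filter -> strand
    assignment -> donor- and acceptor-anchored grouping -> median frequency
    matrices -> grid fit, and reports the fitted shape per anchor role
    alongside the ground truth.
    """
    ds = generate(config, out_dir)
    tables = [jio.parse_sj_tab(p) for p in ds.sj_paths]
    merged = jio.merge_samples(tables)
    kept = jio.filter_min_samples(merged, min_samples)
    stranded, strand_report = jio.assign_strand(kept, ds.gtf_path)
    fits: dict[str, wb.ShapeFit] = {}
    matrices: dict[str, asites.MedianFrequencyMatrix] = {}
    for role in (jio.DONOR, jio.ACCEPTOR):
        groups = asites.group_by_anchor(stranded, role)
        mf = asites.median_frequency_matrix(groups, Kmax=Kmax, Mmax=Mmax)
        matrices[role] = mf
        fits[role] = wb.fit_shape(mf, grid=grid, reps=reps, seed=fit_seed)
    return RecoveryReport(
        a_true=config.a_true,
        fits=fits,
        matrices=matrices,
        n_junctions=len(stranded),
        strand_report=strand_report,
    )
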