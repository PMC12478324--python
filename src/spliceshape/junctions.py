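"""Reading, merging, filtering and strand-resolving splice junctions.

The entry format is the splice-junction table emitted by the STAR aligner
(``SJ.out.tab``): nine tab-separated columns per junction, with 1-based
inclusive intron coordinates, a strand code (0 undefined, 1 ``+``, 2 ``-``),
the intron motif, an annotation flag, unique- and multi-mapping read counts,
and the maximum spliced-alignment overhang.  Only uniquely mapped reads are
used as the expression level of a splicing event.

Gene strand is taken from a GTF annotation rather than from the aligner:
a junction inherits the strand of the gene(s) whose span contains its whole
intron, and junctions that are intergenic or span genes with conflicting
strands are discarded.  On the ``+`` strand the left (5') end of a junction
is the donor site and the right (3') end the acceptor; on the ``-`` strand
the roles are mirrored.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import gffutils
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: STAR strand column values -> strand symbols ("?" = undefined).
STRAND_CODES = {0: "?", 1: "+", 2: "-"}
STRAND_TO_CODE = {"?": 0, "+": 1, "-": 2}

DONOR = "donor"
ACCEPTOR = "acceptor"


class SJParseError(ValueError):
    """A malformed line in an SJ.out.tab file."""


class AnnotationError(ValueError):
    """An unusable gene annotation (unreadable, or without strand info)."""


@dataclass(frozen=True)
class SpliceSite:
    """One splice site: a genomic position acting as donor or acceptor."""

    chrom: str
    position: int
    strand: str
    role: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"splice site strand must be + or -, got {self.strand!r}")
        if self.role not in (DONOR, ACCEPTOR):
            raise ValueError(f"role must be 'donor' or 'acceptor', got {self.role!r}")


@dataclass
class Junction:
    """One splice junction with its pooled read support.

    ``intron_start``/``intron_end`` are the 1-based first and last intronic
    bases (STAR convention).  ``unique_reads`` counts uniquely mapped
    junction-spanning reads; ``n_samples`` counts the samples in which the
    junction was observed with at least one unique read.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "?"
    unique_reads: int = 0
    n_samples: int = 1
    max_overhang: int = 0
    #: strand reported by the aligner, kept for QC against the GTF strand
    star_strand: str = "?"

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be nonnegative")
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


def parse_sj_tab(path: Union[str, Path]) -> list[Junction]:
    """Parse one STAR ``SJ.out.tab`` file into a list of junctions.

    Each line must carry at least the nine standard columns; extra columns
    (e.g. those appended by :func:`write_sj_tab`) are ignored.  Only the
    unique-read count is kept as expression evidence; ``n_samples`` starts
    at 1 since one file is one sample.

    Raises :class:`SJParseError` naming the offending line for malformed
    input (wrong field count, non-integer fields, negative counts).
    """
    path = Path(path)
    junctions: list[Junction] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise SJParseError(
                    f"{path}:{lineno}: expected >= 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                strand_code = int(fields[3])
                unique = int(fields[6])
                overhang = int(fields[8])
            except ValueError as exc:
                raise SJParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if unique < 0 or overhang < 0:
                raise SJParseError(f"{path}:{lineno}: negative count")
            if strand_code not in STRAND_CODES:
                raise SJParseError(f"{path}:{lineno}: invalid strand code {strand_code}")
            strand = STRAND_CODES[strand_code]
            try:
                junctions.append(
                    Junction(
                        chrom=fields[0],
                        intron_start=start,
                        intron_end=end,
                        strand=strand,
                        unique_reads=unique,
                        n_samples=1,
                        max_overhang=overhang,
                        star_strand=strand,
                    )
                )
            except ValueError as exc:
                raise SJParseError(f"{path}:{lineno}: {exc}") from None
    return junctions


def write_sj_tab(
    junctions: Iterable[Junction],
    path: Union[str, Path],
    extra_columns: bool = False,
) -> None:
    """Write junctions in the nine-column SJ.out.tab layout.

    With ``extra_columns`` two fields are appended: ``n_samples`` and the
    resolved strand symbol.  Motif and annotation columns are written as 0
    (they carry no information in this pipeline) and the multi-mapping read
    count as 0, since only unique reads are tracked.
    """
    path = Path(path)
    with path.open("w") as fh:
        for j in junctions:
            row = [
                j.chrom,
                str(j.intron_start),
                str(j.intron_end),
                str(STRAND_TO_CODE[j.star_strand]),
                "0",
                "0",
                str(j.unique_reads),
                "0",
                str(j.max_overhang),
            ]
            if extra_columns:
                row += [str(j.n_samples), j.strand]
            fh.write("\t".join(row) + "\n")


def merge_samples(tables: Sequence[Sequence[Junction]]) -> list[Junction]:
    """Pool per-sample junction lists into one multi-sample collection.

    Junctions are keyed by (chrom, intron_start, intron_end).  Unique-read
    counts are summed across samples, ``n_samples`` counts the samples where
    the junction had at least one unique read, and ``max_overhang`` is the
    maximum over samples.  The result is sorted by genomic coordinates so the
    output does not depend on sample order.
    """
    if len(tables) < 1:
        raise ValueError("merge_samples requires at least one sample table")
    merged: dict[tuple[str, int, int], Junction] = {}
    for table in tables:
        for j in table:
            cur = merged.get(j.key)
            if cur is None:
                merged[j.key] = replace(j, n_samples=1 if j.unique_reads > 0 else 0)
            else:
                cur.unique_reads += j.unique_reads
                cur.max_overhang = max(cur.max_overhang, j.max_overhang)
                if j.unique_reads > 0:
                    cur.n_samples += 1
                if cur.star_strand == "?":
                    cur.star_strand = j.star_strand
                    cur.strand = j.strand
    out = [j for j in merged.values()]
    out.sort(key=lambda j: j.key)
    return out


def filter_min_samples(junctions: Iterable[Junction], min_samples: int = 3) -> list[Junction]:
    """Keep junctions detected in at least ``min_samples`` independent samples.

    The default of 3 removes spurious junctions seen in fewer than three
    samples; ``min_samples=1`` is the identity.  Input order is preserved.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    return [j for j in junctions if j.n_samples >= min_samples]


def filter_min_overhang(junctions: Iterable[Junction], min_overhang: int = 0) -> list[Junction]:
    """Optionally drop junctions whose maximum overhang is below a threshold."""
    if min_overhang <= 0:
        return list(junctions)
    return [j for j in junctions if j.max_overhang >= min_overhang]


@dataclass
class StrandReport:
    """Bookkeeping from strand assignment."""

    retained: int = 0
    intergenic: int = 0
    conflicting: int = 0
    #: retained junctions whose aligner strand disagreed with the gene strand
    star_disagreements: int = 0

    @property
    def discarded(self) -> int:
        return self.intergenic + self.conflicting


class GeneIndex:
    """Interval index of gene spans built from the ``gene`` lines of a GTF."""

    def __init__(self, genes: Iterable[tuple[str, int, int, str]]):
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for chrom, start, end, strand in genes:
            if strand not in ("+", "-"):
                raise AnnotationError(f"gene without usable strand: {chrom}:{start}-{end}")
            # interval end is exclusive
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, strand)
            n += 1
        self.n_genes = n

    @classmethod
    def from_gtf(cls, gtf_path: Union[str, Path]) -> "GeneIndex":
        gtf_path = Path(gtf_path)
        if not gtf_path.exists():
            raise AnnotationError(f"GTF not found: {gtf_path}")
        try:
            db = gffutils.create_db(
                str(gtf_path),
                dbfn=":memory:",
                force=True,
                keep_order=True,
                disable_infer_genes=True,
                disable_infer_transcripts=True,
            )
        except Exception as exc:  # gffutils raises assorted parse errors
            raise AnnotationError(f"unreadable GTF {gtf_path}: {exc}") from exc
        genes = [
            (f.seqid, f.start, f.end, f.strand) for f in db.features_of_type("gene")
        ]
        if not genes:
            raise AnnotationError(f"no 'gene' features found in {gtf_path}")
        return cls(genes)

    def strands_containing(self, chrom: str, start: int, end: int) -> set[str]:
        """Strands of all genes whose span fully contains [start, end]."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {
            iv.data
            for iv in tree.overlap(start, end + 1)
            if iv.begin <= start and iv.end >= end + 1
        }


def assign_strand(
    junctions: Iterable[Junction],
    annotation: Union[str, Path, GeneIndex],
) -> tuple[list[Junction], StrandReport]:
    """Resolve each junction's strand from the containing gene's strand.

    A junction is retained when the gene spans containing its full intron
    agree on one strand; junctions contained in no gene (intergenic) or in
    genes of opposite strand (conflicting) are discarded and tallied in the
    report.  The GTF-derived strand overrides the aligner's strand column;
    disagreements are counted and logged.
    """
    index = annotation if isinstance(annotation, GeneIndex) else GeneIndex.from_gtf(annotation)
    retained: list[Junction] = []
    report = StrandReport()
    for j in junctions:
        strands = index.strands_containing(j.chrom, j.intron_start, j.intron_end)
        if not strands:
            report.intergenic += 1
        elif len(strands) > 1:
            report.conflicting += 1
        else:
            (strand,) = strands
            if j.star_strand != "?" and j.star_strand != strand:
                report.star_disagreements += 1
            retained.append(replace(j, strand=strand))
    report.retained = len(retained)
    if report.star_disagreements:
        logger.warning(
            "%d junctions kept with gene strand overriding the aligner strand",
            report.star_disagreements,
        )
    return retained, report


def junction_sites(junction: Junction) -> tuple[SpliceSite, SpliceSite]:
    """Return the (donor, acceptor) sites of a strand-resolved junction.

    ``+`` strand: the left intron end is the 5' donor, the right end the 3'
    acceptor.  ``-`` strand: the roles are swapped.
    """
    if junction.strand == "+":
        donor_pos, acceptor_pos = junction.intron_start, junction.intron_end
    elif junction.strand == "-":
        donor_pos, acceptor_pos = junction.intron_end, junction.intron_start
    else:
        raise ValueError("junction strand must be resolved to + or - first")
    donor = SpliceSite(junction.chrom, donor_pos, junction.strand, DONOR)
    acceptor = SpliceSite(junction.chrom, acceptor_pos, junction.strand, ACCEPTOR)
    return donor, acceptor
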