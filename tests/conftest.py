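import numpy as np
import pytest

from spliceshape import Junction


@pytest.fixture
def sj_file(tmp_path):
    """Write SJ.out.tab lines to a temp file and return its path."""

    def _write(lines, name="sample.SJ.out.tab"):
        p = tmp_path / name
        p.write_text("".join(line + "\n" for line in lines))
        return p

    return _write


@pytest.fixture
def gtf_file(tmp_path):
    """Write minimal Ensembl-style gene lines to a GTF and return its path."""

    def _write(genes, name="genes.gtf"):
        # genes: iterable of (chrom, start, end, strand, gene_id)
        lines = []
        for chrom, start, end, strand, gid in genes:
            attrs = f'gene_id "{gid}"; gene_name "{gid}";'
            lines.append(
                "\t".join(
                    [chrom, "test", "gene", str(start), str(end), ".", strand, ".", attrs]
                )
            )
        p = tmp_path / name
        p.write_text("".join(line + "\n" for line in lines))
        return p

    return _write


def make_junction(chrom="chr1", start=100, end=200, strand="+", reads=10, **kw):
    return Junction(
        chrom=chrom,
        intron_start=start,
        intron_end=end,
        strand=strand,
        unique_reads=reads,
        star_strand=kw.pop("star_strand", strand),
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
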