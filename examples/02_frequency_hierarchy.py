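"""Group junctions into alternative-site sets and inspect f(k,M) and mf(k,M).

Parses the synthetic dataset from example 01 (generating it if needed),
merges samples, applies the 3-sample detection filter, resolves strands
from the GTF, and prints the frequency hierarchy of donor-anchored groups.
"""

from pathlib import Path

from spliceshape import (
    SyntheticConfig,
    assign_strand,
    filter_min_samples,
    frequencies,
    generate,
    group_by_anchor,
    median_frequency_matrix,
    merge_samples,
    parse_sj_tab,
)

out = Path("scratch/example_dataset")
if not (out / "genes.gtf").exists():
    generate(SyntheticConfig(a_true=0.14, n_genes=1000, depth=5000,
                             n_samples=3, seed=42), out)

tables = [parse_sj_tab(p) for p in sorted(out.glob("*.SJ.out.tab"))]
merged = merge_samples(tables)
kept = filter_min_samples(merged, 3)
stranded, report = assign_strand(kept, out / "genes.gtf")
print(f"{len(merged)} merged junctions, {len(kept)} in >=3 samples, "
      f"{report.retained} strand-resolved ({report.discarded} discarded)")

groups = group_by_anchor(stranded, "donor")
pair = next(g for g in groups if g.M == 2)
f = frequencies(pair).f
print(f"one donor with M=2 alternative acceptors: f(1,2)={f[0]:.3f}, f(2,2)={f[1]:.3f}")

mf = median_frequency_matrix(groups)
print("median top-site frequency mf(1,M) by multiplicity M:")
for M in (1, 2, 3, 5):
    if mf.group_counts[M - 1]:
        print(f"  M={M:2d}: mf(1,M)={mf.cell(1, M):.3f}  ({mf.group_counts[M-1]} groups)")
print("mf(1,M) near 1 means one acceptor dominates each donor site - the")
print("signature of a small Weibull shape parameter (high splicing efficiency).")
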