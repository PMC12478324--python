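"""Generate a synthetic multi-sample splice-junction dataset.

Writes STAR-style SJ.out.tab tables for several samples, a matching gene
annotation (GTF) and a ground-truth table, for a known Weibull shape
parameter.  Every downstream stage can then be checked against the truth.
"""

from pathlib import Path

from spliceshape import SyntheticConfig, generate, parse_sj_tab

out = Path("scratch/example_dataset")
config = SyntheticConfig(a_true=0.14, n_genes=1000, depth=5000, n_samples=3, seed=42)
dataset = generate(config, out)

junctions = parse_sj_tab(dataset.sj_paths[0])
print(f"wrote {len(dataset.sj_paths)} samples to {out}")
print(f"sample 1 contains {len(junctions)} junctions; first three:")
for j in junctions[:3]:
    print(f"  {j.chrom}:{j.intron_start}-{j.intron_end}  reads={j.unique_reads}")
print("Each junction line is one observed splicing event; its read count is")
print("the expression level of that donor-acceptor pair in that sample.")
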