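"""Dual-criterion differential expression across regeneration time points.

A gene is DE only when it passes BOTH a simple TPM fold-change screen
(>=1.7) and the negative-binomial Wald test (|log2FC| >= log2 1.7 and
BH-adjusted p < 0.05), evaluated separately at each time point against the
matched control.
"""

import numpy as np

from lncdisc import SimConfig, call_de, gen_counts

cfg = SimConfig(seed=1, n_genes_counts=2000, de_fraction=0.05)
counts, tpm, meta, truth = gen_counts(cfg)
meta = meta.set_index("sample_id")
print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples "
      f"({len(cfg.time_points)} time points, control vs regeneration, "
      f"{cfg.n_reps_counts} replicates each)")

table, summary = call_de(counts, tpm, meta)
print("\nup/down DE calls per regeneration stage:")
for stage, ud in summary["per_stage"].items():
    print(f"  {stage:6s} up={ud['up']:<4d} down={ud['down']}")
print(f"union across stages: {summary['n_union']} genes; "
      f"DE at every stage: {summary['n_always']}")

m = table.merge(truth, on=["gene_id", "time_point"])
planted = m[m.is_de]
print(f"\nplanted-effect recovery: {planted.de_call.mean():.2f} "
      f"(fold changes {sorted(set(np.round(2.0**np.abs(planted.true_log2fc), 1)))})")
# The intersection rule mirrors a conservative screen: only genes that move
# enough in TPM *and* are statistically supported at the count level count.
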