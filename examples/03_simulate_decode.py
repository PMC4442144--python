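"""Simulate a 100:10:1 isoform mixture and decode it back.

Three isoforms are mixed at a 100:10:1 molar ratio, ligated in silico,
sequenced as overlapping 250-nt paired-end reads, merged and decoded.  The
recovered percentages should match the input ratio to within multinomial
sampling error — the quantitative-recovery property of the assay.
"""

import seqzip as sz

model = sz.synth_gene(variants_per_cluster=[2, 2, 2], exon_length=60,
                      block_length=60, similarity=0.5, seed=3)
pools = sz.plan_dual_pools(model, barcode_seed=5)
keys = sz.enumerate_isoforms(model)[:3]
props = dict(zip(keys, (100.0, 10.0, 1.0)))

sim = sz.SimConfig(seed=23, n_molecules=8_000, proportions=props)
res = sz.run_simulation(model, pools, sim)
table, assigns = sz.decode_pairs(res.reads, model, pools)

n = table.assigned_total
print(f"decoded {n}/{len(res.reads)} read pairs; status totals: "
      f"{table.status_totals}\n")
print(f"{'isoform':<20}{'input %':>10}{'recovered %':>14}")
total_w = sum(props.values())
for k in keys:
    print(f"{k:<20}{100 * props[k] / total_w:>10.2f}"
          f"{100 * table.counts.get(k, 0) / n:>14.2f}")
# Error-free reads decode completely and the three-order-of-magnitude
# input ratio is recovered to within sampling noise.
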