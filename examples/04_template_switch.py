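"""Detect template switching with dual differentially barcoded pools.

The sample is split across two ligamer pools that differ only in their
internal barcodes.  A genuine single-molecule product carries barcodes from
one pool; a chimera assembled across molecules mixes the two — the switch
signature.  At switch_rate=0 the decoder reports exactly zero switched
reads; at 2% it recovers the simulated rate.
"""

import seqzip as sz

model = sz.synth_gene(variants_per_cluster=[2, 2, 2], exon_length=60,
                      block_length=60, similarity=0.5, seed=3)
pools = sz.plan_dual_pools(model, barcode_seed=5)
keys = sz.enumerate_isoforms(model)[:3]

for rate in (0.0, 0.02):
    sim = sz.SimConfig(seed=22, n_molecules=5_000,
                       proportions={k: 1.0 for k in keys}, switch_rate=rate)
    res = sz.run_simulation(model, pools, sim)
    _table, assigns = sz.decode_pairs(res.reads, model, pools)
    rep = sz.switch_report(assigns)
    truth = (res.truth["artifact"] == "switched").mean()
    print(f"simulated switch rate {rate:.0%}: decoder reports "
          f"{rep.n_switched}/{rep.n_total} switched "
          f"({rep.fraction:.3%}); truth ledger {truth:.3%}")
# The decoded fraction tracks the simulated rate because every internal
# ligamer is differentially coded, so any cross-molecule junction is visible.
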