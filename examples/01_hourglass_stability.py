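"""Whole-embryo developmental stability across stages (the hourglass pattern).

Simulates sex-matched inbred twin embryos at four developmental stages with
an hourglass noise profile, computes the whole-embryo variation V for every
twin pair, and tests stage differences with Kruskal-Wallis + Steel-Dwass.
A smaller mean V means the stage is developmentally more stable; the two
mid ("phylotypic") stages should come out most stable.
"""
import devstab as ds

cfg = ds.SimulationConfig(n_genes=2000, n_pairs_per_stage=20, seed=1)
per_stage = {}
for stage in cfg.stages:
    tpm, _ = ds.simulate_twin_matrix(cfg, stage)
    logm = ds.log_transform(tpm)
    pairs = ds.twin_pairs(logm.metadata)
    per_stage[stage] = ds.stage_stability(logm, pairs)
    print(f"{stage:>7}: mean V over {len(pairs)} twin pairs = {per_stage[stage].mean:.4f}")

comp = ds.compare_stages({s: r.values for s, r in per_stage.items()})
print(f"\nKruskal-Wallis: H = {comp.h:.1f}, p = {comp.p:.2e}")
print("Steel-Dwass pairwise p (smaller = stages differ):")
print(comp.pairwise_p.round(4))
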