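"""Regulatory features around TSSs: peaks, substitutions, TATA boxes.

Simulates a toy genome, assigns open-chromatin peaks to the gene with the
closest TSS (distal +/-5 kb, proximal -100..+50 bp windows, strict
more-than-half overlap rule), counts homozygous substitutions inside the
retained regions across 8 resequenced samples, and scans 150-bp proximal
promoters for the four exact TATA-box motifs on both strands.
"""
import devstab as ds

cfg = ds.SimulationConfig(n_genes=200, n_pairs_per_stage=2, seed=6)
annotation, truth = ds.simulate_genome_annotation(cfg)

features = ds.regulatory_features(annotation)
print("per-gene regulatory features (first rows):")
print(features.head())
print(f"\nmean retained peaks/gene:  {features['n_peaks'].mean():.2f}")
print(f"mean substitution events:  {features['n_snps'].mean():.2f} (summed over 8 samples)")
print(f"mean TATA matches/promoter: {features['n_tata'].mean():.2f}")
match = (features["n_tata"].to_numpy() == truth.tata_counts.to_numpy()).all()
print(f"scanner reproduces planted TATA counts exactly: {match}")

print(f"\nscan_tata('TATATATATATA') = {ds.scan_tata('TATATATATATA')} "
      "(3 two-base-shifted forward matches + 3 on the reverse strand)")
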