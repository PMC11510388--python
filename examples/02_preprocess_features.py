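"""Preprocess an ASV count table: filter, rarefy, normalise, aggregate.

Generates a small synthetic cohort, then applies the standard amplicon
preprocessing chain and prints what each step did to the table.
"""

from asdgm.features import aggregate_at_rank, css_normalize, filter_features, rarefy
from asdgm.synth import SynthConfig, generate_cohort

cohort = generate_cohort(SynthConfig(n_cases=20, n_controls=10, n_asv=120, seed=42))
table = cohort.case_table
print(f"raw table: {table.shape[0]} ASVs x {table.shape[1]} samples")

# keep ASVs present in >=25% of samples AND exceeding 1% relative abundance
filtered, removal_log = filter_features(table)
print(f"after filtering: {filtered.shape[0]} ASVs "
      f"({len(removal_log)} removed; first reasons: "
      f"{removal_log['removed_by'].value_counts().to_dict()})")

# subsample every sample to the smallest library size (for diversity analyses)
rarefied = rarefy(filtered, depth="min", seed=1)
print(f"rarefied depth: {int(rarefied.sample_totals().iloc[0])} reads/sample")

# cumulative sum scaling (for differential-abundance models)
normalized = css_normalize(filtered)
print(f"CSS-normalized value range: {normalized.data.values.min():.2f}"
      f" .. {normalized.data.values.max():.2f}")

# collapse ASVs to genera; per-sample totals are conserved
genus = aggregate_at_rank(filtered, cohort.taxonomy, "genus")
print(f"genus table: {genus.shape[0]} genera (totals conserved: "
      f"{bool((genus.sample_totals() == filtered.sample_totals()).all())})")
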