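"""Generate a synthetic circRNA/lncRNA dataset and extract its features.

Builds a small labeled fixture (toy genome + junction table included), then
computes the full 543-column feature matrix: 341 k-mer frequencies, the ORF
coverage/length pair, and 200 splice-junction codes.
"""

from pcirc import FixtureConfig, build_feature_table, generate_dataset

config = FixtureConfig(n_pos=60, n_neg=60, seed=42)
dataset = generate_dataset(config)
print(f"{len(dataset.records)} records on a {len(dataset.genome['chr1']):,} nt toy genome")

table = build_feature_table(dataset.records, dataset.genome, dataset.junctions)
features = table.drop(columns=["label"])
print(f"feature matrix: {features.shape[0]} records x {features.shape[1]} features")

# circRNA-like positives carry short ORFs, lncRNA-like negatives long ones
medians = table.groupby("label")["ORF_length"].median()
print("median optimal-ORF length by class:")
print(medians.to_string())
# positives should sit at <= config.pos_orf_max nt, negatives >= config.neg_orf_min
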