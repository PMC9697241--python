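"""Euler-region cardinalities of kinase-group target sets.

Builds target sets with planted region cardinalities, recounts the regions,
then applies the two simplification steps: keeping only groups that target
more than 2% of the dataset, and merging groups with identical target sets.
"""
from phosphonet import (
    SyntheticConfig,
    merge_identical,
    prominent_groups,
    region_counts,
    simulate_kinase_targets,
)

cfg = SyntheticConfig(
    seed=3,
    kinase_region_counts={
        ("TK",): 1500,
        ("AGC",): 100,
        ("CMGC",): 80,
        ("AGC", "CMGC", "TK"): 150,
        # STE, CK1 and CAMK appear only in the all-six centre, so their
        # target sets are identical and will merge into one composite group
        ("AGC", "CAMK", "CK1", "CMGC", "STE", "TK"): 224,
        # a tiny group that fails the >2% prominence filter
        ("TKL",): 10,
    },
)
kmap = simulate_kinase_targets(cfg)

regions = region_counts(kmap)
print("regions (signature -> cardinality):")
print(regions.as_frame().to_string(index=False))
print(f"distinct targets: {regions.total}")
# each region holds the proteins phosphorylated by exactly that combination
# of kinase groups; 224 proteins sit in the centre, hit by all six groups.

trimmed = merge_identical(prominent_groups(kmap, fraction=0.02))
print("\nafter the >2% prominence filter and identical-set merge:")
print(region_counts(trimmed).as_frame().to_string(index=False))
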