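"""Group recovery with binned d2S: simulate three community groups,
compare samples, cluster, and score the tree against the truth.

Run:  python examples/group_comparison.py
"""

from afmeta.benchmarks import run_group_analog

result = run_group_analog(seed=1)

frac = result["binned"] / result["max_triplets"]
print(f"samples: {result['n_samples']} (3 groups x 5 replicates)")
print(f"triplet distance, 4 GC bins : {result['binned']}")
print(f"triplet distance, no binning: {result['unbinned']}")
print(f"max possible (all 3-subsets): {result['max_triplets']}")
print(f"binned fraction             : {frac:.3f}")
print()
print("The triplet distance counts 3-sample subsets whose rooted topology")
print("in the UPGMA tree contradicts the true grouping; 0 is perfect")
print("recovery, and a smaller value for the binned statistic means GC-")
print("stratified read binning sharpened the between-sample signal.")
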