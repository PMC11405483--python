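"""EdU S-phase patterns and run-length clustering along cell files.

Nuclei are classified S0 (no EdU), S1 (homogeneous incorporation, early
S phase) or S2 (spotted, heterochromatin-colocalized, late S phase).
Within each longitudinal cell file, consecutive same-state nuclei form
clusters whose size distribution reveals spatial coordination of
replication.
"""

import rootcarto as rc

params = rc.SyntheticParams()
stack, labels, truth = rc.generate_root(params, seed=2)

calls, spots = rc.classify_all(stack, labels)
merged = calls.merge(truth[["id", "edu_pattern"]], on="id")
acc = (merged["pattern"] == merged["edu_pattern"]).mean()
print("pattern counts:", calls["pattern"].value_counts().to_dict())
print(f"classification accuracy vs ground truth: {100 * acc:.1f}%")

overlap = rc.mark_overlap_by_pattern(calls, stack, labels)
summary = rc.summarize_overlap(overlap)
het = summary[summary["mark"] == "heterochromatin"].set_index("pattern")
print(f"EdU×heterochromatin overlap: S1 {het.loc['S1', 'mean_overlap']:.2f}, "
      f"S2 {het.loc['S2', 'mean_overlap']:.2f}")
print("-> spotted S2 incorporation sits on chromocenters (late-replicating"
      " heterochromatin), homogeneous S1 does not.")

annotations = truth.rename(columns={"s": "z_cyl"})[["id", "layer", "file",
                                                    "z_cyl"]]
dist = rc.file_run_lengths(annotations, calls)
for state in ("S0", "S1+S2"):
    hist = dist.histogram(state)
    total = dist.total_runs(state)
    singles = hist.get(1, 0) / total
    pairs = hist.get(2, 0) / total
    print(f"{state}: {total} clusters, mean size "
          f"{dist.mean_run_length(state):.2f}; "
          f"{100 * singles:.1f}% singletons, {100 * pairs:.1f}% pairs")
print("-> cluster-size histograms per state feed the homogeneity test"
      " (compare_cluster_distributions) across tissues or zones.")
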