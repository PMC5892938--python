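"""Cluster a reduced synthetic benchmark and score it against truth.

Run:  python examples/03_benchmark_clustering.py   (~30 s)
"""

from peakclust import KernelParams, build_benchmark, survey_thresholds

# 30 instances per motif + 150 uniform random decoys
ds = build_benchmark(n_per_motif=30, n_decoys=150, seed=13)
table = survey_thresholds(
    list(ds.records),
    KernelParams(R=2, D=2),
    option=11,
    thresholds=[0.30, 0.35, 0.40, 0.45, 0.50, 0.55],
    truth=ds.labels,
    min_samples=10,
)
print(table.round(3).to_string(index=False))
print("\nEach row is one DBSCAN run on the same kernel matrix. n_clusters")
print("counts non-noise clusters (5 = one per motif). VMS is the V-measure")
print("(harmonic mean of homogeneity and completeness) against the true")
print("motif classes, with all decoys one class and all noise one cluster.")
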