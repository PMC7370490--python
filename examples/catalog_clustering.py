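"""Build a non-redundant gene-cassette catalog and assess its diversity.

Runs the pipeline on simulated arrays, deduplicates (attC, ORF) pairs,
prints the catalog's length/GC statistics and abundance, then clusters
the proteins by global-alignment identity at three cutoffs.
"""

from cassettescan import (
    ScanConfig, SimParams, cluster_by_identity, reference_model,
    run_pipeline, simulate_metagenome, summarize,
)

records, truth = simulate_metagenome(SimParams(seed=9, n_contigs=15,
                                               n_arrays=15))
model = reference_model(seed=0)
result = run_pipeline(ScanConfig(), records, model=model)

stats = summarize(result.entries,
                  total_bases_scanned=result.report["total_bases_scanned"],
                  n_attc=result.report["n_attc"])
print(f"catalog: {stats['n_entries']} unique (attC, ORF) pairs")
print(f"  gene length median {stats['length_median']:.0f} nt "
      f"(sd {stats['length_sd']:.0f}); G/C median {stats['gc_median']:.2f} "
      f"(sd {stats['gc_sd']:.2f})")
print(f"  attC abundance: {stats['attc_copies_per_mb']:.1f} copies per "
      f"million bases scanned")
print("  (background false sites and their short spurious genes enter the "
      "catalog too,\n   pulling the length median below the ~400 nt of the "
      "planted genes; see docs/methods.md)")

proteins = [(e.entry_id, e.orf_aa) for e in result.entries][:150]
print(f"\nclustering {len(proteins)} catalog proteins by global identity:")
for cutoff in (0.97, 0.70, 0.50):
    res = cluster_by_identity(proteins, cutoff)
    print(f"  cutoff {cutoff:.2f}: {res.n_clusters} clusters, "
          f"{res.n_singletons} singletons, largest {res.max_cluster_size}")
print("\nA cluster count close to the gene count at every cutoff means the "
      "catalog is\nhighly diverse: most cassette genes have no close "
      "homolog in the set.")
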