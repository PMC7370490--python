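"""Negative control: dinucleotide-preserving shuffle of positive contigs.

Shuffling destroys the planted attC sites while keeping length and exact
dinucleotide composition, so anything the pipeline still reports measures
its false-positive behaviour on realistic background sequence.
"""

from collections import Counter

from cassettescan import (
    ScanConfig, SimParams, reference_model, run_pipeline, shuffle_negative,
    simulate_metagenome,
)

params = SimParams(seed=5, n_contigs=5, n_arrays=5,
                   contig_len=(400_000, 400_000), verify_truth=False)
records, truth = simulate_metagenome(params)
negatives = shuffle_negative(records, seed=5)
mb = sum(len(s) for _, s in negatives) / 1e6

orig = Counter(zip(records[0][1], records[0][1][1:]))
shuf = Counter(zip(negatives[0][1], negatives[0][1][1:]))
print(f"shuffled {len(records)} contigs ({mb:.1f} Mb); dinucleotide table "
      f"preserved exactly: {orig == shuf}")

model = reference_model(seed=0)
result = run_pipeline(ScanConfig(), negatives, model=model)
r = result.report
print(f"\non shuffled sequence the pipeline reports {r['n_raw_hits']} raw "
      f"gHMM hits,\n{r['n_validated_hits']} surviving the structure filter "
      f"({r['n_validated_hits'] / mb:.0f} per Mb),\nand {r['n_arrays']} "
      f"cassette arrays after proximity grouping and singleton removal.")
print("\nThe surviving background density is the pipeline's intrinsic "
      "false-positive rate\nat the score>0 / structure>=0.75 operating "
      "point; docs/methods.md quantifies it.")
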