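"""Per-timepoint differential abundance with the joint FC + p gate.

Simulates the default dataset, converts it to a log2 ratio matrix, tests
each disease timepoint against the grouped controls (two-sample pooled t),
and applies the classic joint gate: fold change > 1.2 (or < 1/1.2) AND
p < 0.05.
"""

from coabund import diffabund, ingest, synth

config = synth.SynthConfig(seed=42)
plexes, truth = synth.simulate_dataset(config)
design = config.design

ratio_tables = {
    p: ingest.reference_ratios(t, design.reference_channel_by_plex[p])
    for p, t in plexes.items()
}
matrix = ingest.log_transform(
    ingest.filter_missing(ingest.merge_plexes(ratio_tables, design), 0.0)
)
print(f"log2 ratio matrix: {matrix.n_proteins} proteins x "
      f"{len(matrix.design.sample_ids)} samples")

print("\ncalls per disease timepoint vs grouped controls (up / down):")
for tp in synth.DISEASE_TIMEPOINTS:
    spec = diffabund.timepoint_vs_grouped_controls(tp)
    table = diffabund.classify_de(diffabund.pairwise_de(matrix, spec))
    counts = table["call"].value_counts()
    truth_up = (truth.de_status(tp) == "up").sum()
    truth_down = (truth.de_status(tp) == "down").sum()
    print(f"  {tp:4s}: called {counts.get('up', 0):4d} up / "
          f"{counts.get('down', 0):4d} down   "
          f"(planted: {truth_up} up / {truth_down} down)")

print("\nCalls track the planted effects; excess calls at a timepoint come")
print("from partial-strength planted shifts plus the ~5% testwise error the")
print("fold-change gate keeps in check.")
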