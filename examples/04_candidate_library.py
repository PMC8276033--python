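"""Build a permutation candidate library and assemble a validation batch.

Derives per-position high-frequency residue sets from a (synthetic) training
batch, enumerates the Cartesian product, scores it with a small ensemble and
selects a stratified strong/weak validation batch.
"""
from ersnet import (
    ModelConfig,
    assemble_validation_batch,
    default_ground_truth,
    enumerate_candidates,
    high_frequency_sets,
    kdel_enriched_tails,
    rank_candidates,
    sample_dataset,
    train_ensemble,
)

gt = default_ground_truth(seed=3)
batch = sample_dataset(gt, kdel_enriched_tails(enrichment=8), n=95, seed=5)

# residues reaching >= 7% frequency at each position span the library
sets = high_frequency_sets(batch, threshold=0.07)
print("per-position sets:", sets.sets)
print("library size (product of set sizes):", sets.n_candidates)

ensemble = train_ensemble(batch, n_models=2,
                          config=ModelConfig(iterations=200), base_seed=0)
ranked = rank_candidates(enumerate_candidates(sets), ensemble, top_n=None)
print("\ntop candidates by RNN score:")
print(ranked.head(5).to_string(index=False))

lo, hi = ranked["score"].quantile([0.25, 0.75])
selected = assemble_validation_batch(
    ranked,
    proteome_tails=set(),            # no proteome here: everything is artificial
    first_batch=[r.tail for r in batch],
    n_strong=4, n_weak=2,
    strong_cutoff=float(hi), weak_cutoff=float(lo),
    artificial_fraction=1.0,
)
print("\nselected validation batch (strong = predicted responders):")
print(selected.table.to_string(index=False))
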