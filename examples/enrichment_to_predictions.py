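"""From raw selection counts to phenotype predictions with uncertainty.

Builds a tiny count table for a 2-site nucleotide library, converts it to
wild-type-anchored log-enrichment scores with pseudocount error variances,
fits a geometric-decay GP, and predicts the one unobserved genotype.
"""

import pandas as pd

import seqgp as sg

counts = pd.DataFrame(
    {
        "sequence": ["AA", "AC", "CA", "GA", "GC", "CC", "AG"],
        "count_input": [120, 95, 110, 130, 80, 100, 90],
        "count_selected": [120, 260, 30, 10, 55, 140, 200],
        "wildtype": [True, False, False, False, False, False, False],
    }
)

table = sg.log_enrichment(counts)
print("log-enrichment scores (relative to wild type AA):")
for seq, y, v in zip(table.sequences, table.y, table.y_var):
    print(f"  {seq}: y = {y:+.3f}  (measurement var {v:.4f})")

model = sg.fit_hyperparameters(table, "geometric", seed=0)
print(f"\nfitted geometric kernel: sigma^2 = {model.kernel.sigma2:.3f}, "
      f"delta = {model.kernel.delta:.3f}, "
      f"uniform noise = {model.noise.uniform_var:.4f}")

unseen = [s for s in table.space.enumerate_sequences() if s not in table.sequences]
pred = sg.posterior_predict(model, unseen)
print("\nposterior for unobserved genotypes:")
for seq, m, v in zip(pred.sequences, pred.mean, pred.var):
    print(f"  {seq}: mean {m:+.3f}, sd {v**0.5:.3f}")
# The posterior sd quantifies how far each unobserved genotype sits from the
# measured ones under the learned correlation decay per mutation.
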