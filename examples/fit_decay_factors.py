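"""Recover site-specific decay factors from a simulated landscape ensemble.

Draws 200 independent landscapes from a connectedness prior on a 5-site
biallelic space, then refits the prior by evidence maximization.  Each decay
factor delta_p is the fraction of phenotype correlation lost when site p is
mutated; recovering them within a few hundredths shows the
generative-inferential loop is consistent.
"""

import numpy as np

import seqgp as sg

space = sg.SequenceSpace.uniform(5, 2)
true_delta = np.array([0.7, 0.5, 0.3, 0.2, 0.1])
prior = sg.ConnectednessKernel(space, sigma2=1.0, delta=true_delta)

tables = sg.simulate_replicate_tables(prior, n_landscapes=200, seed=42)
model = sg.fit_hyperparameters(tables, "connectedness", seed=1)

print("site   true delta   fitted delta")
for lab, t, f in zip(space.site_labels, true_delta, model.kernel.delta):
    print(f"{lab:>4}   {t:10.2f}   {f:12.3f}")
print(f"prior variance sigma^2: fitted {model.kernel.sigma2:.3f} (true 1.0)")
print(f"log evidence: {model.evidence:.1f} nats")
# Each fitted delta should sit within ~0.05 of its generating value; the
# uniform noise term absorbs any residual sequence-independent variance.
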