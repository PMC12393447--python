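"""Variance-component spectra of three landscape priors.

Projects each kernel onto the interaction-order eigenspaces of the Hamming
graph.  lambda_k is the expected variance carried by order-k interactions:
a smooth geometric kernel concentrates variance at low orders, the
House-of-Cards kernel spreads it in proportion to the eigenspace dimensions,
and raising any decay factor shifts weight toward higher orders.
"""

import numpy as np

import seqgp as sg
from seqgp.spectral import variance_components

space = sg.SequenceSpace.uniform(4, 2)

kernels = {
    "geometric (delta=0.2)": sg.GeometricKernel(space, 1.0, 0.2),
    "connectedness (0.8,0.4,0.2,0.1)": sg.ConnectednessKernel(
        space, 1.0, [0.8, 0.4, 0.2, 0.1]
    ),
    "House-of-Cards": sg.hoc_kernel(space, 1.0),
}

print(f"{'prior':35} " + " ".join(f"lam_{k}" for k in range(5)))
for name, kern in kernels.items():
    lam = variance_components(kern).lambdas
    print(f"{name:35} " + " ".join(f"{v:5.3f}" for v in lam))
print()
print("Rows sum to sigma^2 = 1.  The HoC row equals C(4,k)/16 — the")
print("dimension of each interaction order's eigenspace over the 16 genotypes.")
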