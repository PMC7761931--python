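"""From band-limited epochs to a PLV matrix and weighted graph features.

One synthetic subject has a strongly coupled node pair (0,1) in the alpha
band; all other pairs are uncoupled noise. The PLV matrix shows the planted
edge, and the graph metrics condense the matrix into the classification
features: local clustering per node, global clustering, and path length.
"""

import numpy as np

from srcnet import (
    CohortConfig,
    CouplingSpec,
    assemble_features,
    bandpass,
    generate_cohort,
    get_band,
    plv_matrix,
)

cfg = CohortConfig(
    n_subjects_per_group=1, n_nodes=6, fs=250.0, n_epochs=10, noise_sd=2.0,
    group_coupling=[[CouplingSpec("alpha", ((0, 1, 0.3),), 10.0)]], seed=3,
)
subject = generate_cohort(cfg)[0]

filtered = bandpass(subject.epochs, get_band("alpha"))
mat = plv_matrix(filtered, band=get_band("alpha"))
print("alpha-band PLV matrix (coupled edge 0-1 planted with sigma=0.3):")
print(np.array_str(mat.values, precision=2, suppress_small=True))
print(f"\ncoupled pair PLV(0,1) = {mat.values[0, 1]:.3f} "
      f"(expected ~exp(-0.3^2/2) = {np.exp(-0.045):.3f} plus finite-sample bias)")
print(f"median uncoupled PLV  = {np.median(mat.values[2:, 2:][np.triu_indices(4, 1)]):.3f} "
      "(finite-sample noise floor)")

fv = assemble_features([mat])
print(f"\nfeature vector: {len(fv)} entries = 6 local CC + global CC + path length")
for name, value in zip(fv.names(), fv.values):
    print(f"  {name:28s} {value:.3f}")
print("\nNodes 0 and 1 carry the highest local clustering: the planted edge"
      "\nstrengthens every triangle through them.")
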