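"""PCA of three diverged populations plus an admixed group.

On the first two principal components the three source populations sit at
the apexes of a triangle and the admixed population falls at an interior
position set by its ancestry proportions.
"""

import numpy as np

from popassign import SimulationConfig, run_pca, simulate_study, \
    write_pca_outputs

config = SimulationConfig(
    n_populations=3, n_individuals=30, n_markers=3000, fst=0.1,
    admixed=[((0.4, 0.35, 0.25), 30)], seed=9)
dataset, _freqs, _truth = simulate_study(config)

result = run_pca(dataset, n_components=2)
pops = np.asarray(result.populations)
print("population   PC1 centroid   PC2 centroid")
for pop in ("POP01", "POP02", "POP03", "ADM01"):
    c = result.coordinates[pops == pop].mean(axis=0)
    print(f"{pop:12s} {c[0]:12.3f} {c[1]:14.3f}")
print(f"variance explained: PC1 {result.variance_fractions[0]:.1%}, "
      f"PC2 {result.variance_fractions[1]:.1%}")

write_pca_outputs(result, "output.pca.evec", "output.eval")
print("wrote output.pca.evec and output.eval")
# The ADM01 centroid lies inside the POP01/POP02/POP03 triangle, pulled
# toward POP01 in proportion to its 40% ancestry share.
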