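"""Simulate a differentiated panel, add missingness, and run the QC cascade.

Builds three Balding-Nichols populations, knocks out 3% of calls, and
pushes the data through the call-rate / HWE / MAF filter cascade.
"""

from popassign import QcConfig, SimulationConfig, inject_missingness, \
    run_qc, simulate_reference

config = SimulationConfig(n_populations=3, n_individuals=20,
                          n_markers=2000, fst=0.1, seed=7)
dataset, _freqs = simulate_reference(config)
dataset = inject_missingness(dataset, rate=0.03, seed=8)

filtered, summary = run_qc(dataset, QcConfig())

print(f"input: {dataset.n_samples} samples x {dataset.n_markers} markers")
for stage in summary.stages:
    print(f"  {stage.name:22s} samples {stage.n_samples_in:3d} -> "
          f"{stage.n_samples_out:3d}   markers {stage.n_markers_in:5d} -> "
          f"{stage.n_markers_out:5d}")
print(f"output: {filtered.n_samples} samples x {filtered.n_markers} markers")
# Each stage line shows what the filter removed: individuals below a 95%
# call rate, markers below 75%, markers failing the exact HWE test at
# P < 0.001 (pooling two diverged populations inflates rejections), and
# markers with MAF < 1%.
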