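"""Rank reference populations by allele sharing distance to a query.

ASD between two individuals is one minus the mean proportion of alleles
alike in state over loci genotyped in both; the closest populations by
mean ASD are the query's best distance-based assignment candidates.
"""

from popassign import SimulationConfig, asd_query_vs_reference, \
    population_asd_summary, simulate_study

config = SimulationConfig(
    n_populations=4, n_individuals=15, n_markers=3000, fst=0.15,
    admixed=[((1.0, 0.0, 0.0, 0.0), 2)], seed=3)
dataset, _freqs, _truth = simulate_study(config)

queries = [s.id for s in dataset.samples if s.population == "ADM01"]
references = [s.id for s in dataset.samples if s.population != "ADM01"]
matrix = asd_query_vs_reference(dataset, queries, references)
summary = population_asd_summary(matrix, top_n=4)

print(summary.to_string(index=False,
                        float_format=lambda v: f"{v:.4f}"))
# The queries were drawn purely from POP01, so POP01 should head each
# ranking with the smallest mean ASD; the min/max columns show the spread
# of distances to that population's individuals.
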