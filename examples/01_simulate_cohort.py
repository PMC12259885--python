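"""Generate a small synthetic annotated-genome cohort and inspect it.

The generator plants defense islands, MGE-borne accessory systems and a
logistic trait ceiling, and records everything in the returned truth
object, so every downstream stage can be checked against known answers.
"""

from defensome import CohortParams, IslandSpec, generate_cohort, validate_cohort

params = CohortParams(n_genomes=25, seed=42,
                      island_spec=IslandSpec(n_islands=3))
cohort, truth = generate_cohort(params)

diag = validate_cohort(cohort)
print(f"genomes: {diag.n_genomes}, genes: {diag.n_genes}, "
      f"systems: {diag.n_systems}, MGEs: {diag.n_mges}, "
      f"violations: {len(diag.violations)}")
print(f"planted islands: {len(truth.planted_islands)}")
for p in truth.planted_islands:
    print(f"  {p.genome_id} {p.contig_id} genes {p.first_index}-"
          f"{p.last_index}, {p.n_defense} defense genes, "
          f"families {sorted(p.families)}")
# A valid cohort reports zero violations; the planted islands all satisfy
# the detection rule (>=5 defense genes, >=3 families, gaps <=10).
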