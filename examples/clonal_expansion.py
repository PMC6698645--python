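"""Drift versus "survival of the smallest" in a Moran model of mtDNA.

Simulates cells holding two deletion species under neutral drift
(alpha = 0) and under a length-dependent replicative advantage
(w = (L_wt/L)^alpha), then asks how often the smallest genome ends up
most prevalent and how compatible an observed 4-of-10 count is with each
regime.
"""

from mitofibre import clonalsim as cs

species = (
    cs.SpeciesSpec("del_10kb", genome_length_kb=6.6, initial_copies=100),
    cs.SpeciesSpec("del_5kb", genome_length_kb=11.6, initial_copies=100),
)

for alpha in (0.0, 0.5, 1.0, 2.0):
    cfg = cs.SimConfig(species=species, alpha=alpha, n_steps=2000,
                       n_cells=2000, seed=7)
    s = cs.simulate_cohort(cfg)
    p = cs.compare_to_observed(s, observed_numerator=4, observed_denominator=10)
    print(f"alpha = {alpha:3.1f}: smallest-most-prevalent fraction = "
          f"{s.smallest_most_prevalent_fraction:.3f} "
          f"({s.n_multi_species_cells} multi-species cells), "
          f"P(4/10 observed | model) = {p:.4f}")

print()
print("At alpha = 0 the two species are exchangeable and the fraction sits")
print("near 0.5; increasing alpha hands the short genome a replication edge")
print("and drives the fraction towards 1. The exact binomial probability")
print("shows which regimes could plausibly generate an observed 4/10 count.")
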