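"""Species proportions from limiting-dilution single-molecule PCR.

Shows the Poisson dilution arithmetic (occupancy from the positive-well
fraction, dilution planning, co-occupancy risk) and recomputes, from the
bundled 79-fibre table, how often the largest deletion (smallest mtDNA
molecule) is the most prevalent species in fibres carrying several
deletions — the readout that tests "survival of the smallest".
"""

from mitofibre import pipeline, smpcr

est = smpcr.estimate_lambda(24, 96)
print(f"24/96 wells positive -> lambda = {est.lam:.4f} molecules/well "
      f"(95% CI {est.ci_lambda[0]:.3f}-{est.ci_lambda[1]:.3f})")
print(f"P(>=2 molecules | positive well) = "
      f"{smpcr.multiplicity_probability(est.lam):.3f}")
print(f"template at lambda = 1.15 needs a {smpcr.dilution_factor(1.15):.3f}x dilution "
      "to reach the 1-in-4 operating point")
print()

cells = smpcr.summaries_from_table(pipeline.load_reference_tables()["smpcr"])
print(smpcr.multiplicity_distribution(cells).to_string(index=False))
print()
print(smpcr.largest_prevalence(cells).to_string(index=False))
print()
print("Across the three patients the largest deletion is strictly most")
print("prevalent in ~40% of multi-deletion fibres - about what symmetric")
print("drift would give, not the excess a strong replicative advantage")
print("for smaller genomes would predict. Flagged rows (tied sizes,")
print("proportions not summing to 1) are surfaced, never corrected.")
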