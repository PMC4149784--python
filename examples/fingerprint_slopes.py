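"""Two-condition regulon fingerprint from a synthetic study.

Simulates triplicate RPKM expression for wild-type cells (untreated,
copper-only, copper + ionophore), computes replicate fold changes against
the untreated reference, keeps the significant >= 2-fold responders to the
ionophore, and fits the iron-group and copper-group lines.  Copper-regulon
genes respond identically with or without the ionophore (slope ~ 1); the
iron regulons respond only to the ionophore-induced functional iron
deficiency (slope ~ 0) — the two-line fingerprint of high copper plus low
iron signalling.
"""

import regulonprint as rp

cfg = rp.SimConfig(seed=42)
matrix, truth = rp.gen_expression(cfg)

fc_ionophore = rp.fold_changes(matrix, ("wt", "untreated"), ("wt", "cubpq"))
fc_cu_only = rp.fold_changes(matrix, ("wt", "untreated"), ("wt", "cu"))

points = rp.assemble_fingerprint(fc_ionophore, fc_cu_only, truth.annotation())
lines = rp.fit_group_lines(points)

print(f"{len(points)} genes respond significantly >= 2-fold to Cu + ionophore")
for line in lines.values():
    print(f"  {line.group:6s} line: slope {line.slope:+.3f}, "
          f"intercept {line.intercept:+.2f}, n = {line.n}")

strong = rp.threshold_table(fc_ionophore, cutoff=4.5, direction="up")
print(f"\ngenes > 4.5-fold up under Cu + ionophore (fold, SD, class):")
for gene, row in strong.iterrows():
    cls = truth.genes.at[gene, "cls"]
    print(f"  {gene:10s} {row['fold']:5.1f} ({row['fold_sd']:.2f})  {cls}")
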