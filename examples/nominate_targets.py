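"""Candidate-target nomination by joining expression calls with motif scans.

Generates promoter/3'-UTR sequences with consensus sites embedded in the
planted candidate genes, scans both consensi (the AU-rich element
UUAUUUAUU + octamer derivatives on the 3'-UTR sense strand; the Aft1 site
PyPuCACCCPu on both promoter strands), and nominates unknown-class genes:
down >= 2-fold with a 3'-UTR ARE (candidate Cth2 targets) or up >= 2-fold
with a promoter Aft1 site (candidate Aft1/2 targets).
"""

import pandas as pd

import regulonprint as rp

cfg = rp.SimConfig(seed=7)
matrix, truth = rp.gen_expression(cfg)
regions = rp.gen_regions(cfg, truth)

fc_ionophore = rp.fold_changes(matrix, ("wt", "untreated"), ("wt", "cubpq"))
fc_cu_only = rp.fold_changes(matrix, ("wt", "untreated"), ("wt", "cu"))
points = rp.assemble_fingerprint(fc_ionophore, fc_cu_only, truth.annotation())

matches = pd.concat([rp.scan(regions, rp.ARE_CONSENSUS),
                     rp.scan(regions, rp.AFT_CONSENSUS)], ignore_index=True)
report = rp.nominate_candidates(points, matches)

print(f"{len(matches)} motif matches across {len(regions)} regions")
print(f"candidate Cth2 targets (down >= 2-fold, ARE in 3'-UTR): "
      f"{', '.join(report.cth2_candidates)}")
print(f"candidate Aft targets  (up >= 2-fold, Aft1 site in promoter): "
      f"{', '.join(report.aft_candidates)}")

planted = sorted(truth.candidate_genes("Cth2") + truth.candidate_genes("Aft"))
print(f"planted ground truth:  {', '.join(planted)}")
print("\nsupporting matches for the first candidate:")
first = (report.cth2_candidates + report.aft_candidates)[0]
print(report.support[report.support.gene == first].to_string(index=False))
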