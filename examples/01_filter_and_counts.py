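"""Exclusion-rule bookkeeping on the deterministic fixtures.

Builds the two fixture cohorts, applies each drug's exclusion rules and
prints the before/after counts.  The 5FU rules drop samples below the
assay limit (52 ng/mL = 0.052 mg/L) or implying a steady-state clearance
D/(IT*C) above 1478 L/h; the sunitinib rule drops parent samples below
0.06 ng/mL together with their paired metabolite record.
"""

from mmpk import (apply_exclusions_5fu, apply_exclusions_sunitinib,
                  generate_acceptance_fixture_5fu,
                  generate_acceptance_fixture_sunitinib)

ds = generate_acceptance_fixture_5fu()
out, rep = apply_exclusions_5fu(ds)
print(f"5FU: {ds.n_observations()} obs / {ds.n_patients} patients"
      f" -> {out.n_observations()} obs / {out.n_patients} patients"
      f"  (excluded {rep.excluded_by_reason})")

ds2 = generate_acceptance_fixture_sunitinib()
out2, rep2 = apply_exclusions_sunitinib(ds2)
print(f"sunitinib: {ds2.n_observations('parent')} parent + "
      f"{ds2.n_observations('metab')} metabolite obs / {ds2.n_patients} patients"
      f" -> {out2.n_observations('parent')} + {out2.n_observations('metab')}"
      f"  ({100 * rep2.excluded_fraction('parent'):.2f}% of parent samples excluded)")

# Expected output:
#   5FU: 549 obs / 157 patients -> 541 obs / 156 patients
#        (excluded {'blq': 4, 'clearance': 4})
#   sunitinib: 308 parent + 308 metabolite obs / 47 patients -> 302 + 302
#        (1.95% of parent samples excluded)
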