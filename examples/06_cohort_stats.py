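"""Descriptive statistics of the packaged Parkinson's disease cohort and a
demonstration of the exact small-sample tests.

With eight patients, normal-theory tests are hard to justify; every test
here is an exact permutation procedure.
"""

import apakit as ak

cohort = ak.load_pd_cohort().frame
print(f"{len(cohort)} patients")
for col, label in (("age", "age (y)"), ("weight_kg", "weight (kg)"),
                   ("updrs_motor", "UPDRS motor"),
                   ("dled_mg", "levodopa-equiv. dose (mg)")):
    d = ak.descriptives(cohort[col])
    print(f"  {label:26s} mean {d.mean:7.2f}  SD {d.sd:6.2f}  "
          f"range {d.min:.0f}-{d.max:.0f}")

print()
print("Does motor severity track disease duration? (Spearman, exact)")
res = ak.spearman(cohort["disease_duration_y"], cohort["updrs_motor"])
print(f"  r_s = {res.r_s:.2f}, exact p = {res.p:.3f} (n = {res.n})")
print()
print("An exact p here enumerates all 8! rank orderings - no normal")
print("approximation is involved at any point.")
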