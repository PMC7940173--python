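"""Screening economics: how much PET scanning does a blood pre-screen save?

Uses published Youden operating points at 18.6% prevalence (82/441) to solve
the 2x2 screening design for the target of 100 PET-positive recruits, then
sweeps prevalence and blood/PET cost ratios.
"""

import amyscreen as amy

P = 82 / 441
print(f"prevalence {100 * P:.1f}% -> without screening, "
      f"{amy.round_half_away(100 / P)} scans find 100 PET-positives\n")

models = {
    "base (age+sex+APOE)": (0.573, 0.783),
    "Simoa Ab42/40": (0.451, 0.780),
    "Simoa p-tau181": (0.707, 0.683),
    "LC-MS Ab42/40": (0.866, 0.719),
    "LC-MS composite": (0.915, 0.657),
}
print(f"{'model':<22}{'NNS':>6}{'NPS':>6}{'saved':>7}{'rel. cost (y/x=0.1)':>21}")
for label, (sens, spec) in models.items():
    proj = amy.solve_screening(amy.TestPerformance(sens, spec, label), P, 100)
    r = proj.rounded()
    cost = amy.relative_cost(proj, pet_cost=1.0, blood_cost=0.1)
    print(f"{label:<22}{r['nns']:>6}{r['nps']:>6}{r['scans_saved']:>7}"
          f"{cost.relative_cost:>21.2f}")

# NNS = people blood-tested; NPS = people sent to scan; a relative cost
# below 1 means the screened programme is cheaper than scanning everyone.
sw = amy.prevalence_sweep(amy.TestPerformance(0.866, 0.719, "LC-MS Ab42/40"))
print("\nLC-MS Ab42/40 across prevalence 10-50%:")
print(sw.round(3).to_string(index=False))
# Scan reduction and PPV/NPV shift with prevalence: pre-screening pays off
# most in low-prevalence populations.
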