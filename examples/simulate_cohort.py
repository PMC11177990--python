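"""Simulate a small labelled cohort and inspect what the generator couples.

Builds 3+2+3 subjects (HD, prodromal HD, controls) with two short
recording days each, then prints per-subject severity, GDM counts and the
clinical scores tied to severity. Higher severity means slower reaches,
more jerk noise, fewer long GDMs, higher motor scores and lower TFC.
"""

import numpy as np

from gdmkin import generate_cohort

cohort = generate_cohort(group_sizes=(3, 2, 3), seed=11, n_days=2, day_length_hours=0.5)

print(f"{'subject':8} {'group':5} {'severity':>8} {'GDMs/day':>9} {'motor':>6} {'TFC':>4} {'UL':>4}")
for member in cohort:
    n_gdm = np.mean([len(rec.true_gdm_intervals) for rec in member.recordings])
    scores = member.scores
    print(
        f"{member.profile.subject_id:8} {member.profile.group:5} "
        f"{member.profile.severity:8.2f} {n_gdm:9.1f} "
        f"{scores.uhdrs_motor:6d} {scores.tfc:4d} {scores.uhdrs_ul:4d}"
    )

print(
    "\nEach row is one simulated participant: GDM rate is roughly constant"
    "\nacross groups (the contrast lives in movement quality, not quantity),"
    "\nwhile motor and upper-limb scores rise and TFC falls with severity."
)
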