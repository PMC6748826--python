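"""Compare stroke-first vs phosphate-first orderings by their Pi signatures.

Predicts ensemble averages under both kinetic orderings at 0 and 10 mM
phosphate (3000 interactions each, 25 ms cutoff, paired seeds) and prints
the deltas that discriminate them: phosphate should enlarge and delay the
post-stroke dip and reduce the total displacement without touching the
stroke rate only if release follows the stroke.
"""

from uffclamp.compare import compare_orderings

report = compare_orderings(forces=[3.0], pi_levels=(0.0, 10.0), seed=3)

cols = ["scheme", "pi_mM", "n_events", "k_stroke", "dip_amplitude_nm",
        "dip_time_s", "total_displacement_nm"]
print(report.table[cols].round(3).to_string(index=False))
print()
print(report.deltas.round(4).to_string(index=False))
print()
for scheme, flags in report.flags.items():
    verdict = "reproduces" if flags["reproduces_pi_signature"] else "does NOT reproduce"
    print(f"{scheme}: {verdict} the experimental phosphate signature")
# Stroke-first: dip grows and arrives later, total displacement drops,
# stroke rate unchanged within CI. Phosphate-first: the stroke rate itself
# slows with added phosphate -- the prediction the measurements rule out.
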