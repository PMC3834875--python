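"""Generate a synthetic staging cohort and summarise it.

Draws 603 patients (the size of the cohort the generator emulates) and
prints the headline descriptives: stage prevalence, PSA moments and the
biopsy-vs-prostatectomy Gleason concordance.
"""

from stagebench import default_params, gleason_transition, noc_labels, sample_cohort

cohort = sample_cohort(default_params(n=603, seed=1))

noc = noc_labels(cohort)
print(f"patients: {len(cohort)}")
print(f"NOC prevalence: {100 * noc.mean():.1f}%  (non-organ-confined at prostatectomy)")
print(f"PSA mean {cohort.psa.mean():.2f} ng/ml, median {cohort.psa.median():.1f} ng/ml")
print(f"age mean {cohort.age.mean():.1f} y")

table = gleason_transition(cohort)
pct = table.overall_percentages()
print(
    f"Gleason concordance: {pct['no_change']}% unchanged, "
    f"{pct['increase']}% upgraded, {pct['decrease']}% downgraded at surgery"
)
# a discordance near 47% means the biopsy grade misleads about half the time
print(f"total grading discordance: {table.discordance_percentage()}%")
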