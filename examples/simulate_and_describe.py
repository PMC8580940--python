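"""Generate a synthetic reporting database, select the analysis set and
print the characteristics table of the target-drug arm.

The percentages describe the included target-drug reports: an elderly,
male-leaning population with hospitalization as the leading seriousness
criterion, mirroring what a serious-only extract for an oral kinase
inhibitor looks like.
"""

from pvsignal import GeneratorConfig, SelectionCriteria, generate, run_pipeline

config = GeneratorConfig(n_reports=20_000, seed=42)
run = run_pipeline(generate(config), selection_criteria=SelectionCriteria())

print(f"generated reports:      {config.n_reports}")
print(f"included after triage:  {len(run.selection.included)}")
print(f"exclusions by rule:     {run.selection.counts_by_rule}")
print(f"target arm / comparator arm: {len(run.target_arm)} / {len(run.comparator_arm)}")

median, q1, q3, lo, hi = run.summary.age_stats
print(f"\ntarget-arm age: median {median:.1f} (IQR {q1:.1f}-{q3:.1f}, range {lo:.0f}-{hi:.0f})")
for section in ("age_group", "sex", "seriousness", "suspected_drugs"):
    print(f"\n{section}:")
    for label, count, pct in run.summary.section(section):
        print(f"  {label:<28} {count:>6}  ({pct}%)")
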