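"""Inject a known drug–event association, run the full pipeline and
triage the detected signals.

One association (10-fold over-reporting of a rare event on the target
drug) is injected into an otherwise null database.  The pipeline should
flag it as a signal of disproportionate reporting (SDR) in both age
strata and, since the event is on neither reference list, triage it as
a potential safety signal.  Common events on the label ("expected")
list stay off the signal list.
"""

from pvsignal import (
    GeneratorConfig,
    SignalSpec,
    default_pt_vocabulary,
    format_results_table,
    generate,
    run_pipeline,
)

vocabulary = default_pt_vocabulary()
novel_pt = min(vocabulary, key=lambda row: abs(row[2] - 5e-4))[0]
labelled_pts = [pt for pt, _soc, _b in vocabulary[:5]]

config = GeneratorConfig(
    n_reports=50_000,
    seed=7,
    signals=[SignalSpec("ibrutinib", novel_pt, 10.0)],
)
run = run_pipeline(generate(config), expected_pts=labelled_pts)

print(f"injected association: ibrutinib x {novel_pt} (multiplier 10)")
print(f"SDRs found: {len(run.sdrs)} of {len(run.decisions)} analyzed pairs\n")

table = format_results_table(run.results, run.decisions)
print(table[table.is_sdr].to_string(index=False))
print("\ntriage tally (percent of assessed SDRs per age stratum):")
print(run.tally.to_string(index=False))
print("\nunique drug-event pairs:", run.unique_pairs)
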