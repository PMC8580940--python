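# pvsignal

Disproportionality-based signal detection for spontaneous adverse-event
reporting databases.

Pharmacovigilance teams screen large collections of individual case
safety reports (ICSRs) for drug–event pairs that are reported more often
than the rest of the database would predict.  `pvsignal` implements that
workflow end-to-end for one drug of interest compared against a
comparator drug class (for example, a kinase inhibitor against all other
antineoplastic agents, ATC class L01): case selection with an exclusion
audit trail, a descriptive characteristics table, age-stratified
report-level 2×2 analysis, the two standard disproportionality
statistics, the combined signal rule, and triage of detected signals
against product-label reference lists.  Because real global
pharmacovigilance databases are access-restricted, the package also
ships a synthetic ICSR generator with injectable ground-truth
associations so every stage can be validated quantitatively.

## The statistics

For each preferred term (PT) within an age stratum, reports are counted
into a 2×2 table — `a`/`b` target-arm reports with/without the PT,
`c`/`d` the same in the comparator arm (a report counts once per PT):

- **Proportional reporting ratio**
  `PRR = [a/(a+b)] / [c/(c+d)]`, with the 95% log-normal Wald interval
  `exp(ln PRR ± 1.959964·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`;
  not estimable when `a = 0` or `c = 0`.
- **Information component**, with `O = a`, `E = (a+b)(a+c)/N`,
  `N = a+b+c+d`:
  `IC = log₂((O+0.5)/(E+0.5))` and the 2.5% credibility bound
  `IC025 = IC − 3.3(O+0.5)^−1/2 − 2(O+0.5)^−3/2`.
  The +0.5 shrinkage keeps the IC finite and conservative at small counts.

A **signal of disproportionate reporting (SDR)** is declared when both
measures are significant — `IC025 > 0` and the PRR 95% lower bound `> 1`
— with at least 3 observed cases (all thresholds configurable).  SDRs
are then triaged: PTs on the label ("expected") list or the
alternative-explanation ("non-signal") list are set aside; the remainder
are **potential safety signals**.

## Worked example

`examples/detect_and_triage_signals.py` injects a single 10-fold
association into an otherwise null database of 50,000 synthetic reports
and runs the whole pipeline:

```
injected association: ibrutinib x pt_164 (multiplier 10)
SDRs found: 3 of 400 analyzed pairs

    pt     stratum   n  ic_ic025           prr_95ci  is_sdr
pt_053    under_75 116 0.36/0.05   1.46 (1.16–1.84)    True
pt_164    under_75  53 1.45/0.99 11.34 (5.93–21.71)    True
pt_164 at_least_75  31 1.34/0.75  8.13 (3.87–17.07)    True
```

The injected pair `pt_164` is flagged in both age strata with PRR near
the true fold-change of 10 and IC025 well above 0; `pt_053` is a chance
finding of the kind the triage step exists to weed out.  Since `pt_164`
is on neither reference list it is classified as a potential safety
signal.

The other examples cover the generator and characteristics table
(`simulate_and_describe.py`), the closed-form statistics on a reference
table (`disproportionality_basics.py`) and report-level co-reporting
overlaps (`coreporting_overlap.py`).  A thin CLI mirrors the stages
(`pvsignal simulate | select | summarize | analyze | signals | overlap |
run-all`); databases travel as a documented three-table TSV extract
(reports / drugs / reactions).

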