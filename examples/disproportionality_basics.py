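"""The two disproportionality statistics on a reference 2×2 table.

The table counts reports at the drug–event level: a = target-arm
reports with the event, b = without; c, d the same in the comparator
arm.  The proportional reporting ratio (PRR) compares the event's
reporting rate between arms; the information component (IC) is a shrunk
log2 observed-over-expected measure whose 2.5% credibility bound
(IC025) above 0 signals disproportionate reporting even at small
counts.
"""

from pvsignal import ContingencyTable, ic_with_credibility, prr_with_ci

table = ContingencyTable(pt="pericardial effusion", stratum="all",
                         a=10, b=90, c=10, d=990)
prr, low, high = prr_with_ci(table)
ic, ic025, expected = ic_with_credibility(table)

print(f"2x2 table: a={table.a} b={table.b} c={table.c} d={table.d}")
print(f"PRR  = {prr:.2f} (95% CI {low:.2f}-{high:.2f})")
print(f"      -> the event is reported {prr:.0f}x more often on the target drug")
print(f"E    = {expected:.2f} expected target-arm reports under no association")
print(f"IC   = {ic:.2f}, IC025 = {ic025:.2f}")
print("      -> IC025 > 0 and PRR lower bound > 1: both criteria significant")
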