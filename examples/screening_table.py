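"""Population screening performance across cut-offs and fetal fractions.

Recomputes the full performance grid — detection rate (DR), false-positive
rate (FPR) and odds of being affected given a positive result (OAPR) — for
one-mutation cut-offs 50/51/52% and fetal fractions 2-20%, at 32,000
deduplicated fragments per site with the ACMG-23 panel (coverage 0.834).

Reading the table: at the preferred cut-off of 51% and a typical 10% fetal
fraction, 70% of affected pregnancies are detected (the ceiling imposed by
panel coverage, 0.834^2), only 0.002% of unaffected pregnancies screen
positive (dominated by the rare OXX placental-mosaicism carriers), and a
positive result carries 14:1 odds of a truly affected pregnancy.
"""

from cfscreen import PopulationParams, render_table1_text, table1

df = table1(PopulationParams())
print(render_table1_text(df))
print("\nColumns: ff = fetal fraction; c1/c2 = cut-offs when one/two "
      "mutations are found (c2 = c1 - ff/2); OAPR = affected:unaffected "
      "odds among screen positives.")
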