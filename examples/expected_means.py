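"""Expected mutant-fragment percentages for every genotype configuration.

Builds the genotype scenarios at a 10% fetal fraction and prints the mean
percentage of plasma DNA fragments carrying the CF mutation at the
informative site.  The affected pregnancy sits at 55% — statistically
separable from the 50%-or-less of every unaffected configuration, which is
what makes the screening test work.
"""

from cfscreen import (
    FetalState,
    GenotypeScenario,
    cpm_shifted_mean,
    expected_mean_denovo,
    expected_mean_one_mutation,
    expected_mean_two_mutations,
)

FF = 10.0

one_mutation = [
    ("affected (parents share the mutation)",
     GenotypeScenario(True, True, FetalState.AFFECTED)),
    ("carrier fetus, maternal mutation",
     GenotypeScenario(True, False, FetalState.CARRIER_MATERNAL)),
    ("carrier fetus, paternal mutation",
     GenotypeScenario(False, True, FetalState.CARRIER_PATERNAL)),
    ("mother carrier, fetus non-carrier",
     GenotypeScenario(True, False, FetalState.NONCARRIER)),
    ("neither parent a carrier",
     GenotypeScenario(False, False, FetalState.NONCARRIER)),
]

print(f"One (or no) CF mutation found in plasma, fetal fraction {FF:.0f}%:")
for label, scen in one_mutation:
    print(f"  {label:45s} {expected_mean_one_mutation(scen, FF):5.1f} %")

two_mutation = [
    ("affected (different parental mutations)",
     GenotypeScenario(True, True, FetalState.AFFECTED, parental_mutations_same=False)),
    ("carrier fetus, paternal mutation",
     GenotypeScenario(True, True, FetalState.CARRIER_PATERNAL, parental_mutations_same=False)),
]
print("\nTwo different CF mutations found (predominant = maternal site):")
for label, scen in two_mutation:
    print(f"  {label:45s} {expected_mean_two_mutations(scen, FF):5.1f} %")

print("\nOXX trisomy-7 confined placental mosaicism shifts the carrier mean:")
print(f"  maternal-origin carrier fetus with OXX CPM   {cpm_shifted_mean(FF):6.2f} %"
      f"   (+{FF / 6:.2f} = ff/6)")

denovo = [
    ("de-novo mutation same as the father's",
     GenotypeScenario(False, True, FetalState.AFFECTED_DENOVO_SAME_AS_FATHER)),
    ("de-novo mutation distinct from both parents'",
     GenotypeScenario(False, False, FetalState.CARRIER_DENOVO_DISTINCT)),
]
print("\nDe-novo fetal mutations (mother not a carrier):")
for label, scen in denovo:
    print(f"  {label:45s} {expected_mean_denovo(scen, FF):5.1f} %")
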