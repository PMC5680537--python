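"""Genotype-conditional expected mutant-fragment fractions in maternal plasma.

In a pregnancy the cell-free DNA in maternal plasma is a mixture of maternal
and placental (fetal) DNA; the placental share is the *fetal fraction* ``ff``
(in percent).  At a CFTR mutation site, the expected percentage of sequenced
fragments that carry the mutation is fully determined by which parental /
fetal alleles carry it:

* the mother, if a carrier, contributes half of the maternal compartment,
  i.e. ``(100 - ff) / 2`` percent of all fragments;
* each fetal mutant allele contributes half of the fetal compartment,
  i.e. ``ff / 2`` percent (an affected fetus, with two mutant alleles at the
  same site, contributes ``ff``).

The functions here map every genotype configuration to that expected mean,
in percent.  They are pure and exact; the sampling noise around the mean is
modelled in :mod:`cfscreen.fragment_counts`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "FetalState",
    "GenotypeScenario",
    "validate_fetal_fraction",
    "expected_mean_one_mutation",
    "expected_mean_two_mutations",
    "expected_mean_denovo",
    "cpm_shifted_mean",
]


class FetalState(enum.Enum):
    """Fetal genotype relative to the parental mutant alleles."""

    AFFECTED = "affected"  # two mutant alleles, one from each parent
    CARRIER_MATERNAL = "carrier_maternal"  # one mutant allele, from the mother
    CARRIER_PATERNAL = "carrier_paternal"  # one mutant allele, from the father
    NONCARRIER = "noncarrier"
    # de-novo configurations (mother is not a carrier):
    AFFECTED_DENOVO_SAME_AS_FATHER = "affected_denovo_same_as_father"
    CARRIER_DENOVO_DISTINCT = "carrier_denovo_distinct"


@dataclass(frozen=True)
class GenotypeScenario:
    """Joint maternal / paternal / fetal mutation configuration.

    Parameters
    ----------
    mother_carrier, father_carrier
        Whether each parent carries one CFTR mutant allele.
    fetal_state
        Fetal genotype, see :class:`FetalState`.
    parental_mutations_same
        When both parents are carriers: whether their mutations are the
        same variant.  Ignored otherwise.
    """

    mother_carrier: bool
    father_carrier: bool
    fetal_state: FetalState
    parental_mutations_same: bool = True

    def __post_init__(self) -> None:
        fs = self.fetal_state
        if fs is FetalState.AFFECTED and not (self.mother_carrier and self.father_carrier):
            raise ValueError(
                "an affected fetus requires a mutant allele from each parent "
                "(use the de-novo states otherwise)"
            )
        if fs is FetalState.CARRIER_MATERNAL and not self.mother_carrier:
            raise ValueError("carrier_maternal requires mother_carrier")
        if fs is FetalState.CARRIER_PATERNAL and not self.father_carrier:
            raise ValueError("carrier_paternal requires father_carrier")
        if fs in (
            FetalState.AFFECTED_DENOVO_SAME_AS_FATHER,
            FetalState.CARRIER_DENOVO_DISTINCT,
        ) and self.mother_carrier:
            raise ValueError("de-novo states model a non-carrier mother")
        if fs is FetalState.AFFECTED_DENOVO_SAME_AS_FATHER and not self.father_carrier:
            raise ValueError(
                "affected_denovo_same_as_father requires a carrier father"
            )

    @property
    def both_parents_carriers(self) -> bool:
        return self.mother_carrier and self.father_carrier

    def two_distinct_mutations_in_plasma(self) -> bool:
        """Whether two different mutations are observable in plasma.

        The maternal mutation is always present in plasma (the mother's own
        DNA dominates); a second, different mutation appears only when the
        fetus carries the paternal mutation and the parental mutations
        differ.
        """
        if not self.both_parents_carriers or self.parental_mutations_same:
            return False
        return self.fetal_state in (FetalState.AFFECTED, FetalState.CARRIER_PATERNAL)


def validate_fetal_fraction(ff: float) -> float:
    """Validate a fetal fraction in percent, returning it as ``float``."""
    ff = float(ff)
    if not 0.0 < ff < 100.0:
        raise ValueError(f"fetal fraction must be in (0, 100) percent, got {ff}")
    return ff


def expected_mean_one_mutation(scenario: GenotypeScenario, ff: float) -> float:
    """Expected mutant-fragment percentage when at most one mutation is seen.

    Covers the configurations where a single CFTR mutation (or none) is
    detectable in plasma: parental mutations identical, or at most one parent
    a carrier.  Returns the mean percentage ``m`` at the informative site:

    ======================================  =======================
    configuration                           mean (percent)
    ======================================  =======================
    affected fetus                          ``(100 - ff)/2 + ff``
    carrier fetus, maternal mutation        ``(100 - ff)/2 + ff/2``
    carrier fetus, paternal mutation        ``ff / 2``
    mother carrier, fetus non-carrier       ``(100 - ff)/2``
    neither parent a carrier                ``0``
    ======================================  =======================

    Raises
    ------
    ValueError
        If the configuration would put two distinct mutations in plasma
        (use :func:`expected_mean_two_mutations`), or a de-novo state is
        passed (use :func:`expected_mean_denovo`).
    """
    ff = validate_fetal_fraction(ff)
    if scenario.two_distinct_mutations_in_plasma():
        raise ValueError(
            "two distinct mutations are observable; use expected_mean_two_mutations"
        )
    fs = scenario.fetal_state
    if fs is FetalState.AFFECTED:
        return (100.0 - ff) / 2.0 + ff
    if fs is FetalState.CARRIER_MATERNAL:
        return (100.0 - ff) / 2.0 + ff / 2.0
    if fs is FetalState.CARRIER_PATERNAL:
        if scenario.mother_carrier:
            # same parental mutation: indistinguishable from carrier_maternal
            return (100.0 - ff) / 2.0 + ff / 2.0
        return ff / 2.0
    if fs is FetalState.NONCARRIER:
        return (100.0 - ff) / 2.0 if scenario.mother_carrier else 0.0
    raise ValueError(f"de-novo state {fs.value}: use expected_mean_denovo")


def expected_mean_two_mutations(scenario: GenotypeScenario, ff: float) -> float:
    """Expected percentage at the predominant site when two mutations are seen.

    Reachable only when both parents carry *different* mutations and the
    fetus inherits the paternal one (otherwise the paternal mutation never
    appears in plasma).  Only the predominant mutation — always the maternal
    one, since the mother's own plasma DNA dominates — is informative:

    * affected fetus: ``(100 - ff)/2 + ff/2``, identically 50 for any ``ff``;
    * carrier fetus (paternal mutation only): ``(100 - ff)/2``.
    """
    ff = validate_fetal_fraction(ff)
    if not scenario.two_distinct_mutations_in_plasma():
        raise ValueError(
            "configuration does not place two distinct mutations in plasma"
        )
    if scenario.fetal_state is FetalState.AFFECTED:
        return (100.0 - ff) / 2.0 + ff / 2.0
    # CARRIER_PATERNAL: maternal site has no fetal contribution
    return (100.0 - ff) / 2.0


def expected_mean_denovo(scenario: GenotypeScenario, ff: float) -> float:
    """Expected percentage for a fetal de-novo mutation, non-carrier mother.

    * de-novo mutation identical to the (carrier) father's, fetus affected:
      the fetus carries two copies of the same mutation, mean ``ff``;
    * de-novo mutation distinct from any parental one, fetus a carrier:
      mean ``ff / 2``.
    """
    ff = validate_fetal_fraction(ff)
    if scenario.mother_carrier:
        raise ValueError("de-novo means are defined for a non-carrier mother")
    fs = scenario.fetal_state
    if fs is FetalState.AFFECTED_DENOVO_SAME_AS_FATHER:
        return ff
    if fs is FetalState.CARRIER_DENOVO_DISTINCT:
        return ff / 2.0
    raise ValueError(f"not a de-novo fetal state: {fs.value}")


def cpm_shifted_mean(ff: float) -> float:
    """Mean for a maternal-origin carrier fetus with OXX trisomy-7 mosaicism.

    With confined placental mosaicism of the OXX type (two of the three
    placental chromosome-7 copies carry the maternal mutation), the placenta
    contributes two-thirds of the fetal fraction instead of one half:

        ``(100 - ff)/2 + (2/3) ff  =  50 + ff/6``

    an upward shift of ``ff/6`` relative to the unshifted carrier mean.
    """
    ff = validate_fetal_fraction(ff)
    return (100.0 - ff) / 2.0 + 2.0 * ff / 3.0
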