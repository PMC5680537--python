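"""Analytic population screening performance: DR, FPR, OAPR.

The screening test calls a pregnancy positive when the percentage of mutant
fragments at the informative CFTR site is at or above a cut-off: ``c1`` when
one (or no) mutation is seen in plasma, and the fetal-fraction-dependent
``c2 = c1 - ff/2`` when two different mutations are seen (chosen so the
affected distribution sits at the same distance from the cut-off in both
branches).

Population performance follows from Gaussian tail areas weighted by the
genotype strata of a random-mating population:

* detection rate (DR) — the affected-distribution tail above the cut-off,
  times the probability ``a**2`` that both parental mutant alleles are on
  the panel (coverage ``a`` per allele, independent under random mating);
* false-positive rate (FPR) — the weighted sum of unaffected-stratum tails,
  including the confined-placental-mosaicism (CPM) stratum in which a
  maternal-origin carrier fetus with an OXX trisomy-7 placenta has its mean
  shifted up by ``ff/6``;
* odds of being affected given a positive result (OAPR) —
  ``(DR / FPR) * prevalence_odds``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .fragment_counts import tail_prob_gaussian

__all__ = [
    "PopulationParams",
    "ScreeningPolicy",
    "PerformanceEstimate",
    "two_mutation_cutoff",
    "detection_rate",
    "false_positive_rate",
    "fpr_strata",
    "oapr",
    "format_odds",
    "carrier_testing_performance",
    "oapr_advantage_ratio",
    "invasive_test_reduction",
    "resource_requirements",
    "compare_with_carrier_testing",
    "table1",
    "render_table1_text",
]


@dataclass(frozen=True)
class PopulationParams:
    """Population-genetic and panel parameters.

    Defaults are the European-ancestry figures the model was built around:
    carrier frequency 1/25, birth prevalence 1/2500 (odds 1:2499, consistent
    with random mating: (1/25)^2 / 4), trisomy-7 CPM prevalence 0.2% of which
    half (0.1%) is the OXX type, and ACMG-23 panel coverage 0.834.
    """

    carrier_freq: float = 1 / 25
    prevalence_odds: float = 1 / 2499  # affected : unaffected
    cpm_trisomy7_prev: float = 0.002
    cpm_oxx_prev: float = 0.001
    panel_coverage: float = 0.834
    p_parental_mutations_differ: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "carrier_freq",
            "cpm_trisomy7_prev",
            "cpm_oxx_prev",
            "panel_coverage",
            "p_parental_mutations_differ",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.cpm_oxx_prev > self.cpm_trisomy7_prev:
            raise ValueError("cpm_oxx_prev cannot exceed cpm_trisomy7_prev")
        if self.prevalence_odds <= 0:
            raise ValueError("prevalence_odds must be positive")


@dataclass(frozen=True)
class ScreeningPolicy:
    """Cut-off policy: one-mutation cut-off ``c1`` (percent) and per-site
    fragment count ``n``; the two-mutation cut-off is ``c1 - ff/2``."""

    c1: float = 51.0
    n: int = 32000

    def __post_init__(self) -> None:
        if not 0.0 < self.c1 < 100.0:
            raise ValueError(f"cut-off must be in (0, 100), got {self.c1}")
        if self.n < 1:
            raise ValueError(f"fragment count must be >= 1, got {self.n}")

    def c2(self, ff: float) -> float:
        return two_mutation_cutoff(self.c1, ff)


@dataclass(frozen=True)
class PerformanceEstimate:
    """A DR / FPR / OAPR triple, in percent / percent / affected:unaffected odds."""

    dr: float
    fpr: float
    oapr_odds: float
    method: str = "analytic"
    dr_se: float | None = None
    fpr_se: float | None = None

    @property
    def oapr(self) -> str:
        return format_odds(self.oapr_odds)


def two_mutation_cutoff(c1: float, ff: float) -> float:
    """Cut-off applied to the predominant site when two mutations are seen.

    ``c2 = c1 - ff/2`` keeps the affected mean (50) at the same distance
    from the cut-off as in the one-mutation branch, so both branches yield
    the same screening performance.
    """
    c2 = c1 - ff / 2.0
    if not 0.0 < c2 < 100.0:
        raise ValueError(f"two-mutation cut-off {c2} outside (0, 100)")
    return c2


def detection_rate(
    policy: ScreeningPolicy,
    ff: float,
    pop: PopulationParams,
    pathway: str = "one_mutation",
) -> float:
    """Detection rate in percent.

    The affected tail above the applicable cut-off, times ``a**2`` (both
    parental mutant alleles must be panel-detectable).  ``pathway`` selects
    the branch the tail is computed through: ``"one_mutation"`` (mean
    ``(100-ff)/2 + ff`` against ``c1``) or ``"two_mutation"`` (predominant
    mean 50 against ``c2``); by construction of ``c2`` the two agree —
    exactly where the tails saturate, and to well within printed rounding
    everywhere (the sd differs slightly between the branch means).
    """
    a = pop.panel_coverage
    if pathway == "one_mutation":
        m = (100.0 - ff) / 2.0 + ff
        tail = tail_prob_gaussian(m, policy.n, policy.c1)
    elif pathway == "two_mutation":
        m = (100.0 - ff) / 2.0 + ff / 2.0
        tail = tail_prob_gaussian(m, policy.n, policy.c2(ff))
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    return 100.0 * tail * a * a


def fpr_strata(
    policy: ScreeningPolicy,
    ff: float,
    pop: PopulationParams,
    cpm_mode: str = "tail",
) -> pd.DataFrame:
    """Per-stratum breakdown of the false-positive rate.

    Enumerates every unaffected stratum with a non-zero plasma signal, its
    population weight, site mean, applicable cut-off and positive
    probability.  ``cpm_mode`` controls the OXX-CPM stratum: ``"tail"``
    computes the Gaussian tail of the shifted distribution (mean
    ``50 + ff/6``); ``"conservative"`` counts the whole stratum as positive.
    """
    if cpm_mode not in ("tail", "conservative"):
        raise ValueError(f"cpm_mode must be 'tail' or 'conservative', got {cpm_mode!r}")
    q, a = pop.carrier_freq, pop.panel_coverage
    n, c1 = policy.n, policy.c1
    c2 = policy.c2(ff)
    cpm = pop.cpm_oxx_prev
    pdiff = pop.p_parental_mutations_differ

    rows = []

    def add(name: str, weight: float, mean: float, cutoff: float, prob: float | None = None):
        p = tail_prob_gaussian(mean, n, cutoff) if prob is None else prob
        rows.append(
            {"stratum": name, "weight": weight, "mean": mean, "cutoff": cutoff,
             "positive_prob": p, "contribution_pct": 100.0 * weight * p}
        )

    # mother carrier, fetus inherits her mutation (mean 50), no CPM
    add("carrier_maternal", q / 2 * a * (1 - cpm), 50.0, c1)
    # same, with OXX trisomy-7 confined placental mosaicism (mean 50 + ff/6)
    add(
        "carrier_maternal_cpm_oxx",
        q / 2 * a * cpm,
        50.0 + ff / 6.0,
        c1,
        prob=1.0 if cpm_mode == "conservative" else None,
    )
    # mother carrier, fetus does not inherit the mutation
    add("maternal_carrier_fetus_noncarrier", q / 2 * a, (100.0 - ff) / 2.0, c1)
    # father-only carrier, fetus inherits his mutation
    add("carrier_paternal", q / 2 * a, ff / 2.0, c1)
    # both parents carriers of different mutations, fetus carries the paternal
    # one only: two mutations seen, predominant (maternal) site against c2
    add(
        "two_mutation_carrier_paternal",
        q * q * pdiff * 0.25 * a * a,
        (100.0 - ff) / 2.0,
        c2,
    )
    return pd.DataFrame(rows)


def false_positive_rate(
    policy: ScreeningPolicy,
    ff: float,
    pop: PopulationParams,
    cpm_mode: str = "tail",
) -> float:
    """False-positive rate in percent (sum of weighted stratum tails)."""
    return float(fpr_strata(policy, ff, pop, cpm_mode)["contribution_pct"].sum())


def oapr(dr: float, fpr: float, pop: PopulationParams) -> float:
    """Odds of being affected given a positive result, as affected:unaffected.

    ``(DR / FPR) * prevalence_odds``.  A zero FPR has no finite odds; callers
    display such results via :func:`format_odds` with the >1000:1 cap.
    """
    if fpr < 0 or dr < 0:
        raise ValueError("rates must be non-negative")
    if fpr == 0.0:
        return math.inf
    return (dr / fpr) * pop.prevalence_odds


def format_odds(odds: float, cap: float = 1000.0) -> str:
    """Render odds as ``x:1`` / ``1:x`` with the >1000:1 display cap."""
    if odds == 0.0:
        return "0:1"
    if odds > cap:
        return f">{cap:.0f}:1"
    if odds >= 1.0:
        return f"{odds:.0f}:1"
    return f"1:{1.0 / odds:.0f}"


def carrier_testing_performance(pop: PopulationParams) -> PerformanceEstimate:
    """Performance of conventional parental carrier testing.

    Both parents are tested against the panel; a carrier couple is the
    positive result.  DR = ``a**2`` (both mutations must be on the panel);
    FPR = ``q**2 * 3/4`` (carrier couples, of whose pregnancies three in
    four are unaffected); OAPR = 1:3 by that same Mendelian ratio.  Note the
    OAPR here comes from the within-couple ratio, not the DR/FPR identity
    (coverage enters the DR but, per the standard presentation, not the
    couple-prevalence FPR).
    """
    q, a = pop.carrier_freq, pop.panel_coverage
    dr = 100.0 * a * a
    fpr = 100.0 * q * q * 0.75
    return PerformanceEstimate(dr=dr, fpr=fpr, oapr_odds=1.0 / 3.0, method="carrier_testing")


def oapr_advantage_ratio(dna: PerformanceEstimate, carrier: PerformanceEstimate) -> float:
    """Fold improvement in OAPR of plasma-DNA screening over carrier testing."""
    if not (math.isfinite(dna.oapr_odds) and math.isfinite(carrier.oapr_odds)):
        raise ValueError("both OAPRs must be finite")
    return dna.oapr_odds / carrier.oapr_odds


def invasive_test_reduction(dna_fpr: float, carrier_fpr: float) -> float:
    """Percent of invasive tests in unaffected pregnancies avoided."""
    if carrier_fpr <= 0:
        raise ValueError("carrier-testing FPR must be positive")
    return 100.0 * (1.0 - dna_fpr / carrier_fpr)


def resource_requirements(
    panel_size: int, n_per_site: int, genome_equiv_per_ml: int = 2400
) -> dict:
    """Sequencing and plasma requirements for a panel.

    ``total_fragments = panel_size * n_per_site`` (sites are multiplexed from
    the same plasma, so the plasma volume is set by the per-site count:
    ``plasma_ml = n_per_site / genome_equiv_per_ml``, with ~2400 haploid
    genome equivalents per ml).
    """
    if panel_size < 1 or n_per_site < 1 or genome_equiv_per_ml < 1:
        raise ValueError("all counts must be positive integers")
    return {
        "total_fragments": panel_size * n_per_site,
        "plasma_ml": n_per_site / genome_equiv_per_ml,
    }


def screening_performance(
    policy: ScreeningPolicy,
    ff: float,
    pop: PopulationParams,
    cpm_mode: str = "tail",
) -> PerformanceEstimate:
    """Full-precision analytic DR / FPR / OAPR for one policy and ff."""
    dr = detection_rate(policy, ff, pop)
    fpr = false_positive_rate(policy, ff, pop, cpm_mode)
    return PerformanceEstimate(dr=dr, fpr=fpr, oapr_odds=oapr(dr, fpr, pop))


def _reported(est: PerformanceEstimate, pop: PopulationParams) -> PerformanceEstimate:
    """Round DR/FPR to headline precision and re-derive the OAPR from them,
    mirroring how the comparison numbers are conventionally presented."""
    dr = round(est.dr)
    fpr = round(est.fpr, 3)
    return PerformanceEstimate(dr=dr, fpr=fpr, oapr_odds=oapr(dr, fpr, pop), method=est.method)


def compare_with_carrier_testing(
    policy: ScreeningPolicy,
    ff: float,
    pop: PopulationParams,
    cpm_mode: str = "tail",
) -> dict:
    """Plasma-DNA screening vs parental carrier testing, side by side.

    Returns the two reported (headline-rounded) estimates, the fold
    improvement in OAPR, the percent of invasive tests avoided, and the
    full-precision plasma-DNA estimate.  The fold and reduction are derived
    from the reported numbers, matching the convention of quoting them from
    the rounded headline triple.
    """
    dna_full = screening_performance(policy, ff, pop, cpm_mode)
    dna = _reported(dna_full, pop)
    carrier = carrier_testing_performance(pop)
    return {
        "dna": dna,
        "dna_full_precision": dna_full,
        "carrier": carrier,
        "oapr_fold": oapr_advantage_ratio(dna, carrier),
        "invasive_reduction_pct": invasive_test_reduction(dna.fpr, carrier.fpr),
    }


def table1(
    pop: PopulationParams | None = None,
    policy_n: int = 32000,
    cutoffs: tuple[float, ...] = (50.0, 51.0, 52.0),
    ffs: tuple[float, ...] = (20.0, 10.0, 4.0, 3.0, 2.0),
    cpm_mode: str = "tail",
) -> pd.DataFrame:
    """Screening-performance grid over cut-offs × fetal fractions.

    Returns one row per (ff, c1) with full-precision ``dr``, ``fpr`` and
    ``oapr_odds`` plus the display strings using the table's rounding
    conventions: DR to the nearest percent ("<0.1" below 0.1), FPR to 0.001
    percent ("<0.001" below that), odds capped at ">1000:1".
    """
    pop = pop or PopulationParams()
    rows = []
    for ff in ffs:
        for c1 in cutoffs:
            policy = ScreeningPolicy(c1=c1, n=policy_n)
            dr = detection_rate(policy, ff, pop)
            fpr = false_positive_rate(policy, ff, pop, cpm_mode)
            odds = oapr(dr, fpr, pop)
            rows.append(
                {
                    "ff": ff,
                    "c1": c1,
                    "c2": policy.c2(ff),
                    "dr": dr,
                    "fpr": fpr,
                    "oapr_odds": odds,
                    "dr_display": "<0.1" if dr < 0.1 else f"{dr:.0f}",
                    "fpr_display": "<0.001" if fpr < 0.0005 else f"{fpr:.3f}" if fpr < 0.1 else f"{fpr:.1f}",
                    "oapr_display": format_odds(odds),
                }
            )
    return pd.DataFrame(rows)


def render_table1_text(df: pd.DataFrame) -> str:
    """Aligned human-readable rendering of a :func:`table1` grid."""
    header = f"{'ff%':>4} {'c1':>5} {'c2':>5} {'DR%':>6} {'FPR%':>8} {'OAPR':>9}"
    lines = [header, "-" * len(header)]
    for _, r in df.iterrows():
        lines.append(
            f"{r.ff:>4.0f} {r.c1:>5.0f} {r.c2:>5.1f} {r.dr_display:>6} "
            f"{r.fpr_display:>8} {r.oapr_display:>9}"
        )
    return "\n".join(lines)
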