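"""Synthetic pregnancy cohorts and Monte-Carlo validation of the model.

Two simulation paths are provided, both working at the level of per-site
deduplicated fragment counts (``K ~ Binomial(n, m/100)`` with ``m`` the
genotype-conditional expected percentage from :mod:`cfscreen.genotype`):

* a *naive* population cohort (:func:`simulate_cohort`,
  :func:`sample_pregnancy`): parental genotypes drawn at the carrier
  frequency under random mating, mutation identities drawn from the panel's
  allele-share distribution (plus an off-panel remainder), Mendelian fetal
  inheritance, optional OXX trisomy-7 confined placental mosaicism, and the
  cut-off classification rule applied to the simulated counts.  Good for
  detection-rate checks; far too small-rate for the ~1e-5 FPR.
* a *stratified* rare-event estimator (:func:`estimate_performance_mc`):
  each genotype/CPM stratum is simulated separately at full replicate count
  and recombined with its analytic prior weight, which makes the tiny FPR
  estimable at desk scale with honest binomial standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import read_panel, panel_coverage
from .performance import (
    PerformanceEstimate,
    PopulationParams,
    ScreeningPolicy,
    detection_rate,
    false_positive_rate,
    fpr_strata,
    oapr,
)

__all__ = [
    "SimulatedPregnancy",
    "StratifiedEstimate",
    "sample_pregnancy",
    "classify",
    "simulate_cohort",
    "estimate_performance_mc",
]

OFF_PANEL = "<off-panel>"


@dataclass(frozen=True)
class SimulatedPregnancy:
    """One simulated pregnancy: genotypes, CPM status and per-site counts.

    ``sites`` maps each panel-detectable mutation carried by mother or fetus
    to its ``(n_total, n_mutant)`` fragment counts; sites absent from both
    genomes (or off-panel) yield no counts.
    """

    ff: float
    mother_mutation: str | None
    father_mutation: str | None
    fetus_has_maternal: bool
    fetus_has_paternal: bool
    cpm_oxx: bool
    affected: bool
    sites: dict[str, tuple[int, int]] = field(default_factory=dict)
    site_means: dict[str, float] = field(default_factory=dict)


def _site_means(
    ff: float,
    mother_mutation: str | None,
    father_mutation: str | None,
    fetus_has_maternal: bool,
    fetus_has_paternal: bool,
    cpm_oxx: bool,
) -> dict[str, float]:
    """Expected mutant percentage at each detectable site, compositionally:
    maternal carrier allele contributes (100-ff)/2, each fetal mutant allele
    ff/2 (2ff/3 for the maternal allele under OXX CPM)."""
    means: dict[str, float] = {}
    if mother_mutation is not None and mother_mutation != OFF_PANEL:
        m = (100.0 - ff) / 2.0
        if fetus_has_maternal:
            m += 2.0 * ff / 3.0 if cpm_oxx else ff / 2.0
        if fetus_has_paternal and father_mutation == mother_mutation:
            m += ff / 2.0
        means[mother_mutation] = m
    if (
        father_mutation is not None
        and father_mutation != OFF_PANEL
        and father_mutation != mother_mutation
        and fetus_has_paternal
    ):
        means[father_mutation] = ff / 2.0
    return means


def sample_pregnancy(
    pop: PopulationParams,
    policy: ScreeningPolicy,
    ff: float,
    rng: np.random.Generator,
    panel: pd.DataFrame | None = None,
) -> SimulatedPregnancy:
    """Draw one pregnancy from the population model.

    Each parent is a carrier with probability ``carrier_freq``; a carrier's
    mutation identity is drawn from the panel allele-share distribution,
    with the remaining ``1 - a`` mass assigned to an off-panel (undetectable)
    pseudo-allele, so per-allele panel-detectability is ``a`` and the
    identity of the two parental mutations (same / different) emerges from
    the draw.  Fetal inheritance is Mendelian; OXX CPM occurs at
    ``cpm_oxx_prev`` among pregnancies where the fetus carries the maternal
    mutation.  Counts at each detectable site are Binomial(n, m/100).
    """
    if panel is None:
        panel = read_panel()
    ids = list(panel["mutation_id"]) + [OFF_PANEL]
    shares = np.asarray(panel["population_share"], dtype=float)
    probs = np.append(shares, max(0.0, 1.0 - shares.sum()))
    probs = probs / probs.sum()

    def draw_allele() -> str | None:
        if rng.random() < pop.carrier_freq:
            return ids[rng.choice(len(ids), p=probs)]
        return None

    mother = draw_allele()
    father = draw_allele()
    fetus_m = mother is not None and rng.random() < 0.5
    fetus_p = father is not None and rng.random() < 0.5
    affected = fetus_m and fetus_p
    cpm = fetus_m and rng.random() < pop.cpm_oxx_prev
    means = _site_means(ff, mother, father, fetus_m, fetus_p, cpm)
    sites = {
        sid: (policy.n, int(rng.binomial(policy.n, m / 100.0)))
        for sid, m in means.items()
    }
    return SimulatedPregnancy(
        ff=ff,
        mother_mutation=mother,
        father_mutation=father,
        fetus_has_maternal=fetus_m,
        fetus_has_paternal=fetus_p,
        cpm_oxx=cpm,
        affected=affected,
        sites=sites,
        site_means=means,
    )


def classify(p: SimulatedPregnancy, policy: ScreeningPolicy, found_floor: int = 0) -> bool:
    """Apply the screening rule to one pregnancy's counts.

    A mutation is "found" when its mutant-fragment count exceeds
    ``found_floor`` (default 0: any mutant fragment, the model being
    noise-free after UMI deduplication).  With two or more mutations found,
    the predominant (highest-percentage) site is judged against
    ``c2 = c1 - ff/2``; with one, against ``c1``; with none the result is
    negative.  The cut-off comparison is inclusive (≥).
    """
    found = {sid: nk for sid, nk in p.sites.items() if nk[1] > found_floor}
    if not found:
        return False
    cutoff = policy.c2(p.ff) if len(found) >= 2 else policy.c1
    best_pct = max(100.0 * k / n for n, k in found.values())
    return best_pct >= cutoff


def simulate_cohort(
    pop: PopulationParams,
    policy: ScreeningPolicy,
    ff: float,
    n_pregnancies: int,
    seed: int,
    panel: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vectorised naive cohort: one row per pregnancy, truth and call.

    Same generative model as :func:`sample_pregnancy`, drawn with numpy
    array operations so million-pregnancy cohorts are cheap.  Columns
    include the parental/fetal genotype flags, CPM status, the (up to two)
    per-site means and mutant counts, the truth label and the screening
    call.  Deterministic for a fixed seed.
    """
    if n_pregnancies < 1:
        raise ValueError("n_pregnancies must be >= 1")
    rng = np.random.default_rng(seed)
    if panel is None:
        panel = read_panel()
    shares = np.asarray(panel["population_share"], dtype=float)
    k_panel = len(shares)
    probs = np.append(shares, max(0.0, 1.0 - shares.sum()))
    probs = probs / probs.sum()
    q = pop.carrier_freq
    n = policy.n
    N = n_pregnancies

    mother_carrier = rng.random(N) < q
    father_carrier = rng.random(N) < q
    # mutation identity codes for carriers (k_panel == off-panel)
    mcode = np.full(N, -1, dtype=np.int64)
    fcode = np.full(N, -1, dtype=np.int64)
    mcode[mother_carrier] = rng.choice(k_panel + 1, size=int(mother_carrier.sum()), p=probs)
    fcode[father_carrier] = rng.choice(k_panel + 1, size=int(father_carrier.sum()), p=probs)
    mat_in_panel = mother_carrier & (mcode < k_panel)
    pat_in_panel = father_carrier & (fcode < k_panel)

    fetus_m = mother_carrier & (rng.random(N) < 0.5)
    fetus_p = father_carrier & (rng.random(N) < 0.5)
    affected = fetus_m & fetus_p
    cpm_oxx = fetus_m & (rng.random(N) < pop.cpm_oxx_prev)
    same = mother_carrier & father_carrier & (mcode == fcode) & mat_in_panel

    # maternal site (exists when the mother's mutation is on the panel)
    mat_mean = np.where(
        mat_in_panel,
        (100.0 - ff) / 2.0
        + np.where(fetus_m, np.where(cpm_oxx, 2.0 * ff / 3.0, ff / 2.0), 0.0)
        + np.where(same & fetus_p, ff / 2.0, 0.0),
        0.0,
    )
    # distinct paternal site (exists when fetus inherited a distinct panel mutation)
    pat_site = pat_in_panel & fetus_p & ~same
    pat_mean = np.where(pat_site, ff / 2.0, 0.0)

    mat_k = np.zeros(N, dtype=np.int64)
    pat_k = np.zeros(N, dtype=np.int64)
    mat_k[mat_in_panel] = rng.binomial(n, mat_mean[mat_in_panel] / 100.0)
    pat_k[pat_site] = rng.binomial(n, pat_mean[pat_site] / 100.0)

    found_mat = mat_in_panel & (mat_k > 0)
    found_pat = pat_site & (pat_k > 0)
    n_found = found_mat.astype(int) + found_pat.astype(int)
    best_pct = 100.0 * np.maximum(mat_k, pat_k) / n
    cutoff = np.where(n_found >= 2, policy.c2(ff), policy.c1)
    call = (n_found > 0) & (best_pct >= cutoff)

    return pd.DataFrame(
        {
            "mother_carrier": mother_carrier,
            "father_carrier": father_carrier,
            "mother_mutation": np.where(
                mat_in_panel, np.array(list(panel["mutation_id"]) + [OFF_PANEL])[np.clip(mcode, 0, k_panel)],
                np.where(mother_carrier, OFF_PANEL, ""),
            ),
            "father_mutation": np.where(
                pat_in_panel, np.array(list(panel["mutation_id"]) + [OFF_PANEL])[np.clip(fcode, 0, k_panel)],
                np.where(father_carrier, OFF_PANEL, ""),
            ),
            "fetus_has_maternal": fetus_m,
            "fetus_has_paternal": fetus_p,
            "cpm_oxx": cpm_oxx,
            "ff": ff,
            "n_fragments": n,
            "mat_site_mean": mat_mean,
            "pat_site_mean": pat_mean,
            "mat_n_mutant": mat_k,
            "pat_n_mutant": pat_k,
            "n_mutations_found": n_found,
            "affected": affected,
            "call_positive": call,
        }
    )


@dataclass(frozen=True)
class StratifiedEstimate:
    """Stratified Monte-Carlo DR/FPR/OAPR with per-stratum detail.

    ``strata`` holds one row per simulated stratum (kind, prior weight,
    site mean, cut-off, replicate count, empirical positive rate and its
    binomial standard error); the combined rates are the weight-averaged
    stratum rates, with standard errors combined in quadrature.
    """

    dr: float
    fpr: float
    oapr_odds: float
    dr_se: float
    fpr_se: float
    strata: pd.DataFrame

    @property
    def estimate(self) -> PerformanceEstimate:
        return PerformanceEstimate(
            dr=self.dr, fpr=self.fpr, oapr_odds=self.oapr_odds,
            method="monte_carlo", dr_se=self.dr_se, fpr_se=self.fpr_se,
        )


def estimate_performance_mc(
    pop: PopulationParams,
    policy: ScreeningPolicy,
    ff: float,
    reps_per_stratum: int,
    seed: int,
    cpm_mode: str = "tail",
) -> StratifiedEstimate:
    """Stratified Monte-Carlo estimate of DR, FPR and OAPR.

    Every genotype / CPM stratum with a non-zero plasma signal is simulated
    separately (``reps_per_stratum`` binomial count draws at its site mean,
    classified against its applicable cut-off) and the conditional positive
    rates are recombined with the analytic prior weights from
    :class:`~cfscreen.performance.PopulationParams`.  Affected strata are
    weighted conditionally on being affected (panel-detectable same-mutation,
    detectable different-mutation, and an undetectable remainder with rate
    zero), so the combined affected rate *is* the DR.  Deterministic for a
    fixed seed.
    """
    if reps_per_stratum < 1:
        raise ValueError("reps_per_stratum must be >= 1")
    rng = np.random.default_rng(seed)
    a = pop.panel_coverage
    pdiff = pop.p_parental_mutations_differ
    n = policy.n
    rows = []

    def run(name, kind, weight, mean, cutoff, fixed_rate=None):
        if fixed_rate is None:
            k = rng.binomial(n, mean / 100.0, size=reps_per_stratum)
            hits = (100.0 * k / n) >= cutoff
            rate = float(hits.mean())
            # Agresti-Coull-adjusted rate for the SE so that strata whose
            # empirical rate saturates at 0 or 1 keep an honest uncertainty
            p_adj = (float(hits.sum()) + 2.0) / (reps_per_stratum + 4.0)
            se = float(np.sqrt(p_adj * (1.0 - p_adj) / reps_per_stratum))
            reps = reps_per_stratum
        else:
            rate, se, reps = float(fixed_rate), 0.0, 0
        rows.append(
            {"stratum": name, "kind": kind, "weight": weight, "mean": mean,
             "cutoff": cutoff, "reps": reps, "rate": rate, "se": se}
        )

    c1, c2 = policy.c1, policy.c2(ff)
    # affected strata (weights conditional on the pregnancy being affected)
    run("affected_one_mutation", "affected", a * a * (1.0 - pdiff),
        (100.0 - ff) / 2.0 + ff, c1)
    run("affected_two_mutation", "affected", a * a * pdiff,
        (100.0 - ff) / 2.0 + ff / 2.0, c2)
    run("affected_panel_undetectable", "affected", 1.0 - a * a, 0.0, c1,
        fixed_rate=0.0)
    # unaffected strata: same enumeration (weights, means, cut-offs) as the
    # analytic FPR, simulated instead of integrated
    for _, s in fpr_strata(policy, ff, pop, cpm_mode="tail").iterrows():
        fixed = None
        if cpm_mode == "conservative" and s["stratum"] == "carrier_maternal_cpm_oxx":
            fixed = 1.0
        run(s["stratum"], "unaffected", s["weight"], s["mean"], s["cutoff"],
            fixed_rate=fixed)

    df = pd.DataFrame(rows)
    aff = df[df.kind == "affected"]
    una = df[df.kind == "unaffected"]
    dr = 100.0 * float((aff.weight * aff.rate).sum())
    dr_se = 100.0 * float(np.sqrt(((aff.weight * aff.se) ** 2).sum()))
    fpr = 100.0 * float((una.weight * una.rate).sum())
    fpr_se = 100.0 * float(np.sqrt(((una.weight * una.se) ** 2).sum()))
    odds = oapr(dr, fpr, pop) if fpr > 0 else float("inf")
    return StratifiedEstimate(dr=dr, fpr=fpr, oapr_odds=odds,
                              dr_se=dr_se, fpr_se=fpr_se, strata=df)
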