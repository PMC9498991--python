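"""Synthetic cohort generator.

Generates cohorts with the statistical structure the downstream analyses
assume: CTCAE grades drawn from the population grade distribution, SF2
anchored at the radioresistant (grade 0) and hyper-radiosensitive (grade 5)
means and linear in grade in between, residual micronuclei and residual
gamma-H2AX foci tied to SF2 through the exponential laws, pATMmax linear in
grade, plus the two hyper-radiosensitive genotypes:

* ``atm_homozygous`` -- no pATM foci at all, and nil (or, optionally, tiny)
  gamma-H2AX foci, because H2AX phosphorylation is ATM-dependent;
* ``lig4_mutated`` -- normal DSB recognition (early gamma-H2AX foci and pATM
  at radioresistant levels) but a gross repair defect (residual gamma-H2AX
  foci above 30 per cell), with grade-5 survival.

With every noise standard deviation at zero the generated endpoints satisfy
the fitted inter-endpoint laws exactly, so the whole analysis stack can be
verified against closed forms; with the default noise the cohort reproduces
the fit quality and the per-endpoint discrimination structure reported for
the real collection (see ``docs/methods.md`` for the calibration).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import CellLineRecord, Cohort, Genotype
from .exceptions import ParameterError

__all__ = [
    "GradeDistribution",
    "GroundTruthParams",
    "SurvivalAssay",
    "sample_grades",
    "simulate_record",
    "simulate_cohort",
    "simulate_survival_assay",
]


@dataclass(frozen=True)
class GradeDistribution:
    """Population probabilities of CTCAE grades 0..5.

    The default mirrors the reported frequencies of radiotherapy toxicity
    grades: about 65, 17, 10, 5, 2.5 and 0.5 % of treated patients.
    """

    probs: tuple = (0.65, 0.17, 0.10, 0.05, 0.025, 0.005)

    def __post_init__(self) -> None:
        if len(self.probs) != 6:
            raise ParameterError("grade distribution needs 6 probabilities")
        if any(not 0.0 <= p <= 1.0 for p in self.probs):
            raise ParameterError("grade probabilities must lie in [0, 1]")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ParameterError(
                f"grade probabilities must sum to 1, got {sum(self.probs)!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass(frozen=True)
class GroundTruthParams:
    """Ground-truth laws and noise model of the generator.

    The law parameters default to the fitted values of the real collection:
    SF2(%) = 61.55 - 11.72 x grade, SF2 = 62.2 exp(-0.107 MN_24h),
    SF2 = 62.56 exp(-0.216 H2AX_24h), pATMmax = 41.72 - 6.78 x grade, with
    the grade-0 / grade-5 SF2 subgroup means (62.1 / 3.3 %) as anchors.
    Noise is additive Gaussian per endpoint, clamped at physical bounds;
    micronuclei and residual-foci noise has a component proportional to the
    law value (scatter grows toward the radiosensitive end).
    """

    # linear SF2-grade law (percent)
    sf2_intercept: float = 61.55
    sf2_slope: float = -11.72
    grade0_sf2_mean: float = 62.1
    grade5_sf2_mean: float = 3.3
    # exponential SF2 decays
    k1: float = 0.107          # per micronucleus / 100 cells
    mn_scale: float = 62.2     # SF2 (%) at MN_24h = 0
    k2: float = 0.216          # per residual gamma-H2AX focus
    h2ax_scale: float = 62.56  # SF2 (%) at H2AX_24h = 0
    # linear pATMmax-grade law (foci per cell)
    patm_intercept: float = 41.72
    patm_slope: float = -6.78
    # DSB induction
    dsb_per_gy: float = 40.0
    dose: float = 2.0          # Gy
    # LIG4 phenotype
    lig4_residual_h2ax_min: float = 30.0
    lig4_residual_h2ax_mean: float = 35.0
    # noise standard deviations (additive Gaussian)
    sf2_sd: float = 3.0
    patm_sd: float = 4.0
    mn_sd_base: float = 0.3
    mn_sd_prop: float = 0.08
    h2ax_sd_base: float = 0.4
    h2ax_sd_prop: float = 0.12
    h2ax_early_sd: float = 4.0
    mn_spont_mean: float = 2.0
    mn_spont_sd: float = 1.0
    # pATM kinetics split
    patm_minor_frac_low: float = 0.4
    patm_minor_frac_high: float = 0.9
    slow_kinetics_fraction: float = 0.5
    # genotype structure
    atm_fraction_of_grade5: float = 0.8
    atm_h2ax_nil: bool = True
    atm_tiny_h2ax: float = 0.8
    # reference lines added to cohorts (skipped for cohorts of < 50):
    # radioresistant controls plus gifted ATM-null and LIG4 lines, which
    # anchor both extremes of every law exactly as in the source collection
    n_rr_reference: int = 14
    n_atm_reference: int = 6
    n_lig4_reference: int = 1
    # clonogenic assay synthesis
    beta_alpha_ratio: float = 0.167  # per Gy
    plating_efficiency_mean: float = 0.3
    plating_efficiency_sd: float = 0.05
    # SF2 observed only on a grade-stratified subset (the clonogenic assay
    # is too slow to run on every line); targets per grade 0..5
    sf2_subset_targets: Optional[tuple] = (10, 1, 6, 6, 6, 7)
    grade_distribution: GradeDistribution = field(default_factory=GradeDistribution)

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ParameterError("dose must be > 0")
        for name in (
            "sf2_sd", "patm_sd", "mn_sd_base", "mn_sd_prop", "h2ax_sd_base",
            "h2ax_sd_prop", "h2ax_early_sd", "mn_spont_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.atm_fraction_of_grade5 <= 1.0:
            raise ParameterError("atm_fraction_of_grade5 must lie in [0, 1]")
        if self.beta_alpha_ratio < 0:
            raise ParameterError("beta_alpha_ratio must be >= 0")

    def noiseless(self) -> "GroundTruthParams":
        """Copy with every noise SD set to zero (laws hold exactly)."""
        return dataclasses.replace(
            self,
            sf2_sd=0.0, patm_sd=0.0, mn_sd_base=0.0, mn_sd_prop=0.0,
            h2ax_sd_base=0.0, h2ax_sd_prop=0.0, h2ax_early_sd=0.0,
            mn_spont_sd=0.0,
        )

    # --- latent (noise-free) laws -------------------------------------
    def sf2_law(self, grade: float) -> float:
        return self.sf2_intercept + self.sf2_slope * grade

    def patm_law(self, grade: float) -> float:
        return self.patm_intercept + self.patm_slope * grade

    def mn_law(self, sf2: float) -> float:
        return max(0.0, -math.log(sf2 / self.mn_scale) / self.k1)

    def h2ax_law(self, sf2: float) -> float:
        return max(0.0, -math.log(sf2 / self.h2ax_scale) / self.k2)


@dataclass
class SurvivalAssay:
    """Clonogenic dose-survival data: colonies (> 50 cells) per dose point."""

    doses: np.ndarray
    seeded_cells: np.ndarray
    colonies: np.ndarray
    plating_efficiency: Optional[float] = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.seeded_cells = np.asarray(self.seeded_cells)
        self.colonies = np.asarray(self.colonies, dtype=float)
        if len({round(d, 12) for d in self.doses}) != len(self.doses):
            raise ParameterError("assay doses must be distinct")
        if np.any(self.doses < 0):
            raise ParameterError("assay doses must be >= 0")


def sample_grades(n: int, dist: Optional[GradeDistribution] = None,
                  seed: Optional[int] = None) -> np.ndarray:
    """Draw ``n`` CTCAE grades from the population grade distribution."""
    if n < 0:
        raise ParameterError("n must be >= 0")
    dist = dist or GradeDistribution()
    rng = np.random.default_rng(seed)
    return rng.choice(6, size=n, p=dist.as_array())


def _clamp(value: float, low: float, high: float = math.inf) -> float:
    return min(max(value, low), high)


def simulate_record(grade: int, genotype: Genotype = Genotype.WILDTYPE_LIKE,
                    params: Optional[GroundTruthParams] = None,
                    rng: Optional[np.random.Generator] = None,
                    record_id: str = "CL0000") -> CellLineRecord:
    """Simulate one cell line at the given grade and genotype.

    Endpoint construction (noise terms are independent Gaussians, clamped
    at physical bounds):

    1. SF2 anchors: grade-0 wildtype at the radioresistant mean, grade-5
       mutants at the hyper-radiosensitive mean, otherwise the linear law;
       clamped to (0.1, 100].
    2. pATMmax: linear law + noise (>= 0); ATM-null lines have exactly 0.
       The 10 min / 1 h values are a split of pATMmax -- radioresistant
       kinetics peak at 10 min (the 1 h value is systematically lower),
       while a configurable fraction of radiosensitive lines peaks at 1 h.
    3. MN_24h and H2AX_24h are the exponential-law inversions of the
       record's own SF2 plus base+proportional noise, so the SF2 laws hold
       exactly at zero noise while the grade-conditional scatter of both
       endpoints grows toward the radiosensitive end.
    4. Early (10 min) gamma-H2AX foci scale the physically induced DSB
       yield (dose x ~40 DSB/Gy) by the latent pATM fraction: recognition
       is ATM-limited.  LIG4 lines recognize normally but keep > 30
       residual foci.
    5. Spontaneous micronuclei are grade-independent.
    """
    if not isinstance(grade, (int, np.integer)) or not 0 <= int(grade) <= 5:
        raise ParameterError(f"grade must be an integer in 0..5, got {grade!r}")
    grade = int(grade)
    genotype = Genotype(genotype)
    params = params or GroundTruthParams()
    rng = rng or np.random.default_rng()
    mutant = genotype in (Genotype.ATM_HOMOZYGOUS, Genotype.LIG4_MUTATED)

    # --- SF2 -----------------------------------------------------------
    if mutant:
        sf2_latent = params.grade5_sf2_mean
    elif grade == 0:
        sf2_latent = params.grade0_sf2_mean
    else:
        sf2_latent = params.sf2_law(grade)
    sf2 = _clamp(sf2_latent + rng.normal(0.0, params.sf2_sd)
                 if params.sf2_sd > 0 else sf2_latent, 0.1, 100.0)

    # --- pATM ----------------------------------------------------------
    if genotype is Genotype.ATM_HOMOZYGOUS:
        patm_latent = 0.0
        patm_max = 0.0
    else:
        patm_latent = (params.patm_intercept if genotype is Genotype.LIG4_MUTATED
                       else params.patm_law(grade))
        patm_max = _clamp(patm_latent + rng.normal(0.0, params.patm_sd)
                          if params.patm_sd > 0 else patm_latent, 0.0)
    minor_frac = rng.uniform(params.patm_minor_frac_low,
                             params.patm_minor_frac_high)
    slow = (grade >= 3 and genotype is not Genotype.LIG4_MUTATED
            and rng.uniform() < params.slow_kinetics_fraction)
    if slow:
        patm_10min, patm_1h = patm_max * minor_frac, patm_max
    else:
        patm_10min, patm_1h = patm_max, patm_max * minor_frac

    # --- micronuclei ----------------------------------------------------
    mn_latent = params.mn_law(sf2)
    mn_sd = params.mn_sd_base + params.mn_sd_prop * mn_latent
    mn_24h = _clamp(mn_latent + rng.normal(0.0, mn_sd)
                    if mn_sd > 0 else mn_latent, 0.0)
    mn_spont = _clamp(params.mn_spont_mean
                      + (rng.normal(0.0, params.mn_spont_sd)
                         if params.mn_spont_sd > 0 else 0.0), 0.0)

    # --- gamma-H2AX -----------------------------------------------------
    max_early = params.dose * params.dsb_per_gy
    if genotype is Genotype.ATM_HOMOZYGOUS:
        tiny = 0.0 if params.atm_h2ax_nil else params.atm_tiny_h2ax
        h2ax_24h = tiny
        h2ax_10min = tiny
        h2ax_1h = tiny
    else:
        if genotype is Genotype.LIG4_MUTATED:
            h_sd = params.h2ax_sd_base
            h2ax_24h = _clamp(params.lig4_residual_h2ax_mean
                              + (rng.normal(0.0, h_sd) if h_sd > 0 else 0.0),
                              params.lig4_residual_h2ax_min + 1e-9)
            early_latent = max_early
        else:
            h_latent = params.h2ax_law(sf2)
            h_sd = params.h2ax_sd_base + params.h2ax_sd_prop * h_latent
            h2ax_24h = _clamp(h_latent + (rng.normal(0.0, h_sd) if h_sd > 0
                                          else 0.0), 0.0)
            early_latent = max_early * patm_latent / params.patm_intercept
        h2ax_10min = _clamp(early_latent
                            + (rng.normal(0.0, params.h2ax_early_sd)
                               if params.h2ax_early_sd > 0 else 0.0),
                            0.0, max_early)
        h2ax_1h = _clamp(h2ax_24h + 0.5 * (h2ax_10min - h2ax_24h)
                         + (rng.normal(0.0, 0.5 * params.h2ax_early_sd)
                            if params.h2ax_early_sd > 0 else 0.0), 0.0)

    pe = _clamp(params.plating_efficiency_mean
                + (rng.normal(0.0, params.plating_efficiency_sd)
                   if params.plating_efficiency_sd > 0 else 0.0), 0.05, 1.0)

    return CellLineRecord(
        id=record_id,
        genotype=genotype,
        ctcae_grade=grade,
        sf2=sf2,
        plating_efficiency=pe,
        mn_spont=mn_spont,
        mn_24h=mn_24h,
        h2ax_10min=h2ax_10min,
        h2ax_1h=h2ax_1h,
        h2ax_24h=h2ax_24h,
        patm_10min=patm_10min,
        patm_1h=patm_1h,
    )


def simulate_cohort(n: int, params: Optional[GroundTruthParams] = None,
                    seed: int = 0) -> Cohort:
    """Simulate a cohort of ``n`` cell lines.

    For cohorts of >= 50 lines, a block of reference lines is included
    first -- radioresistant grade-0 controls plus gifted ATM-null and LIG4
    grade-5 lines -- mirroring how such collections are assembled (the
    hyper-radiosensitive extreme is essentially absent among surviving
    radiotherapy patients and must come from syndrome donors).  The
    remaining lines' grades are drawn from the configured population grade
    distribution; sampled grade-5 lines are assigned the ATM-null or LIG4
    genotype according to ``atm_fraction_of_grade5``.

    When ``sf2_subset_targets`` is set, SF2 (and plating efficiency) are
    retained only on a grade-stratified subset of lines, emulating the
    partial coverage of the clonogenic assay; the masked values are simply
    absent, as in a real table.

    Deterministic for a fixed seed: one master seed spawns independent
    child streams per record.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    params = params or GroundTruthParams()
    reference = []
    if n >= 50:
        reference += [("REF-RR", 0, Genotype.WILDTYPE_LIKE)] * params.n_rr_reference
        reference += [("REF-AT", 5, Genotype.ATM_HOMOZYGOUS)] * params.n_atm_reference
        reference += [("REF-LIG4", 5, Genotype.LIG4_MUTATED)] * params.n_lig4_reference
    reference = reference[:n]
    n_sampled = n - len(reference)
    master = np.random.SeedSequence(seed)
    grade_ss, genotype_ss, subset_ss, *record_ss = master.spawn(n + 3)
    grades = np.random.default_rng(grade_ss).choice(
        6, size=n_sampled, p=params.grade_distribution.as_array())
    geno_rng = np.random.default_rng(genotype_ss)
    records = []
    tag_counts: dict = {}
    for tag, grade, genotype in reference:
        tag_counts[tag] = tag_counts.get(tag, 0) + 1
        records.append(simulate_record(
            grade, genotype, params,
            np.random.default_rng(record_ss[len(records)]),
            record_id=f"{tag}-{tag_counts[tag]:02d}",
        ))
    for i, grade in enumerate(grades):
        if grade == 5:
            genotype = (Genotype.ATM_HOMOZYGOUS
                        if geno_rng.uniform() < params.atm_fraction_of_grade5
                        else Genotype.LIG4_MUTATED)
        else:
            genotype = Genotype.WILDTYPE_LIKE
        records.append(simulate_record(
            int(grade), genotype, params,
            np.random.default_rng(record_ss[len(records)]),
            record_id=f"CL{i:04d}",
        ))
    if params.sf2_subset_targets is not None:
        _mask_sf2_subset(records, params.sf2_subset_targets,
                         np.random.default_rng(subset_ss))
    provenance = {
        "generator": "radiosens.simulate.simulate_cohort",
        "seed": int(seed),
        "n": int(n),
        "params": dataclasses.asdict(params),
    }
    return Cohort(records=records, provenance=provenance)


def _mask_sf2_subset(records, targets, rng) -> None:
    """Keep SF2/PE on at most ``targets[g]`` lines per grade, drop elsewhere."""
    keep = set()
    for grade in range(6):
        indices = [i for i, r in enumerate(records) if r.ctcae_grade == grade]
        take = min(int(targets[grade]), len(indices))
        if take > 0:
            keep.update(rng.choice(indices, size=take, replace=False).tolist())
    for i, rec in enumerate(records):
        if i not in keep:
            rec.sf2 = None
            rec.plating_efficiency = None


def simulate_survival_assay(sf2: float, params: Optional[GroundTruthParams] = None,
                            doses: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 6.0),
                            seeded_cells: Sequence[int] = (500, 500, 500, 1000, 2000),
                            rng: Optional[np.random.Generator] = None,
                            noiseless: bool = False) -> SurvivalAssay:
    """Synthesize a clonogenic assay consistent with a target SF2.

    The linear-quadratic parameters are chosen with the configured beta/alpha
    ratio r so that S(2 Gy) = sf2/100: alpha = -ln(S(2))/(2 + 4 r),
    beta = r alpha.  Colony counts are Poisson with mean
    seeded x PE x S(D); in ``noiseless`` mode the exact expectations are
    returned (useful for round-trip fitting checks).
    """
    params = params or GroundTruthParams()
    if not 0.0 < sf2 <= 100.0:
        raise ParameterError(f"sf2 must lie in (0, 100], got {sf2}")
    doses = np.asarray(doses, dtype=float)
    seeded = np.asarray(seeded_cells)
    if np.any(seeded < 1):
        raise ParameterError("seeded_cells must be >= 1")
    if len(seeded) != len(doses):
        raise ParameterError("doses and seeded_cells must have equal length")
    rng = rng or np.random.default_rng()
    log_s2 = -math.log(sf2 / 100.0)
    alpha = log_s2 / (2.0 + 4.0 * params.beta_alpha_ratio)
    beta = params.beta_alpha_ratio * alpha
    pe = params.plating_efficiency_mean
    survival = np.exp(-(alpha * doses + beta * doses ** 2))
    expected = seeded * pe * survival
    colonies = expected if noiseless else rng.poisson(expected).astype(float)
    return SurvivalAssay(doses=doses, seeded_cells=seeded,
                         colonies=colonies, plating_efficiency=pe)
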