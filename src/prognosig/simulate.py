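"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators emulate the study's data layers so every downstream stage
is testable without any download:

* a paired tissue cohort — log2 LFQ matrices for the invasive tumor front
  (ITF) and the inner tumor with planted differential proteins and
  intensity-dependent missingness;
* a saliva SRM cohort — transition-level light/heavy peptide areas for an
  N0/N+ patient set with group-wise shifts planted on chosen peptides;
* an IHC cohort — intensity/percentage category ratings per region and
  rater, with the "lower in ITF" phenotype linked to a binary outcome
  through a configurable odds ratio.

Each generator is deterministic given its seed and always returns the
ground truth (planted effects, true ratios, true calls) alongside the data.
The distributional choices (log-normal multiplicative noise on areas,
logistic intensity-dependent dropout) are modelling conventions, chosen
for plausibility on MS intensity data and documented in the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError
from .tissue import QuantMatrix

#: Monitored saliva peptides (name, proteotypic sequence). Names encode the
#: parent protein after the underscore.
CANONICAL_PEPTIDES: list[tuple[str, str]] = [
    ("Pep1_MB", "HGATVLTALGGILK"),
    ("Pep2_MB", "YLEFISECIIQVLQSK"),
    ("Pep3_PGK1", "VLNNMEIGTSLFDEEGAK"),
    ("Pep4_PGK1", "VLPGVDALSNI"),
    ("Pep5_ITGAV", "LQEVGQVSVSLQR"),
    ("Pep6_ITGAV", "STGLNAVPSQILEGQWAAR"),
    ("Pep7_LTA4H", "LTYTAEVSVPK"),
    ("Pep8_LTA4H", "DLSSHQLNEFLAQTLQR"),
    ("Pep9_COL6A1", "GLEQLLVGGSHLK"),
    ("Pep10_COL6A1", "TAEYDVAYGESHLFR"),
    ("Pep11_NDRG1", "EMQDVDLAEVKPLVEK"),
    ("Pep12_CSTB", "HDELTYF"),
    ("Pep13_CSTB", "SQVVAGTNYFIK"),
    ("Pep14_CSTB", "VHVGDEDFVHLR"),
]


def peptide_protein(peptide_name: str) -> str:
    """Parent protein symbol encoded in a ``PepN_PROT`` peptide name."""
    return peptide_name.split("_", 1)[1] if "_" in peptide_name else peptide_name


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


# --------------------------------------------------------------------------
# Tissue cohort
# --------------------------------------------------------------------------


@dataclass
class TissueSimConfig:
    """Paired ITF/inner LFQ cohort parameters.

    ``effect_log2`` is added to the ITF true abundance of the planted
    fraction of proteins; ``missing_rate_base`` sets the average dropout
    rate, modulated logistically so low-abundance values drop out more.
    """

    n_patients: int = 20
    n_proteins: int = 500
    frac_differential: float = 0.05
    effect_log2: float = 1.5
    missing_rate_base: float = 0.1
    sd_within: float = 0.7
    sd_patient: float = 0.5
    baseline_mean_log2: float = 26.0
    baseline_sd_log2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_patients > 0 and self.n_proteins > 0, "counts must be positive")
        _require(0.0 <= self.frac_differential <= 1.0, "frac_differential must be in [0,1]")
        _require(0.0 <= self.missing_rate_base <= 1.0, "missing_rate_base must be in [0,1]")
        _require(self.sd_within > 0, "sd_within must be > 0")
        _require(self.sd_patient >= 0, "sd_patient must be >= 0")
        _require(self.baseline_sd_log2 > 0, "baseline_sd_log2 must be > 0")


@dataclass
class TissueCohort:
    itf: QuantMatrix
    inner: QuantMatrix
    truth: pd.DataFrame  # per protein: planted flag, effect_log2, baseline


def gen_tissue_cohort(cfg: TissueSimConfig) -> TissueCohort:
    """Generate a paired two-region LFQ cohort with planted differentials.

    Per protein a baseline log2 abundance is drawn; the first
    ``round(frac_differential * n_proteins)`` proteins (after a seeded
    shuffle) carry ``effect_log2`` in the ITF region. Observed values add
    within-sample noise; dropout probability decreases logistically with
    the underlying abundance, so missingness concentrates in low-intensity
    proteins as in real LFQ data.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = [f"PROT{i + 1:04d}" for i in range(cfg.n_proteins)]
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]

    baseline = rng.normal(cfg.baseline_mean_log2, cfg.baseline_sd_log2, cfg.n_proteins)
    n_planted = int(round(cfg.frac_differential * cfg.n_proteins))
    planted_idx = rng.choice(cfg.n_proteins, size=n_planted, replace=False)
    effects = np.zeros(cfg.n_proteins)
    effects[planted_idx] = cfg.effect_log2

    # patient x protein biology shared by both regions: makes pairs correlated
    patient_effect = rng.normal(0.0, cfg.sd_patient, (cfg.n_proteins, cfg.n_patients))

    def _region(true_means: np.ndarray) -> pd.DataFrame:
        vals = (
            true_means[:, None]
            + patient_effect
            + rng.normal(0.0, cfg.sd_within, (cfg.n_proteins, cfg.n_patients))
        )
        if cfg.missing_rate_base > 0:
            # dropout logistic in the underlying abundance, centred on the
            # baseline mean so the average rate tracks missing_rate_base
            p_miss = np.clip(
                2.0
                * cfg.missing_rate_base
                * expit((cfg.baseline_mean_log2 - vals) / cfg.baseline_sd_log2),
                0.0,
                1.0,
            )
            vals = np.where(rng.random(vals.shape) < p_miss, np.nan, vals)
        return pd.DataFrame(vals, index=proteins, columns=patients)

    itf_vals = _region(baseline + effects)
    inner_vals = _region(baseline)

    def _annot(region: str) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient": patients, "region": region, "compartment": "island"},
            index=patients,
        )

    truth = pd.DataFrame(
        {
            "baseline_log2": baseline,
            "planted": effects != 0,
            "effect_log2": effects,
        },
        index=proteins,
    )
    return TissueCohort(
        itf=QuantMatrix(values=itf_vals, samples=_annot("ITF")),
        inner=QuantMatrix(values=inner_vals, samples=_annot("inner")),
        truth=truth,
    )


# --------------------------------------------------------------------------
# Saliva SRM cohort
# --------------------------------------------------------------------------


@dataclass
class SrmSimConfig:
    """Saliva SRM cohort parameters.

    ``group_effect_log2`` gives, per peptide, the N+ minus N0 shift on the
    log2 light/heavy ratio (negative = lower in N+). ``noise_cv`` is the
    coefficient of variation of the multiplicative technical noise on
    transition areas; ``sd_biological_log2`` is the between-patient spread
    of the true log2 ratio around the group mean.
    """

    n_N0: int = 14
    n_Nplus: int = 26
    peptide_names: list[str] = field(
        default_factory=lambda: [name for name, _ in CANONICAL_PEPTIDES]
    )
    n_transitions_per_peptide: int = 3
    n_replicates: int = 3
    group_effect_log2: list[float] | None = None
    noise_cv: float = 0.2
    sd_biological_log2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_N0 > 0 and self.n_Nplus > 0, "group sizes must be positive")
        _require(
            self.n_transitions_per_peptide > 0 and self.n_replicates > 0,
            "transition and replicate counts must be positive",
        )
        _require(self.noise_cv >= 0, "noise_cv must be >= 0")
        _require(self.sd_biological_log2 >= 0, "sd_biological_log2 must be >= 0")
        if self.group_effect_log2 is None:
            self.group_effect_log2 = [0.0] * len(self.peptide_names)
        _require(
            len(self.group_effect_log2) == len(self.peptide_names),
            f"group_effect_log2 length {len(self.group_effect_log2)} != "
            f"{len(self.peptide_names)} peptides",
        )


@dataclass
class SrmCohort:
    records: pd.DataFrame  # long transition table
    truth: pd.DataFrame  # patient x peptide true L/H ratio (linear scale)
    config: SrmSimConfig


TRANSITION_COLUMNS = [
    "patient", "group", "peptide", "protein", "transition",
    "isotope", "replicate", "area", "rt",
]


def gen_srm_cohort(cfg: SrmSimConfig) -> SrmCohort:
    """Generate a transition-level SRM table with planted group shifts.

    Heavy (spiked standard) areas are group-independent; light areas equal
    heavy times the patient's true ratio, so the per-replicate sum-ratio
    recovers the truth exactly at ``noise_cv = 0``. Technical noise is
    log-normal multiplicative with log2 sd ``log2(1 + noise_cv)``, applied
    independently to each light and heavy transition area.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pep = len(cfg.peptide_names)
    patients = [f"N0_{i + 1:02d}" for i in range(cfg.n_N0)] + [
        f"Np_{i + 1:02d}" for i in range(cfg.n_Nplus)
    ]
    groups = ["N0"] * cfg.n_N0 + ["N+"] * cfg.n_Nplus
    effects = np.asarray(cfg.group_effect_log2, dtype=float)

    # per-peptide relative transition pattern and absolute heavy scale
    heavy_base = 2.0 ** rng.uniform(14.0, 20.0, (n_pep, cfg.n_transitions_per_peptide))
    pep_rt = rng.uniform(8.0, 45.0, n_pep)
    mu_pep = rng.normal(0.0, 0.3, n_pep)  # baseline log2 L/H per peptide

    # true per-patient log2 ratio = peptide baseline + group effect + biology
    is_nplus = np.array([g == "N+" for g in groups])
    true_log2 = (
        mu_pep[None, :]
        + np.outer(is_nplus, effects)
        + rng.normal(0.0, cfg.sd_biological_log2, (len(patients), n_pep))
    )
    true_ratio = 2.0**true_log2

    log2_noise_sd = np.log2(1.0 + cfg.noise_cv)
    rows: dict[str, list] = {c: [] for c in TRANSITION_COLUMNS}
    for pi, (pat, grp) in enumerate(zip(patients, groups)):
        for ki, pep in enumerate(cfg.peptide_names):
            prot = peptide_protein(pep)
            for rep in range(1, cfg.n_replicates + 1):
                rt = pep_rt[ki] + rng.normal(0.0, 0.05)
                for trans in range(1, cfg.n_transitions_per_peptide + 1):
                    hb = heavy_base[ki, trans - 1]
                    for isotope, scale in (("light", true_ratio[pi, ki]), ("heavy", 1.0)):
                        area = hb * scale
                        if log2_noise_sd > 0:
                            area *= 2.0 ** rng.normal(0.0, log2_noise_sd)
                        rows["patient"].append(pat)
                        rows["group"].append(grp)
                        rows["peptide"].append(pep)
                        rows["protein"].append(prot)
                        rows["transition"].append(trans)
                        rows["isotope"].append(isotope)
                        rows["replicate"].append(rep)
                        rows["area"].append(area)
                        rows["rt"].append(rt)

    truth = pd.DataFrame(true_ratio, index=patients, columns=cfg.peptide_names)
    truth.index.name = "patient"
    return SrmCohort(records=pd.DataFrame(rows), truth=truth, config=cfg)


def count_monitored_transitions(records: pd.DataFrame) -> int:
    """Number of distinct monitored transitions: peptide x transition x isotope."""
    return len(records.drop_duplicates(["peptide", "transition", "isotope"]))


# --------------------------------------------------------------------------
# IHC cohort
# --------------------------------------------------------------------------


@dataclass
class IHCSimConfig:
    """IHC rating cohort parameters.

    ``outcome_association_or`` is the odds ratio linking the "lower in ITF"
    phenotype to the adverse binary outcome; 1.0 means no association.
    ``rater_agreement`` is the probability a rater reproduces the consensus
    category exactly (otherwise jittered by one category).
    """

    n_cases: int = 125
    raters: int = 3
    p_lower_itf: float = 0.5
    outcome_association_or: float = 2.0
    baseline_outcome_rate: float = 0.3
    rater_agreement: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cases > 0, "n_cases must be positive")
        _require(self.raters >= 2, "need at least 2 raters")
        _require(0.0 <= self.p_lower_itf <= 1.0, "p_lower_itf must be in [0,1]")
        _require(self.outcome_association_or > 0, "odds ratio must be > 0")
        _require(0.0 < self.baseline_outcome_rate < 1.0, "baseline rate must be in (0,1)")
        _require(0.0 <= self.rater_agreement <= 1.0, "rater_agreement must be in [0,1]")


@dataclass
class IHCCohort:
    ratings: pd.DataFrame  # case, rater, region, intensity, percentage
    cases: pd.DataFrame  # consensus scores, true call, outcomes


def _split_combined(rng: np.random.Generator, combined: int) -> tuple[int, int]:
    """Random (intensity, percentage) pair in 0-3 x 0-3 summing to ``combined``."""
    lo, hi = max(0, combined - 3), min(3, combined)
    intensity = int(rng.integers(lo, hi + 1))
    return intensity, combined - intensity


def gen_ihc_cohort(cfg: IHCSimConfig) -> IHCCohort:
    """Generate per-rater IHC category ratings with a planted region call.

    Each case gets consensus combined scores (0-6) for ITF and inner tumor
    consistent with its latent call ("lower in ITF" with probability
    ``p_lower_itf``, otherwise equal-or-higher); raters reproduce the
    consensus categories with probability ``rater_agreement`` and otherwise
    shift one category. The adverse outcome is Bernoulli with log-odds
    shifted by ``log(outcome_association_or)`` for lower-in-ITF cases.
    """
    rng = np.random.default_rng(cfg.seed)
    case_ids = [f"C{i + 1:03d}" for i in range(cfg.n_cases)]
    lower = rng.random(cfg.n_cases) < cfg.p_lower_itf

    case_rows, rating_rows = [], []
    for ci, case in enumerate(case_ids):
        if lower[ci]:
            inner_c = int(rng.integers(1, 7))
            itf_c = int(rng.integers(0, inner_c))
        else:
            itf_c = int(rng.integers(0, 7))
            inner_c = int(rng.integers(0, itf_c + 1))
        consensus = {"ITF": _split_combined(rng, itf_c), "inner": _split_combined(rng, inner_c)}
        for rater in range(1, cfg.raters + 1):
            for region, (inten, pct) in consensus.items():
                if rng.random() >= cfg.rater_agreement:
                    inten = int(np.clip(inten + rng.choice([-1, 1]), 0, 3))
                if rng.random() >= cfg.rater_agreement:
                    pct = int(np.clip(pct + rng.choice([-1, 1]), 0, 3))
                rating_rows.append(
                    {
                        "case": case,
                        "rater": rater,
                        "region": region,
                        "intensity": inten,
                        "percentage": pct,
                    }
                )
        p_out = expit(
            logit(cfg.baseline_outcome_rate)
            + np.log(cfg.outcome_association_or) * float(lower[ci])
        )
        case_rows.append(
            {
                "case": case,
                "combined_ITF": itf_c,
                "combined_inner": inner_c,
                "true_lower_in_itf": bool(lower[ci]),
                "recurrence": bool(rng.random() < p_out),
                "second_primary": bool(rng.random() < 0.15),
            }
        )
    return IHCCohort(
        ratings=pd.DataFrame(rating_rows), cases=pd.DataFrame(case_rows).set_index("case")
    )
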