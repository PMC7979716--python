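"""Synthetic neoadjuvant cohort tables with a known effect structure.

Emulates the clinical layer of a three-timepoint (baseline / day 15 /
surgery) anti-HER2 window-of-opportunity cohort: pathologist-scored sTILs per
sample, hormone-receptor status, PAM50 subtype, pathological complete
response, and a targeted expression panel in which a small set of
immune genes tracks sTILs while the rest are null.  Default effects mirror
the regime the analyses assume: the day-15 sTIL rise is concentrated in
HR-negative disease (+12.5 points vs +2.1 in HR-positive), sTILs fall at
surgery in responders (-21.5) but not in residual disease (-0.9).

Scores are rounded the way pathologists report them (nearest 5 below 10%,
nearest 10 above), which is what makes exactly "stable" sTIL trajectories
possible.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

TIMEPOINTS = ("baseline", "day15", "surgery")

TIL_LINKED_GENES = ("MS4A1", "PD1", "CD8A", "CD19", "IKBKE",
                    "IDO1", "TAP1", "TYMP", "CD3G", "LAG3")
HOUSEKEEPING_GENES = ("ACTB", "MRPL19", "PSMC4", "RPLP0", "SF3A1")
PAM50_SUBTYPES = ("LumA", "LumB", "HER2E", "Basal", "Normal")


def _default_pam50() -> dict:
    # HER2-enriched dominates early HER2+ disease; HR+ tumours skew luminal.
    return {
        "negative": {"LumA": 0.02, "LumB": 0.02, "HER2E": 0.80,
                     "Basal": 0.14, "Normal": 0.02},
        "positive": {"LumA": 0.22, "LumB": 0.18, "HER2E": 0.52,
                     "Basal": 0.04, "Normal": 0.04},
    }


@dataclass
class CohortEffects:
    """Effect structure of the generated cohort (per-stratum parameters)."""

    hr_negative_prob: float = 0.45
    pam50_probs: dict = field(default_factory=_default_pam50)
    #: baseline sTILs ~ 100 * Beta(mean*k, (1-mean)*k) per HR stratum
    baseline_mean: dict = field(default_factory=lambda: {"negative": 0.15,
                                                         "positive": 0.08})
    baseline_concentration: float = 6.0
    #: mean day-15 shift in sTIL points per HR stratum
    day15_shift: dict = field(default_factory=lambda: {"negative": 12.5,
                                                       "positive": 2.1})
    #: Gaussian-copula correlation of the baseline and day-15 draws; under a
    #: zero shift the two timepoints are exchangeable (an exact null).
    within_patient_corr: float = 0.7
    #: pCR probability per HR stratum
    pcr_prob: dict = field(default_factory=lambda: {"negative": 0.43,
                                                    "positive": 0.18})
    #: mean surgery - day15 shift conditional on response
    surgery_shift: dict = field(default_factory=lambda: {"pcr": -21.5,
                                                         "rd": -0.9})
    surgery_shift_sd: float = 8.0
    #: Pearson correlation of TIL-linked genes with sTILs (log2 scale)
    gene_til_correlation: float = 0.5
    n_genes: int = 555
    til_linked_genes: tuple = TIL_LINKED_GENES
    housekeeping_genes: tuple = HOUSEKEEPING_GENES

    def __post_init__(self):
        for p in (self.hr_negative_prob, *self.pcr_prob.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for probs in self.pam50_probs.values():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("PAM50 stratum probabilities must sum to 1")
        if not -1 <= self.gene_til_correlation <= 1:
            raise ValueError("gene_til_correlation must lie in [-1, 1]")

    @classmethod
    def null(cls) -> "CohortEffects":
        """Zero shifts and no gene–TIL coupling (for null simulations)."""
        return cls(day15_shift={"negative": 0.0, "positive": 0.0},
                   surgery_shift={"pcr": 0.0, "rd": 0.0},
                   gene_til_correlation=0.0)


def round_stils(value: float) -> float:
    """Pathologist-style sTIL granularity: nearest 5 below 10%, else nearest 10."""
    v = float(np.clip(value, 0.0, 100.0))
    if v < 10.0:
        return float(np.clip(5.0 * round(v / 5.0), 0.0, 100.0))
    return float(np.clip(10.0 * round(v / 10.0), 0.0, 100.0))


def generate_cohort(n_patients: int, effects: CohortEffects | None = None,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the cohort table (3 rows per patient) and expression matrix.

    Returns ``(cohort, expression)``: ``cohort`` has one row per patient and
    timepoint with hr_status, pam50, pcr and stils_pct; ``expression`` is a
    gene x sample raw-count matrix whose columns are
    ``"<patient_id>_<timepoint>"``.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    eff = effects or CohortEffects()
    rng = np.random.default_rng(seed)

    rows = []
    true_stils = {}  # (patient, timepoint) -> pre-rounding value
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        hr = "negative" if rng.uniform() < eff.hr_negative_prob else "positive"
        pam_probs = eff.pam50_probs[hr]
        pam50 = rng.choice(PAM50_SUBTYPES, p=[pam_probs[s] for s in PAM50_SUBTYPES])
        pcr = bool(rng.uniform() < eff.pcr_prob[hr])

        m = eff.baseline_mean[hr]
        k = eff.baseline_concentration
        # Shared Beta marginal through a Gaussian copula: baseline and day 15
        # are exchangeable when the shift is zero (no clipping bias), and an
        # additive shift moves the mean difference by exactly that amount.
        rho = eff.within_patient_corr
        z1 = rng.normal()
        z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.normal()
        a, b = m * k, (1 - m) * k
        base = 100.0 * float(sps.beta.ppf(sps.norm.cdf(z1), a, b))
        d15 = float(np.clip(100.0 * sps.beta.ppf(sps.norm.cdf(z2), a, b)
                            + eff.day15_shift[hr], 0.0, 100.0))
        shift = eff.surgery_shift["pcr" if pcr else "rd"]
        surg = np.clip(d15 + shift + rng.normal(0.0, eff.surgery_shift_sd),
                       0.0, 100.0)
        for tp, val in zip(TIMEPOINTS, (base, d15, surg)):
            true_stils[(pid, tp)] = float(val)
            rows.append({"patient_id": pid, "timepoint": tp, "hr_status": hr,
                         "pam50": str(pam50), "pcr": pcr,
                         "stils_pct": round_stils(val)})
    cohort = pd.DataFrame(rows)

    expression = _generate_expression(cohort, true_stils, eff, rng)
    return cohort, expression


def _generate_expression(cohort: pd.DataFrame, true_stils: dict,
                         eff: CohortEffects, rng) -> pd.DataFrame:
    samples = [f"{r.patient_id}_{r.timepoint}" for r in cohort.itertuples()]
    s = np.array([true_stils[(r.patient_id, r.timepoint)]
                  for r in cohort.itertuples()])
    z = (s - s.mean()) / (s.std() or 1.0)
    n = len(samples)

    linked = list(eff.til_linked_genes)
    hk = list(eff.housekeeping_genes)
    n_null = eff.n_genes - len(linked)
    if n_null < 0:
        raise ValueError("n_genes smaller than the TIL-linked gene list")
    genes = linked + [f"GENE{i + 1:04d}" for i in range(n_null)] + hk

    rho = eff.gene_til_correlation
    log2 = np.empty((len(genes), n), dtype=float)
    for gi, g in enumerate(genes):
        mu = rng.uniform(6.0, 10.0)
        if g in linked and rho != 0.0:
            x = rho * z + np.sqrt(1.0 - rho ** 2) * rng.normal(size=n)
        elif g in hk:
            x = rng.normal(scale=0.1, size=n)
            mu = rng.uniform(9.0, 11.0)
        else:
            x = rng.normal(size=n)
        log2[gi] = mu + x
    counts = np.rint(np.power(2.0, log2)).astype(np.int64)
    return pd.DataFrame(counts, index=genes, columns=samples)
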