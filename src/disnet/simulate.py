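"""Synthetic longitudinal claims cohorts with known ground truth.

Real national claims cohorts (e.g. the Korean NHIS sample cohort this package's
pipeline is modelled on) are access-restricted, so every downstream stage is
exercised against simulated cohorts in which the answers are planted: directed
progression pairs with a chosen risk ratio, disease clusters induced by shared
age/sex prevalence gradients, and duplicate claim records that the exposure
stage must collapse.

The generative model is deliberately simple. Each patient is assigned a sex and
an age band; within a time window every disease is drawn independently per
patient with probability ``baseline_prevalence x age_effect[band] x
(sex_effect if female)``. A planted progression ``D1 -> D2`` multiplies the
outcome-window probability of ``D2`` by ``planted_rr`` for patients diagnosed
with ``D1`` in the observation window, which makes the planted value the true
risk ratio that the association stage should recover. Every diagnosed
(patient, code, window) event is emitted as ``1 + Poisson(lambda)`` dated claim
rows so that deduplication is exercised downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "DiseaseSpec",
    "ProgressionSpec",
    "SyntheticCohort",
    "SpecValidationError",
    "generate_cohort",
    "write_claims",
    "demo_scenario",
]

CODE_RE = re.compile(r"^[A-Z][0-9]{2}$")

#: default age bands (inclusive year ranges) mirroring the <30 / 30-59 / >=60
#: convention used throughout the network's demographic encoding
DEFAULT_AGE_BANDS = ((0, 29), (30, 59), (60, 90))
#: rough South-Korea-circa-2002 population shares for the three bands
DEFAULT_AGE_PROBS = (0.45, 0.43, 0.12)


class SpecValidationError(ValueError):
    """A simulation spec is internally inconsistent."""


@dataclass(frozen=True)
class PopulationSpec:
    """Demographic composition of a simulated cohort.

    Parameters
    ----------
    n_patients:
        Number of patients to simulate.
    sex_ratio:
        Fraction of the cohort that is female, in [0, 1].
    age_distribution:
        Sequence of ``((lo, hi), probability)`` age bands; probabilities must
        sum to 1. Ages are drawn uniformly (whole years) within each band.
    reference_date:
        Calendar date at which the sampled ages hold; birth years are derived
        from it.
    """

    n_patients: int
    sex_ratio: float = 0.5
    age_distribution: tuple = tuple(zip(DEFAULT_AGE_BANDS, DEFAULT_AGE_PROBS))
    reference_date: date = date(2002, 1, 1)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SpecValidationError("n_patients must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise SpecValidationError("sex_ratio must lie in [0, 1]")
        probs = [p for _, p in self.age_distribution]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise SpecValidationError(
                f"age band probabilities must sum to 1, got {sum(probs)!r}"
            )
        for (lo, hi), _ in self.age_distribution:
            if lo > hi or lo < 0:
                raise SpecValidationError(f"invalid age band ({lo}, {hi})")


@dataclass(frozen=True)
class DiseaseSpec:
    """Per-window prevalence model for one 3-character diagnosis code.

    ``age_effect`` is a multiplier per age band (same order as the population's
    ``age_distribution``); ``sex_effect`` multiplies the probability for female
    patients. ``cluster_id`` tags diseases that belong to a planted cluster and
    is carried through as ground truth only.
    """

    code: str
    baseline_prevalence: float
    age_effect: tuple = (1.0, 1.0, 1.0)
    sex_effect: float = 1.0
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if not CODE_RE.match(self.code):
            raise SpecValidationError(
                f"disease code {self.code!r} does not match [A-Z][0-9][0-9]"
            )
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise SpecValidationError(
                f"{self.code}: baseline_prevalence must lie in (0, 1)"
            )
        if self.sex_effect < 0 or any(a < 0 for a in self.age_effect):
            raise SpecValidationError(f"{self.code}: effects must be >= 0")

    def stratum_probs(self, pop: PopulationSpec) -> np.ndarray:
        """Per-(band, sex) probabilities, clamped to [0, 1]; shape (bands, 2)
        with column 0 = male, column 1 = female."""
        bands = len(pop.age_distribution)
        if len(self.age_effect) != bands:
            raise SpecValidationError(
                f"{self.code}: age_effect has {len(self.age_effect)} entries "
                f"for {bands} age bands"
            )
        out = np.empty((bands, 2))
        for b in range(bands):
            p = self.baseline_prevalence * self.age_effect[b]
            out[b, 0] = p
            out[b, 1] = p * self.sex_effect
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class ProgressionSpec:
    """A planted directed progression: exposure to ``source_code`` in the
    observation window multiplies the outcome-window probability of
    ``target_code`` by ``planted_rr`` (the true risk ratio)."""

    source_code: str
    target_code: str
    planted_rr: float

    def __post_init__(self) -> None:
        if self.source_code == self.target_code:
            raise SpecValidationError(
                f"progression {self.source_code}->{self.target_code}: "
                "source and target must differ"
            )
        if self.planted_rr < 0:
            raise SpecValidationError("planted_rr must be >= 0")


@dataclass
class SyntheticCohort:
    """Generated claims plus the ground truth that produced them."""

    claims: pd.DataFrame        # columns: patient_id, code, date
    demographics: pd.DataFrame  # columns: patient_id, sex, birth_year
    truth: list = field(default_factory=list)  # the ProgressionSpecs planted
    seed: int | None = None
    diagnosed_counts: dict | None = None  # {(window_label, code): n patients}


def _validate(pop, diseases, progressions):
    if not diseases:
        raise SpecValidationError("disease list is empty")
    codes = [d.code for d in diseases]
    if len(set(codes)) != len(codes):
        raise SpecValidationError("duplicate disease codes in spec")
    by_code = {d.code: d for d in diseases}
    for pr in progressions:
        for c in (pr.source_code, pr.target_code):
            if c not in by_code:
                raise SpecValidationError(
                    f"progression {pr.source_code}->{pr.target_code}: "
                    f"code {c!r} not in disease list"
                )
        target = by_code[pr.target_code]
        worst = float(target.stratum_probs(pop).max()) * pr.planted_rr
        if worst > 1.0 + 1e-12:
            raise SpecValidationError(
                f"progression {pr.source_code}->{pr.target_code}: planted_rr "
                f"{pr.planted_rr} x max stratum probability gives {worst:.3f} > 1"
            )
    return by_code


def _window_days(start: date, end: date) -> int:
    n = (end - start).days + 1
    if n < 1:
        raise SpecValidationError(f"window {start}..{end} is empty")
    return n


def _emit_claims(rng, patient_ids, codes, diag, start, end, dup_lambda):
    """Expand a boolean (patient x disease) diagnosis matrix into dated claim
    rows, 1 + Poisson(dup_lambda) rows per diagnosis, dates uniform in-window."""
    p_idx, c_idx = np.nonzero(diag)
    reps = 1 + rng.poisson(dup_lambda, size=p_idx.size)
    pats = np.repeat(patient_ids[p_idx], reps)
    cods = np.repeat(np.asarray(codes, dtype=object)[c_idx], reps)
    offsets = rng.integers(0, _window_days(start, end), size=int(reps.sum()))
    dates = np.datetime64(start, "D") + offsets
    return pd.DataFrame(
        {"patient_id": pats, "code": cods, "date": pd.to_datetime(dates)}
    )


def generate_cohort(pop, diseases, progressions, windows, seed,
                    dup_lambda: float = 0.5) -> SyntheticCohort:
    """Simulate a cohort of dated diagnosis claims.

    ``windows`` is a :class:`disnet.cohort.WindowConfig`; observation-window
    diagnoses are drawn independently per disease/stratum, outcome-window
    probabilities are modified by the planted progressions (a patient exposed
    to one or more planted sources gets the largest planted risk ratio among
    them as multiplier). Identical arguments and seed give identical output.
    """
    by_code = _validate(pop, diseases, progressions)
    rng = np.random.default_rng(seed)
    n = pop.n_patients
    codes = [d.code for d in diseases]
    code_idx = {c: i for i, c in enumerate(codes)}

    # demographics
    patient_ids = np.arange(1, n + 1, dtype=np.int64)
    female = rng.random(n) < pop.sex_ratio
    bands = rng.choice(len(pop.age_distribution), size=n,
                       p=[p for _, p in pop.age_distribution])
    lo = np.array([b[0] for b, _ in pop.age_distribution])
    hi = np.array([b[1] for b, _ in pop.age_distribution])
    ages = rng.integers(lo[bands], hi[bands] + 1)
    birth_year = pop.reference_date.year - ages
    demographics = pd.DataFrame(
        {"patient_id": patient_ids,
         "sex": np.where(female, "F", "M"),
         "birth_year": birth_year.astype(np.int64)}
    )

    # per-patient base probability for each disease (stratum lookup)
    sex_col = female.astype(np.intp)
    base = np.empty((n, len(codes)))
    for j, d in enumerate(diseases):
        base[:, j] = d.stratum_probs(pop)[bands, sex_col]

    obs_diag = rng.random((n, len(codes))) < base

    # outcome window: planted progressions scale the target's probability
    p_out = base.copy()
    targets: dict[int, list] = {}
    for pr in progressions:
        targets.setdefault(code_idx[pr.target_code], []).append(pr)
    for t_idx, prs in targets.items():
        mult = np.full(n, -np.inf)
        exposed_any = np.zeros(n, dtype=bool)
        for pr in prs:
            e = obs_diag[:, code_idx[pr.source_code]]
            mult = np.where(e, np.maximum(mult, pr.planted_rr), mult)
            exposed_any |= e
        eff = np.where(exposed_any, mult, 1.0)
        p_out[:, t_idx] = np.clip(base[:, t_idx] * eff, 0.0, 1.0)

    out_diag = rng.random((n, len(codes))) < p_out

    claims = pd.concat(
        [
            _emit_claims(rng, patient_ids, codes, obs_diag,
                         windows.observation_start, windows.observation_end,
                         dup_lambda),
            _emit_claims(rng, patient_ids, codes, out_diag,
                         windows.outcome_start, windows.outcome_end,
                         dup_lambda),
        ],
        ignore_index=True,
    )

    diagnosed_counts = {}
    for label, diag in (("observation", obs_diag), ("outcome", out_diag)):
        for j, c in enumerate(codes):
            diagnosed_counts[(label, c)] = int(diag[:, j].sum())

    return SyntheticCohort(
        claims=claims,
        demographics=demographics,
        truth=list(progressions),
        seed=seed,
        diagnosed_counts=diagnosed_counts,
    )


def write_claims(cohort: SyntheticCohort, claims_path, demographics_path) -> None:
    """Write the cohort as the two-CSV interchange format.

    Claims: ``patient_id,code,date`` (ISO-8601 dates); demographics:
    ``patient_id,sex,birth_year``. UTF-8 with a header row; round-trips
    losslessly through :func:`disnet.cohort.load_claims`.
    """
    try:
        out = cohort.claims.copy()
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(claims_path, index=False)
        cohort.demographics.to_csv(demographics_path, index=False)
    except OSError as exc:
        raise OSError(
            f"writing cohort to {claims_path!r}/{demographics_path!r}: {exc}"
        ) from exc


def demo_scenario(n_patients: int = 100_000):
    """A ready-made study: three demographically distinct disease clusters
    plus background diagnoses and within/cross-cluster planted progressions.

    Cluster 1 skews elderly (chronic/degenerative codes), cluster 2 is
    dominated by women of reproductive age (obstetric/gynaecologic codes),
    cluster 3 skews young (respiratory/infectious codes). Returns
    ``(PopulationSpec, diseases, progressions)``.
    """
    pop = PopulationSpec(n_patients=n_patients)
    elderly = (0.25, 1.0, 3.5)
    repro = (0.8, 1.5, 0.05)
    young = (2.5, 0.7, 0.4)
    flat = (1.0, 1.0, 1.0)
    D = DiseaseSpec
    diseases = [
        # cluster 1: chronic debilitation, elderly
        D("I10", 0.15, elderly, 1.0, 1),   # essential hypertension
        D("E11", 0.08, elderly, 1.0, 1),   # type 2 diabetes
        D("N18", 0.012, elderly, 1.0, 1),  # chronic kidney disease
        D("I12", 0.008, elderly, 1.0, 1),  # hypertensive renal disease
        D("D63", 0.010, elderly, 1.0, 1),  # anaemia in chronic disease
        D("H25", 0.06, elderly, 1.0, 1),   # senile cataract
        D("M17", 0.05, elderly, 1.5, 1),   # knee arthrosis
        D("G63", 0.012, elderly, 1.0, 1),  # polyneuropathy
        # cluster 2: women's diseases
        D("O20", 0.012, repro, 12.0, 2),   # haemorrhage in early pregnancy
        D("O24", 0.006, repro, 12.0, 2),   # diabetes mellitus in pregnancy
        D("N91", 0.02, repro, 8.0, 2),     # absent/rare menstruation
        D("N76", 0.03, repro, 15.0, 2),    # vaginitis
        D("P59", 0.006, repro, 6.0, 2),    # neonatal jaundice (mother's account)
        # cluster 3: young / infectious
        D("J20", 0.25, young, 1.0, 3),     # acute bronchitis
        D("J06", 0.20, young, 1.0, 3),     # acute upper respiratory infection
        D("A09", 0.08, young, 1.0, 3),     # gastroenteritis
        D("B34", 0.06, young, 1.0, 3),     # viral infection, unspecified
        D("H66", 0.05, young, 1.0, 3),     # otitis media
        D("L22", 0.02, young, 1.0, 3),     # diaper dermatitis
        # background, no cluster
        D("K29", 0.10, flat, 1.0, None),   # gastritis
        D("M54", 0.12, flat, 1.0, None),   # dorsalgia
        D("J30", 0.07, flat, 1.0, None),   # vasomotor/allergic rhinitis
        D("K05", 0.09, flat, 1.0, None),   # gingivitis
        D("R51", 0.05, flat, 1.0, None),   # headache
    ]
    P = ProgressionSpec
    progressions = [
        # chronic cluster
        P("I10", "N18", 6.0),
        P("E11", "N18", 8.0),
        P("N18", "I12", 20.0),
        P("N18", "D63", 18.0),
        P("E11", "G63", 10.0),
        P("I10", "I12", 9.0),
        P("E11", "H25", 3.5),
        P("M17", "G63", 4.5),
        # women's cluster
        P("O24", "P59", 10.0),
        P("O20", "P59", 8.0),
        P("O20", "N91", 3.0),
        P("N76", "N91", 3.0),
        # cross-cluster: neonatal jaundice -> diaper dermatitis
        P("P59", "L22", 9.0),
        # young cluster
        P("J06", "H66", 3.0),
        P("A09", "B34", 4.0),
        P("J20", "H66", 3.5),
    ]
    return pop, diseases, progressions
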