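"""Claims ingestion, temporal windowing and analysis-code selection.

The study design splits calendar time into an *observation* window (which
defines disease exposure and the cohort itself: only patients with at least
one claim in it are retained) and a later *outcome* window (in which incident
diagnoses are read). Codes are truncated to their 3-character category and the
analysis set is the most prevalent codes covering a requested share of cases,
subject to a minimum patient count per code.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "WindowConfig",
    "ExposureMatrix",
    "CodeSelection",
    "SchemaError",
    "load_claims",
    "truncate_codes",
    "build_exposure",
    "select_codes",
]

# 3+ character diagnosis code: letter, two digits, optional alphanumeric tail
_LOAD_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")


class SchemaError(ValueError):
    """Input file does not match the declared CSV schema."""


@dataclass(frozen=True)
class WindowConfig:
    """Observation and outcome periods (inclusive calendar dates)."""

    observation_start: date = date(2002, 1, 1)
    observation_end: date = date(2003, 12, 31)
    outcome_start: date = date(2004, 1, 1)
    outcome_end: date = date(2013, 12, 31)

    def __post_init__(self) -> None:
        if self.observation_start > self.observation_end:
            raise ValueError("observation window is empty")
        if self.outcome_start > self.outcome_end:
            raise ValueError("outcome window is empty")
        if self.observation_end >= self.outcome_start:
            raise ValueError("observation window must end before outcome window")

    @property
    def observation(self) -> tuple[date, date]:
        return self.observation_start, self.observation_end

    @property
    def outcome(self) -> tuple[date, date]:
        return self.outcome_start, self.outcome_end


@dataclass
class ExposureMatrix:
    """Boolean patient x code presence within one named window.

    ``presence[i, j]`` is True iff patient ``patients[i]`` has at least one
    claim of ``codes[j]`` dated inside the window (idempotent under claim
    duplication).
    """

    label: str
    patients: np.ndarray      # ordered patient ids
    codes: list               # ordered 3-character codes
    presence: np.ndarray      # bool, shape (n_patients, n_codes)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.patients), len(self.codes)):
            raise ValueError("presence shape does not match patients x codes")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def code_index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"code {code!r} not in exposure matrix") from None

    def column(self, code: str) -> np.ndarray:
        return self.presence[:, self.code_index(code)]

    def counts(self) -> pd.Series:
        """Distinct-patient count per code within the window."""
        return pd.Series(self.presence.sum(axis=0), index=self.codes,
                         name=f"{self.label}_patients")

    def restrict(self, codes) -> "ExposureMatrix":
        """New matrix limited to ``codes`` (kept in the given order)."""
        idx = [self.code_index(c) for c in codes]
        return ExposureMatrix(self.label, self.patients, list(codes),
                              self.presence[:, idx])


@dataclass
class CodeSelection:
    """Analysis code set chosen by prevalence coverage."""

    selected_codes: list
    coverage_achieved: float
    min_patients: int
    counts: pd.Series  # per-code patient counts (observation window)

    def __iter__(self):
        return iter(self.selected_codes)

    def __len__(self):
        return len(self.selected_codes)


def load_claims(claims_path, demographics_path, *,
                on_missing_patient: str = "drop"):
    """Read the claims/demographics CSV pair and validate it.

    Returns ``(claims, demographics)`` DataFrames. Rows with malformed codes
    or dates are rejected (counts logged). Claims whose patient is absent from
    the demographics table are dropped with a warning by default;
    ``on_missing_patient="error"`` raises instead.
    """
    claims = pd.read_csv(claims_path, dtype={"code": str})
    demo = pd.read_csv(demographics_path)
    for frame, need, path in (
        (claims, {"patient_id", "code", "date"}, claims_path),
        (demo, {"patient_id", "sex", "birth_year"}, demographics_path),
    ):
        missing = need - set(frame.columns)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")

    n0 = len(claims)
    code_ok = claims["code"].astype(str).str.match(_LOAD_CODE_RE).fillna(False)
    dates = pd.to_datetime(claims["date"], format="%Y-%m-%d", errors="coerce")
    date_ok = dates.notna()
    bad = int((~code_ok | ~date_ok).sum())
    if bad:
        log.warning("rejected %d/%d malformed claim rows (%d bad codes, %d bad dates)",
                    bad, n0, int((~code_ok).sum()), int((~date_ok).sum()))
    claims = claims.loc[code_ok & date_ok].copy()
    claims["date"] = dates[code_ok & date_ok]

    known = set(demo["patient_id"])
    orphan = ~claims["patient_id"].isin(known)
    if orphan.any():
        if on_missing_patient == "error":
            raise SchemaError(
                f"{int(orphan.sum())} claims reference patients missing from "
                f"{demographics_path}"
            )
        log.warning("dropping %d claims for patients absent from demographics",
                    int(orphan.sum()))
        claims = claims.loc[~orphan].copy()
    return claims.reset_index(drop=True), demo


def truncate_codes(claims: pd.DataFrame) -> pd.DataFrame:
    """Truncate every diagnosis code to its 3-character category.

    Record count is unchanged; codes shorter than 3 characters should already
    have been rejected at load time and raise here.
    """
    codes = claims["code"].astype(str)
    if (codes.str.len() < 3).any():
        raise ValueError("claims contain codes shorter than 3 characters")
    out = claims.copy()
    out["code"] = codes.str[:3]
    return out


def build_exposure(claims: pd.DataFrame, window: tuple, label: str, *,
                   patients=None, codes=None) -> ExposureMatrix:
    """Build the boolean presence matrix for one window.

    ``window`` is an inclusive ``(start, end)`` date pair. When ``patients``
    is None the patient axis is exactly the patients with >=1 claim in the
    window (this is how the observation window defines the cohort); passing an
    explicit array keeps patients with no in-window claims as all-False rows.
    """
    start, end = window
    d = claims["date"]
    sub = claims.loc[(d >= pd.Timestamp(start)) & (d <= pd.Timestamp(end))]
    if patients is None:
        patients = np.sort(sub["patient_id"].unique())
        if len(patients) == 0:
            raise ValueError(f"no claims fall inside the {label} window")
    else:
        patients = np.asarray(patients)
    if codes is None:
        codes = sorted(sub["code"].unique())
    codes = list(codes)

    presence = np.zeros((len(patients), len(codes)), dtype=bool)
    pi = pd.Index(patients).get_indexer(sub["patient_id"])
    ci = pd.Index(codes).get_indexer(sub["code"])
    keep = (pi >= 0) & (ci >= 0)
    presence[pi[keep], ci[keep]] = True
    return ExposureMatrix(label, patients, codes, presence)


def select_codes(observation: ExposureMatrix, coverage: float,
                 min_patients: int = 947, *,
                 counts: pd.Series | None = None) -> CodeSelection:
    """Choose the analysis code set by descending prevalence.

    Codes are ranked by observation-window distinct-patient count (ties broken
    lexicographically); the shortest prefix whose cumulative share of the
    total reaches ``coverage`` is taken, then codes with fewer than
    ``min_patients`` patients are dropped. ``counts`` may override the ranking
    statistic (e.g. raw record counts instead of patient counts).
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    if counts is None:
        counts = observation.counts()
    ranked = counts.sort_index().sort_values(ascending=False, kind="stable")
    total = float(ranked.sum())
    if total <= 0:
        raise ValueError("no cases in the observation window")
    cum = ranked.cumsum() / total
    # shortest prefix reaching the coverage target
    n_keep = int(np.searchsorted(cum.values, coverage - 1e-12) + 1)
    n_keep = min(n_keep, len(ranked))
    prefix = ranked.iloc[:n_keep]
    kept = prefix[prefix >= min_patients]
    if kept.empty:
        raise ValueError(
            f"no code reaches min_patients={min_patients} "
            f"(largest count is {int(ranked.iloc[0])})"
        )
    achieved = float(prefix.sum() / total)
    return CodeSelection(list(kept.index), achieved, min_patients, counts)
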