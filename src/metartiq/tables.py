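"""Study tables: per-case records and per-reader ordinal scores.

A :class:`CaseRecord` is one reconstruction case of the reader study: the
acquisition/reconstruction covariates (kVp, IQ level, kernel, iMAR preset,
VMI energy, slice thickness), the four objective artifact metrics, and the
visual-grading tallies Q1-Q6 with their sum VG_SUM.  A
:class:`ReaderScoreTable` holds the raw case x reader x question ordinal
scores (1-5) those tallies derive from.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "KERNEL_LEVELS",
    "IMAR_LEVELS",
    "VMI_LEVELS",
    "QUESTIONS",
    "CaseRecord",
    "ReaderScoreTable",
    "read_case_table",
    "cases_to_dataframe",
]

KERNEL_LEVELS = (
    "Qr36f", "Qr40f", "Qr44f", "Qr56f",
    "Bl56f",
    "Bv36f", "Bv40f", "Bv44f", "Bv56f",
)
IMAR_LEVELS = ("None", "Pacemaker", "ThoracicCoils", "HipImplants", "ExtremityImplants")
# VMI levels are stored as strings: numeric keV, the poly-energetic T3D, and
# the spectral post-processing level SPP-70 (distinct from plain 70 keV).
VMI_LEVELS = ("40", "62", "67", "70", "90", "110", "190", "SPP-70", "T3D")
QUESTIONS = ("Q1", "Q2", "Q3", "Q4", "Q5", "Q6")

#: abbreviations used in the printed study tables -> canonical preset names
IMAR_ABBREVIATIONS = {
    "Pa": "Pacemaker",
    "Th": "ThoracicCoils",
    "Tc": "ThoracicCoils",
    "Hi": "HipImplants",
    "Ex": "ExtremityImplants",
    "Ei": "ExtremityImplants",
    "None": "None",
}


@dataclass
class CaseRecord:
    """One reconstruction case: covariates, artifact metrics and VG tallies."""

    case_id: str
    kvp: float
    iq: float
    kernel: str
    imar: str
    vmi: str
    slice_mm: float
    diff_hu: float
    sd_artifact: float
    bloom_vol: float | None  # cm**3; None when not measurable for the case
    amplitude_low_freq: float
    cv: float
    q1: int
    q2: int
    q3: int
    q4: int
    q5: int
    q6: int
    vg_sum: int
    n_readers: int = 6

    def __post_init__(self) -> None:
        if self.kernel not in KERNEL_LEVELS:
            raise ValueError(
                f"case {self.case_id}: unknown kernel {self.kernel!r}; allowed: {KERNEL_LEVELS}"
            )
        if self.imar not in IMAR_LEVELS:
            raise ValueError(
                f"case {self.case_id}: unknown iMAR preset {self.imar!r}; allowed: {IMAR_LEVELS}"
            )
        self.vmi = str(self.vmi)
        if self.vmi not in VMI_LEVELS:
            raise ValueError(
                f"case {self.case_id}: unknown VMI level {self.vmi!r}; allowed: {VMI_LEVELS}"
            )
        tallies = self.tallies
        for q, v in zip(QUESTIONS, tallies):
            if not 0 <= v <= self.n_readers:
                raise ValueError(f"case {self.case_id}: {q} tally {v} outside [0, {self.n_readers}]")
        if self.vg_sum != sum(tallies):
            raise ValueError(
                f"case {self.case_id}: vg_sum {self.vg_sum} != sum of Q1..Q6 {sum(tallies)}"
            )
        if self.bloom_vol is not None and math.isnan(self.bloom_vol):
            self.bloom_vol = None

    @property
    def tallies(self) -> tuple[int, ...]:
        return (self.q1, self.q2, self.q3, self.q4, self.q5, self.q6)

    @property
    def vmi_numeric(self) -> float | None:
        """VMI energy in keV, or None for the poly-energetic/SPP levels."""
        try:
            return float(self.vmi)
        except ValueError:
            return None


_CASE_COLUMNS = [
    "case_id", "kvp", "iq", "kernel", "imar", "vmi", "slice_mm",
    "diff_hu", "sd_artifact", "bloom_vol", "amplitude_low_freq", "cv",
    "q1", "q2", "q3", "q4", "q5", "q6", "vg_sum",
]


def read_case_table(path: str | os.PathLike) -> list[CaseRecord]:
    """Read a delimited per-case table into validated :class:`CaseRecord`s.

    Expected columns: ``case_id,kvp,iq,kernel,imar,vmi,slice_mm,diff_hu,
    sd_artifact,bloom_vol,amplitude_low_freq,cv,q1..q6,vg_sum``.  Missing
    values are empty fields; iMAR abbreviations from the printed tables
    ("Pa", "Th", ...) are expanded to full preset names.
    """
    # keep_default_na=False so the iMAR level "None" survives as a string;
    # only empty fields are missing values
    df = pd.read_csv(
        path,
        dtype={"vmi": str, "case_id": str, "imar": str, "kernel": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in _CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"case table {path} is missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        imar = IMAR_ABBREVIATIONS.get(str(row["imar"]), str(row["imar"]))
        bloom = row["bloom_vol"]
        records.append(
            CaseRecord(
                case_id=str(row["case_id"]),
                kvp=float(row["kvp"]),
                iq=float(row["iq"]),
                kernel=str(row["kernel"]),
                imar=imar,
                vmi=str(row["vmi"]),
                slice_mm=float(row["slice_mm"]),
                diff_hu=float(row["diff_hu"]),
                sd_artifact=float(row["sd_artifact"]),
                bloom_vol=None if pd.isna(bloom) else float(bloom),
                amplitude_low_freq=float(row["amplitude_low_freq"]),
                cv=float(row["cv"]),
                q1=int(row["q1"]), q2=int(row["q2"]), q3=int(row["q3"]),
                q4=int(row["q4"]), q5=int(row["q5"]), q6=int(row["q6"]),
                vg_sum=int(row["vg_sum"]),
            )
        )
    return records


def cases_to_dataframe(cases: Iterable[CaseRecord]) -> pd.DataFrame:
    """Tabulate case records; missing bloom_vol becomes NaN."""
    rows = []
    for c in cases:
        rows.append({
            "case_id": c.case_id, "kvp": c.kvp, "iq": c.iq, "kernel": c.kernel,
            "imar": c.imar, "vmi": c.vmi, "slice_mm": c.slice_mm,
            "diff_hu": c.diff_hu, "sd_artifact": c.sd_artifact,
            "bloom_vol": np.nan if c.bloom_vol is None else c.bloom_vol,
            "amplitude_low_freq": c.amplitude_low_freq, "cv": c.cv,
            "q1": c.q1, "q2": c.q2, "q3": c.q3, "q4": c.q4, "q5": c.q5, "q6": c.q6,
            "vg_sum": c.vg_sum,
        })
    return pd.DataFrame(rows).set_index("case_id")


@dataclass
class ReaderScoreTable:
    """Ordinal 1-5 scores per (case, reader, question) with case covariates.

    ``scores`` maps ``(case_id, reader_id, question)`` to an integer score;
    ``metadata`` maps ``case_id`` to a covariate mapping (kvp, iq, kernel,
    imar, vmi, slice_mm) used by the regression layer.
    """

    scores: dict[tuple[str, str, str], int]
    metadata: dict[str, Mapping[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, s in self.scores.items():
            if s not in (1, 2, 3, 4, 5):
                raise ValueError(f"score {s} for {key} outside 1..5")
            if key[2] not in QUESTIONS:
                raise ValueError(f"unknown question {key[2]!r} (expected one of {QUESTIONS})")

    @property
    def case_ids(self) -> list[str]:
        return sorted({k[0] for k in self.scores})

    @property
    def reader_ids(self) -> list[str]:
        return sorted({k[1] for k in self.scores})

    def question_matrix(self, question: str) -> pd.DataFrame:
        """Case x reader score matrix for one question (NaN where missing)."""
        if question not in QUESTIONS:
            raise ValueError(f"unknown question {question!r}")
        cases, readers = self.case_ids, self.reader_ids
        mat = pd.DataFrame(np.nan, index=cases, columns=readers)
        for (cid, rid, q), s in self.scores.items():
            if q == question:
                mat.loc[cid, rid] = s
        return mat

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"case_id": c, "reader_id": r, "question": q, "score": s}
            for (c, r, q), s in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, metadata: Mapping[str, Mapping[str, object]] | None = None
    ) -> "ReaderScoreTable":
        scores: dict[tuple[str, str, str], int] = {}
        for _, row in df.iterrows():
            key = (str(row["case_id"]), str(row["reader_id"]), str(row["question"]))
            if key in scores:
                raise ValueError(f"duplicate score entry for {key}")
            scores[key] = int(row["score"])
        return cls(scores=scores, metadata=dict(metadata or {}))
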