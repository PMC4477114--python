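"""Study design table: subjects, group labels, age, and behavior scores."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StudyDesign", "read_design", "write_design", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "depression_score",
    "executive_score",
)


@dataclass
class StudyDesign:
    """Per-subject design information.

    ``group`` is categorical (e.g. control / depressed, optionally with
    sub-labels such as remitted / active); levels are kept in first-seen
    file order. Subject IDs must be unique.
    """

    subject_ids: list[str]
    group: np.ndarray
    age: np.ndarray
    depression_score: np.ndarray
    executive_score: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        seen: set[str] = set()
        for sid in self.subject_ids:
            if sid in seen:
                raise ValueError(f"duplicate subject ID: {sid}")
            seen.add(sid)
        n = len(self.subject_ids)
        self.group = np.asarray(self.group, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        self.depression_score = np.asarray(self.depression_score, dtype=float)
        self.executive_score = np.asarray(self.executive_score, dtype=float)
        for name in ("group", "age", "depression_score", "executive_score"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def group_levels(self) -> list[str]:
        """Group labels in first-seen order."""
        levels: list[str] = []
        for g in self.group:
            if g not in levels:
                levels.append(g)
        return levels

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.group == g).sum()) for g in self.group_levels}

    def indices_of(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.group == group)

    def subset(self, idx: np.ndarray) -> "StudyDesign":
        idx = np.asarray(idx)
        return StudyDesign(
            subject_ids=[self.subject_ids[i] for i in idx],
            group=self.group[idx],
            age=self.age[idx],
            depression_score=self.depression_score[idx],
            executive_score=self.executive_score[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "group": self.group,
                "age": self.age,
                "depression_score": self.depression_score,
                "executive_score": self.executive_score,
            }
        )


def read_design(path: str | os.PathLike) -> StudyDesign:
    """Read a study design TSV.

    The header must contain ``subject_id``, ``group``, ``age``,
    ``depression_score`` and ``executive_score``. Raises on duplicate
    subject IDs (naming the first offender) or missing columns.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table missing required column(s): {missing}")
    return StudyDesign(
        subject_ids=list(df["subject_id"]),
        group=df["group"].to_numpy(dtype=object),
        age=df["age"].to_numpy(dtype=float),
        depression_score=df["depression_score"].to_numpy(dtype=float),
        executive_score=df["executive_score"].to_numpy(dtype=float),
    )


def write_design(design: StudyDesign, path: str | os.PathLike) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)
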