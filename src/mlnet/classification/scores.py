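"""Per-case predicted probabilities paired with ids and true labels."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ScoreSet"]


@dataclass
class ScoreSet:
    patient_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.patient_ids) == self.scores.size == self.labels.size):
            raise ValueError("ids, scores and labels must have equal length")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("scores must lie in [0, 1]")
        if not np.isin(np.unique(self.labels), (0, 1)).all():
            raise ValueError("labels must be binary")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids in score set")

    def __len__(self) -> int:
        return self.scores.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_ids, "score": self.scores, "label": self.labels}
        )

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreSet":
        df = pd.read_csv(path, dtype={"patient_id": str})
        return cls(df["patient_id"].tolist(), df["score"].values, df["label"].values)
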