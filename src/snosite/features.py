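"""Assembly of the full 458-dimensional feature vector and the labelled
feature matrix.

Order is fixed package-wide: 400 evolutionary-conservation features,
then 9 secondary-structure features, then 49 physicochemical features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .physchem import PropertyTable, encode_physchem, load_property_table
from .pssm import EVO_FEATURE_NAMES, PSSMProfile, encode_evolutionary
from .sstruct import SS_FEATURE_NAMES, SSString, encode_secondary
from .windows import PeptideWindow

N_FEATURES = 458


def feature_names(table: PropertyTable | None = None) -> list[str]:
    """The 458 feature names in canonical encoder order."""
    if table is None:
        table = load_property_table()
    return EVO_FEATURE_NAMES + SS_FEATURE_NAMES + table.feature_names


def encode_window(
    window: PeptideWindow,
    profile: PSSMProfile,
    ss: SSString,
    table: PropertyTable,
) -> np.ndarray:
    """Concatenate the three encoders for one window: 400 + 9 + 49 = 458."""
    return np.concatenate([
        encode_evolutionary(window, profile),
        encode_secondary(window, ss),
        encode_physchem(window, table),
    ])


@dataclass
class FeatureMatrix:
    """Samples x named features with binary labels (1 = SNO site)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("one label per sample row required")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("one name per feature column required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.X.shape[0])]
        elif len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("one id per sample row required")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names,
                          index=pd.Index(self.sample_ids, name="sample"))
        df.insert(0, "label", self.y)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "label" not in df.columns:
            raise ValueError(f"{path}: missing 'label' column")
        y = df.pop("label").to_numpy()
        return cls(X=df.to_numpy(dtype=np.float64), y=y,
                   feature_names=[str(c) for c in df.columns],
                   sample_ids=[str(i) for i in df.index])


def build_feature_matrix(
    windows: Sequence[PeptideWindow],
    profiles: Mapping[str, PSSMProfile],
    ss_strings: Mapping[str, SSString],
    table: PropertyTable | None = None,
) -> FeatureMatrix:
    """Encode labelled windows into a samples x 458 matrix.

    Every window must carry a label and have a profile and a
    secondary-structure string for its parent protein.
    """
    if table is None:
        table = load_property_table()
    names = feature_names(table)
    rows, labels, ids = [], [], []
    for w in windows:
        if w.label is None:
            raise ValueError(f"{w.protein_id}:{w.center_pos}: unlabelled window")
        if w.protein_id not in profiles:
            raise KeyError(f"no PSSM profile for protein {w.protein_id!r}")
        if w.protein_id not in ss_strings:
            raise KeyError(f"no secondary structure for protein {w.protein_id!r}")
        rows.append(encode_window(w, profiles[w.protein_id],
                                  ss_strings[w.protein_id], table))
        labels.append(w.label)
        ids.append(f"{w.protein_id}:{w.center_pos}")
    X = np.array(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(X=X, y=np.array(labels, dtype=np.int64),
                         feature_names=names, sample_ids=ids)
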