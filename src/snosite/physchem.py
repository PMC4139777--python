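"""Physicochemical-property features.

A window is summarized against a table of 49 per-residue properties
(physical-chemical, energetic and conformational scales): each feature is
the mean of one property over the window's non-padded residues. The
encoder is agnostic to the particular table — any 49-property x 20-residue
table with canonical one-letter column headers works.

The bundled default table is a synthetic stand-in: 49 deterministic,
heterogeneously-scaled pseudo-properties generated once and frozen
(see ``data/physchem_properties_synthetic.csv``). It exercises the
averaging contract; substitute a curated table via
:func:`load_property_table` for scientific use.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._alphabet import AA_INDEX, AA_ORDER
from .windows import FormatError, PeptideWindow

N_PHYSCHEM_FEATURES = 49

_BUNDLED = "physchem_properties_synthetic.csv"


@dataclass
class PropertyTable:
    """49 named per-amino-acid property scales.

    ``values`` is 49 x 20 with columns in the canonical alphabetical
    amino-acid order.
    """

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_PHYSCHEM_FEATURES, 20):
            raise FormatError(
                f"property table must be {N_PHYSCHEM_FEATURES} x 20, "
                f"got {self.values.shape}"
            )
        if len(self.names) != N_PHYSCHEM_FEATURES:
            raise FormatError("one name per property row required")
        if len(set(self.names)) != len(self.names):
            raise FormatError("property names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("property table contains missing/non-finite entries")

    @property
    def feature_names(self) -> list[str]:
        return [f"pc_{n}" for n in self.names]


def load_property_table(path: str | Path | None = None) -> PropertyTable:
    """Load a property table CSV (rows: properties; columns: one-letter
    amino-acid codes, any order; first column: property name). With no
    path, the bundled synthetic default is used."""
    if path is None:
        ref = resources.files("snosite.data") / _BUNDLED
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    cols = [str(c).strip().upper() for c in df.columns]
    unknown = [c for c in cols if c not in AA_INDEX]
    if unknown:
        raise FormatError(f"unknown amino-acid column header(s): {unknown}")
    if sorted(cols) != sorted(AA_ORDER):
        raise FormatError("property table must have exactly the 20 standard "
                          "amino-acid columns")
    df.columns = cols
    df = df[list(AA_ORDER)]  # re-map to canonical order by header letters
    return PropertyTable(names=[str(n) for n in df.index], values=df.to_numpy())


def encode_physchem(window: PeptideWindow, table: PropertyTable,
                    denominator: str = "residues") -> np.ndarray:
    """49 per-property means over the window's non-padded residues.

    Padding X positions contribute nothing to the sums. With
    ``denominator="residues"`` (default) the sums are divided by the
    non-X residue count; ``denominator="window"`` divides by the full
    window length instead, treating padding as zero-valued context. An
    all-X window encodes to zeros either way.
    """
    if denominator not in ("residues", "window"):
        raise ValueError("denominator must be 'residues' or 'window'")
    idx = [AA_INDEX[aa] for aa in window.peptide if aa != "X"]
    if not idx:
        return np.zeros(N_PHYSCHEM_FEATURES)
    den = len(window.peptide) if denominator == "window" else len(idx)
    return table.values[:, idx].sum(axis=1) / den
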