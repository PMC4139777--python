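"""Predicted secondary-structure features.

Per-residue three-state predictions (H = helix, E = strand, C = coil),
e.g. from PSIPRED, are summarized over the residues a peptide window
actually covers (padding X positions excluded). For each state the
encoder reports the residue total, the average maximal-run length, and
the composition fraction — nine features per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from pathlib import Path

import numpy as np

from ._alphabet import SS_STATES
from .windows import FormatError, PeptideWindow

N_SS_FEATURES = 9

#: fixed output order: per state (H, E, C): total, average run length, composition
SS_FEATURE_NAMES = [
    f"ss_{state}_{stat}"
    for state in SS_STATES
    for stat in ("total", "avglen", "comp")
]


@dataclass(frozen=True)
class SSString:
    """Per-residue secondary-structure states of one protein."""

    protein_id: str
    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(SS_STATES)
        if bad:
            raise FormatError(
                f"{self.protein_id}: secondary-structure states {sorted(bad)} "
                f"outside {{H, E, C}}"
            )
        if not self.labels:
            raise FormatError(f"{self.protein_id}: empty secondary structure")

    def __len__(self) -> int:
        return len(self.labels)


def parse_ss2(path: str | Path, protein_id: str | None = None) -> SSString:
    """Parse a PSIPRED vertical-format (.ss2) prediction.

    Rows are ``index residue state p_coil p_helix p_strand``; comment
    lines start with '#'. The state-letter column is taken as the
    prediction (it is PSIPRED's own argmax). Lowercase state letters are
    normalized. A single-line plain H/E/C string file is also accepted,
    for hand-written fixtures.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    labels: list[str] = []
    expected = 1
    body = [
        (n, ln) for n, ln in enumerate(path.read_text().splitlines(), 1)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not body:
        raise FormatError(f"{path}: empty secondary-structure file")
    if len(body) == 1 and len(body[0][1].split()) == 1:
        # plain-string fixture dialect: one line of H/E/C letters
        return SSString(protein_id=protein_id, labels=body[0][1].strip().upper())
    for lineno, line in body:
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected index, residue, state")
        try:
            idx = int(parts[0])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: bad index {parts[0]!r}") from None
        if idx != expected:
            raise FormatError(
                f"{path}:{lineno}: non-contiguous index {idx} (expected {expected})"
            )
        expected += 1
        state = parts[2].upper()
        if state not in SS_STATES:
            raise FormatError(f"{path}:{lineno}: unknown state {parts[2]!r}")
        labels.append(state)
    return SSString(protein_id=protein_id, labels="".join(labels))


def write_ss2(ss: SSString, residues: str) -> str:
    """Render a state string to the vertical format (uniform fake
    probabilities); round-trips through :func:`parse_ss2`."""
    lines = ["# PSIPRED VFORMAT", ""]
    probs = {"C": "1.000 0.000 0.000", "H": "0.000 1.000 0.000",
             "E": "0.000 0.000 1.000"}
    for i, (aa, st) in enumerate(zip(residues, ss.labels), 1):
        lines.append(f"{i:4d} {aa} {st}   {probs[st]}")
    lines.append("")
    return "\n".join(lines)


def _segment_stats(slice_labels: str, comp_denominator: int) -> np.ndarray:
    values = np.zeros(9)
    for si, state in enumerate(SS_STATES):
        total = slice_labels.count(state)
        runs = sum(1 for key, _ in groupby(slice_labels) if key == state)
        avglen = total / runs if runs else 0.0
        comp = total / comp_denominator if comp_denominator else 0.0
        values[3 * si: 3 * si + 3] = (total, avglen, comp)
    return values


def encode_secondary(window: PeptideWindow, ss: SSString,
                     denominator: str = "residues") -> np.ndarray:
    """Nine segment statistics of the window's secondary structure.

    The state labels at the window's non-padded positions are sliced out;
    per state the residue total, average maximal-run length (0 when the
    state is absent) and composition fraction are computed on that slice.
    A run truncated by the window boundary counts as one run. An all-X
    window yields nine zeros. ``denominator`` picks the composition
    denominator: the non-X residue count (default) or the full window
    length (``"window"``).
    """
    if denominator not in ("residues", "window"):
        raise ValueError("denominator must be 'residues' or 'window'")
    L = len(ss)
    chars = []
    for pos, aa in zip(window.parent_positions, window.peptide):
        if aa == "X":
            continue
        if not (1 <= pos <= L):
            raise ValueError(
                f"{window.protein_id}:{pos}: window position outside "
                f"secondary structure of length {L}"
            )
        chars.append(ss.labels[pos - 1])
    comp_den = len(window.peptide) if denominator == "window" else len(chars)
    return _segment_stats("".join(chars), comp_den)
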