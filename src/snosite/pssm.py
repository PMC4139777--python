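"""Evolutionary-conservation features from PSI-BLAST position-specific
scoring matrices.

The profile of a protein of length L is an L x 20 integer matrix of
log-odds substitution scores: entry (i, j) scores the residue at sequence
position i being substituted by amino-acid type j over the alignment.
Positive scores mark substitutions observed more often than expected by
chance, negative scores the opposite.

A peptide window is encoded by aggregating the profile rows it covers
into a 20 x 20 matrix keyed by (source residue type, target type): the
row of every non-padded window position is summed into the row of its
residue's type. Flattened row-major this yields 400 features. Padded X
positions contribute nothing, so an all-X window encodes to zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._alphabet import AA_INDEX, AA_ORDER
from .windows import FormatError, PeptideWindow

N_EVO_FEATURES = 400

EVO_FEATURE_NAMES = [f"evo_{a}>{b}" for a in AA_ORDER for b in AA_ORDER]


@dataclass
class PSSMProfile:
    """Per-protein substitution-score profile.

    ``scores`` is an L x 20 integer matrix with columns in the canonical
    alphabetical amino-acid order; ``residues`` is the length-L sequence
    the profile was computed on.
    """

    protein_id: str
    scores: np.ndarray
    residues: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"scores must be L x 20, got {self.scores.shape}")
        if self.scores.shape[0] != len(self.residues):
            raise ValueError(
                f"{self.protein_id}: {self.scores.shape[0]} score rows for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


def parse_pssm(path: str | Path, protein_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (the ``-Q``/``-out_ascii_pssm`` dialect).

    The file starts with free-text header lines, then a line of amino-acid
    column letters (20 letters, or 40 when the weighted-percentage block is
    present), then one row per position: index, residue, 20 log-odds
    integers, optionally 20 percentages and two trailing floats. Only the
    log-odds block is kept. Columns are re-mapped from the file's own
    header order to the canonical alphabetical order.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    lines = path.read_text().splitlines()

    header_cols: list[str] | None = None
    rows: list[list[int]] = []
    residues: list[str] = []
    expected_index = 1
    for lineno, line in enumerate(lines, 1):
        parts = line.split()
        if header_cols is None:
            if parts and all(len(p) == 1 and p in AA_INDEX for p in parts) \
                    and len(parts) in (20, 40):
                header_cols = parts[:20]
            continue
        if not parts:
            continue
        if not parts[0].isdigit():
            break  # footer (K/lambda statistics) terminates the table
        if len(parts) < 22:
            raise FormatError(
                f"{path}:{lineno}: expected index, residue and >=20 scores"
            )
        idx = int(parts[0])
        if idx != expected_index:
            raise FormatError(
                f"{path}:{lineno}: non-contiguous position index {idx} "
                f"(expected {expected_index})"
            )
        expected_index += 1
        residue = parts[1]
        if len(residue) != 1:
            raise FormatError(f"{path}:{lineno}: bad residue field {residue!r}")
        try:
            scores = [int(v) for v in parts[2:22]]
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-integer log-odds score"
            ) from None
        residues.append(residue.upper())
        rows.append(scores)
    if header_cols is None:
        raise FormatError(f"{path}: no amino-acid header line found")
    if not rows:
        raise FormatError(f"{path}: no score rows found")

    mat = np.array(rows, dtype=np.int64)
    # re-map file column order -> canonical alphabetical order
    order = np.array([AA_INDEX[a] for a in header_cols])
    canonical = np.empty_like(mat)
    canonical[:, order] = mat
    return PSSMProfile(protein_id=protein_id, scores=canonical,
                       residues="".join(residues))


def check_profile_consistency(profile: PSSMProfile, sequence: str) -> None:
    """Warn if the profile's residue column disagrees with the sequence."""
    if profile.residues != sequence:
        n_bad = sum(a != b for a, b in zip(profile.residues, sequence)) \
            + abs(len(profile.residues) - len(sequence))
        warnings.warn(
            f"profile {profile.protein_id!r}: residue column disagrees with "
            f"the protein sequence at {n_bad} position(s)",
            stacklevel=2,
        )


def encode_evolutionary(window: PeptideWindow, profile: PSSMProfile,
                        normalize: bool = False) -> np.ndarray:
    """400-dimensional evolutionary feature vector of a window.

    For each non-X window position whose parent residue has type i, the
    20 profile scores of that position are added into row i of a 20 x 20
    accumulation matrix; the result is the row-major flattening. With
    ``normalize=True`` each row is divided by the count of window
    residues of its type (rows of absent types stay zero); the default
    keeps the plain sums.
    """
    m = np.zeros((20, 20), dtype=np.float64)
    counts = np.zeros(20)
    L = len(profile)
    for pos, aa in zip(window.parent_positions, window.peptide):
        if aa == "X":
            continue
        if not (1 <= pos <= L):
            raise ValueError(
                f"{window.protein_id}:{pos}: non-padded window position "
                f"outside profile of length {L}"
            )
        m[AA_INDEX[aa]] += profile.scores[pos - 1]
        counts[AA_INDEX[aa]] += 1
    if normalize:
        m[counts > 0] /= counts[counts > 0, None]
    return m.ravel()


def format_pssm(profile: PSSMProfile) -> str:
    """Render a profile back to the PSI-BLAST ASCII dialect (log-odds
    block only); round-trips through :func:`parse_pssm`."""
    blast_order = "ARNDCQEGHILKMFPSTWYV"
    cols = [AA_INDEX[a] for a in blast_order]
    out = [
        "",
        "Last position-specific scoring matrix computed",
        "            " + "  ".join(blast_order),
    ]
    for i, (aa, row) in enumerate(zip(profile.residues, profile.scores), 1):
        vals = " ".join(f"{row[c]:3d}" for c in cols)
        out.append(f"{i:5d} {aa}  {vals}")
    out.append("")
    return "\n".join(out)
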