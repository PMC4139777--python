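"""Cysteine-centered peptide windows.

A candidate S-nitrosylation site is a cysteine residue; its sequence
context is captured as a fixed-length window of ``2*xi + 1`` residues
centered on the cysteine. Positions that fall outside the protein are
padded with the dummy residue ``X``. Site coordinates are 1-based
throughout the package, matching the convention of curated PTM site
databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from ._alphabet import AA_SET, PAD

DEFAULT_XI = 10

POSITIVE = 1
NEGATIVE = 0


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class SiteValidationError(ValueError):
    """Raised when a labelled site does not point at a cysteine."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 standard one-letter codes."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if not self.sequence:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_SET - {PAD}
        if bad:
            raise FormatError(
                f"protein {self.id!r}: non-standard residues {sorted(bad)}; "
                "use unknown='mask' in read_fasta to map them to X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideWindow:
    """A ``2*xi + 1``-mer centered on a cysteine, X-padded at the termini.

    ``center_pos`` is the 1-based index of the central cysteine in the
    parent protein; ``label`` is 1 for an SNO site, 0 for a non-SNO site,
    or None when unlabelled.
    """

    protein_id: str
    center_pos: int
    xi: int
    peptide: str
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.peptide) != 2 * self.xi + 1:
            raise ValueError(
                f"window length {len(self.peptide)} != 2*{self.xi}+1"
            )
        if self.peptide[self.xi] != "C":
            raise ValueError(
                f"{self.protein_id}:{self.center_pos}: central residue "
                f"{self.peptide[self.xi]!r} is not C"
            )

    @property
    def parent_positions(self) -> range:
        """1-based parent coordinates covered by the window (may exceed
        the protein; compare against the parent length before use)."""
        return range(self.center_pos - self.xi, self.center_pos + self.xi + 1)


def read_fasta(path: str | Path, unknown: str = "error") -> list[ProteinRecord]:
    """Read protein records from a FASTA file, in file order.

    Parameters
    ----------
    path : file path
    unknown : {"error", "mask"}
        "error" rejects sequences containing residues outside the 20
        standard letters; "mask" maps them to the dummy code X.
    """
    if unknown not in ("error", "mask"):
        raise ValueError("unknown must be 'error' or 'mask'")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if unknown == "mask":
            seq = "".join(c if c in AA_SET else PAD for c in seq)
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def window_at(protein: ProteinRecord, center_pos: int, xi: int = DEFAULT_XI,
              label: int | None = None) -> PeptideWindow:
    """Build the window around a 1-based cysteine position."""
    if not (1 <= center_pos <= len(protein)):
        raise SiteValidationError(
            f"{protein.id}: position {center_pos} outside 1..{len(protein)}"
        )
    if protein.sequence[center_pos - 1] != "C":
        raise SiteValidationError(
            f"{protein.id}: residue at position {center_pos} is "
            f"{protein.sequence[center_pos - 1]!r}, not C"
        )
    chars = []
    for pos in range(center_pos - xi, center_pos + xi + 1):
        if 1 <= pos <= len(protein):
            chars.append(protein.sequence[pos - 1])
        else:
            chars.append(PAD)
    return PeptideWindow(protein_id=protein.id, center_pos=center_pos,
                         xi=xi, peptide="".join(chars), label=label)


def extract_windows(protein: ProteinRecord, xi: int = DEFAULT_XI) -> list[PeptideWindow]:
    """One window per cysteine in the protein, in increasing position."""
    if xi < 1:
        raise ValueError("xi must be >= 1")
    return [
        window_at(protein, i + 1, xi)
        for i, aa in enumerate(protein.sequence)
        if aa == "C"
    ]


def read_site_labels(
    path: str | Path,
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> list[tuple[str, int, int]]:
    """Parse a site-label TSV: ``protein_id<TAB>position<TAB>label(1/0)``.

    Duplicated (protein, position) rows are rejected. When ``proteins``
    is given, every site is validated to point at a cysteine of a known
    protein; offenders are reported together, not silently skipped.
    """
    triples: list[tuple[str, int, int]] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            pid, pos_s, lab_s = parts
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: position {pos_s!r} is not an integer") from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be positive")
            if lab_s not in ("0", "1"):
                raise FormatError(f"{path}:{lineno}: label {lab_s!r} must be 1 or 0")
            key = (pid, pos)
            if key in seen:
                raise FormatError(f"{path}:{lineno}: duplicate site {pid}:{pos}")
            seen.add(key)
            triples.append((pid, pos, int(lab_s)))
    if proteins is not None:
        offenders = []
        for pid, pos, _ in triples:
            if pid not in proteins:
                offenders.append(f"{pid}:{pos} (unknown protein)")
            elif not (1 <= pos <= len(proteins[pid])):
                offenders.append(f"{pid}:{pos} (outside 1..{len(proteins[pid])})")
            elif proteins[pid].sequence[pos - 1] != "C":
                offenders.append(
                    f"{pid}:{pos} (residue {proteins[pid].sequence[pos - 1]})"
                )
        if offenders:
            raise SiteValidationError(
                "labelled sites not at a cysteine: " + "; ".join(offenders)
            )
    return triples


def compile_windows(
    proteins: Iterable[ProteinRecord],
    sites: Iterable[tuple[str, int, int]],
    xi: int = DEFAULT_XI,
) -> list[PeptideWindow]:
    """Labelled windows for every (protein, position, label) site triple."""
    by_id = {p.id: p for p in proteins}
    out = []
    for pid, pos, label in sites:
        if pid not in by_id:
            raise SiteValidationError(f"site references unknown protein {pid!r}")
        out.append(window_at(by_id[pid], pos, xi=xi, label=label))
    return out
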