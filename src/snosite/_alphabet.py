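"""Canonical amino-acid alphabet shared by every encoder in the package.

The 20 standard residues are kept in alphabetical one-letter order
(A, C, D, ..., Y). Every matrix with an amino-acid axis — PSSM columns,
the 20x20 evolutionary aggregation, the physicochemical property table —
uses this order. Files that arrive in a different order (e.g. the
PSI-BLAST ARNDCQEGHILKMFPSTWYV column layout) are re-mapped at parse time
using their own header letters.
"""

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
AA_SET = frozenset(AA_ORDER)

#: dummy residue used to pad windows that run off a protein terminus
PAD = "X"

#: secondary-structure states: helix, strand, coil
SS_STATES = "HEC"
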