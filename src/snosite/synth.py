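"""Synthetic fixtures: proteins, PSSM-like profiles, secondary-structure
strings, labelled sites, and two-class feature sets with controllable
separation.

Everything is drawn from a single NumPy PCG64 ``default_rng`` stream
keyed by the config seed, so generation is fully deterministic and
byte-stable across runs. The feature-set generator plants
``n_informative_features`` whose class means differ by ``effect_size``
within-class standard deviations; the remaining features are identically
distributed in both classes. Default class sizes (731 positive / 810
negative) mirror a typical curated SNO training set. The generator makes
no attempt to emulate real S-nitrosylation sequence motifs; it exists so
every pipeline stage has parseable, statistically controllable input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._alphabet import AA_ORDER, SS_STATES
from .features import FeatureMatrix, N_FEATURES
from .pssm import PSSMProfile, format_pssm
from .sstruct import SSString, write_ss2
from .windows import ProteinRecord

_NON_CYS = AA_ORDER.replace("C", "")


@dataclass
class SynthConfig:
    seed: int = 0
    n_proteins: int = 30
    protein_length_range: tuple[int, int] = (60, 300)
    cys_rate: float = 0.03
    pssm_score_range: tuple[int, int] = (-10, 10)
    ss_run_length_mean: float = 5.0
    n_informative_features: int = 5
    effect_size: float = 3.0
    n_pos: int = 731
    n_neg: int = 810
    positive_site_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.cys_rate < 1) or not (0 < self.positive_site_rate < 1):
            raise ValueError("rates must lie in (0, 1)")
        if self.protein_length_range[0] < 1 or \
                self.protein_length_range[0] > self.protein_length_range[1]:
            raise ValueError("bad protein length range")
        if self.ss_run_length_mean <= 0:
            raise ValueError("ss_run_length_mean must be positive")
        if not (0 <= self.n_informative_features <= N_FEATURES):
            raise ValueError(f"n_informative_features outside 0..{N_FEATURES}")


def _random_protein(rng: np.random.Generator, cfg: SynthConfig, pid: str) -> ProteinRecord:
    lo, hi = cfg.protein_length_range
    L = int(rng.integers(lo, hi + 1))
    is_cys = rng.random(L) < cfg.cys_rate
    other = rng.integers(0, len(_NON_CYS), L)
    seq = ["C" if c else _NON_CYS[o] for c, o in zip(is_cys, other)]
    if "C" not in seq:  # force at least one candidate site
        seq[int(rng.integers(0, L))] = "C"
    return ProteinRecord(id=pid, sequence="".join(seq))


def _random_profile(rng: np.random.Generator, cfg: SynthConfig,
                    protein: ProteinRecord) -> PSSMProfile:
    lo, hi = cfg.pssm_score_range
    L = len(protein)
    scores = rng.integers(lo, hi + 1, size=(L, 20))
    # favor conservation: bump each position's own residue column
    own = np.array([AA_ORDER.index(a) for a in protein.sequence])
    scores[np.arange(L), own] = np.clip(scores[np.arange(L), own] + 4, lo, hi)
    return PSSMProfile(protein_id=protein.id, scores=scores,
                       residues=protein.sequence)


def _random_ss(rng: np.random.Generator, cfg: SynthConfig,
               protein: ProteinRecord) -> SSString:
    labels: list[str] = []
    L = len(protein)
    while len(labels) < L:
        state = SS_STATES[int(rng.integers(0, 3))]
        run = 1 + int(rng.poisson(cfg.ss_run_length_mean - 1))
        labels.extend(state * run)
    return SSString(protein_id=protein.id, labels="".join(labels[:L]))


def generate_protein_set(cfg: SynthConfig) -> tuple[
    list[ProteinRecord], dict[str, PSSMProfile], dict[str, SSString],
    list[tuple[str, int, int]],
]:
    """Mutually consistent proteins, profiles, structure strings and
    randomly labelled cysteine sites."""
    rng = np.random.default_rng(cfg.seed)
    proteins = [_random_protein(rng, cfg, f"synth{i:04d}")
                for i in range(cfg.n_proteins)]
    profiles = {p.id: _random_profile(rng, cfg, p) for p in proteins}
    ss = {p.id: _random_ss(rng, cfg, p) for p in proteins}
    sites = []
    for p in proteins:
        for i, aa in enumerate(p.sequence):
            if aa == "C":
                label = int(rng.random() < cfg.positive_site_rate)
                sites.append((p.id, i + 1, label))
    return proteins, profiles, ss, sites


def write_fixture_dir(cfg: SynthConfig, outdir: str | Path) -> Path:
    """Write a complete on-disk fixture set: proteins.fasta, per-protein
    ``<id>.pssm`` and ``<id>.ss2`` files, and sites.tsv."""
    outdir = Path(outdir)
    (outdir / "pssm").mkdir(parents=True, exist_ok=True)
    (outdir / "ss").mkdir(parents=True, exist_ok=True)
    proteins, profiles, ss, sites = generate_protein_set(cfg)
    with open(outdir / "proteins.fasta", "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")
    for p in proteins:
        (outdir / "pssm" / f"{p.id}.pssm").write_text(format_pssm(profiles[p.id]))
        (outdir / "ss" / f"{p.id}.ss2").write_text(
            write_ss2(ss[p.id], p.sequence))
    with open(outdir / "sites.tsv", "w") as fh:
        for pid, pos, label in sites:
            fh.write(f"{pid}\t{pos}\t{label}\n")
    return outdir


def generate_feature_dataset(cfg: SynthConfig, n_features: int = N_FEATURES
                             ) -> tuple[FeatureMatrix, np.ndarray]:
    """Two-class feature matrix with planted informative features.

    The informative columns (positions chosen at random) jointly
    separate the two class means by ``effect_size`` within-class
    standard deviations: the block-level Mahalanobis separation is
    ``effect_size``, so each of the k informative columns is shifted by
    ``effect_size / sqrt(k)``. Splitting the separation across the block
    keeps every informative feature individually useful — performance
    keeps improving as each one enters a growing feature subset — rather
    than letting a single column saturate the classifier. All other
    columns are shared noise. Each column gets its own log-normal scale
    so the matrix has heterogeneous feature magnitudes, like the real
    encoder stack. Returns the matrix and the informative column indices
    (sorted).
    """
    if cfg.n_informative_features > n_features:
        raise ValueError("more informative features than features")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pos + cfg.n_neg
    y = np.concatenate([np.ones(cfg.n_pos, dtype=np.int64),
                        np.zeros(cfg.n_neg, dtype=np.int64)])
    X = rng.normal(size=(n, n_features))
    informative = np.sort(rng.choice(n_features, cfg.n_informative_features,
                                     replace=False))
    per_feature = cfg.effect_size / np.sqrt(max(cfg.n_informative_features, 1))
    shift = np.where(y == 1, per_feature / 2, -per_feature / 2)
    X[:, informative] += shift[:, None]
    scales = np.exp(rng.normal(0.0, 1.0, n_features))
    X *= scales
    names = [f"f{j:03d}" for j in range(n_features)]
    fm = FeatureMatrix(X=X, y=y, feature_names=names)
    return fm, informative
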