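"""Synthetic inputs with known ground truth.

The generator produces everything the pipeline consumes, so the whole
analysis can be exercised and validated without any external data:

* a synthetic proteome (FASTA) with lengths spread uniformly +/-20 % around
  a target mean and residues drawn from a configurable composition;
* an in-silico stochastic digest: every peptide bond C-terminal to residue
  ``r`` is cut with probability ``specificity[r]`` per generation, a crude
  but sufficient model of protease preference (a broad-specificity
  subtilisin-like profile versus a Leu/Phe-preferring neutral-protease
  profile).  Fragments outside the 3--65 residue identification window are
  retained in the log (they count for the true DH) but excluded from the
  observable peptide table, mirroring how free amino acids, dipeptides and
  under-identified short peptides escape MS identification;
* MS1-like intensities: log-normal with an optional negative length bias,
  emulating the shorter-peptides-fly-better tendency of electrospray MS;
* dose--response absorbance series with a known IC50 for validating the
  regression-based IC50 estimator.

Every output is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import PeptideRecord
from .properties import AMINO_ACIDS

__all__ = [
    "UNIFORM_FREQUENCIES",
    "FISH_MUSCLE_FREQUENCIES",
    "NEUTRASE_LIKE",
    "ALCALASE_LIKE",
    "DigestConfig",
    "IntensityModel",
    "Fragment",
    "DigestLog",
    "DigestResult",
    "generate_proteome",
    "digest",
    "assign_intensities",
    "generate_assay_series",
]

_ORDERED_AA = sorted(AMINO_ACIDS)

#: Uniform residue composition (the default null model).
UNIFORM_FREQUENCIES: dict[str, float] = {a: 1.0 / 20 for a in _ORDERED_AA}

#: Approximate white-fish muscle residue composition (mole fractions,
#: normalized at use).  Rich in Glu/Asp/Lys/Leu as muscle protein is.
FISH_MUSCLE_FREQUENCIES: dict[str, float] = {
    "G": 0.045, "A": 0.062, "S": 0.042, "P": 0.035, "V": 0.051,
    "T": 0.046, "C": 0.011, "L": 0.081, "I": 0.046, "N": 0.040,
    "D": 0.098, "Q": 0.042, "K": 0.090, "E": 0.120, "M": 0.030,
    "H": 0.022, "F": 0.039, "R": 0.060, "Y": 0.034, "W": 0.010,
}

#: Neutral-protease-like specificity: strong preference for Leu and Phe.
NEUTRASE_LIKE: dict[str, float] = {"L": 0.8, "F": 0.8}

#: Subtilisin-like broad specificity towards bulky, uncharged residues.
ALCALASE_LIKE: dict[str, float] = {a: 0.6 for a in "AVLIMFWY"}


@dataclass(frozen=True)
class DigestConfig:
    """Stochastic cleavage model: per-residue C-terminal cut probability,
    applied for ``n_generations`` rounds; fragments outside the retention
    window are logged but unobservable."""

    specificity: Mapping[str, float]
    n_generations: int = 1
    min_len: int = 3
    max_len: int = 65
    seed: int = 0

    def __post_init__(self):
        if self.specificity is None:
            raise ValueError("specificity map is required (may be empty = no cuts)")
        for res, prob in self.specificity.items():
            if res not in AMINO_ACIDS:
                raise ValueError(f"unknown residue {res!r} in specificity")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"cleavage probability {prob} outside [0, 1]")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("retention window must satisfy 1 <= min <= max")
        if self.n_generations < 1:
            raise ValueError("need at least one digestion generation")


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal MS1 intensity with multiplicative length penalty
    ``exp(-length_bias * PCL)``; ``length_bias=0`` removes the bias."""

    log_mean: float = 14.0   # ln-scale; exp(14) ~ 1.2e6 arbitrary units
    log_sd: float = 1.5
    length_bias: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")


@dataclass(frozen=True)
class Fragment:
    protein_id: str
    start: int          # 0-based offset in the parent protein
    sequence: str


@dataclass
class DigestLog:
    """Exact bookkeeping of one digest: every bond and every cut."""

    total_bonds: int = 0
    cut_bonds: int = 0
    cuts: dict[str, tuple[int, ...]] = field(default_factory=dict)
    n_generations: int = 1


@dataclass
class DigestResult:
    observable: list[Fragment]
    unobservable: list[Fragment]
    log: DigestLog

    @property
    def fragments(self) -> list[Fragment]:
        """All fragments, observable or not, in protein order."""
        return sorted(
            self.observable + self.unobservable,
            key=lambda f: (f.protein_id, f.start),
        )


def generate_proteome(
    n_entries: int,
    mean_length: float,
    seed: int = 0,
    frequencies: Mapping[str, float] | None = None,
) -> list[tuple[str, str]]:
    """Synthetic protein sequences as ``(identifier, sequence)`` pairs.

    Lengths are uniform over +/-20 % of the target mean; residues are drawn
    i.i.d. from ``frequencies`` (default: fish-muscle-like composition).
    """
    if n_entries < 1:
        raise ValueError("need at least one protein entry")
    if mean_length < 10:
        raise ValueError("mean length below 10 is not a protein-scale target")
    freqs = frequencies or FISH_MUSCLE_FREQUENCIES
    probs = np.array([freqs.get(a, 0.0) for a in _ORDERED_AA], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("residue frequency table sums to zero")
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    lo = max(1, int(round(0.8 * mean_length)))
    hi = int(round(1.2 * mean_length))
    lengths = rng.integers(lo, hi + 1, size=n_entries)
    aa = np.array(_ORDERED_AA)
    entries = []
    for i, length in enumerate(lengths):
        seq = "".join(aa[rng.choice(len(aa), size=int(length), p=probs)])
        entries.append((f"synprot_{i:05d}", seq))
    return entries


def digest(
    proteome: Iterable[tuple[str, str]],
    config: DigestConfig,
) -> DigestResult:
    """Stochastic in-silico digest of a proteome.

    Concatenating each protein's fragments (observable plus unobservable)
    in order reconstructs the protein exactly.
    """
    rng = np.random.default_rng(config.seed)
    observable: list[Fragment] = []
    unobservable: list[Fragment] = []
    log = DigestLog(n_generations=config.n_generations)
    for protein_id, seq in proteome:
        n_bonds = len(seq) - 1
        log.total_bonds += n_bonds
        probs = np.array(
            [config.specificity.get(res, 0.0) for res in seq[:-1]], dtype=float
        )
        cut = np.zeros(n_bonds, dtype=bool)
        for _ in range(config.n_generations):
            cut |= rng.random(n_bonds) < probs
        positions = tuple(int(i) for i in np.flatnonzero(cut))
        log.cuts[protein_id] = positions
        log.cut_bonds += len(positions)
        starts = [0] + [p + 1 for p in positions]
        ends = [p + 1 for p in positions] + [len(seq)]
        for start, end in zip(starts, ends):
            frag = Fragment(protein_id, start, seq[start:end])
            if config.min_len <= end - start <= config.max_len:
                observable.append(frag)
            else:
                unobservable.append(frag)
    return DigestResult(observable=observable, unobservable=unobservable, log=log)


def assign_intensities(
    peptides: Sequence,
    model: IntensityModel,
    sample: str = "synthetic_sample",
) -> list[PeptideRecord]:
    """Attach MS1-like intensities to digest fragments or plain sequences."""
    if not peptides:
        raise ValueError("empty peptide set")
    sequences = [
        p.sequence if hasattr(p, "sequence") else str(p) for p in peptides
    ]
    rng = np.random.default_rng(model.seed)
    base = rng.lognormal(model.log_mean, model.log_sd, size=len(sequences))
    lengths = np.array([len(s) for s in sequences])
    intensity = base * np.exp(-model.length_bias * lengths)
    return [
        PeptideRecord(seq, sample, float(inten))
        for seq, inten in zip(sequences, intensity)
    ]


def generate_assay_series(
    true_ic50: float,
    slope: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose--response series with known ground truth.

    Inhibition% = 50 + slope * (conc - true_ic50) + Gaussian noise, so the
    noiseless line passes through 50 % exactly at ``true_ic50``.
    """
    if slope <= 0:
        raise ValueError("slope must be positive for a meaningful IC50")
    concs = [float(c) for c in concentrations]
    if len(set(concs)) < 2:
        raise ValueError("need at least two distinct concentrations")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(concs)) if noise_sd > 0 else 0.0
    inhibition = 50.0 + slope * (np.array(concs) - true_ic50) + noise
    return pd.DataFrame(
        {"concentration_mg_per_ml": concs, "inhibition_pct": inhibition}
    )
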