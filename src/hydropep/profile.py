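"""Population-level characterization of a hydrolysate sample.

A hydrolysate is summarized by intensity-weighted and unweighted means of
PCL, PMW and Pz over all identified peptides,

    x_avg = sum_p x_p * I_p / sum_p I_p,

with the spread of the weighted mean given by

    SD = sqrt( sum_p I_p (x_p - x_avg)^2 / ( (M-1)/M * sum_p I_p ) ),

where M counts the non-zero weights.  With unit weights this reduces to the
ordinary sample statistics, so a single formula serves both columns of the
summary table.

The module also provides relative-intensity abundance (a peptide's share of
the total sample MS1 signal, in percent), cross-sample fold changes, top-N
selection with chain-length filters, the fixed binning rules used for
histogram depiction, and two proteome-scale counting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._format import round_half_up
from .io_tables import PeptideRecord, ProteomeStats
from .properties import PropertyVector, compute_properties

__all__ = [
    "WeightedSummary",
    "AbundanceEntry",
    "BinnedHistogram",
    "weighted_mean",
    "weighted_sd",
    "summarize_sample",
    "relative_intensity",
    "fold_change",
    "format_fold_change",
    "top_n",
    "bin_pcl",
    "bin_pmw",
    "bin_pz",
    "histogram",
    "substring_count",
    "combinatorial_space",
]


@dataclass(frozen=True)
class WeightedSummary:
    """Weighted and unweighted population means and SDs for one sample."""

    pcl_avg: float
    pmw_avg: float
    pz_avg: float
    pcl_avg_u: float
    pmw_avg_u: float
    pz_avg_u: float
    sd_pcl: float
    sd_pmw: float
    sd_pz: float
    sd_pcl_u: float
    sd_pmw_u: float
    sd_pz_u: float
    n_peptides: int
    m_nonzero: int

    def as_dict(self) -> dict[str, float]:
        return {
            "n_peptides": self.n_peptides,
            "m_nonzero": self.m_nonzero,
            "pcl_avg": self.pcl_avg, "pmw_avg": self.pmw_avg,
            "pz_avg": self.pz_avg,
            "pcl_avg_u": self.pcl_avg_u, "pmw_avg_u": self.pmw_avg_u,
            "pz_avg_u": self.pz_avg_u,
            "sd_pcl": self.sd_pcl, "sd_pmw": self.sd_pmw, "sd_pz": self.sd_pz,
            "sd_pcl_u": self.sd_pcl_u, "sd_pmw_u": self.sd_pmw_u,
            "sd_pz_u": self.sd_pz_u,
        }


@dataclass(frozen=True)
class AbundanceEntry:
    """A peptide's share of the sample's total MS1 intensity."""

    sequence: str
    ri: float          # percent of total intensity
    rank: int          # 1-based, descending intensity
    intensity: float


@dataclass(frozen=True)
class BinnedHistogram:
    variable: str                      # "PCL" | "PMW" | "Pz"
    bins: tuple[float, ...]            # ordered bin labels
    weighted_fraction: tuple[float, ...]
    unweighted_fraction: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "bin": self.bins,
                "weighted_fraction": self.weighted_fraction,
                "unweighted_fraction": self.unweighted_fraction,
            }
        )


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights differ in length")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights sum to zero; weighted mean undefined")
    return float((values * weights).sum() / total)


def weighted_sd(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted standard deviation with the (M-1)/M finite-population factor,
    M being the number of non-zero weights."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights differ in length")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    m = int((weights != 0).sum())
    if m < 2:
        raise ValueError("need at least two non-zero weights")
    mean = (values * weights).sum() / total
    num = (weights * (values - mean) ** 2).sum()
    return float(math.sqrt(num / ((m - 1) / m * total)))


def summarize_sample(
    records: Sequence[PeptideRecord],
    properties: Mapping[str, PropertyVector] | None = None,
) -> WeightedSummary:
    """Weighted and unweighted PCL/PMW/Pz means and SDs for one sample.

    ``properties`` may carry precomputed per-sequence property vectors;
    missing sequences are computed on the fly.
    """
    if not records:
        raise ValueError("empty sample")
    props = dict(properties) if properties else {}
    for rec in records:
        if rec.sequence not in props:
            props[rec.sequence] = compute_properties(rec.sequence)
    weights = [rec.intensity for rec in records]
    if sum(w > 0 for w in weights) < 2:
        raise ValueError("need at least two records with non-zero intensity")
    unit = [1.0] * len(records)
    cols = {
        "pcl": [props[r.sequence].pcl for r in records],
        "pmw": [props[r.sequence].pmw for r in records],
        "pz": [props[r.sequence].pz for r in records],
    }
    return WeightedSummary(
        pcl_avg=weighted_mean(cols["pcl"], weights),
        pmw_avg=weighted_mean(cols["pmw"], weights),
        pz_avg=weighted_mean(cols["pz"], weights),
        pcl_avg_u=weighted_mean(cols["pcl"], unit),
        pmw_avg_u=weighted_mean(cols["pmw"], unit),
        pz_avg_u=weighted_mean(cols["pz"], unit),
        sd_pcl=weighted_sd(cols["pcl"], weights),
        sd_pmw=weighted_sd(cols["pmw"], weights),
        sd_pz=weighted_sd(cols["pz"], weights),
        sd_pcl_u=weighted_sd(cols["pcl"], unit),
        sd_pmw_u=weighted_sd(cols["pmw"], unit),
        sd_pz_u=weighted_sd(cols["pz"], unit),
        n_peptides=len(records),
        m_nonzero=int(sum(w > 0 for w in weights)),
    )


def relative_intensity(records: Sequence[PeptideRecord]) -> list[AbundanceEntry]:
    """Relative-intensity abundance, descending, ties broken by sequence.

    Intensities of duplicate sequences within the sample are summed before
    normalization; the RI values over a sample total 100 %.
    """
    if not records:
        raise ValueError("empty sample")
    totals: dict[str, float] = {}
    for rec in records:
        totals[rec.sequence] = totals.get(rec.sequence, 0.0) + rec.intensity
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total intensity is zero")
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        AbundanceEntry(seq, 100.0 * inten / grand, rank, inten)
        for rank, (seq, inten) in enumerate(ordered, start=1)
    ]


def fold_change(ri_a: float, ri_b: float) -> float:
    """Abundance ratio of the same peptide between two samples."""
    if ri_b <= 0:
        raise ValueError("reference relative intensity must be positive")
    return ri_a / ri_b


def format_fold_change(ri_a: float, ri_b: float) -> float:
    """Fold change at the one-decimal report precision."""
    return round_half_up(fold_change(ri_a, ri_b), 1)


def top_n(
    entries: Sequence[AbundanceEntry],
    n: int,
    min_len: int | None = None,
    max_len: int | None = None,
) -> list[AbundanceEntry]:
    """First ``n`` abundance entries after the chain-length filter.

    ``min_len`` is exclusive (PCL > min_len) and ``max_len`` inclusive
    (PCL <= max_len), matching the two candidate filters used in practice:
    PCL > 6 for emulsifier scoring, PCL <= 30 for antioxidant candidates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    kept = []
    for entry in sorted(entries, key=lambda e: e.rank):
        length = len(entry.sequence)
        if min_len is not None and not length > min_len:
            continue
        if max_len is not None and not length <= max_len:
            continue
        kept.append(entry)
        if len(kept) == n:
            break
    return kept


def bin_pcl(pcl: float) -> int:
    """Chain-length bin: width 5, labelled by the centre (3--7 -> 5, ...)."""
    return int(5 * math.floor((pcl + 2) / 5))


def bin_pmw(pmw: float) -> int:
    """Two-stage mass binning: nearest-100 labels regrouped into 500-wide
    bins ([150, 750) -> 500, [750, 1250) -> 1000, ...), everything above
    4250 Da collected in the 4500 Da bin."""
    if pmw > 4250:
        return 4500
    if pmw < 750:
        return 500
    return int(500 * math.floor((pmw + 250) / 500))


def bin_pz(pz: float) -> int:
    """Charge bin: nearest integer (half-up), capped at -7 below -6.51 and
    at +3 above +2.5."""
    if pz <= -6.51:
        return -7
    if pz > 2.5:
        return 3
    label = int(math.floor(pz + 0.5))
    return max(-7, min(3, label))


_BINNERS = {"PCL": bin_pcl, "PMW": bin_pmw, "Pz": bin_pz}
_PROP_FIELD = {"PCL": "pcl", "PMW": "pmw", "Pz": "pz"}


def histogram(
    records: Sequence[PeptideRecord],
    variable: str,
    properties: Mapping[str, PropertyVector] | None = None,
) -> BinnedHistogram:
    """Binned distribution of one property, intensity-weighted and unweighted.

    Every peptide falls in exactly one bin and each fraction vector sums
    to 1.
    """
    if variable not in _BINNERS:
        raise ValueError(f"unknown variable {variable!r}; expected PCL/PMW/Pz")
    if not records:
        raise ValueError("empty sample")
    props = dict(properties) if properties else {}
    binner = _BINNERS[variable]
    field = _PROP_FIELD[variable]
    w_mass: dict[float, float] = {}
    u_mass: dict[float, float] = {}
    total_w = 0.0
    for rec in records:
        if rec.sequence not in props:
            props[rec.sequence] = compute_properties(rec.sequence)
        label = binner(getattr(props[rec.sequence], field))
        w_mass[label] = w_mass.get(label, 0.0) + rec.intensity
        u_mass[label] = u_mass.get(label, 0.0) + 1.0
        total_w += rec.intensity
    if total_w <= 0:
        raise ValueError("total intensity is zero")
    bins = tuple(sorted(u_mass))
    return BinnedHistogram(
        variable=variable,
        bins=bins,
        weighted_fraction=tuple(w_mass.get(b, 0.0) / total_w for b in bins),
        unweighted_fraction=tuple(u_mass[b] / len(records) for b in bins),
    )


def substring_count(stats: ProteomeStats, k: int) -> float:
    """Number of length-k substrings in a proteome of ``n_entries`` sequences
    of the given mean length (counting one window set per entry)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > stats.mean_length:
        return 0.0
    return stats.n_entries * (stats.mean_length - k + 1)


def combinatorial_space(k: int, n_mods_per_residue: int = 0) -> int:
    """Size of the length-k peptide sequence space over the 20 standard
    residues, optionally enlarging the alphabet by per-residue variable
    modifications."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return (20 + n_mods_per_residue) ** k
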