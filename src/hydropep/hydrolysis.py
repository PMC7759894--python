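"""Degree-of-hydrolysis arithmetic.

DH is the percentage of cleaved peptide bonds in the substrate.  The bench
estimate uses free alpha-amino nitrogen: DH% = 100 * aAN_hyd / aAN_tot,
where aAN_hyd is the alpha-amino-N content of the hydrolysate and aAN_tot
that of the fully hydrolyzed substrate (both mM/g).  The DH-based mean
chain length is the reciprocal of the hydrolyzed-bond fraction,
PCL_DH = 100 / DH%, so complete hydrolysis (DH = 100 %) yields free
residues (PCL_DH = 1).

For synthetic digests the *true* DH is bookkept exactly from the cleavage
log: cleaved bonds over total substrate bonds.  Bench DH and true DH need
not agree, which is part of what the synthetic generator lets one study.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._format import round_half_up

__all__ = [
    "HydrolysisResult",
    "compute_dh",
    "pcl_from_dh",
    "relative_dh_change",
    "true_dh",
]


@dataclass(frozen=True)
class HydrolysisResult:
    dh: float        # percent of cleaved bonds
    pcl_dh: float    # residues, 100 / dh
    aan_hyd: float   # mM/g
    aan_tot: float   # mM/g


def compute_dh(aan_hyd: float, aan_tot: float) -> float:
    """DH% from alpha-amino-N readings of hydrolysate and total hydrolysis."""
    if aan_tot <= 0:
        raise ValueError("total alpha-amino-N must be positive")
    if aan_hyd < 0:
        raise ValueError("hydrolysate alpha-amino-N must be non-negative")
    if aan_hyd > aan_tot:
        raise ValueError(
            "hydrolysate alpha-amino-N exceeds the fully hydrolyzed total"
        )
    return 100.0 * aan_hyd / aan_tot


def pcl_from_dh(dh: float, decimals: int | None = None) -> float:
    """DH-based mean chain length, 100 / DH%.

    ``decimals`` applies half-up display rounding (reports use one decimal).
    """
    if dh <= 0:
        raise ValueError("DH must be positive")
    if dh > 100:
        raise ValueError("DH cannot exceed 100 %")
    value = 100.0 / dh
    return round_half_up(value, decimals) if decimals is not None else value


def hydrolysis_result(aan_hyd: float, aan_tot: float) -> HydrolysisResult:
    dh = compute_dh(aan_hyd, aan_tot)
    return HydrolysisResult(dh=dh, pcl_dh=pcl_from_dh(dh),
                            aan_hyd=aan_hyd, aan_tot=aan_tot)


def relative_dh_change(dh_ref: float, dh_alt: float) -> float:
    """Relative decrease of DH (percent of the reference value)."""
    if dh_ref <= 0:
        raise ValueError("reference DH must be positive")
    return 100.0 * (dh_ref - dh_alt) / dh_ref


def true_dh(digest_log) -> float:
    """Ground-truth DH of a synthetic digest: cleaved over total bonds.

    Accepts any object exposing ``total_bonds`` and ``cut_bonds`` counts
    (see :class:`hydropep.synthetic.DigestLog`).
    """
    total = int(digest_log.total_bonds)
    cut = int(digest_log.cut_bonds)
    if total <= 0:
        raise ValueError("digest log records no peptide bonds")
    if not 0 <= cut <= total:
        raise ValueError("cleaved bond count outside 0..total_bonds")
    return 100.0 * cut / total
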