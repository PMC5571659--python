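"""Significantly associated loci (SALs): peak SNPs with LD-contiguous intervals.

A SAL is called greedily: the unassigned significant variant with the lowest P
becomes a peak, and the interval extends over consecutive panel variants on
the same chromosome while their r2 with the peak stays at or above ``ld_min``
(the "consecutive region with SNPs in LD above 0.6 around the associated
locus" rule).  Significant variants absorbed by an interval are not allowed to
seed further SALs, so every significant variant belongs to exactly one SAL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, LdUndefinedError, _r2_vectors
from .mlm import AssocScan, PermThreshold

__all__ = ["Sal", "detect_sals", "sal_overlap", "sals_to_frame"]


@dataclass
class Sal:
    trait: str
    tier: str  # "primary" | "secondary"
    peak: str
    members: list
    chrom: str
    start: int
    end: int
    min_p: float
    context: str = "full_population"

    def __post_init__(self):
        if self.peak not in self.members:
            raise ValueError("peak must be a member of its own interval")
        if self.tier not in ("primary", "secondary"):
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def n_members(self) -> int:
        return len(self.members)


def _threshold_value(threshold) -> float:
    if isinstance(threshold, PermThreshold):
        return threshold.threshold
    return float(threshold)


def _safe_r2(x, y):
    try:
        return _r2_vectors(x, y)
    except LdUndefinedError:
        return np.nan  # monomorphic neighbour: treat as unlinked


def detect_sals(scan: AssocScan, threshold, G: GenotypeMatrix, ld_min: float = 0.6,
                tier: str = "primary") -> list:
    """Group significant variants into peak-anchored LD intervals."""
    thr = _threshold_value(threshold)
    tbl = scan.table
    if list(tbl["id"]) != G.ids:
        raise ValueError("scan and genotype matrix must share variant order")
    p = tbl["p"].to_numpy()
    tested = tbl["tested"].to_numpy()
    chroms = np.asarray([v.chrom for v in G.variants])
    pos = np.asarray([v.pos for v in G.variants])
    sig = set(np.flatnonzero(tested & (p <= thr)).tolist())
    sals = []
    X = G.dosages
    while sig:
        # lowest P, ties broken by leftmost genomic position
        peak = min(sig, key=lambda j: (p[j], chroms[j], pos[j]))
        xpeak = X[:, peak]
        lo = peak
        while lo - 1 >= 0 and chroms[lo - 1] == chroms[peak]:
            r2 = _safe_r2(xpeak, X[:, lo - 1])
            if not (r2 >= ld_min):
                break
            lo -= 1
        hi = peak
        while hi + 1 < G.n_variants and chroms[hi + 1] == chroms[peak]:
            r2 = _safe_r2(xpeak, X[:, hi + 1])
            if not (r2 >= ld_min):
                break
            hi += 1
        members = [G.variants[j].id for j in range(lo, hi + 1)]
        sals.append(
            Sal(
                trait=scan.trait,
                tier=tier,
                peak=G.variants[peak].id,
                members=members,
                chrom=str(chroms[peak]),
                start=int(pos[lo]),
                end=int(pos[hi]),
                min_p=float(p[peak]),
                context=scan.context,
            )
        )
        sig -= set(range(lo, hi + 1))
    sals.sort(key=lambda s: (s.chrom, s.start))
    return sals


def sal_overlap(a: Sal, b: Sal, G: GenotypeMatrix) -> bool:
    """True iff the intervals intersect positionally or the peaks are in LD (r2 >= 0.6)."""
    if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
        return True
    r2 = _safe_r2(G.dosage(a.peak), G.dosage(b.peak))
    return bool(r2 >= 0.6)


def sals_to_frame(sals) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": s.trait,
                "tier": s.tier,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "peak_id": s.peak,
                "min_p": s.min_p,
                "n_members": s.n_members,
                "context": s.context,
            }
            for s in sals
        ]
    )
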