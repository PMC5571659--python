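"""Conditional (subgroup) re-scan for minor-effect and epistatic loci.

The population is split at the top SNP of a primary SAL into the two
homozygous dosage classes; heterozygous or missing accessions are excluded
(immaterial on a selfing panel).  Each subgroup larger than ``min_n``
accessions is re-scanned with freshly derived kinship, principal components
and a per-subgroup MAF filter.  A subgroup SAL that does not overlap any
primary SAL of the trait is a secondary SAL; a secondary signal significant in
exactly one homozygous background is classified as allele-specific (the
epistatic pattern), while a signal seen in both backgrounds is an ordinary
additive locus uncovered by the reduced background variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, GenotypeError, filter_variants
from .mlm import MixedModelGWAS, AssocScan
from .sal import Sal, detect_sals, sal_overlap

__all__ = [
    "SubgroupSplit",
    "EpistasisCall",
    "SplitError",
    "split_population",
    "conditional_gwas",
    "classify_epistasis",
]


class SplitError(GenotypeError):
    """Subgroup split rejected (monomorphic peak or both groups too small)."""


@dataclass
class SubgroupSplit:
    split_variant: str
    groups: dict  # homozygous dosage class (0 | 2) -> list of accession labels
    excluded: list
    min_n: int = 100

    def analyzable(self, dosage_class: int) -> bool:
        return len(self.groups.get(dosage_class, [])) > self.min_n

    @property
    def analyzable_classes(self):
        return [c for c in (0, 2) if self.analyzable(c)]


@dataclass
class EpistasisCall:
    primary: Sal
    secondary: Sal
    pattern: str | None  # "one_subgroup_only" | "both_subgroups" | None
    detected_in: list
    determinable: bool = True


def split_population(G: GenotypeMatrix, sal: Sal, min_n: int = 100) -> SubgroupSplit:
    """Partition accessions by homozygous dosage at the SAL peak.

    The analysis rule is strict: a subgroup is analyzable only if it has more
    than ``min_n`` accessions.
    """
    g = G.dosage(sal.peak)
    acc = np.asarray(G.accessions)
    grp0 = acc[g == 0.0].tolist()
    grp2 = acc[g == 2.0].tolist()
    excluded = acc[~((g == 0.0) | (g == 2.0))].tolist()
    if not grp0 or not grp2:
        raise SplitError(f"peak {sal.peak} is monomorphic among homozygous calls")
    if len(grp0) <= min_n and len(grp2) <= min_n:
        raise SplitError(
            f"both subgroups at {sal.peak} have <= {min_n} accessions "
            f"({len(grp0)} and {len(grp2)})"
        )
    return SubgroupSplit(sal.peak, {0: grp0, 2: grp2}, excluded, min_n=min_n)


def subgroup_engine(G: GenotypeMatrix, labels, maf_min: float = 0.05, n_pcs: int = 3) -> tuple:
    """Subset the panel to a subgroup, re-apply the MAF filter, and build a
    scan engine with recomputed kinship and principal components."""
    Gs = filter_variants(G.take_accessions(labels), maf_min=maf_min, miss_max=1.1)
    return Gs, MixedModelGWAS(Gs, n_pcs=n_pcs)


def conditional_gwas(
    y,
    G: GenotypeMatrix,
    split: SubgroupSplit,
    thresholds,
    primary_sals=(),
    trait: str = "trait",
    maf_min: float = 0.05,
    n_pcs: int = 3,
    ld_min: float = 0.6,
):
    """Re-scan each analyzable subgroup and call secondary SALs.

    Parameters
    ----------
    y : array aligned to ``G.accessions``.
    thresholds : float | PermThreshold | dict keyed by dosage class.
    primary_sals : SALs of the trait from the full-population scan; subgroup
        SALs overlapping any of them are not secondary.

    Returns
    -------
    scans : dict dosage class -> AssocScan
    secondary : list of Sal (tier "secondary")
    errors : dict dosage class -> Exception for subgroups whose scan failed
    """
    y = np.asarray(y, dtype=float)
    pos = {a: i for i, a in enumerate(G.accessions)}
    scans, secondary, errors = {}, [], {}
    for cls in split.analyzable_classes:
        labels = split.groups[cls]
        thr = thresholds[cls] if isinstance(thresholds, dict) else thresholds
        try:
            Gs, engine = subgroup_engine(G, labels, maf_min=maf_min, n_pcs=n_pcs)
            ys = y[[pos[a] for a in labels]]
            scan = engine.scan(ys, trait=trait, context=f"subgroup_{cls}")
            scans[cls] = scan
            for s in detect_sals(scan, thr, Gs, ld_min=ld_min, tier="secondary"):
                if not any(sal_overlap(s, ps, G) for ps in primary_sals):
                    secondary.append(s)
        except Exception as exc:  # keep the other subgroup alive
            errors[cls] = exc
    return scans, secondary, errors


def classify_epistasis(primary: Sal, subgroup_scans: dict, secondary: Sal,
                       thresholds) -> EpistasisCall | None:
    """Classify a secondary SAL by the backgrounds in which its peak passes
    the subgroup threshold.  Returns None when it passes in neither."""
    if len(subgroup_scans) < 2:
        return EpistasisCall(primary, secondary, None, [], determinable=False)
    detected = []
    for cls, scan in subgroup_scans.items():
        thr = thresholds[cls] if isinstance(thresholds, dict) else thresholds
        thr = getattr(thr, "threshold", thr)
        row = scan.table[scan.table["id"] == secondary.peak]
        if len(row) and bool(row["tested"].iloc[0]) and float(row["p"].iloc[0]) <= thr:
            detected.append(cls)
    if not detected:
        return None
    pattern = "one_subgroup_only" if len(detected) == 1 else "both_subgroups"
    return EpistasisCall(primary, secondary, pattern, detected)
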