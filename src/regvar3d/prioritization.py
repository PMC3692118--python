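"""Fisher-combined re-ranking of leading variants.

Each proxy variant V of a leading variant L carries up to three component
p-values:

* ``P_GWAS = min(1, p_L / r2)`` — the leading variant's association p-value
  propagated through the LD between V and L (capped at 1, since the raw
  division can exceed 1 and p-values above 1 are invalid);
* ``P_BDA`` — the most significant empirical p-value of the binding-affinity
  LOD across motifs;
* ``P_CONS`` — the constraint p-value of the most significant conserved
  element containing V.

The measured components are combined by Fisher's method into CP; the most
significant CP among a leading variant's proxies becomes that leading
variant's new score, and leading variants are re-ranked by it.

A component that was never measured (no GWAS p-value supplied, no motif
pair passing the scan threshold, no overlapping constrained element) is
*omitted* from the combination rather than entered as p = 1: Fisher's
method assumes every combined p-value is Uniform(0,1) under the null, and a
degenerate always-1 placeholder would push CP off the uniform scale for
exactly the variants with the least evidence, distorting the ranking and
the null behaviour.  The number of combined components is recorded per
record.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import chi2

from .binding_affinity import AffinityResult
from .errors import ValidationError
from .regulatory_signals import GenomicInterval, RegulatorySignal
from .variant_io import Variant, point_0based

#: floor applied to component p-values before taking logs
P_FLOOR = 1e-300


@dataclass(frozen=True)
class ConservationElement:
    interval: GenomicInterval
    element_p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.element_p <= 1.0):
            raise ValidationError(f"element p must lie in (0,1], got {self.element_p}")


class ConservationIndex:
    """Point lookup of evolutionary-constraint p-values."""

    def __init__(self, elements: list[ConservationElement] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for e in elements or ():
            self.add(e)

    def add(self, element: ConservationElement) -> None:
        tree = self._trees.setdefault(element.interval.chrom, IntervalTree())
        tree.addi(element.interval.start, element.interval.end, element)

    @classmethod
    def from_bed(cls, path: str | Path, p_column: int = 4) -> "ConservationIndex":
        """BED4+ with the element p-value in ``p_column`` (0-based)."""
        index = cls()
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split()
                if len(parts) <= p_column:
                    continue
                index.add(
                    ConservationElement(
                        interval=GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                        element_p=float(parts[p_column]),
                    )
                )
        return index

    def query(self, chrom: str, point: int) -> list[ConservationElement]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(point)]


def gwas_effect(p_leading: float, r2: float) -> float:
    """Propagate the leading variant's association p through LD:
    ``min(1, p_L / r2)``."""
    if not (0.0 < p_leading <= 1.0):
        raise ValueError(f"leading p-value must lie in (0,1], got {p_leading}")
    if not (0.0 < r2 <= 1.0):
        raise ValueError(f"r2 must lie in (0,1], got {r2}")
    return min(1.0, p_leading / r2)


def best_binding_p(results: list[AffinityResult]) -> float | None:
    """Most significant empirical LOD p-value among eligible motif results;
    None when no motif pair passed the scan threshold (no measurement)."""
    ps = [r.lod_p for r in results if r.eligible and r.lod_p is not None]
    return min(ps) if ps else None


def conservation_p(variant: Variant, elements: ConservationIndex) -> float | None:
    """Constraint p of the most significant element containing the variant;
    None when the variant lies in no constrained element."""
    hits = elements.query(variant.chrom, point_0based(variant.pos))
    return min(e.element_p for e in hits) if hits else None


def fisher_combine(pvalues: list[float], floor: float = P_FLOOR) -> float:
    """Fisher's combined probability test.

    ``X = -2 * sum(ln p_i)`` follows a chi-square with 2k degrees of
    freedom under the null; CP is its upper-tail probability.  Component
    p-values are floored at ``floor`` before logging.  With a single
    component the combination is the identity.
    """
    if not pvalues:
        raise ValueError("fisher_combine needs at least one p-value")
    for p in pvalues:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must lie in (0,1], got {p}")
    x = -2.0 * float(np.sum(np.log(np.maximum(pvalues, floor))))
    return float(chi2.sf(x, df=2 * len(pvalues)))


@dataclass(frozen=True)
class ProxyScore:
    """All components for one proxy variant V of a leading variant L."""

    leading_key: str
    variant: Variant
    r2: float
    p_gwas: float | None
    p_bda: float | None
    p_cons: float | None
    cp: float
    k: int  # number of combined components
    signals: tuple[RegulatorySignal, ...] = ()
    best_motif: str = ""


@dataclass(frozen=True)
class PrioritizationRecord:
    leading_key: str
    best_proxy: ProxyScore
    rank: int

    @property
    def cp(self) -> float:
        return self.best_proxy.cp


def score_proxy(
    leading_key: str,
    variant: Variant,
    r2: float,
    p_leading: float | None,
    affinity: list[AffinityResult],
    conservation: ConservationIndex,
    signals: tuple[RegulatorySignal, ...] = (),
) -> ProxyScore:
    """Assemble the component p-values and Fisher-combine the measured ones."""
    p_gwas = gwas_effect(p_leading, r2) if p_leading is not None else None
    p_bda = best_binding_p(affinity)
    p_cons = conservation_p(variant, conservation)
    components = [p for p in (p_gwas, p_bda, p_cons) if p is not None]
    cp = fisher_combine(components) if components else 1.0
    best_motif = ""
    if p_bda is not None:
        best = min(
            (r for r in affinity if r.eligible and r.lod_p is not None),
            key=lambda r: (r.lod_p, r.motif_name),
        )
        best_motif = best.motif_name
    return ProxyScore(
        leading_key=leading_key,
        variant=variant,
        r2=r2,
        p_gwas=p_gwas,
        p_bda=p_bda,
        p_cons=p_cons,
        cp=cp,
        k=len(components),
        signals=tuple(signals),
        best_motif=best_motif,
    )


def assign_and_rank(proxy_scores: list[ProxyScore]) -> list[PrioritizationRecord]:
    """Assign each leading variant its most significant proxy CP and re-rank.

    Ties break deterministically on (CP, chrom, pos, variant id).
    """
    def order(s: ProxyScore):
        return (s.cp, s.variant.chrom, s.variant.pos, s.variant.id)

    best: dict[str, ProxyScore] = {}
    for s in proxy_scores:
        cur = best.get(s.leading_key)
        if cur is None or order(s) < order(cur):
            best[s.leading_key] = s
    ranked = sorted(best.values(), key=order)
    return [
        PrioritizationRecord(leading_key=s.leading_key, best_proxy=s, rank=i + 1)
        for i, s in enumerate(ranked)
    ]
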