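"""Cell-type regulatory tracks, interaction anchors and variant annotation.

A variant overlapping any loaded regulatory region — active mark peaks
(H3K4me1, H3K27ac, p300, CTCF, DHS), ChromHMM "Strong" promoter/enhancer/
insulator elements, a user promoter region, or an anchor of a long-range
chromosome interaction — carries a regulatory signal; variants with no
signal are filtered out before affinity scoring.

Overlap arithmetic is BED 0-based half-open with the variant as the single
point ``pos - 1`` (indels use their leftmost base).  Raw Hi-C contact
matrices can be balanced by iterative correction (ICE-style matrix
balancing) so every bin has equal total coverage, and strong balanced
contacts can be turned into paired interaction anchors for fixture-driven
runs; 5C/ChIA-PET style interactions arrive pre-called as BEDPE and are
used verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from intervaltree import IntervalTree

from .errors import UnknownCellTypeError, ValidationError
from .variant_io import Variant, point_0based

log = logging.getLogger(__name__)

MARK_CLASSES = frozenset(
    {
        "H3K4me1", "H3K27ac", "p300", "CTCF", "DHS",
        "chromhmm_promoter", "chromhmm_enhancer", "chromhmm_insulator",
        "user_promoter", "interaction_anchor",
    }
)
#: pseudo cell type that unions every loaded track ("no cell type restriction")
MERGED_CELL_TYPE = "merged"


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval start >= end: {self.chrom}:{self.start}-{self.end}"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class RegulatorySignal:
    mark_class: str
    cell_type: str
    interval: GenomicInterval
    partner: GenomicInterval | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.mark_class not in MARK_CLASSES:
            raise ValidationError(f"unknown mark class {self.mark_class!r}")
        if (self.partner is not None) != (self.mark_class == "interaction_anchor"):
            raise ValidationError(
                "partner interval is present iff mark_class is interaction_anchor"
            )


class SignalIndex:
    """Point-overlap queries over all loaded tracks, per cell type."""

    def __init__(self) -> None:
        # cell_type -> chrom -> IntervalTree of RegulatorySignal payloads
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        self._signals: dict[str, list[RegulatorySignal]] = {}

    @property
    def cell_types(self) -> list[str]:
        return sorted(self._trees)

    def add(self, signal: RegulatorySignal) -> None:
        for ct in (signal.cell_type, MERGED_CELL_TYPE):
            tree = self._trees.setdefault(ct, {}).setdefault(
                signal.interval.chrom, IntervalTree()
            )
            tree.addi(signal.interval.start, signal.interval.end, signal)
            self._signals.setdefault(ct, []).append(signal)

    def query_point(self, cell_type: str, chrom: str, point: int) -> list[RegulatorySignal]:
        if cell_type not in self._trees:
            raise UnknownCellTypeError(
                f"unknown cell type {cell_type!r}; available: {self.cell_types}"
            )
        tree = self._trees[cell_type].get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(point)]
        hits.sort(key=lambda s: (s.mark_class, s.interval.start, s.interval.end))
        return hits

    def signals(self, cell_type: str) -> list[RegulatorySignal]:
        return list(self._signals.get(cell_type, []))


def _read_bed(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            yield lineno, parts


def load_bed_track(
    path: str | Path, mark_class: str, cell_type: str,
    name_filter: str | None = None,
) -> list[RegulatorySignal]:
    """Load a BED3+ track; ChromHMM-like tracks keep only rows whose name
    column contains ``name_filter`` (e.g. "Strong")."""
    signals = []
    for lineno, parts in _read_bed(path):
        if len(parts) < 3:
            continue
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: BED start >= end")
        if name_filter is not None:
            name = parts[3] if len(parts) > 3 else ""
            if name_filter not in name:
                continue
        intensity = None
        if len(parts) > 4:
            try:
                intensity = float(parts[4])
            except ValueError:
                intensity = None
        signals.append(
            RegulatorySignal(
                mark_class=mark_class,
                cell_type=cell_type,
                interval=GenomicInterval(chrom, start, end),
                intensity=intensity,
            )
        )
    if not signals:
        log.warning("track %s (%s/%s) is empty", path, mark_class, cell_type)
    return signals


def load_bedpe_track(
    path: str | Path, cell_type: str
) -> list[RegulatorySignal]:
    """Each BEDPE row yields two anchor signals, each carrying the other
    side as its partner."""
    signals = []
    for lineno, parts in _read_bed(path):
        if len(parts) < 6:
            continue
        a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
        b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
        intensity = None
        if len(parts) > 7:
            try:
                intensity = float(parts[7])
            except ValueError:
                intensity = None
        for left, right in ((a, b), (b, a)):
            signals.append(
                RegulatorySignal(
                    mark_class="interaction_anchor",
                    cell_type=cell_type,
                    interval=left,
                    partner=right,
                    intensity=intensity,
                )
            )
    return signals


def load_tracks(manifest: str | Path | list[dict]) -> SignalIndex:
    """Build a :class:`SignalIndex` from a track manifest.

    The manifest is a YAML list (or an already-parsed list) of entries
    ``{mark_class, cell_type, path}``; ``interaction_anchor`` entries point
    at BEDPE, everything else at BED.  ChromHMM classes apply the "Strong"
    state-name filter.  Relative paths resolve against the manifest file.
    """
    base = Path(".")
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, list):
        raise ValidationError("track manifest must be a list of entries")
    index = SignalIndex()
    for entry in manifest:
        mark_class = entry["mark_class"]
        cell_type = entry["cell_type"]
        path = Path(entry["path"])
        if not path.is_absolute():
            path = base / path
        if mark_class == "interaction_anchor":
            signals = load_bedpe_track(path, cell_type)
        elif mark_class.startswith("chromhmm_"):
            signals = load_bed_track(
                path, mark_class, cell_type,
                name_filter=entry.get("state_filter", "Strong"),
            )
        else:
            signals = load_bed_track(path, mark_class, cell_type)
        for s in signals:
            index.add(s)
    return index


def annotate_signals(
    variant: Variant,
    index: SignalIndex,
    cell_type: str,
    promoter_regions: list[GenomicInterval] | None = None,
) -> list[RegulatorySignal]:
    """All signals of the requested cell type containing the variant point.

    An empty list means the variant carries no regulatory signal.  A user
    promoter BED contributes ``user_promoter`` signals regardless of cell
    type.
    """
    point = point_0based(variant.pos)
    hits = index.query_point(cell_type, variant.chrom, point)
    for region in promoter_regions or ():
        if region.chrom == variant.chrom and region.start <= point < region.end:
            hits.append(
                RegulatorySignal(
                    mark_class="user_promoter", cell_type=cell_type, interval=region
                )
            )
    return hits


def filter_to_signal_variants(
    proxies: dict[str, list[tuple[Variant, float]]],
    index: SignalIndex,
    cell_type: str,
    promoter_regions: list[GenomicInterval] | None = None,
) -> tuple[
    dict[str, list[tuple[Variant, float, list[RegulatorySignal]]]],
    list[str],
]:
    """Restrict each proxy set to variants carrying at least one signal.

    Returns the annotated mapping and the side report: leading variants
    whose entire proxy set was filtered out ("no signal"), excluded from
    re-ranking.
    """
    surviving: dict[str, list[tuple[Variant, float, list[RegulatorySignal]]]] = {}
    no_signal: list[str] = []
    for lead_key, plist in proxies.items():
        kept = []
        for variant, r2 in plist:
            signals = annotate_signals(variant, index, cell_type, promoter_regions)
            if signals:
                kept.append((variant, r2, signals))
        if kept:
            surviving[lead_key] = kept
        else:
            no_signal.append(lead_key)
    return surviving, no_signal


# ---------------------------------------------------------------------------
# Hi-C contact matrices


@dataclass
class ContactMatrix:
    """Square symmetric contact matrix over fixed-width genomic bins."""

    bins: list[GenomicInterval]
    counts: np.ndarray
    balanced: bool = False
    mask: np.ndarray | None = field(default=None)  # True = bin kept

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match {n} bins"
            )
        if np.any(self.counts < 0):
            raise ValidationError("contact counts must be nonnegative")

    @classmethod
    def from_files(cls, matrix_path: str | Path, bins_path: str | Path) -> "ContactMatrix":
        bins = [
            GenomicInterval(p[0], int(p[1]), int(p[2]))
            for _, p in _read_bed(bins_path)
            if len(p) >= 3
        ]
        counts = np.loadtxt(matrix_path, dtype=float, ndmin=2)
        return cls(bins=bins, counts=counts)


def ice_normalize(
    raw: ContactMatrix, max_iter: int = 200, tol: float = 1e-5
) -> ContactMatrix:
    """Iteratively correct a raw contact matrix so bin coverage is uniform.

    Bins whose row is entirely zero are masked out; the remaining rows are
    rescaled by an iterative proportional (Sinkhorn-style symmetric)
    correction until every unmasked row sum lies within ``tol`` relative of
    their common mean.  The output keeps the input's mean unmasked row sum,
    so rescaling the input by a positive constant rescales the output by
    the same constant.  Only the balancing step of the ICE algorithm is
    performed; the eigenvector-decomposition step is not needed here.
    """
    M = np.asarray(raw.counts, dtype=float)
    if M.size == 0 or not np.any(M > 0):
        raise ValidationError("cannot balance an all-zero contact matrix")
    if not np.allclose(M, M.T, rtol=1e-8, atol=1e-12):
        raise ValidationError("contact matrix is not symmetric")
    mask = M.sum(axis=1) > 0
    sub = M[np.ix_(mask, mask)].copy()
    target = sub.sum(axis=1).mean()

    bias = np.ones(sub.shape[0])
    converged = False
    for _ in range(max_iter):
        W = sub / np.outer(bias, bias)
        rs = W.sum(axis=1)
        mean_rs = rs.mean()
        dev = np.max(np.abs(rs / mean_rs - 1.0))
        if dev < tol:
            converged = True
            break
        adjust = np.sqrt(rs / mean_rs)
        bias *= adjust
    if not converged:
        log.warning("ICE balancing did not converge within %d iterations", max_iter)

    W = sub / np.outer(bias, bias)
    W *= target / W.sum(axis=1).mean()
    out = np.zeros_like(M)
    out[np.ix_(mask, mask)] = W
    out = (out + out.T) / 2.0
    return ContactMatrix(bins=raw.bins, counts=out, balanced=True, mask=mask)


def call_interaction_anchors(
    balanced: ContactMatrix, quantile: float, cell_type: str = "hic"
) -> list[RegulatorySignal]:
    """Turn strong balanced contacts into paired interaction anchors.

    Off-diagonal bin pairs with nonzero balanced count at or above the given
    quantile of the nonzero off-diagonal entries become two anchor signals
    each (one per side), with intensity = balanced count.  At quantile 1
    the selection is strict, so the list is empty.
    """
    if not (0.0 <= quantile <= 1.0):
        raise ValueError(f"quantile must lie in [0,1], got {quantile}")
    C = balanced.counts
    iu = np.triu_indices(C.shape[0], k=1)
    values = C[iu]
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return []
    threshold = float(np.quantile(nonzero, quantile))
    signals = []
    for i, j, v in zip(*iu, values):
        keep = v > 0 and (v > threshold if quantile >= 1.0 else v >= threshold)
        if keep:
            a, b = balanced.bins[i], balanced.bins[j]
            for left, right in ((a, b), (b, a)):
                signals.append(
                    RegulatorySignal(
                        mark_class="interaction_anchor",
                        cell_type=cell_type,
                        interval=left,
                        partner=right,
                        intensity=float(v),
                    )
                )
    return signals
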