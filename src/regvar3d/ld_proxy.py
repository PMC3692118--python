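"""Linkage-disequilibrium proxy expansion.

Each leading variant L from the association results is expanded into the set
of proxy variants V with r² strictly above a user cutoff, read from a
population-tagged pairwise LD table (computing r² from genotypes is out of
scope; the table plays the role HapMap/1000G pairwise files play upstream).
Every L is always its own proxy with r² = 1, so a leading variant that is
itself regulatory remains scoreable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import ValidationError
from .variant_io import Variant, VariantCatalog

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDProxy:
    leading_id: str
    proxy_id: str
    r2: float
    population: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(f"r2 must lie in [0,1], got {self.r2}")


class LDIndex:
    """Symmetric in-memory pairwise r² index for one population."""

    def __init__(self, population: str) -> None:
        self.population = population
        self._pairs: dict[str, dict[str, float]] = {}

    def add(self, a: str, b: str, r2: float) -> None:
        self._pairs.setdefault(a, {})[b] = r2
        self._pairs.setdefault(b, {})[a] = r2

    def partners(self, variant_id: str) -> dict[str, float]:
        return self._pairs.get(variant_id, {})

    @property
    def n_pairs(self) -> int:
        return sum(len(d) for d in self._pairs.values()) // 2


def load_ld_table(path: str | Path, population: str) -> LDIndex:
    """Load a TSV of (ID_A, ID_B, R2, POP) rows restricted to one population.

    Any r² outside [0,1] is fatal, citing the offending line number.
    """
    index = LDIndex(population)
    populations_seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                continue
            if lineno == 1 and not _is_float(parts[2]):
                continue  # header
            a, b, r2_s, pop = parts[:4]
            try:
                r2 = float(r2_s)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: unparsable r2 {r2_s!r}"
                ) from exc
            if not (0.0 <= r2 <= 1.0):
                raise ValidationError(
                    f"{path}:{lineno}: r2 {r2} outside [0,1]"
                )
            populations_seen.add(pop)
            if pop == population:
                index.add(a, b, r2)
    if index.n_pairs == 0:
        log.warning(
            "no LD pairs for population %r in %s (populations present: %s)",
            population, path, sorted(populations_seen) or "none",
        )
    return index


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def expand_ld(
    leading: list[Variant],
    ld: LDIndex,
    r2_cutoff: float,
    catalog: VariantCatalog | None = None,
) -> dict[str, list[tuple[Variant, float]]]:
    """Map each leading variant to its proxies with r² strictly above cutoff.

    The comparison is strict (``r2 > cutoff``): at cutoff 1.0 only the
    self-proxy survives.  Proxy alleles are resolved against the catalogue;
    proxies that resolve nowhere are dropped with a logged count (they
    cannot be affinity-scored).
    """
    if not (0.0 <= r2_cutoff <= 1.0):
        raise ValueError(f"r2 cutoff must lie in [0,1], got {r2_cutoff}")
    out: dict[str, list[tuple[Variant, float]]] = {}
    unresolved = 0
    for lead in leading:
        proxies: list[tuple[Variant, float]] = [(lead, 1.0)]
        for proxy_id, r2 in sorted(ld.partners(lead.key).items()):
            if not (r2 > r2_cutoff):
                continue
            if proxy_id == lead.key:
                continue
            proxy = Variant(id=proxy_id, source_format="rsid")
            if catalog is not None:
                hit = catalog.lookup(proxy)
                if hit is None:
                    unresolved += 1
                    continue
                proxy = replace(hit, id=hit.id or proxy_id)
            proxies.append((proxy, r2))
        out[lead.key] = proxies
    if unresolved:
        log.info("dropped %d LD proxies unresolvable against the catalogue", unresolved)
    return out
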