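"""One-command pipeline driver.

Runs the full chain — p-value prefilter, LD expansion, regulatory-signal
filter, binding-affinity scoring against the empirical null, Fisher-combined
prioritization — and writes the prioritization table, the per-proxy
annotation report, the no-signal side report and circle-plot link data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from . import binding_affinity as ba
from . import ld_proxy, prioritization, regulatory_signals, variant_io
from .errors import GenomeMismatchError, ValidationError
from .prioritization import PrioritizationRecord, ProxyScore
from .regulatory_signals import GenomicInterval
from .variant_io import Variant, point_0based

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_ALL_FILTERED = 3


@dataclass
class PipelineConfig:
    gwas_path: str
    genome_path: str
    motifs_path: str
    catalog_path: str
    tracks_manifest: str
    format: str = "auto"
    pcut: float = 1.0
    ld_path: str | None = None
    population: str = "CEU"
    r2_cutoff: float = 0.8
    cell_type: str = regulatory_signals.MERGED_CELL_TYPE
    promoter_bed: str | None = None
    conserved_path: str | None = None
    genes_path: str | None = None
    null_path: str | None = None
    null_size: int = 10_000
    seed: int = 0
    scan_threshold: float = ba.DEFAULT_SCAN_THRESHOLD
    flank: int = ba.DEFAULT_FLANK
    top_n: int = 10
    out_dir: str | None = None


@dataclass
class PipelineResult:
    records: list[PrioritizationRecord]
    proxy_scores: list[ProxyScore]
    no_signal_leads: list[str]
    no_gwas_mode: bool
    stage_counts: dict[str, int] = field(default_factory=dict)
    null: ba.NullDistribution | None = None
    links: list["LinkRecord"] = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return EXIT_OK if self.records else EXIT_ALL_FILTERED


@dataclass(frozen=True)
class LinkRecord:
    source: str
    target: str
    intensity: float
    variant_key: str


class GeneIndex:
    """Gene-name lookup from a BED4 annotation (RefGene-like)."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneIndex":
        index = cls()
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    continue
                tree = index._trees.setdefault(parts[0], IntervalTree())
                tree.addi(int(parts[1]), int(parts[2]), parts[3])
        return index

    def label(self, interval: GenomicInterval) -> str:
        """Name of a gene containing the interval midpoint, else the locus."""
        tree = self._trees.get(interval.chrom)
        if tree is not None:
            mid = (interval.start + interval.end) // 2
            hits = sorted(iv.data for iv in tree.at(mid))
            if hits:
                return hits[0]
        return str(interval)

    def label_point(self, chrom: str, point: int, fallback: GenomicInterval) -> str:
        tree = self._trees.get(chrom)
        if tree is not None:
            hits = sorted(iv.data for iv in tree.at(point))
            if hits:
                return hits[0]
        return self.label(fallback)


def export_links(
    records: list[PrioritizationRecord],
    genes: GeneIndex,
    top_n: int,
) -> list[LinkRecord]:
    """Circle-plot link data for the top records: every interaction anchor
    carried by a best proxy yields one source→target link; intensities are
    copied from the track, never recomputed."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    links = []
    for rec in records[:top_n]:
        v = rec.best_proxy.variant
        for sig in rec.best_proxy.signals:
            if sig.mark_class != "interaction_anchor" or sig.partner is None:
                continue
            links.append(
                LinkRecord(
                    source=genes.label_point(v.chrom, point_0based(v.pos), sig.interval),
                    target=genes.label(sig.partner),
                    intensity=float(sig.intensity or 0.0),
                    variant_key=v.key,
                )
            )
    return links


def _fmt_p(p: float | None) -> str:
    return "NA" if p is None else repr(p)


def write_prioritization_table(records: list[PrioritizationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#rank\tleading\tbest_proxy\tchrom\tpos\tr2\tp_gwas\tp_bda\tp_cons\t"
            "k\tcp\tsignal_classes\tbest_motif\n"
        )
        for rec in records:
            s = rec.best_proxy
            classes = ",".join(sorted({sig.mark_class for sig in s.signals})) or "."
            fh.write(
                "\t".join(
                    [
                        str(rec.rank), rec.leading_key, s.variant.key,
                        s.variant.chrom, str(s.variant.pos), repr(s.r2),
                        _fmt_p(s.p_gwas), _fmt_p(s.p_bda), _fmt_p(s.p_cons),
                        str(s.k), repr(s.cp), classes, s.best_motif or ".",
                    ]
                )
                + "\n"
            )


def read_prioritization_table(path: str | Path) -> list[dict]:
    cols = [
        "rank", "leading", "best_proxy", "chrom", "pos", "r2",
        "p_gwas", "p_bda", "p_cons", "k", "cp", "signal_classes", "best_motif",
    ]
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            vals = line.split("\t")
            row = dict(zip(cols, vals))
            row["rank"] = int(row["rank"])
            row["pos"] = int(row["pos"])
            row["k"] = int(row["k"])
            row["r2"] = float(row["r2"])
            row["cp"] = float(row["cp"])
            for key in ("p_gwas", "p_bda", "p_cons"):
                row[key] = None if row[key] == "NA" else float(row[key])
            rows.append(row)
    return rows


def _load_promoter_bed(path: str | Path) -> list[GenomicInterval]:
    regions = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) >= 3:
                regions.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return regions


def _open_genome(path: str | Path):
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute filter → LD expand → signal filter → affinity → prioritize →
    report, logging per-stage counts."""
    counts: dict[str, int] = {}

    variants, report = variant_io.parse_variants(config.gwas_path, config.format)
    counts["parsed"] = report.parsed
    counts["malformed"] = report.skipped

    catalog = variant_io.VariantCatalog.from_tsv(config.catalog_path)
    resolved, dropped = variant_io.resolve_alleles(variants, catalog)
    counts["resolved"] = len(resolved)
    counts["unmapped"] = len(dropped)

    no_gwas = all(v.gwas_p is None for v in resolved)
    leading = variant_io.filter_by_pvalue(resolved, config.pcut, no_gwas_mode=no_gwas)
    counts["after_pcut"] = len(leading)

    if config.ld_path:
        ld = ld_proxy.load_ld_table(config.ld_path, config.population)
    else:
        ld = ld_proxy.LDIndex(config.population)
    proxies = ld_proxy.expand_ld(leading, ld, config.r2_cutoff, catalog)
    counts["proxies"] = sum(len(v) for v in proxies.values())

    index = regulatory_signals.load_tracks(config.tracks_manifest)
    promoters = _load_promoter_bed(config.promoter_bed) if config.promoter_bed else None
    surviving, no_signal = regulatory_signals.filter_to_signal_variants(
        proxies, index, config.cell_type, promoters
    )
    counts["with_signal"] = sum(len(v) for v in surviving.values())
    counts["no_signal_leads"] = len(no_signal)

    if not surviving:
        log.warning("all variants were filtered before scoring")
        return PipelineResult(
            records=[], proxy_scores=[], no_signal_leads=no_signal,
            no_gwas_mode=no_gwas, stage_counts=counts,
        )

    motifs = ba.load_motifs(config.motifs_path)
    genome = _open_genome(config.genome_path)
    if config.null_path and Path(config.null_path).exists():
        null = ba.NullDistribution.load(config.null_path)
    else:
        null = ba.build_null(
            catalog.variants(), motifs, genome,
            n=config.null_size, seed=config.seed,
            scan_threshold=config.scan_threshold, flank=config.flank,
        )
        if config.null_path:
            null.save(config.null_path)
    counts["null_size"] = null.n

    if config.conserved_path:
        conservation = prioritization.ConservationIndex.from_bed(config.conserved_path)
    else:
        conservation = prioritization.ConservationIndex()

    p_by_lead = {v.key: v.gwas_p for v in leading}
    proxy_scores: list[ProxyScore] = []
    for lead_key, plist in surviving.items():
        for variant, r2, signals in plist:
            try:
                affinity = ba.score_affinity_change(
                    variant, motifs, genome,
                    scan_threshold=config.scan_threshold,
                    flank=config.flank, null=null,
                )
            except (GenomeMismatchError, ValidationError) as exc:
                log.warning("skipping proxy %s: %s", variant.key, exc)
                continue
            proxy_scores.append(
                prioritization.score_proxy(
                    leading_key=lead_key,
                    variant=variant,
                    r2=r2,
                    p_leading=None if no_gwas else p_by_lead.get(lead_key),
                    affinity=affinity,
                    conservation=conservation,
                    signals=tuple(signals),
                )
            )
    records = prioritization.assign_and_rank(proxy_scores)
    counts["ranked"] = len(records)

    links: list[LinkRecord] = []
    if config.genes_path and records:
        genes = GeneIndex.from_bed(config.genes_path)
        links = export_links(records, genes, config.top_n)

    result = PipelineResult(
        records=records, proxy_scores=proxy_scores, no_signal_leads=no_signal,
        no_gwas_mode=no_gwas, stage_counts=counts, null=null, links=links,
    )
    if config.out_dir:
        _write_outputs(result, config)
    for stage, n in counts.items():
        log.info("stage %s: %d", stage, n)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_prioritization_table(result.records, out / "prioritization.tsv")
    with open(out / "proxies.tsv", "w") as fh:
        fh.write("#leading\tproxy\tchrom\tpos\tr2\tp_gwas\tp_bda\tp_cons\tk\tcp\tsignals\n")
        for s in result.proxy_scores:
            classes = ",".join(sorted({sig.mark_class for sig in s.signals})) or "."
            fh.write(
                "\t".join(
                    [
                        s.leading_key, s.variant.key, s.variant.chrom,
                        str(s.variant.pos), repr(s.r2), _fmt_p(s.p_gwas),
                        _fmt_p(s.p_bda), _fmt_p(s.p_cons), str(s.k),
                        repr(s.cp), classes,
                    ]
                )
                + "\n"
            )
    with open(out / "no_signal_leads.txt", "w") as fh:
        for key in result.no_signal_leads:
            fh.write(key + "\n")
    with open(out / "links.tsv", "w") as fh:
        fh.write("#source\ttarget\tintensity\tvariant\n")
        for link in result.links:
            fh.write(
                f"{link.source}\t{link.target}\t{link.intensity!r}\t{link.variant_key}\n"
            )
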