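"""Seeded synthetic input bundles for every pipeline stage.

The generator emulates, at desk scale, the data a real run consumes: a
random reference genome, a PFM motif library, a biallelic variant
catalogue whose reference alleles match the genome, association results
for a set of leading variants, a population-tagged pairwise LD table,
cell-type BED/BEDPE regulatory tracks (including a raw ChromHMM-like track
with Strong/Weak state names), GERP-like constrained elements with
per-element p-values, and a gene annotation BED.

A *planted* regulatory variant is constructed the way the method expects a
causal proxy to look: the genome carries the planted motif's consensus, the
variant sits on the motif's most informative column with the alternative
allele destroying it, an enhancer (in one cell type only), an interaction
anchor and a constrained element overlap the site, and the planted proxy is
tied to its leading variant by a high-r² LD row.  The planted motif has one
highly informative column and moderately informative flanks, the profile
under which a single-base disruption moves the best-site probability the
most; background motifs are homogeneous.

The same spec and seed always produce a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedVariant:
    """Ground truth for one planted regulatory proxy."""

    leading_index: int = 0
    r2: float = 0.95
    motif_index: int = 0
    element_p: float = 1e-6
    cell_type: str = "cellA"


@dataclass
class FixtureSpec:
    """Study conditions of a synthetic cohort.

    Defaults describe the standard positive-control cohort: 20 leading
    variants with association p-values log-uniform in [1e-8, 1e-4] (the
    range typical of reported GWAS hits), ~3 background LD proxies each
    with r² uniform in [0.5, 1), a 4-motif library, a 2x60 kb genome with
    a 4,000-variant catalogue, regulatory tracks covering most variants in
    two synthetic cell types, and exactly one planted causal proxy.
    """

    n_chroms: int = 2
    chrom_length: int = 60_000
    n_motifs: int = 4
    motif_widths: tuple[int, ...] = (12, 8, 10, 9)
    n_catalog: int = 4_000
    n_leading: int = 20
    proxies_per_leading: int = 3
    population: str = "CEU"
    leading_p_log10_range: tuple[float, float] = (-8.0, -4.0)
    background_r2_range: tuple[float, float] = (0.5, 1.0)
    enhancer_coverage: float = 0.85
    n_background_elements: int = 40
    conservation_tiling: bool = False  # one U(0,1) element per leading variant
    uniform_gwas_p: bool = False       # p ~ U(0,1] instead of log-uniform
    planted: tuple[PlantedVariant, ...] = (PlantedVariant(),)

    @classmethod
    def negative_control(cls, n_leading: int = 150) -> "FixtureSpec":
        """No planted variant, no LD proxies, every leading variant tiled by
        an enhancer and a single-base U(0,1) constrained element, uniform
        association p-values: under these conditions every measured
        component p-value is Uniform(0,1) and the combined CP should be
        too."""
        return cls(
            n_leading=n_leading,
            proxies_per_leading=0,
            enhancer_coverage=1.0,
            n_background_elements=0,
            conservation_tiling=True,
            uniform_gwas_p=True,
            planted=(),
        )


@dataclass
class FixtureBundle:
    """Paths of one generated bundle plus the planted ground truth."""

    out_dir: Path
    genome: Path
    motifs: Path
    catalog: Path
    gwas: Path
    ld: Path
    tracks_manifest: Path
    conserved: Path
    genes: Path
    truth: dict = field(default_factory=dict)


def _random_pfm(rng: np.random.Generator, width: int, planted: bool) -> np.ndarray:
    """Heterogeneous Dirichlet columns, like real PFMs.

    Homogeneous columns would make single-base disruptions of different
    sites share identical log-odds values, an artifact real motif
    libraries do not have.  The planted motif gets one near-deterministic
    column (maximal single-base disruption) flanked by moderately
    informative, individually jittered columns.
    """
    if not planted:
        pfm = rng.dirichlet(np.full(4, 0.4), size=width)
        return pfm / pfm.sum(axis=1, keepdims=True)
    consensus = rng.integers(0, 4, size=width)
    pfm = np.empty((width, 4))
    for i in range(width):
        cons = rng.uniform(0.5, 0.65)
        rest = rng.dirichlet(np.full(3, 4.0)) * (1.0 - cons)
        col = np.insert(rest, consensus[i], cons)
        pfm[i] = col
    key = width // 2
    pfm[key] = 0.001
    pfm[key, consensus[key]] = 0.997
    return pfm / pfm.sum(axis=1, keepdims=True)


def _write_fasta(path: Path, chroms: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for name, codes in chroms.items():
            fh.write(f">{name}\n")
            seq = "".join(_BASES[c] for c in codes)
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def generate_bundle(spec: FixtureSpec, out_dir: str | Path, seed: int = 0) -> FixtureBundle:
    """Write a complete synthetic input bundle under ``out_dir``."""
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    widths = tuple(spec.motif_widths[i % len(spec.motif_widths)] for i in range(spec.n_motifs))
    if any(w > spec.chrom_length for w in widths):
        raise ValidationError("planted spec unsatisfiable: motif longer than a chromosome")
    if spec.planted and spec.n_leading < 1:
        raise ValidationError("cannot plant without leading variants")
    for p in spec.planted:
        if p.leading_index >= spec.n_leading or p.motif_index >= spec.n_motifs:
            raise ValidationError("planted index outside the cohort")

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chroms = {
        name: rng.integers(0, 4, size=spec.chrom_length).astype(np.int8)
        for name in chrom_names
    }

    # motif library; motif 0 is the plantable one
    pfms = [
        _random_pfm(rng, w, planted=(i == 0))
        for i, w in enumerate(widths)
    ]

    # plant first: choose planted sites, rewrite the genome with the motif
    # consensus, and keep every other catalogue position out of the planted
    # footprint (a second variant inside the consensus would disrupt it just
    # like the planted one and contaminate the null's tail)
    margin = 50
    planted_sites: list[dict] = []
    excluded: dict[str, set[int]] = {name: set() for name in chrom_names}
    for k, plant in enumerate(spec.planted):
        chrom = chrom_names[k % spec.n_chroms]
        pfm = pfms[plant.motif_index]
        width = pfm.shape[0]
        if spec.chrom_length <= 2 * (margin + width):
            raise ValidationError("planted spec unsatisfiable: site clips the chromosome")
        pos = int(rng.integers(margin + width, spec.chrom_length - margin - width))
        key_col = int(np.argmax(pfm.max(axis=1) - pfm.min(axis=1)))
        consensus = pfm.argmax(axis=1)
        start0 = (pos - 1) - key_col
        chroms[chrom][start0 : start0 + width] = consensus
        excluded[chrom].update(range(start0, start0 + width + 1))
        weakest = int(np.argmin(pfm[key_col]))
        planted_sites.append(
            {"chrom": chrom, "pos": pos, "alt_code": weakest, "plant": plant}
        )

    # catalogue positions, clear of chromosome ends so affinity windows never
    # clip, and clear of planted footprints
    positions: list[tuple[str, int]] = []
    planted_rows: list[dict] = []
    for name in chrom_names:
        n_here = spec.n_catalog // spec.n_chroms
        here_planted = [s for s in planted_sites if s["chrom"] == name]
        allowed = np.array(
            [
                p
                for p in range(margin, spec.chrom_length - margin)
                if p - 1 not in excluded[name]
            ]
        )
        pos = rng.choice(allowed, size=n_here - len(here_planted), replace=False)
        merged = np.sort(
            np.concatenate([pos, np.array([s["pos"] for s in here_planted], dtype=int)])
        )
        for s in here_planted:
            s["proxy_index"] = len(positions) + int(np.searchsorted(merged, s["pos"]))
        positions.extend((name, int(p)) for p in merged)
    planted_rows = planted_sites

    # leading variants and their background proxies are catalogue draws
    planted_idx = {s["proxy_index"] for s in planted_sites}
    order = np.array([i for i in rng.permutation(len(positions)) if i not in planted_idx])
    lead_idx = order[: spec.n_leading]
    proxy_pool = order[spec.n_leading :]
    pool_cursor = 0

    genome_path = out / "genome.fa"
    _write_fasta(genome_path, chroms)

    # catalogue: ref straight off the (final) genome, one random alt
    alt_draw = rng.integers(1, 4, size=len(positions))  # offset from ref, mod 4
    ref_codes = np.array([chroms[c][p - 1] for c, p in positions])
    alt_codes = (ref_codes + alt_draw) % 4
    for row in planted_rows:
        i = row["proxy_index"]
        if row["alt_code"] == ref_codes[i]:  # weakest base equals consensus: impossible by construction
            raise ValidationError("planted alt equals ref")
        alt_codes[i] = row["alt_code"]
    ids = [f"rs{i + 1}" for i in range(len(positions))]
    catalog_path = out / "catalog.tsv"
    with open(catalog_path, "w") as fh:
        fh.write("#ID\tCHROM\tPOS\tREF\tALTS\n")
        for i, (chrom, pos) in enumerate(positions):
            fh.write(
                f"{ids[i]}\t{chrom}\t{pos}\t{_BASES[ref_codes[i]]}\t{_BASES[alt_codes[i]]}\n"
            )

    # association results (plink-like)
    lo, hi = spec.leading_p_log10_range
    if spec.uniform_gwas_p:
        lead_p = rng.uniform(0.0, 1.0, size=spec.n_leading)
        lead_p[lead_p == 0.0] = 1.0
    else:
        lead_p = 10.0 ** rng.uniform(lo, hi, size=spec.n_leading)
    gwas_path = out / "gwas.tsv"
    with open(gwas_path, "w") as fh:
        fh.write("#ID\tCHROM\tPOS\tP\n")
        for j, i in enumerate(lead_idx):
            chrom, pos = positions[i]
            fh.write(f"{ids[i]}\t{chrom}\t{pos}\t{float(lead_p[j])!r}\n")

    # LD table: background proxies per leading variant, plus planted rows
    ld_path = out / "ld.tsv"
    lo_r2, hi_r2 = spec.background_r2_range
    covered_variant_idx: set[int] = set(int(i) for i in lead_idx)
    with open(ld_path, "w") as fh:
        fh.write("#ID_A\tID_B\tR2\tPOP\n")
        for j, i in enumerate(lead_idx):
            for _ in range(spec.proxies_per_leading):
                q = int(proxy_pool[pool_cursor]); pool_cursor += 1
                r2 = float(rng.uniform(lo_r2, hi_r2))
                fh.write(f"{ids[i]}\t{ids[q]}\t{r2!r}\t{spec.population}\n")
                covered_variant_idx.add(q)
        for row in planted_rows:
            plant = row["plant"]
            lead_i = int(lead_idx[plant.leading_index])
            fh.write(
                f"{ids[lead_i]}\t{ids[row['proxy_index']]}\t{plant.r2!r}\t{spec.population}\n"
            )

    # regulatory tracks: enhancers per cell type, a ChromHMM-like raw track,
    # and interaction anchors around planted sites
    half = 10
    tracks: dict[str, list[str]] = {"cellA_enh": [], "cellB_enh": [], "chromhmm": []}
    for i in sorted(covered_variant_idx):
        chrom, pos = positions[i]
        for track, ct_cov in (("cellA_enh", spec.enhancer_coverage),
                              ("cellB_enh", spec.enhancer_coverage * 0.8)):
            if rng.uniform() < ct_cov:
                lo_b = max(0, pos - 1 - int(rng.integers(2, half)))
                hi_b = pos + int(rng.integers(2, half))
                tracks[track].append(f"{chrom}\t{lo_b}\t{hi_b}")
        state = "11_Strong_Enhancer" if rng.uniform() < 0.5 else "7_Weak_Enhancer"
        tracks["chromhmm"].append(f"{chrom}\t{max(0, pos - 6)}\t{pos + 5}\t{state}")
    bedpe_rows = []
    genes_rows = []
    for n, row in enumerate(planted_rows):
        plant, chrom, pos = row["plant"], row["chrom"], row["pos"]
        tracks["cellA_enh"].append(f"{chrom}\t{pos - 1 - half}\t{pos + half}")
        partner_start = min(pos + 5_000, spec.chrom_length - 200)
        bedpe_rows.append(
            f"{chrom}\t{pos - 1 - 15}\t{pos + 15}\t{chrom}\t{partner_start}\t"
            f"{partner_start + 100}\tloop{n + 1}\t{8.0 + n}"
        )
        genes_rows.append(f"{chrom}\t{pos - 1 - 200}\t{pos + 200}\tPLANT_GENE{n + 1}")
        genes_rows.append(
            f"{chrom}\t{partner_start - 50}\t{partner_start + 150}\tPARTNER_GENE{n + 1}"
        )
    genes_rows.append(f"{chrom_names[0]}\t1000\t2500\tBG_GENE1")

    track_files = {
        "cellA_enh": ("H3K27ac", "cellA", "cellA_enhancer.bed"),
        "cellB_enh": ("H3K27ac", "cellB", "cellB_enhancer.bed"),
        "chromhmm": ("chromhmm_enhancer", "cellA", "cellA_chromhmm.bed"),
    }
    manifest = []
    for key, (mark, ct, fname) in track_files.items():
        path = out / fname
        with open(path, "w") as fh:
            for line in sorted(set(tracks[key])):
                fh.write(line + "\n")
        manifest.append({"mark_class": mark, "cell_type": ct, "path": fname})
    bedpe_path = out / "cellA_interactions.bedpe"
    with open(bedpe_path, "w") as fh:
        for line in bedpe_rows:
            fh.write(line + "\n")
    manifest.append(
        {"mark_class": "interaction_anchor", "cell_type": "cellA",
         "path": "cellA_interactions.bedpe"}
    )
    manifest_path = out / "tracks.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    # constrained elements
    conserved_rows = []
    if spec.conservation_tiling:
        for i in sorted(covered_variant_idx):
            chrom, pos = positions[i]
            p = float(rng.uniform())
            conserved_rows.append(f"{chrom}\t{pos - 1}\t{pos}\telem_{ids[i]}\t{p or 1.0!r}")
    else:
        for n in range(spec.n_background_elements):
            chrom = chrom_names[int(rng.integers(0, spec.n_chroms))]
            start = int(rng.integers(margin, spec.chrom_length - margin - 30))
            p = float(rng.uniform())
            conserved_rows.append(f"{chrom}\t{start}\t{start + 25}\tbg_elem{n + 1}\t{p or 1.0!r}")
    for n, row in enumerate(planted_rows):
        chrom, pos = row["chrom"], row["pos"]
        conserved_rows.append(
            f"{chrom}\t{pos - 6}\t{pos + 5}\tplanted_elem{n + 1}\t"
            f"{row['plant'].element_p!r}"
        )
    conserved_path = out / "conserved.bed"
    with open(conserved_path, "w") as fh:
        for line in conserved_rows:
            fh.write(line + "\n")

    genes_path = out / "genes.bed"
    with open(genes_path, "w") as fh:
        for line in sorted(set(genes_rows)):
            fh.write(line + "\n")

    motifs_path = out / "motifs.pfm"
    with open(motifs_path, "w") as fh:
        for i, pfm in enumerate(pfms):
            fam = "PLANTED" if i == 0 else f"FAM{i}"
            fh.write(f">motif{i + 1} {fam}\n")
            for col in pfm:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")

    truth = {
        "seed": seed,
        "planted": [
            {
                "leading_id": ids[int(lead_idx[row["plant"].leading_index])],
                "proxy_id": ids[row["proxy_index"]],
                "chrom": row["chrom"],
                "pos": row["pos"],
                "motif": f"motif{row['plant'].motif_index + 1}",
                "r2": row["plant"].r2,
                "cell_type": row["plant"].cell_type,
            }
            for row in planted_rows
        ],
        "leading_ids": [ids[int(i)] for i in lead_idx],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    return FixtureBundle(
        out_dir=out,
        genome=genome_path,
        motifs=motifs_path,
        catalog=catalog_path,
        gwas=gwas_path,
        ld=ld_path,
        tracks_manifest=manifest_path,
        conserved=conserved_path,
        genes=genes_path,
        truth=truth,
    )
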