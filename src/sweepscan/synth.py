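"""Ground-truthed synthetic datasets for the selection-scan pipeline.

Generates a complete toy study — reference FASTA, GFF3 gene models, a
multi-sample VCF for two populations, a pathway-membership table and a
machine-checkable truth table — with the statistical structure the
analysis assumes:

* background SNPs with realistic two-population differentiation, drawn
  either from the structured-coalescent engine (default) or from a fast
  Balding-Nichols i.i.d. model;
* injected selective-sweep windows of strongly elevated differentiation;
* planted fixed functional variants at designed CDS/UTR/splice positions
  (every consequence category reachable by construction);
* per-genotype missingness;
* one pathway enriched for the planted functional genes.

Each toy gene has the same two-exon architecture (5'-UTR, coding sequence
split by one intron, 3'-UTR), laid on alternating strands; planted coding
positions use designed codons so the expected amino-acid change is known
without running the classifier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import effects as fx
from .coalescent import (
    DemographicModel,
    default_dog_wolf_model,
    simulate_window,
)
from .effects import GeneModel, build_gene_model
from .genotypes import PopulationMap

# gene architecture (offsets from gene start, 1-based lengths)
_UTR_LEN = 200
_CDS1_LEN = 200
_INTRON_LEN = 1000
_CDS2_LEN = 1000
_GENE_SPAN = _UTR_LEN + _CDS1_LEN + _INTRON_LEN + _CDS2_LEN + _UTR_LEN  # 2600
_N_CODONS = (_CDS1_LEN + _CDS2_LEN) // 3  # 400

# designed codons (transcript orientation): codon index -> (ref codon,
# position within codon, transcript alt base, consequence, aa change)
_DESIGNS = {
    fx.MISSENSE: (10, "GAA", 0, "A", "E/K"),
    fx.SYNONYMOUS: (20, "GGA", 2, "G", "G/G"),
    fx.STOP_GAINED: (30, "TGG", 2, "A", "W/*"),
    fx.STOP_LOST: (_N_CODONS - 1, "TAA", 0, "C", "*/Q"),
}
_FILLER_CODON = "GCT"
_STOP_CODON = "TAA"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SweepSpec:
    """A region to inject as a selective sweep."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    target_fst: float = 0.85
    n_extra_sites: int = 40


@dataclass(frozen=True)
class PlantedVariant:
    """A fixed functional difference placed inside a toy gene."""

    gene_index: int
    consequence: str  # one of the classifier's consequence labels


@dataclass
class SyntheticConfig:
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    population_sizes: dict[str, int] = field(
        default_factory=lambda: {"dog": 67, "wolf": 7}
    )
    n_genes: int = 20
    background_mode: str = "coalescent"  # or "iid"
    #: i.i.d. mode: Balding-Nichols differentiation level of background SNPs
    background_fst: float = 0.14
    #: i.i.d. mode: background SNPs per chromosome
    background_sites_per_chrom: int = 1500
    #: coalescent mode: demography for background variation (defaults to the
    #: illustrative dog/wolf model with smaller blocks for speed)
    demography: DemographicModel | None = None
    #: scan window size the toy genome is designed for (smaller than the
    #: full-scale 500 kb so a 2 x 5 Mb genome still yields ~100 windows,
    #: enough for a meaningful genome-wide Z-score)
    window_size: int = 100_000
    sweeps: list[SweepSpec] = field(
        default_factory=lambda: [
            SweepSpec("chr1", 2_400_001, 2_500_000),
            SweepSpec("chr2", 3_700_001, 3_800_000),
        ]
    )
    planted: list[PlantedVariant] = field(
        default_factory=lambda: [
            PlantedVariant(0, fx.MISSENSE),
            PlantedVariant(2, fx.FIVE_PRIME_UTR),
            PlantedVariant(4, fx.THREE_PRIME_UTR),
            PlantedVariant(6, fx.SPLICE_REGION),
            PlantedVariant(8, fx.STOP_GAINED),
            PlantedVariant(10, fx.STOP_LOST),
            PlantedVariant(12, fx.SYNONYMOUS),
            PlantedVariant(14, fx.MISSENSE),
            PlantedVariant(16, fx.THREE_PRIME_UTR),
        ]
    )
    missing_rate: float = 0.05
    n_pathways: int = 4
    enriched_pathway: str = "catecholamine_signalling"
    seed: int = 0


@dataclass
class DatasetBundle:
    root: Path
    fasta: Path
    gff3: Path
    vcf: Path
    popmap: Path
    pathways: Path
    truth: Path
    models: list[GeneModel]

    def truth_frame(self) -> pd.DataFrame:
        return pd.read_csv(self.truth, sep="\t")


def _gene_layout(config: SyntheticConfig) -> list[tuple[str, int, str, str]]:
    """(gene_id, start, chrom, strand) for each toy gene, evenly spaced and
    kept clear of sweep regions."""
    chroms = list(config.chromosomes)
    per_chrom = math.ceil(config.n_genes / len(chroms))
    out = []
    for gi in range(config.n_genes):
        chrom = chroms[gi // per_chrom]
        length = config.chromosomes[chrom]
        slot = gi % per_chrom
        start = int((slot + 0.5) * length / per_chrom - _GENE_SPAN // 2)
        out.append((f"gene{gi:02d}", start, chrom, "+" if gi % 2 == 0 else "-"))
    return out


def _design_cds() -> str:
    codons = [_FILLER_CODON] * _N_CODONS
    for idx, ref_codon, _, _, _ in _DESIGNS.values():
        codons[idx] = ref_codon
    codons[-1] = _DESIGNS[fx.STOP_LOST][1]  # terminal stop
    return "".join(codons)


def _build_models(
    layout: Sequence[tuple[str, int, str, str]],
    sequences: dict[str, bytearray],
) -> list[GeneModel]:
    models = []
    decoded = {chrom: arr.decode() for chrom, arr in sequences.items()}
    for gene_id, start, chrom, strand in layout:
        s = start
        exon_a = (s, s + _UTR_LEN + _CDS1_LEN - 1)
        cds_a = (s + _UTR_LEN, s + _UTR_LEN + _CDS1_LEN - 1)
        intron_end = cds_a[1] + _INTRON_LEN
        cds_b = (intron_end + 1, intron_end + _CDS2_LEN)
        exon_b = (cds_b[0], cds_b[1] + _UTR_LEN)
        seq = decoded[chrom]
        models.append(
            build_gene_model(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                chrom=chrom,
                strand=strand,
                exons=[exon_a, exon_b],
                cds=[cds_a, cds_b],
                chrom_seq=seq,
            )
        )
    return models


def _write_cds_into_genome(
    sequences: dict[str, bytearray],
    layout: Sequence[tuple[str, int, str, str]],
    cds_design: str,
) -> None:
    """Place the designed coding sequence (transcript orientation) into the
    genome, reverse-complemented for minus-strand genes."""
    for gene_id, start, chrom, strand in layout:
        s = start
        cds_a = list(range(s + _UTR_LEN, s + _UTR_LEN + _CDS1_LEN))
        b0 = s + _UTR_LEN + _CDS1_LEN + _INTRON_LEN
        cds_b = list(range(b0, b0 + _CDS2_LEN))
        genomic = cds_a + cds_b  # ascending genomic positions of CDS bases
        if strand == "+":
            for p, base in zip(genomic, cds_design):
                sequences[chrom][p - 1] = ord(base)
        else:
            rc = "".join(_COMPLEMENT[b] for b in reversed(cds_design))
            for p, base in zip(genomic, rc):
                sequences[chrom][p - 1] = ord(base)


def _planted_site(
    model: GeneModel, consequence: str, rng: np.random.Generator
) -> tuple[int, str, str, str | None]:
    """Resolve a planted consequence to (genomic pos, ref, alt, aa_change)."""
    if consequence in _DESIGNS:
        codon_idx, ref_codon, within, alt_t, aa = _DESIGNS[consequence]
        off = 3 * codon_idx + within
        pos = model.cds_positions[off]
        ref_t = model.cds_seq[off]
        assert ref_t == ref_codon[within]
        if model.strand == "+":
            return pos, ref_t, alt_t, aa
        return pos, _COMPLEMENT[ref_t], _COMPLEMENT[alt_t], aa
    if consequence == fx.FIVE_PRIME_UTR:
        iv = model.utr5[0]
    elif consequence == fx.THREE_PRIME_UTR:
        iv = model.utr3[0]
    elif consequence == fx.SPLICE_REGION:
        intron = model.introns()[0]
        pos = intron[0] + 4  # 5 bp into the intron
        iv = (pos, pos)
    else:
        raise ValueError(f"cannot plant consequence {consequence!r}")
    pos = (iv[0] + iv[1]) // 2
    # non-coding: ref comes from the genome; pick any different alt
    return pos, "", "", None


def _bn_population_freqs(
    p: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols draw of a population allele frequency around an
    ancestral frequency p, with expected differentiation ``fst``."""
    if fst <= 0:
        return p.copy()
    c = (1.0 - fst) / fst
    return rng.beta(p * c, (1.0 - p) * c)


def generate_dataset(config: SyntheticConfig, outdir: str | Path) -> DatasetBundle:
    """Write the full synthetic bundle and its truth table.

    Deterministic given ``config.seed``. Planted variants are placed with
    full call rate (missingness applies to background sites only) so their
    recovery is a property of the pipeline, not of luck.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = list(config.population_sizes)
    if len(labels) != 2:
        raise ValueError("exactly two populations required")
    pop_a, pop_b = labels  # convention: pop_a carries the derived alleles
    n_a, n_b = config.population_sizes[pop_a], config.population_sizes[pop_b]
    samples = [f"{pop_a}{i + 1}" for i in range(n_a)] + [
        f"{pop_b}{i + 1}" for i in range(n_b)
    ]

    # --- genome + genes
    base_map = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {
        chrom: bytearray(base_map[rng.integers(0, 4, size=length)].tobytes())
        for chrom, length in config.chromosomes.items()
    }
    layout = _gene_layout(config)
    for _, start, chrom, _ in layout:
        end = start + _GENE_SPAN - 1
        if start < 1 or end > config.chromosomes[chrom]:
            raise ValueError("gene layout exceeds chromosome bounds")
    _write_cds_into_genome(sequences, layout, _design_cds())
    models = _build_models(layout, sequences)

    # --- planted fixed functional variants
    truth_rows: list[dict] = []
    planted_sites: dict[tuple[str, int], tuple[str, str]] = {}  # (chrom,pos)->(ref,alt)
    for plant in config.planted:
        if plant.gene_index >= len(models):
            raise ValueError(
                f"planted variant references gene {plant.gene_index}, "
                f"but only {len(models)} genes exist"
            )
        model = models[plant.gene_index]
        pos, ref, alt, aa = _planted_site(model, plant.consequence, rng)
        if not ref:  # non-coding: take ref from genome
            ref = chr(sequences[model.chrom][pos - 1])
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        planted_sites[(model.chrom, pos)] = (ref, alt)
        truth_rows.append(
            {
                "kind": "fixed_variant",
                "chrom": model.chrom,
                "pos": pos,
                "start": "",
                "end": "",
                "gene": model.gene_id,
                "consequence": plant.consequence,
                "detail": aa or "",
            }
        )

    # --- background variation
    bg: list[tuple[str, int, np.ndarray]] = []  # (chrom, pos, genotype codes)
    if config.background_mode == "iid":
        for chrom, length in config.chromosomes.items():
            n_sites = config.background_sites_per_chrom
            pos = np.sort(
                rng.choice(np.arange(1, length + 1), size=n_sites, replace=False)
            )
            p_anc = rng.uniform(0.05, 0.95, size=n_sites)
            p1 = _bn_population_freqs(p_anc, config.background_fst, rng)
            p2 = _bn_population_freqs(p_anc, config.background_fst, rng)
            g_a = rng.binomial(2, p1[:, None], size=(n_sites, n_a))
            g_b = rng.binomial(2, p2[:, None], size=(n_sites, n_b))
            geno = np.concatenate([g_a, g_b], axis=1)
            for j in range(n_sites):
                bg.append((chrom, int(pos[j]), geno[j]))
    elif config.background_mode == "coalescent":
        model = config.demography or default_dog_wolf_model(
            window_length=config.window_size, blocks=10
        )
        hap_samples = {pop_a: 2 * n_a, pop_b: 2 * n_b}
        for chrom, length in config.chromosomes.items():
            n_segments = math.ceil(length / model.window_length)
            for seg in range(n_segments):
                window = simulate_window(model, hap_samples, rng)
                offset = seg * model.window_length
                haps = window.haplotypes
                geno = haps[: 2 * n_a].reshape(n_a, 2, -1).sum(axis=1)
                geno_b = haps[2 * n_a :].reshape(n_b, 2, -1).sum(axis=1)
                geno = np.concatenate([geno, geno_b], axis=0)  # (samples, sites)
                for j in range(window.n_sites):
                    pos = offset + int(window.positions[j])
                    if pos <= length:
                        bg.append((chrom, pos, geno[:, j]))
    else:
        raise ValueError(f"unknown background_mode {config.background_mode!r}")

    # --- sweep injection: redraw genotypes inside sweep spans and add sites
    sweep_spans = {(s.chrom, s.start, s.end): s for s in config.sweeps}

    def _sweep_genotypes(n_sites: int, target: float) -> np.ndarray:
        lo = max(0.0, min(target, 0.999))
        p1 = rng.uniform(lo, 1.0, size=n_sites)
        p2 = rng.uniform(0.0, 1.0 - lo, size=n_sites)
        g_a = rng.binomial(2, p1[:, None], size=(n_sites, n_a))
        g_b = rng.binomial(2, p2[:, None], size=(n_sites, n_b))
        return np.concatenate([g_a, g_b], axis=1)

    for spec in config.sweeps:
        if spec.chrom not in config.chromosomes:
            raise ValueError(f"sweep on unknown chromosome {spec.chrom!r}")
        inside = [
            i
            for i, (c, p, _) in enumerate(bg)
            if c == spec.chrom and spec.start <= p <= spec.end
        ]
        redraw = _sweep_genotypes(len(inside), spec.target_fst)
        for row, i in enumerate(inside):
            c, p, _ = bg[i]
            bg[i] = (c, p, redraw[row])
        taken = {p for c, p, _ in bg if c == spec.chrom} | {
            p for c, p in planted_sites if c == spec.chrom
        }
        extra_pos = []
        while len(extra_pos) < spec.n_extra_sites:
            p = int(rng.integers(spec.start, spec.end + 1))
            if p not in taken:
                taken.add(p)
                extra_pos.append(p)
        extra_geno = _sweep_genotypes(len(extra_pos), spec.target_fst)
        for row, p in enumerate(sorted(extra_pos)):
            bg.append((spec.chrom, p, extra_geno[row]))
        truth_rows.append(
            {
                "kind": "sweep_window",
                "chrom": spec.chrom,
                "pos": "",
                "start": spec.start,
                "end": spec.end,
                "gene": "",
                "consequence": "",
                "detail": f"target_fst={spec.target_fst}",
            }
        )

    # drop background colliding with planted positions, add planted genotypes
    bg = [(c, p, g) for c, p, g in bg if (c, p) not in planted_sites]

    # --- missingness on background sites
    n_samples = n_a + n_b
    for i, (c, p, g) in enumerate(bg):
        mask = rng.random(n_samples) < config.missing_rate
        g = g.astype(np.int64)
        g[mask] = -1
        bg[i] = (c, p, g)

    planted_geno = np.concatenate(
        [np.full(n_a, 2, dtype=int), np.zeros(n_b, dtype=int)]
    )
    all_sites = bg + [
        (c, p, planted_geno.copy()) for (c, p) in planted_sites
    ]
    all_sites.sort(key=lambda t: (t[0], t[1]))

    # --- pathway table
    functional_planted = sorted(
        {
            r["gene"]
            for r in truth_rows
            if r["kind"] == "fixed_variant"
            and r["consequence"] in fx.FUNCTIONAL_CONSEQUENCES
        }
    )
    all_genes = [m.gene_id for m in models]
    enriched_members = functional_planted[: max(2, len(functional_planted) - 1)]
    remaining = [g for g in all_genes if g not in enriched_members]
    pathway_rows = [(config.enriched_pathway, g) for g in enriched_members]
    for k in range(config.n_pathways - 1):
        size = min(5, len(remaining))
        members = rng.choice(remaining, size=size, replace=False)
        pathway_rows.extend((f"pathway_{k + 1}", g) for g in sorted(members))
    truth_rows.append(
        {
            "kind": "enriched_pathway",
            "chrom": "",
            "pos": "",
            "start": "",
            "end": "",
            "gene": ";".join(enriched_members),
            "consequence": "",
            "detail": config.enriched_pathway,
        }
    )

    # --- write files
    fasta_path = outdir / "genome.fa"
    with fasta_path.open("w") as fh:
        for chrom, arr in sequences.items():
            fh.write(f">{chrom}\n")
            seq = arr.decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    gff_path = outdir / "genes.gff3"
    _write_gff3(gff_path, models, config.chromosomes)

    vcf_path = outdir / "variants.vcf"
    _write_vcf(vcf_path, all_sites, samples, sequences, config.chromosomes,
               planted_sites)

    popmap_path = outdir / "popmap.tsv"
    popmap_path.write_text(
        "".join(
            f"{s}\t{pop_a if i < n_a else pop_b}\n" for i, s in enumerate(samples)
        )
    )

    pathway_path = outdir / "pathways.tsv"
    pathway_path.write_text(
        "".join(f"{p}\t{g}\n" for p, g in pathway_rows)
    )

    truth_path = outdir / "truth.tsv"
    pd.DataFrame(
        truth_rows,
        columns=["kind", "chrom", "pos", "start", "end", "gene", "consequence",
                 "detail"],
    ).to_csv(truth_path, sep="\t", index=False)

    return DatasetBundle(
        root=outdir,
        fasta=fasta_path,
        gff3=gff_path,
        vcf=vcf_path,
        popmap=popmap_path,
        pathways=pathway_path,
        truth=truth_path,
        models=models,
    )


def _write_gff3(
    path: Path, models: Sequence[GeneModel], chrom_lengths: dict[str, int]
) -> None:
    lines = ["##gff-version 3"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for i, m in enumerate(models):
        lo, hi = m.span
        lines.append(
            f"{m.chrom}\ttoy\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
            f"ID={m.gene_id};Name={m.gene_id}"
        )
        lines.append(
            f"{m.chrom}\ttoy\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
            f"ID={m.transcript_id};Parent={m.gene_id}"
        )
        for s, e in m.exons:
            lines.append(
                f"{m.chrom}\ttoy\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"Parent={m.transcript_id}"
            )
        for s, e in m.cds:
            lines.append(
                f"{m.chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                f"Parent={m.transcript_id}"
            )
        # half the genes get explicit UTR features; the rest exercise the
        # exon-minus-CDS derivation path in the loader
        if i % 2 == 0:
            for s, e in m.utr5:
                lines.append(
                    f"{m.chrom}\ttoy\tfive_prime_UTR\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}"
                )
            for s, e in m.utr3:
                lines.append(
                    f"{m.chrom}\ttoy\tthree_prime_UTR\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}"
                )
    path.write_text("\n".join(lines) + "\n")


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _write_vcf(
    path: Path,
    sites: Sequence[tuple[str, int, np.ndarray]],
    samples: Sequence[str],
    sequences: dict[str, bytearray],
    chrom_lengths: dict[str, int],
    planted_sites: Mapping[tuple[str, int], tuple[str, str]],
) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=sweepscan-synth"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    alt_of = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for chrom, pos, geno in sites:
        if (chrom, pos) in planted_sites:
            ref, alt = planted_sites[(chrom, pos)]
        else:
            ref = chr(sequences[chrom][pos - 1])
            alt = alt_of[ref]
        gts = "\t".join(_GT[int(g)] for g in geno)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class RecoveryReport:
    """Pipeline output scored against the truth table."""

    sweep_recall: float
    sweep_precision: float
    fixed_variant_recall: float
    consequence_accuracy: float
    enriched_pathway_rank: int | None  # 1 = most significant
    n_outlier_windows: int

    def to_dict(self) -> dict:
        return {
            "sweep_recall": self.sweep_recall,
            "sweep_precision": self.sweep_precision,
            "fixed_variant_recall": self.fixed_variant_recall,
            "consequence_accuracy": self.consequence_accuracy,
            "enriched_pathway_rank": self.enriched_pathway_rank,
            "n_outlier_windows": self.n_outlier_windows,
        }


def evaluate_against_truth(
    truth: pd.DataFrame,
    outlier_windows: Sequence,  # WindowStat with outlier flags set
    divergent_sites: Sequence,  # DivergentSite with effects attached
    enrichment: pd.DataFrame | None = None,
) -> RecoveryReport:
    """Precision/recall of sweep detection, fixed-variant recovery with
    consequence labels, and the rank of the planted enriched pathway."""
    flagged = [w for w in outlier_windows if w.outlier]
    sweep_rows = truth[truth["kind"] == "sweep_window"]
    hit = 0
    for _, row in sweep_rows.iterrows():
        s, e = int(row["start"]), int(row["end"])
        if any(
            w.chrom == row["chrom"] and w.start <= e and w.end >= s for w in flagged
        ):
            hit += 1
    sweep_recall = hit / len(sweep_rows) if len(sweep_rows) else float("nan")
    used = sum(
        1
        for w in flagged
        if any(
            w.chrom == row["chrom"]
            and w.start <= int(row["end"])
            and w.end >= int(row["start"])
            for _, row in sweep_rows.iterrows()
        )
    )
    sweep_precision = used / len(flagged) if flagged else float("nan")

    fixed_rows = truth[truth["kind"] == "fixed_variant"]
    fixed_sites = {
        (d.chrom, d.pos): d for d in divergent_sites if d.fixed
    }
    n_found = 0
    n_label = 0
    for _, row in fixed_rows.iterrows():
        d = fixed_sites.get((row["chrom"], int(row["pos"])))
        if d is None:
            continue
        n_found += 1
        if any(
            e.gene_id == row["gene"] and e.consequence == row["consequence"]
            for e in d.effects
        ):
            n_label += 1
    n_truth = len(fixed_rows)
    fixed_recall = n_found / n_truth if n_truth else float("nan")
    consequence_accuracy = n_label / n_truth if n_truth else float("nan")

    rank = None
    path_rows = truth[truth["kind"] == "enriched_pathway"]
    if enrichment is not None and len(path_rows):
        name = path_rows.iloc[0]["detail"]
        tested = enrichment[enrichment["p_value"].notna()].reset_index(drop=True)
        where = tested.index[tested["pathway"] == name]
        rank = int(where[0]) + 1 if len(where) else None

    return RecoveryReport(
        sweep_recall=sweep_recall,
        sweep_precision=sweep_precision,
        fixed_variant_recall=fixed_recall,
        consequence_accuracy=consequence_accuracy,
        enriched_pathway_rank=rank,
        n_outlier_windows=len(flagged),
    )
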