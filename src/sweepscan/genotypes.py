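"""Genotype input: VCF reading, population maps, call-rate filtering.

Variants enter the analysis as per-population genotype *counts* — phase and
individual identity are irrelevant to every downstream statistic, so records
are collapsed at read time. Only biallelic SNPs are retained; indels and
multi-allelic records are skipped and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of samples to exactly two population labels."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignments.values()))
        if len(labels) != 2:
            raise ValueError(
                f"population map must contain exactly two labels, got {labels}"
            )

    @property
    def labels(self) -> tuple[str, str]:
        return tuple(sorted(set(self.assignments.values())))  # type: ignore[return-value]

    def population_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not present in population map") from None

    def samples(self, label: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == label]

    def size(self, label: str) -> int:
        return sum(1 for p in self.assignments.values() if p == label)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        """Read a two-column (sample_id, population) TSV; '#' lines ignored."""
        assignments: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed population map line: {line!r}")
            sample, pop = parts
            if sample in assignments:
                raise ValueError(f"sample {sample!r} assigned twice")
            assignments[sample] = pop
        return cls(assignments)


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype class counts for one population at one site."""

    hom_ref: int
    het: int
    hom_alt: int
    missing: int

    @property
    def size(self) -> int:
        return self.hom_ref + self.het + self.hom_alt + self.missing

    @property
    def called(self) -> int:
        return self.size - self.missing

    @property
    def called_fraction(self) -> float:
        return self.called / self.size if self.size else 0.0

    @property
    def alt_frequency(self) -> float:
        """Alt-allele frequency among called genotypes; NaN when none called."""
        if self.called == 0:
            return math.nan
        return (2 * self.hom_alt + self.het) / (2 * self.called)


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP with per-population genotype counts."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    counts: dict[str, GenotypeCounts]

    def called_fraction(self, population: str) -> float:
        return self.counts[population].called_fraction

    def alt_frequency(self, population: str) -> float:
        return self.counts[population].alt_frequency


@dataclass
class ReadStats:
    """Bookkeeping from a VCF pass."""

    n_records: int = 0
    n_retained: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_non_snp: int = 0


def _is_snp(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref in _BASES
        and alts[0] in _BASES
    )


def read_sites(
    vcf_path: str | Path,
    popmap: PopulationMap,
    stats: ReadStats | None = None,
) -> list[SiteRecord]:
    """Read biallelic SNPs from a VCF into per-population genotype counts.

    Non-SNP and multi-allelic records are skipped (counted in ``stats`` and
    logged). Every sample in the VCF must be present in ``popmap``. Phase is
    ignored; haploid calls count as a single allele carrier is not supported
    by the count model and such genotypes are treated by allele content
    (cyvcf2 reports them in the hom classes).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    pops = [popmap.population_of(s) for s in vcf.samples]
    label_a, label_b = popmap.labels
    idx_by_pop = {
        label_a: [i for i, p in enumerate(pops) if p == label_a],
        label_b: [i for i, p in enumerate(pops) if p == label_b],
    }
    if stats is None:
        stats = ReadStats()

    sites: list[SiteRecord] = []
    for variant in vcf:
        stats.n_records += 1
        if len(variant.ALT) > 1:
            stats.n_skipped_multiallelic += 1
            continue
        if not _is_snp(variant.REF, variant.ALT):
            stats.n_skipped_non_snp += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown/missing, 3=hom-alt
        gt = variant.gt_types
        counts = {}
        for label, idx in idx_by_pop.items():
            sub = gt[idx]
            counts[label] = GenotypeCounts(
                hom_ref=int((sub == 0).sum()),
                het=int((sub == 1).sum()),
                hom_alt=int((sub == 3).sum()),
                missing=int((sub == 2).sum()),
            )
        sites.append(
            SiteRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0],
                counts=counts,
            )
        )
        stats.n_retained += 1

    if stats.n_skipped_multiallelic or stats.n_skipped_non_snp:
        log.info(
            "skipped %d multi-allelic and %d non-SNP records of %d",
            stats.n_skipped_multiallelic,
            stats.n_skipped_non_snp,
            stats.n_records,
        )
    return sites


def filter_by_call_rate(
    sites: Iterable[SiteRecord], min_fraction: float = 0.5
) -> list[SiteRecord]:
    """Keep sites whose called fraction is >= ``min_fraction`` in *both*
    populations (inclusive boundary)."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    return [
        s
        for s in sites
        if all(c.called_fraction >= min_fraction for c in s.counts.values())
    ]


def allele_frequency(site: SiteRecord, population: str) -> float:
    """Alt-allele frequency in one population; NaN if no called genotypes."""
    return site.counts[population].alt_frequency


def write_sites_vcf(
    sites: Sequence[SiteRecord],
    popmap: PopulationMap,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write SiteRecords back out as a minimal VCF.

    Individual genotypes are reconstructed from the class counts in a fixed
    order within each population; counts (the quantity the pipeline uses)
    round-trip exactly, individual assignment does not.
    """
    samples_by_pop = {lab: popmap.samples(lab) for lab in popmap.labels}
    header_samples = [s for lab in popmap.labels for s in samples_by_pop[lab]]
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(header_samples)
    )
    for site in sites:
        gts: list[str] = []
        for lab in popmap.labels:
            c = site.counts[lab]
            if c.size != len(samples_by_pop[lab]):
                raise ValueError(
                    f"count total {c.size} != population size "
                    f"{len(samples_by_pop[lab])} for {lab!r} at "
                    f"{site.chrom}:{site.pos}"
                )
            gts.extend(
                ["0/0"] * c.hom_ref
                + ["0/1"] * c.het
                + ["1/1"] * c.hom_alt
                + ["./."] * c.missing
            )
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")
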