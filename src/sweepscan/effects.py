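"""Variant effect classification against transcript models.

A deliberately compact consequence predictor covering the categories that
matter for scans of coding and near-gene regulatory change: coding changes
(missense, synonymous, stop gained/lost), UTR location, and splice-region
proximity. Consequences are computed per overlapping transcript; a site may
therefore carry several effects.

Splice-region convention: 1-3 bp into an exon from an exon-intron junction,
or 1-8 bp into an intron (the first 2 intronic bases are the canonical
donor/acceptor dinucleotides and are reported under the same coarse
splice_region label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .genotypes import SiteRecord

log = logging.getLogger(__name__)

# consequence labels
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
FRAMESHIFT = "frameshift"  # defined for completeness; unreachable with SNPs
FIVE_PRIME_UTR = "five_prime_utr"
THREE_PRIME_UTR = "three_prime_utr"
SPLICE_REGION = "splice_region"
NON_FUNCTIONAL = "non_functional"

#: most to least severe, used for gene-level "most severe" summaries
SEVERITY_ORDER = (
    STOP_GAINED,
    STOP_LOST,
    FRAMESHIFT,
    MISSENSE,
    SPLICE_REGION,
    FIVE_PRIME_UTR,
    THREE_PRIME_UTR,
    SYNONYMOUS,
    NON_FUNCTIONAL,
)

FUNCTIONAL_CONSEQUENCES = frozenset(
    {
        MISSENSE,
        STOP_GAINED,
        STOP_LOST,
        FRAMESHIFT,
        FIVE_PRIME_UTR,
        THREE_PRIME_UTR,
        SPLICE_REGION,
    }
)

Interval = tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class VariantEffect:
    chrom: str
    pos: int
    gene_id: str | None
    transcript_id: str | None
    consequence: str
    aa_change: str | None = None  # "M/V" style, coding consequences only


@dataclass(frozen=True)
class GeneModel:
    """One transcript with exon/CDS/UTR structure and its coding sequence.

    ``cds_positions`` lists the genomic position of every CDS base in
    transcript (5'->3') orientation; ``cds_seq`` is the corresponding
    sequence, so codon lookups need no further genome access.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    utr5: tuple[Interval, ...]
    utr3: tuple[Interval, ...]
    cds_positions: tuple[int, ...]
    cds_seq: str

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the coding sequence
        (transcript orientation), or None if not a CDS base."""
        try:
            return self.cds_positions.index(pos)
        except ValueError:
            return None

    def introns(self) -> list[Interval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


def _in_any(pos: int, intervals: Iterable[Interval]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _subtract(exons: Sequence[Interval], cds: Sequence[Interval]) -> list[Interval]:
    """Exonic intervals minus CDS intervals (all 1-based inclusive)."""
    out: list[Interval] = []
    for es, ee in exons:
        segments = [(es, ee)]
        for cs, ce in cds:
            nxt: list[Interval] = []
            for s, e in segments:
                if ce < s or cs > e:
                    nxt.append((s, e))
                    continue
                if cs > s:
                    nxt.append((s, cs - 1))
                if ce < e:
                    nxt.append((ce + 1, e))
            segments = nxt
        out.extend(segments)
    return sorted(out)


def build_gene_model(
    gene_id: str,
    transcript_id: str,
    chrom: str,
    strand: str,
    exons: Sequence[Interval],
    cds: Sequence[Interval],
    chrom_seq: str,
    utr5: Sequence[Interval] | None = None,
    utr3: Sequence[Interval] | None = None,
) -> GeneModel:
    """Assemble a GeneModel, deriving UTRs by exon-minus-CDS subtraction
    when they are not annotated explicitly."""
    exons = tuple(sorted(exons))
    cds_sorted = tuple(sorted(cds))
    if utr5 is None or utr3 is None:
        non_coding = _subtract(exons, cds_sorted)
        cds_lo, cds_hi = cds_sorted[0][0], cds_sorted[-1][1]
        upstream = [iv for iv in non_coding if iv[1] < cds_lo]
        downstream = [iv for iv in non_coding if iv[0] > cds_hi]
        if strand == "+":
            utr5, utr3 = upstream, downstream
        else:
            utr5, utr3 = downstream, upstream

    positions: list[int] = []
    for s, e in cds_sorted:
        positions.extend(range(s, e + 1))
    seq = "".join(chrom_seq[p - 1] for p in positions).upper()
    if strand == "-":
        positions = positions[::-1]
        seq = str(Seq(seq).reverse_complement())
    if len(seq) % 3 != 0:
        raise ValueError(
            f"transcript {transcript_id}: CDS length {len(seq)} not divisible by 3"
        )
    return GeneModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds_sorted,
        utr5=tuple(sorted(utr5)),
        utr3=tuple(sorted(utr3)),
        cds_positions=tuple(positions),
        cds_seq=seq,
    )


def load_gene_models(gff3_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Read transcript models from GFF3 + reference FASTA.

    One GeneModel per mRNA feature. UTRs are taken from five_prime_UTR /
    three_prime_UTR features when present, otherwise derived by subtraction.
    Transcripts whose CDS length is not a multiple of 3 are skipped with a
    warning; a chromosome referenced by the GFF3 but absent from the FASTA
    is fatal.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        if mrna.seqid not in fasta:
            raise KeyError(f"chromosome {mrna.seqid!r} missing from FASTA")
        chrom_seq = str(fasta[mrna.seqid][:])
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        utr5 = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="five_prime_UTR")
        ] or None
        utr3 = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="three_prime_UTR")
        ] or None
        if not cds or not exons:
            continue
        try:
            models.append(
                build_gene_model(
                    gene_id, mrna.id, mrna.seqid, mrna.strand, exons, cds,
                    chrom_seq, utr5=utr5, utr3=utr3,
                )
            )
        except ValueError as err:
            log.warning("skipping transcript: %s", err)
    return models


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[base.upper()]


def _coding_effect(model: GeneModel, pos: int, ref: str, alt: str) -> VariantEffect:
    off = model.cds_offset(pos)
    assert off is not None
    ref_t = ref.upper() if model.strand == "+" else _complement(ref)
    alt_t = alt.upper() if model.strand == "+" else _complement(alt)
    if model.cds_seq[off] != ref_t:
        log.warning(
            "reference mismatch at %s:%d in %s (CDS has %s, variant ref %s)",
            model.chrom, pos, model.transcript_id, model.cds_seq[off], ref_t,
        )
    codon_start = (off // 3) * 3
    ref_codon = model.cds_seq[codon_start : codon_start + 3]
    within = off - codon_start
    alt_codon = ref_codon[:within] + alt_t + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        consequence = SYNONYMOUS
    elif alt_aa == "*":
        consequence = STOP_GAINED
    elif ref_aa == "*":
        consequence = STOP_LOST
    else:
        consequence = MISSENSE
    return VariantEffect(
        chrom=model.chrom,
        pos=pos,
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        consequence=consequence,
        aa_change=f"{ref_aa}/{alt_aa}",
    )


def _in_splice_region(
    model: GeneModel, pos: int, exonic_span: int = 3, intronic_span: int = 8
) -> bool:
    for s, e in model.introns():
        if s - exonic_span <= pos <= s - 1 or e + 1 <= pos <= e + exonic_span:
            return True  # exonic side of a junction
        if s <= pos <= min(e, s + intronic_span - 1):
            return True  # intronic, donor side
        if max(s, e - intronic_span + 1) <= pos <= e:
            return True  # intronic, acceptor side
    return False


def classify_variant(
    site: SiteRecord | tuple[str, int, str, str],
    models: Sequence[GeneModel],
    splice_exonic: int = 3,
    splice_intronic: int = 8,
) -> list[VariantEffect]:
    """Consequence call(s) for a SNP against a set of transcript models.

    Returns one or more effects per overlapping transcript (a coding or UTR
    call may co-occur with splice_region). A site overlapping no transcript
    — including one on a chromosome with no models — yields a single
    non_functional effect.
    """
    if isinstance(site, SiteRecord):
        chrom, pos, ref, alt = site.chrom, site.pos, site.ref, site.alt
    else:
        chrom, pos, ref, alt = site

    effects: list[VariantEffect] = []
    for model in models:
        if model.chrom != chrom or not model.contains(pos):
            continue
        primary: VariantEffect | None = None
        if model.cds_offset(pos) is not None:
            primary = _coding_effect(model, pos, ref, alt)
        elif _in_any(pos, model.utr5):
            primary = VariantEffect(chrom, pos, model.gene_id, model.transcript_id,
                                    FIVE_PRIME_UTR)
        elif _in_any(pos, model.utr3):
            primary = VariantEffect(chrom, pos, model.gene_id, model.transcript_id,
                                    THREE_PRIME_UTR)
        if primary is not None:
            effects.append(primary)
        if _in_splice_region(model, pos, splice_exonic, splice_intronic):
            effects.append(
                VariantEffect(chrom, pos, model.gene_id, model.transcript_id,
                              SPLICE_REGION)
            )
        elif primary is None:
            # deep intronic
            effects.append(
                VariantEffect(chrom, pos, model.gene_id, model.transcript_id,
                              NON_FUNCTIONAL)
            )
    if not effects:
        effects.append(VariantEffect(chrom, pos, None, None, NON_FUNCTIONAL))
    return effects


def is_putatively_functional(effect: VariantEffect) -> bool:
    """True for consequences taken as candidates for phenotypic impact:
    protein-changing, UTR, or splice-region; synonymous and non_functional
    are the neutral reference."""
    return effect.consequence in FUNCTIONAL_CONSEQUENCES


def most_severe(effects: Iterable[VariantEffect]) -> VariantEffect:
    """The single most severe effect under the fixed severity order."""
    rank = {c: i for i, c in enumerate(SEVERITY_ORDER)}
    return min(effects, key=lambda e: rank[e.consequence])
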