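"""Fixed and highly differentiated sites, joined to effects and windows.

"High" divergence means per-site theta-hat at or above a threshold (default
0.75). "Fixed" is stricter than theta-hat ~= 1 to machine precision: the two
populations must also be monomorphic for opposite alleles among their called
genotypes, which is the biological definition and guards against rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .effects import VariantEffect, is_putatively_functional
from .fst import FstSite, WindowStat
from .genotypes import SiteRecord

_FIXED_TOL = 1e-12


@dataclass(frozen=True)
class DivergentSite:
    chrom: str
    pos: int
    fst: float
    fixed: bool
    record: SiteRecord | None = None
    effects: tuple[VariantEffect, ...] = ()
    window: tuple[str, int, int] | None = None  # chrom, start, end
    in_outlier_window: bool = False
    neighbours_outlier_window: bool = False


def _biologically_fixed(record: SiteRecord) -> bool:
    """Both populations monomorphic, for opposite alleles, among called
    genotypes."""
    freqs = []
    for counts in record.counts.values():
        if counts.called == 0:
            return False
        if counts.het > 0:
            return False
        freqs.append(counts.alt_frequency)
    return sorted(freqs) == [0.0, 1.0]


def select_divergent_sites(
    fst_sites: Sequence[FstSite],
    records: Sequence[SiteRecord] | None = None,
    threshold: float = 0.75,
    effects_by_site: dict[tuple[str, int], Sequence[VariantEffect]] | None = None,
) -> list[DivergentSite]:
    """Sites with theta-hat >= threshold (inclusive), fixed sites marked.

    ``records``, when given, must parallel ``fst_sites`` and is used for the
    monomorphic-opposite-alleles fixation check; without records, fixation
    falls back to theta-hat == 1 within 1e-12.
    """
    if records is not None and len(records) != len(fst_sites):
        raise ValueError("records must parallel fst_sites")
    out: list[DivergentSite] = []
    for i, s in enumerate(fst_sites):
        if math.isnan(s.fst) or s.fst < threshold:
            continue
        rec = records[i] if records is not None else None
        near_one = abs(s.fst - 1.0) <= _FIXED_TOL
        fixed = near_one and (_biologically_fixed(rec) if rec is not None else True)
        effects = ()
        if effects_by_site is not None:
            effects = tuple(effects_by_site.get((s.chrom, s.pos), ()))
        out.append(
            DivergentSite(
                chrom=s.chrom, pos=s.pos, fst=s.fst, fixed=fixed,
                record=rec, effects=effects,
            )
        )
    return out


def attach_effects(
    divergent: Sequence[DivergentSite],
    effects: Iterable[VariantEffect],
) -> list[DivergentSite]:
    """Join classifier output onto divergent sites by (chrom, pos)."""
    by_site: dict[tuple[str, int], list[VariantEffect]] = {}
    for e in effects:
        by_site.setdefault((e.chrom, e.pos), []).append(e)
    return [
        replace(d, effects=tuple(by_site.get((d.chrom, d.pos), ())))
        for d in divergent
    ]


def genes_with_functional_divergence(
    divergent: Sequence[DivergentSite],
) -> dict[str, list[DivergentSite]]:
    """Map gene id -> its putatively functional divergent sites.

    Genes whose only divergent sites are synonymous (or intergenic/deep
    intronic) do not appear. A site shared by overlapping transcripts of
    two genes counts for both.
    """
    out: dict[str, list[DivergentSite]] = {}
    for d in divergent:
        genes = {
            e.gene_id
            for e in d.effects
            if e.gene_id is not None and is_putatively_functional(e)
        }
        for g in sorted(genes):
            out.setdefault(g, []).append(d)
    return out


def annotate_window_context(
    divergent: Sequence[DivergentSite],
    windows: Sequence[WindowStat],
) -> list[DivergentSite]:
    """Label each site with its containing scan window and whether that
    window, or an immediately neighbouring one, is an outlier."""
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for ws in by_chrom.values():
        ws.sort(key=lambda w: w.start)

    out: list[DivergentSite] = []
    for d in divergent:
        ws = by_chrom.get(d.chrom, [])
        idx = next(
            (i for i, w in enumerate(ws) if w.start <= d.pos <= w.end), None
        )
        if idx is None:
            out.append(d)
            continue
        w = ws[idx]
        neighbours = [ws[j] for j in (idx - 1, idx + 1) if 0 <= j < len(ws)]
        out.append(
            replace(
                d,
                window=(w.chrom, w.start, w.end),
                in_outlier_window=w.outlier,
                neighbours_outlier_window=any(n.outlier for n in neighbours),
            )
        )
    return out
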