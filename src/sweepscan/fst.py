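"""Weir & Cockerham per-site Fst, windowed means, Z-scores and bins.

The per-site estimator is the two-population diploid theta-hat of Weir &
Cockerham (1984), built from three variance components: ``a`` (among
populations), ``b`` (among individuals within populations) and ``c``
(between gametes within individuals, i.e. the heterozygote term). Sample
sizes enter through the n-bar / n_c corrections, so the estimator is
unbiased for unequal samples and can go negative; theta-hat = a/(a+b+c)
is undefined (NaN) when the denominator is zero — in particular at sites
monomorphic across both populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .genotypes import GenotypeCounts, SiteRecord

__all__ = [
    "FstSite",
    "WindowStat",
    "wc_fst_site",
    "compute_site_fst",
    "window_mean_fst",
    "z_transform",
    "flag_outlier_windows",
    "flanking_mean_fst",
    "assign_fst_bin",
    "FST_BIN_LABELS",
]


@dataclass(frozen=True)
class FstSite:
    """Per-site Fst with its W&C variance components."""

    chrom: str
    pos: int
    a: float
    b: float
    c: float
    fst: float  # NaN when a + b + c == 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.fst)


@dataclass
class WindowStat:
    """One genomic window (1-based inclusive bounds) of the scan."""

    chrom: str
    start: int
    end: int
    n_sites: int
    mean_fst: float | None  # unweighted mean of per-site theta-hat
    weighted_fst: float | None  # ratio of sums: sum(a) / sum(a+b+c)
    z_fst: float | None = None
    outlier: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def wc_fst_site(
    counts_pop1: GenotypeCounts | tuple[int, int, int],
    counts_pop2: GenotypeCounts | tuple[int, int, int],
) -> tuple[float, float, float, float]:
    """Weir & Cockerham (1984) variance components for one biallelic site.

    Parameters are genotype-class counts (hom-ref, het, hom-alt) per
    population; missing genotypes are simply absent from the counts.
    Returns ``(a, b, c, theta_hat)`` with ``theta_hat = a / (a + b + c)``,
    NaN when the denominator is zero or either population has no called
    genotypes.
    """

    def _unpack(c) -> tuple[int, int, int]:
        if isinstance(c, GenotypeCounts):
            return c.hom_ref, c.het, c.hom_alt
        return tuple(c)  # type: ignore[return-value]

    r1, h1, a1 = _unpack(counts_pop1)
    r2, h2, a2 = _unpack(counts_pop2)
    n1, n2 = r1 + h1 + a1, r2 + h2 + a2
    if n1 == 0 or n2 == 0:
        return (math.nan, math.nan, math.nan, math.nan)

    p1 = (2 * a1 + h1) / (2 * n1)
    p2 = (2 * a2 + h2) / (2 * n2)
    hf1, hf2 = h1 / n1, h2 / n2

    r = 2  # number of populations
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * hf1 + n2 * hf2) / (r * nbar)

    if nbar <= 1:
        # single diploid per population: within-population variance
        # components are inestimable
        return (math.nan, math.nan, math.nan, math.nan)

    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1))
        * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0

    denom = a + b + c
    theta = a / denom if denom != 0.0 else math.nan
    return (a, b, c, theta)


def compute_site_fst(
    sites: Iterable[SiteRecord],
    populations: tuple[str, str] | None = None,
) -> list[FstSite]:
    """Per-site theta-hat for a stream of SiteRecords."""
    out: list[FstSite] = []
    for s in sites:
        if populations is None:
            populations = tuple(sorted(s.counts))  # type: ignore[assignment]
        a, b, c, theta = wc_fst_site(s.counts[populations[0]], s.counts[populations[1]])
        out.append(FstSite(chrom=s.chrom, pos=s.pos, a=a, b=b, c=c, fst=theta))
    return out


def window_mean_fst(
    sites: Sequence[FstSite],
    window_size: int = 500_000,
    min_sites: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Tile each chromosome into ``window_size`` windows and average Fst.

    Windows are 1-based inclusive: window k spans [(k-1)*W + 1, k*W].
    ``mean_fst`` is the unweighted arithmetic mean of defined per-site
    theta-hat; ``weighted_fst`` is the ratio-of-sums estimator
    sum(a)/sum(a+b+c) over the same sites. Windows with fewer than
    ``min_sites`` defined sites carry no mean. When ``chrom_lengths`` is
    given, empty trailing windows are emitted too; otherwise tiling stops
    at the last window containing a site.
    """
    by_chrom: dict[str, list[FstSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    windows: list[WindowStat] = []
    chroms = list(chrom_lengths) if chrom_lengths else sorted(by_chrom)
    for chrom in chroms:
        chrom_sites = sorted(by_chrom.get(chrom, []), key=lambda s: s.pos)
        if chrom_lengths:
            n_windows = max(1, math.ceil(chrom_lengths[chrom] / window_size))
        elif chrom_sites:
            n_windows = (chrom_sites[-1].pos - 1) // window_size + 1
        else:
            continue
        buckets: list[list[FstSite]] = [[] for _ in range(n_windows)]
        for s in chrom_sites:
            k = (s.pos - 1) // window_size
            if k < n_windows:
                buckets[k].append(s)
        for k, bucket in enumerate(buckets):
            defined = [s for s in bucket if s.defined]
            if len(defined) >= min_sites:
                mean = float(np.mean([s.fst for s in defined]))
                denom = sum(s.a + s.b + s.c for s in defined)
                weighted = sum(s.a for s in defined) / denom if denom else None
            else:
                mean = None
                weighted = None
            windows.append(
                WindowStat(
                    chrom=chrom,
                    start=k * window_size + 1,
                    end=(k + 1) * window_size,
                    n_sites=len(defined),
                    mean_fst=mean,
                    weighted_fst=weighted,
                )
            )
    return windows


def z_transform(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, sample (n-1) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to Z-transform")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("constant input has no dispersion; Z undefined")
    return (x - x.mean()) / sd


def flag_outlier_windows(
    windows: Sequence[WindowStat], threshold: float = 5.0
) -> list[WindowStat]:
    """Z-transform window means genome-wide and flag the upper tail.

    A window is an outlier when its Z(Fst) is at least ``threshold``
    (inclusive); the scan is one-sided — only elevated divergence is of
    interest. Windows without a defined mean get z_fst None and are never
    outliers. Input windows are not mutated.
    """
    defined = [w for w in windows if w.mean_fst is not None]
    z = z_transform([w.mean_fst for w in defined])  # type: ignore[list-item]
    zmap = {id(w): float(v) for w, v in zip(defined, z)}
    out: list[WindowStat] = []
    for w in windows:
        zv = zmap.get(id(w))
        out.append(replace(w, z_fst=zv, outlier=zv is not None and zv >= threshold))
    return out


def flanking_mean_fst(
    sites: Sequence[FstSite],
    focal: tuple[str, int],
    span: int = 50_000,
) -> float:
    """Mean per-site theta-hat in a window of ``span`` bp centred on a site.

    The window is [pos - span/2, pos + span/2], inclusive, restricted to the
    focal chromosome; the focal site itself contributes. Windows running off
    a chromosome end are simply truncated. NaN when no defined site falls in
    the window.
    """
    chrom, pos = focal
    lo, hi = pos - span // 2, pos + span // 2
    vals = [
        s.fst for s in sites if s.chrom == chrom and lo <= s.pos <= hi and s.defined
    ]
    return float(np.mean(vals)) if vals else math.nan


FST_BIN_LABELS = ("0.85-0.9", "0.9-0.95", "0.95-1", "1")

_DEFAULT_EDGES = (0.85, 0.90, 0.95)


def assign_fst_bin(
    fst: float, edges: Sequence[float] = _DEFAULT_EDGES
) -> str | None:
    """Assign an Fst value to its half-open bin.

    Bins are left-inclusive: [0.85, 0.90), [0.90, 0.95), [0.95, 1.0), and
    exact fixation (fst == 1, to 1e-12) gets its own label "1". Values below
    the lowest edge return None.
    """
    if math.isnan(fst) or fst < edges[0]:
        return None
    if fst >= 1.0 - 1e-12:
        return "1"
    all_edges = list(edges) + [1.0]
    for i in range(len(all_edges) - 1):
        if all_edges[i] <= fst < all_edges[i + 1]:
            lo, hi = all_edges[i], all_edges[i + 1]
            return f"{lo:g}-{hi:g}"
    return None
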