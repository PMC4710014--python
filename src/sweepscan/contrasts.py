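"""Functional-category spectra across Fst bins, and flanking-Fst contrasts.

Two questions about the set of highly differentiated sites:

* how does the functional make-up of sites change as differentiation
  approaches fixation? (per-bin category percentages);
* is the differentiation of the *region around* a functional site — mean
  Fst in a flanking window — different between consequence categories?
  (one-way ANOVA followed by Tukey's range test, synonymous sites serving
  as the neutral reference).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import effects as fx
from .divergence import DivergentSite
from .fst import FstSite, assign_fst_bin, flanking_mean_fst

#: the six consequence categories used for the flanking contrast
CONTRAST_CATEGORIES = (
    fx.FIVE_PRIME_UTR,
    fx.THREE_PRIME_UTR,
    fx.MISSENSE,
    fx.SPLICE_REGION,
    fx.STOP_GAINED,
    fx.SYNONYMOUS,
)


@dataclass(frozen=True)
class BinSpectrum:
    """Per-Fst-bin counts of sites by consequence category."""

    counts: dict[str, dict[str, int]]  # bin -> category -> count
    totals: dict[str, int]  # bin -> total sites in bin

    def percentages(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for b, cats in self.counts.items():
            total = self.totals[b]
            out[b] = {
                c: (100.0 * n / total if total else 0.0) for c, n in cats.items()
            }
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        pct = self.percentages()
        for b in self.totals:
            for c, n in sorted(self.counts[b].items()):
                rows.append(
                    {"bin": b, "category": c, "count": n, "percent": pct[b][c]}
                )
        return pd.DataFrame(rows)


def bin_spectrum(
    divergent: Sequence[DivergentSite],
    mode: str = "multi",
    bin_labels: Sequence[str] | None = None,
) -> BinSpectrum:
    """Category counts/percentages per Fst bin.

    mode="multi": a site contributes once to every distinct consequence it
    carries (so per-bin percentages can exceed 100 in total).
    mode="exclusive": only the most severe consequence counts.
    A site's bin total counts it once regardless of mode. Sites below the
    lowest bin edge are ignored.
    """
    if mode not in ("multi", "exclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    from .fst import FST_BIN_LABELS

    labels = list(bin_labels) if bin_labels is not None else list(FST_BIN_LABELS)
    counts: dict[str, dict[str, int]] = {b: {} for b in labels}
    totals: dict[str, int] = {b: 0 for b in labels}
    for d in divergent:
        b = assign_fst_bin(d.fst)
        if b is None or b not in counts:
            continue
        totals[b] += 1
        if not d.effects:
            continue
        if mode == "exclusive":
            cats = {fx.most_severe(d.effects).consequence}
        else:
            cats = {e.consequence for e in d.effects}
        for c in sorted(cats):
            counts[b][c] = counts[b].get(c, 0) + 1
    return BinSpectrum(counts=counts, totals=totals)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classic equal-variance one-way ANOVA.

    F = MS_between / MS_within with df = (k - 1, N - k); p is the upper
    tail of the F distribution.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least two values")
    grand = np.concatenate(list(arrays.values()))
    k, N = len(arrays), grand.size
    gm = grand.mean()
    ss_between = sum(a.size * (a.mean() - gm) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    if ss_within == 0 and ss_between == 0:
        raise ValueError("all values identical; F undefined")
    df_b, df_w = k - 1, N - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0:
        raise ValueError("zero within-group variance; F undefined")
    f = ms_b / ms_w
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f=float(f), df_between=df_b, df_within=df_w, p=p)


@dataclass(frozen=True)
class TukeyPair:
    group1: str
    group2: str
    diff: float  # mean(group1) - mean(group2)
    q: float  # studentized-range statistic
    p_adjusted: float


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> list[TukeyPair]:
    """Tukey(-Kramer) all-pairs comparison after a one-way ANOVA.

    For each pair, q = |diff| / sqrt((MS_within / 2) * (1/n1 + 1/n2)) and
    the family-wise adjusted p is the upper tail of the studentized range
    distribution with parameters (k, N - k). Results are order-invariant
    in the groups supplied (pairs sorted by name).
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in sorted(groups.items())}
    anova = one_way_anova(arrays)
    k = len(arrays)
    ms_w = (
        sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / anova.df_within
    )
    out: list[TukeyPair] = []
    for g1, g2 in itertools.combinations(arrays, 2):
        a1, a2 = arrays[g1], arrays[g2]
        diff = float(a1.mean() - a2.mean())
        se = math.sqrt((ms_w / 2.0) * (1.0 / a1.size + 1.0 / a2.size))
        q = abs(diff) / se if se > 0 else math.inf
        p = float(stats.studentized_range.sf(q, k, anova.df_within))
        out.append(TukeyPair(group1=g1, group2=g2, diff=diff, q=q, p_adjusted=p))
    return out


@dataclass(frozen=True)
class CategoryContrast:
    groups: dict[str, list[float]]
    anova: AnovaResult
    tukey: list[TukeyPair]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pair": f"{t.group1} vs {t.group2}",
                    "diff": t.diff,
                    "q": t.q,
                    "p_adjusted": t.p_adjusted,
                }
                for t in self.tukey
            ]
        )


def category_flanking_contrast(
    divergent: Sequence[DivergentSite],
    fst_sites: Sequence[FstSite],
    span: int = 50_000,
    categories: Sequence[str] = CONTRAST_CATEGORIES,
) -> CategoryContrast:
    """Flanking mean Fst per consequence category, ANOVA + Tukey.

    For every divergent site carrying a category of interest, the mean
    per-site Fst in a window of ``span`` bp centred on the site is computed;
    a site with several relevant consequences contributes its flanking value
    to each. Categories with fewer than two sites are dropped from the
    contrast.
    """
    groups: dict[str, list[float]] = {c: [] for c in categories}
    for d in divergent:
        cats = {e.consequence for e in d.effects} & set(categories)
        if not cats:
            continue
        val = flanking_mean_fst(fst_sites, (d.chrom, d.pos), span=span)
        if math.isnan(val):
            continue
        for c in sorted(cats):
            groups[c].append(val)
    usable = {c: v for c, v in groups.items() if len(v) >= 2}
    anova = one_way_anova(usable)
    tukey = tukey_hsd(usable)
    return CategoryContrast(groups=groups, anova=anova, tukey=tukey)
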