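"""Analytic layer: variant k-mer spans, coverage profiles, the genome-size
versus k-mer-diversity regression, and frequency-spectrum summaries.

For a variant with non-repetitive flanks the number of novel k-mers it
creates follows simple closed forms: a substitution is covered by exactly
k windows; a junction created by a translocation, inversion breakpoint or
deletion is covered by k-1 windows; an insertion of length i by k+i-1.
The per-base coverage of those novel windows peaks at k for one base
(substitution), two bases (junction plateau) or i bases (insertion).
Repetitive contexts can collide away some novel windows, which is why the
empirical enumeration, not the formula, is the ground truth there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .kmer_core import KmerTable, iter_canonical_kmers

__all__ = [
    "CoverageProfile",
    "RegressionFit",
    "variant_kmer_span",
    "novel_kmer_windows",
    "variant_coverage_profile",
    "plateau_width",
    "diversity_regression",
    "frequency_spectrum_summary",
]

_JUNCTION_TYPES = {"junction", "translocation", "inversion", "deletion"}


def variant_kmer_span(vtype: str, k: int, i: Optional[int] = None) -> int:
    """Number of k-mers associated with a variant (non-repetitive flanks).

    Substitution: k.  Junction-creating events (translocation, inversion
    breakpoint, or a deletion as seen from the genome carrying it): k-1.
    Insertion of length i (the view from the genome carrying the extra
    bases): k+i-1.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError("k must be an odd integer >= 3")
    if vtype == "snp":
        return k
    if vtype in _JUNCTION_TYPES:
        return k - 1
    if vtype == "insertion":
        if i is None or i < 1:
            raise ValueError("insertion span requires the insertion length i >= 1")
        return k + i - 1
    raise ValueError(f"unknown variant type {vtype!r}")


@dataclass
class CoverageProfile:
    """Per-base counts of variant-specific k-mer windows over a context."""

    counts: np.ndarray

    def max(self) -> int:
        return int(self.counts.max(initial=0))

    def total(self) -> int:
        return int(self.counts.sum())


def novel_kmer_windows(ref_context: str, alt_context: str, k: int) -> list[int]:
    """Start offsets (on alt_context) of k-windows absent from ref_context.

    Both strands of the reference are honoured by comparing canonical
    forms, so the enumeration is strand-insensitive like the tables.
    """
    ref_set = set(iter_canonical_kmers(ref_context, k))
    out = []
    for idx, kmer in enumerate(iter_canonical_kmers(alt_context, k)):
        if kmer not in ref_set:
            out.append(idx)
    return out


def _flank_agreement(ref: str, alt: str) -> tuple[int, int]:
    pre = 0
    for a, b in zip(ref, alt):
        if a != b:
            break
        pre += 1
    suf = 0
    for a, b in zip(reversed(ref), reversed(alt)):
        if a != b:
            break
        suf += 1
    return pre, suf


def variant_coverage_profile(
    ref_context: str, alt_context: str, k: int
) -> CoverageProfile:
    """Per-base coverage of the alt-only k-mers across alt_context.

    Requires the contexts to share flanks of at least k-1 bases on both
    sides of the variant, otherwise edge effects would truncate the
    profile.  Total coverage equals span*k for interior variants.
    """
    pre, suf = _flank_agreement(ref_context, alt_context)
    if min(pre, suf) < k - 1:
        raise ValueError(
            f"contexts must share flanks of >= k-1={k - 1} bases "
            f"(got {pre} and {suf})"
        )
    counts = np.zeros(len(alt_context), dtype=int)
    for start in novel_kmer_windows(ref_context, alt_context, k):
        counts[start : start + k] += 1
    return CoverageProfile(counts=counts)


def plateau_width(profile: CoverageProfile) -> int:
    """Length of the longest run of positions attaining the profile maximum."""
    counts = profile.counts
    if counts.size == 0:
        raise ValueError("empty coverage profile")
    peak = counts.max()
    if peak == 0:
        return 0
    best = run = 0
    for c in counts:
        run = run + 1 if c == peak else 0
        best = max(best, run)
    return best


@dataclass
class RegressionFit:
    """OLS fit of distinct-k-mer diversity against genome size."""

    slope: float
    intercept: float
    n_points: int
    residuals: list[float]  # observed - predicted, for every input point


def diversity_regression(
    points: Sequence[tuple[float, float]],
    ir_flags: Sequence[bool],
) -> RegressionFit:
    """Fit diversity = a + b * genome_size over the IR-flagged points only.

    Genomes without an inverted repeat sit on the 1:1 line and are excluded
    from the fit; residuals are reported for *all* points so outliers (IR
    or not) can be flagged by the caller.  Invariant to point order and to
    consistent rescaling of both axes.
    """
    if len(points) != len(ir_flags):
        raise ValueError("points and ir_flags must have equal length")
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    mask = np.array(ir_flags, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least two IR-flagged points to fit a line")
    fit = stats.linregress(xs[mask], ys[mask])
    residuals = (ys - (fit.intercept + fit.slope * xs)).tolist()
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=int(mask.sum()),
        residuals=residuals,
    )


def frequency_spectrum_summary(table: KmerTable) -> tuple[float, int, float]:
    """(mean count, max count, max/mean ratio) of a frequency table.

    The ratio separates genomes whose expansion came from proliferating
    very short repeats (ratio >> 1) from those that duplicated long
    segments (ratio near 1).
    """
    if not table.entries:
        raise ValueError("empty k-mer table has no frequency spectrum")
    counts = np.fromiter(table.entries.values(), dtype=float)
    mean = float(counts.mean())
    peak = int(counts.max())
    return mean, peak, peak / mean
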