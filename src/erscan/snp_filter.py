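"""SNP calling and coverage-based site filtering on sync data.

Implements the study's filtering rules at count level: a site is a SNP if at
least one founder replicate individually shows a second allele; sites in the
upper and lower tails of the coverage distribution are removed (upper tail
judged on the single deepest library, lower tail on total coverage); masked
intervals (BED) drop sites; and libraries can be binomially thinned to a
common target mean coverage, the count-space analogue of read downsampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from erscan.sync_io import AlleleCounts, BiallelicSite, polarize


@dataclass
class CoverageThresholds:
    """Removal bounds for the coverage filter.

    Sites whose focal-library depth is ``>= upper`` or whose total depth is
    ``<= lower`` are removed, mirroring the published tail rule.
    """

    upper: int
    lower: int
    upper_basis: str
    lower_basis: str = "total coverage across all samples"
    degenerate: bool = False

    def __post_init__(self) -> None:
        # upper and lower live on different scales (single deepest library
        # vs. total over all samples), so they are not mutually ordered;
        # degeneracy means the pair would remove every site.
        if self.upper < 0 or self.lower < 0:
            raise ValueError(f"thresholds must be >= 0, got {self.upper}, {self.lower}")


@dataclass
class FilterReport:
    """Per-rule tally of removed sites; tallies sum to input - output."""

    n_in: int = 0
    n_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def tally(self, rule: str, n: int = 1) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + n

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def call_snps(
    sites: Iterable[AlleleCounts],
    founder_samples: Sequence[str],
    min_minor_count: int = 1,
    report: FilterReport | None = None,
) -> list[BiallelicSite]:
    """Select polymorphic sites and polarize them on the founder samples.

    A site qualifies when at least one founder sample individually carries
    ``min_minor_count`` or more reads of a second allele (its second most
    common nucleotide).  Base-quality screening is assumed applied upstream.
    """
    if not founder_samples:
        raise ValueError("founder_samples must be non-empty")
    founders = list(founder_samples)
    out: list[BiallelicSite] = []
    for site in sites:
        if report is not None:
            report.n_in += 1
        poly = False
        for label in founders:
            idx = site.sample_labels.index(label)
            acgt = sorted(site.samples[idx][:4], reverse=True)
            if acgt[1] >= min_minor_count:
                poly = True
                break
        if not poly:
            if report is not None:
                report.tally("monomorphic_in_founders")
            continue
        out.append(polarize(site, founders))
        if report is not None:
            report.n_out += 1
    return out


def _nearest_rank(sorted_values: np.ndarray, q: float) -> int:
    """Nearest-rank quantile: value at rank ceil(q*n) of the ascending sort."""
    n = len(sorted_values)
    rank = min(max(math.ceil(q * n), 1), n)
    return int(sorted_values[rank - 1])


def coverage_thresholds(
    sites: Sequence[AlleleCounts],
    quantile: float = 0.01,
    upper_library: str | None = None,
) -> CoverageThresholds:
    """Derive tail-removal bounds from the empirical coverage distribution.

    ``upper`` is the (1-q) nearest-rank quantile of per-site depth in the
    single library with the highest mean depth (or ``upper_library`` if
    given); ``lower`` is the q quantile of per-site total depth over all
    samples.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("coverage_thresholds requires at least one site")
    labels = sites[0].sample_labels
    per_lib = np.array([[site.coverage(i) for i in range(len(labels))] for site in sites])
    totals = per_lib.sum(axis=1)
    if upper_library is None:
        upper_library = labels[int(per_lib.mean(axis=0).argmax())]
    lib_idx = labels.index(upper_library)
    upper = _nearest_rank(np.sort(per_lib[:, lib_idx]), 1.0 - quantile)
    lower = _nearest_rank(np.sort(totals), quantile)
    degenerate = bool(np.all((per_lib[:, lib_idx] >= upper) | (totals <= lower)))
    if degenerate:
        warnings.warn(
            f"degenerate coverage thresholds (upper {upper}, lower {lower}): "
            "every site falls in a removed tail",
            stacklevel=2,
        )
    return CoverageThresholds(
        upper=upper,
        lower=lower,
        upper_basis=upper_library,
        degenerate=degenerate,
    )


def apply_coverage_filter(
    sites: Iterable[BiallelicSite],
    thresholds: CoverageThresholds,
    report: FilterReport | None = None,
) -> list[BiallelicSite]:
    """Remove sites in the coverage tails defined by ``thresholds``."""
    out = []
    for site in sites:
        if report is not None:
            report.n_in += 1
        focal = site.coverage(thresholds.upper_basis)
        if focal >= thresholds.upper:
            if report is not None:
                report.tally("coverage_upper_tail")
            continue
        if site.total_coverage() <= thresholds.lower:
            if report is not None:
                report.tally("coverage_lower_tail")
            continue
        out.append(site)
        if report is not None:
            report.n_out += 1
    return out


def mask_intervals(
    sites: Iterable[BiallelicSite],
    mask: Mapping[str, IntervalTree] | Sequence[tuple[str, int, int]],
    report: FilterReport | None = None,
) -> list[BiallelicSite]:
    """Drop sites inside masked intervals.

    ``mask`` is BED-style 0-based half-open, either pre-built interval trees
    per chromosome or raw ``(chrom, start, end)`` records; a 1-based site
    position ``pos`` is masked when ``start <= pos - 1 < end``.
    """
    if not isinstance(mask, Mapping):
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in mask:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        mask = trees
    out = []
    for site in sites:
        if report is not None:
            report.n_in += 1
        tree = mask.get(site.chrom)
        if tree is not None and tree.overlaps_point(site.pos - 1):
            if report is not None:
                report.tally("masked_interval")
            continue
        out.append(site)
        if report is not None:
            report.n_out += 1
    return out


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a minimal BED3 file (0-based half-open intervals)."""
    records = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            records.append((chrom, int(start), int(end)))
    return records


def downsample_counts(
    sites: Sequence[BiallelicSite],
    target_mean_coverage: float,
    seed: int | np.random.Generator,
) -> list[BiallelicSite]:
    """Binomially thin each library's counts to a target mean coverage.

    Each library is thinned with its own probability target/mean, emulating
    read subsampling to equalize library means; the expected allele
    frequency at every site is unchanged.  Libraries already at or below the
    target are left untouched; a target above every library mean is an
    error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = list(sites)
    if not sites:
        return []
    labels = sites[0].sample_labels
    cov = np.array([[s.coverage(i) for i in range(len(labels))] for s in sites], float)
    means = cov.mean(axis=0)
    if target_mean_coverage > means.max():
        raise ValueError(
            f"target mean coverage {target_mean_coverage} exceeds every library "
            f"mean (max {means.max():.1f})"
        )
    ratios = np.minimum(target_mean_coverage / means, 1.0)
    out = []
    for site in sites:
        new_counts = []
        for j, (maj, mino) in enumerate(site.counts):
            p = ratios[j]
            if p >= 1.0:
                new_counts.append((maj, mino))
            else:
                new_counts.append(
                    (int(rng.binomial(maj, p)), int(rng.binomial(mino, p)))
                )
        out.append(
            BiallelicSite(
                chrom=site.chrom,
                pos=site.pos,
                major=site.major,
                minor=site.minor,
                counts=tuple(new_counts),
                sample_labels=site.sample_labels,
                dropped=site.dropped,
            )
        )
    return out
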