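"""Reading, writing and polarizing PoPoolation2-style sync files.

The sync format is the pipeline's only on-disk representation of observed
allele counts: one line per site, ``chrom<TAB>pos<TAB>ref`` followed by one
``A:T:C:G:N:del`` count sextuple per population sample.  Coverage is defined
as A+T+C+G; N and deletion counts never enter allele-frequency arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

#: column order of the count sextuple in a sync file
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")

#: deterministic tie-break order for major/minor polarization
TIE_ORDER = ("A", "C", "G", "T")

#: index of each nucleotide inside the sync sextuple
_NUC_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3}


class SyncParseError(ValueError):
    """A sync line could not be parsed (wrong fields, bad integer, pos < 1)."""


class SyncFormatError(SyncParseError):
    """The file violates the format contract (inconsistent column count)."""


class PolarizationError(ValueError):
    """Major/minor axis undefined (zero founder coverage)."""


@dataclass(frozen=True)
class AlleleCounts:
    """Per-site, per-sample nucleotide counts parsed from one sync line.

    ``samples`` holds one ``(A, T, C, G, N, del)`` sextuple per population
    sample, in file column order; ``sample_labels`` identifies each column
    (time point, replicate).
    """

    chrom: str
    pos: int
    ref: str
    samples: tuple[tuple[int, int, int, int, int, int], ...]
    sample_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if len(self.samples) != len(self.sample_labels):
            raise ValueError(
                f"{len(self.samples)} count columns but "
                f"{len(self.sample_labels)} sample labels"
            )
        for sextuple in self.samples:
            if len(sextuple) != 6 or any(c < 0 for c in sextuple):
                raise ValueError(f"invalid count sextuple {sextuple!r}")

    def coverage(self, sample: int | str) -> int:
        """Read depth of one sample: A+T+C+G (N and del excluded)."""
        if isinstance(sample, str):
            sample = self.sample_labels.index(sample)
        return sum(self.samples[sample][:4])

    def total_coverage(self) -> int:
        """Summed A+T+C+G depth over all samples."""
        return sum(sum(s[:4]) for s in self.samples)


@dataclass(frozen=True)
class BiallelicSite:
    """A polarized biallelic SNP: (major, minor) read counts per sample.

    The major/minor axis is fixed once per site from the pooled founder
    samples and reused for all samples; reads of third/fourth alleles are
    dropped and their total recorded in ``dropped``.
    """

    chrom: str
    pos: int
    major: str
    minor: str
    counts: tuple[tuple[int, int], ...]
    sample_labels: tuple[str, ...]
    dropped: int = 0

    def coverage(self, sample: int | str) -> int:
        if isinstance(sample, str):
            sample = self.sample_labels.index(sample)
        maj, mino = self.counts[sample]
        return maj + mino

    def total_coverage(self) -> int:
        return sum(a + b for a, b in self.counts)

    def frequency(self, sample: int | str) -> float:
        """Major-allele read frequency in one sample (nan if coverage 0)."""
        if isinstance(sample, str):
            sample = self.sample_labels.index(sample)
        maj, mino = self.counts[sample]
        cov = maj + mino
        return maj / cov if cov else float("nan")


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"s{i + 1}" for i in range(n))


def read_sync(
    path: str | Path, sample_labels: Sequence[str] | None = None
) -> Iterator[AlleleCounts]:
    """Stream :class:`AlleleCounts` from a sync file, one per line.

    Raises :class:`SyncParseError` naming the offending line on malformed
    input, and :class:`SyncFormatError` if the column count changes
    mid-file.
    """
    expected_cols: int | None = None
    labels = tuple(sample_labels) if sample_labels is not None else None
    with open(path, "rt") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(
                    f"{path}: line {lineno}: expected at least 4 tab-separated "
                    f"fields, got {len(fields)}"
                )
            if expected_cols is None:
                expected_cols = len(fields)
                if labels is None:
                    labels = _default_labels(expected_cols - 3)
                elif len(labels) != expected_cols - 3:
                    raise SyncFormatError(
                        f"{path}: {len(labels)} sample labels given but file "
                        f"has {expected_cols - 3} count columns"
                    )
            elif len(fields) != expected_cols:
                raise SyncFormatError(
                    f"{path}: line {lineno}: {len(fields)} columns, "
                    f"previous lines had {expected_cols}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(
                    f"{path}: line {lineno}: non-integer position {pos_s!r}"
                ) from None
            if pos < 1:
                raise SyncParseError(f"{path}: line {lineno}: position {pos} < 1")
            samples = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise SyncParseError(
                        f"{path}: line {lineno}: count column {col!r} does not "
                        "have 6 colon-separated fields"
                    )
                try:
                    counts = tuple(int(p) for p in parts)
                except ValueError:
                    raise SyncParseError(
                        f"{path}: line {lineno}: non-integer count in {col!r}"
                    ) from None
                if any(c < 0 for c in counts):
                    raise SyncParseError(
                        f"{path}: line {lineno}: negative count in {col!r}"
                    )
                samples.append(counts)
            yield AlleleCounts(chrom, pos, ref, tuple(samples), labels)


def write_sync(sites: Iterable[AlleleCounts], path: str | Path) -> None:
    """Write sites as canonical sync text (inverse of :func:`read_sync`)."""
    with open(path, "wt") as handle:
        for site in sites:
            cols = "\t".join(":".join(str(c) for c in s) for s in site.samples)
            handle.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{cols}\n")


def format_sync_line(site: AlleleCounts) -> str:
    cols = "\t".join(":".join(str(c) for c in s) for s in site.samples)
    return f"{site.chrom}\t{site.pos}\t{site.ref}\t{cols}"


def polarize(site: AlleleCounts, founder_samples: Iterable[str]) -> BiallelicSite:
    """Fix the major/minor allele axis of a site from its founder samples.

    The major allele is the nucleotide with the highest count summed over
    the founder samples, the minor allele the second highest; ties are
    broken by the fixed order A < C < G < T.  Counts of the remaining
    alleles are dropped from every sample and tallied in ``dropped``.
    """
    founders = set(founder_samples)
    missing = founders - set(site.sample_labels)
    if missing:
        raise KeyError(f"founder labels not in site: {sorted(missing)}")
    pooled = {nuc: 0 for nuc in TIE_ORDER}
    for label, counts in zip(site.sample_labels, site.samples):
        if label in founders:
            for nuc, idx in _NUC_INDEX.items():
                pooled[nuc] += counts[idx]
    if sum(pooled.values()) == 0:
        raise PolarizationError(
            f"{site.chrom}:{site.pos}: zero founder coverage, polarization undefined"
        )
    # sort by (count desc, A<C<G<T); TIE_ORDER iteration makes the sort stable
    ranked = sorted(TIE_ORDER, key=lambda nuc: -pooled[nuc])
    major, minor = ranked[0], ranked[1]
    i_maj, i_min = _NUC_INDEX[major], _NUC_INDEX[minor]
    pair_counts = []
    dropped = 0
    for counts in site.samples:
        maj, mino = counts[i_maj], counts[i_min]
        pair_counts.append((maj, mino))
        dropped += sum(counts[:4]) - maj - mino
    return BiallelicSite(
        chrom=site.chrom,
        pos=site.pos,
        major=major,
        minor=minor,
        counts=tuple(pair_counts),
        sample_labels=site.sample_labels,
        dropped=dropped,
    )
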