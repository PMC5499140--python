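"""Synthetic evolve-and-resequence data with known ground truth.

Stands in for the study's deposited sequencing data: emits founder and
evolved sync files whose background SNPs drift neutrally and independently,
with optional planted selected loci surrounded by "linked" blocks, plus
truth tables (BED of planted blocks, TSV of per-locus selection and final
true frequencies) for end-to-end testing.

Linkage is emulated, not simulated: a block neighbor's trajectory is its own
independent neutral trajectory plus rho times the focal locus's deviation
from its starting frequency, clipped to [0, 1].  This preserves each
neighbor's starting frequency, reduces to independence at rho = 0 and to
perfect hitchhiking of frequency changes at rho = 1, and is sufficient to
produce the peak-shaped signatures a scan must detect — it is not a model of
recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from erscan.sync_io import AlleleCounts, write_sync
from erscan.wf_sim import (
    CoverageModel,
    observe_poolseq,
    sample_founder_spectrum,
    simulate_trajectories,
)

_OTHER = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class PlantedLocus:
    """A selected locus with an optional linked block around it."""

    chrom: str
    pos: int
    s: float
    block_halfwidth: int = 0
    rho: float = 0.0
    p0: float | None = None  # starting frequency; None draws from the spectrum

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.s <= -1:
            raise ValueError("selection coefficient must exceed -1")


@dataclass
class SynthSpec:
    """Conditions the generator emulates (defaults mirror the experiment:
    3 replicates, 60 generations, census 1000 diploids, founder/evolved mean
    depths 259x/100x, rare-variant-skewed founder spectrum)."""

    chromosomes: dict[str, int]
    n_snps: dict[str, int]
    replicates: int = 3
    generations: int = 60
    ne: int = 285
    n_census: int = 1000
    founder_coverage_mean: float = 259.0
    evolved_coverage_mean: float = 100.0
    pool_size_founder: int = 2000
    pool_size_evolved: int = 2000
    spectrum_alpha: float = 0.2
    spectrum_beta: float = 0.2
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for locus in self.planted_loci:
            if locus.chrom not in self.chromosomes:
                raise ValueError(f"planted locus on unknown chromosome {locus.chrom}")
            if not 1 <= locus.pos <= self.chromosomes[locus.chrom]:
                raise ValueError(
                    f"planted locus {locus.chrom}:{locus.pos} outside chromosome bounds"
                )
        for chrom in self.n_snps:
            if chrom not in self.chromosomes:
                raise ValueError(f"n_snps given for unknown chromosome {chrom}")


@dataclass
class SynthResult:
    """In-memory products of one synthetic experiment."""

    founder_sites: list[AlleleCounts]
    evolved_sites: list[AlleleCounts]
    truth: pd.DataFrame  # chrom, pos, p0, s, linked_to, final true freq per replicate
    blocks: list[tuple[str, int, int]]  # truth BED records, 0-based half-open

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "founder_sync": outdir / "founder.sync",
            "evolved_sync": outdir / "evolved.sync",
            "truth_tsv": outdir / "truth_loci.tsv",
            "truth_bed": outdir / "truth_blocks.bed",
        }
        write_sync(self.founder_sites, paths["founder_sync"])
        write_sync(self.evolved_sites, paths["evolved_sync"])
        self.truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
        with open(paths["truth_bed"], "wt") as handle:
            for chrom, start, end in self.blocks:
                handle.write(f"{chrom}\t{start}\t{end}\n")
        return paths


def generate(spec: SynthSpec) -> SynthResult:
    """Generate a full synthetic experiment, deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    founder_cov = CoverageModel(mean=spec.founder_coverage_mean)
    evolved_cov = CoverageModel(mean=spec.evolved_coverage_mean)

    founder_sites: list[AlleleCounts] = []
    evolved_sites: list[AlleleCounts] = []
    truth_rows = []
    blocks: list[tuple[str, int, int]] = []
    f_labels = tuple(f"F{r + 1}" for r in range(spec.replicates))
    e_labels = tuple(f"E{r + 1}" for r in range(spec.replicates))

    for chrom, length in spec.chromosomes.items():
        n_bg = spec.n_snps.get(chrom, 0)
        planted = [l for l in spec.planted_loci if l.chrom == chrom]
        pos = _draw_positions(rng, length, n_bg, exclude={l.pos for l in planted})
        pos = np.sort(np.concatenate([pos, np.array([l.pos for l in planted], int)]))
        n = pos.size
        p0 = sample_founder_spectrum(
            n, rng, spec.spectrum_alpha, spec.spectrum_beta, spec.n_census
        )
        s = np.zeros(n)
        planted_idx = {}
        for locus in planted:
            i = int(np.searchsorted(pos, locus.pos))
            s[i] = locus.s
            if locus.p0 is not None:
                p0[i] = locus.p0
            planted_idx[locus.pos] = i
            start0 = max(locus.pos - locus.block_halfwidth - 1, 0)
            end0 = min(locus.pos + locus.block_halfwidth, length)
            blocks.append((chrom, start0, end0))

        traj = simulate_trajectories(
            p0, spec.ne, spec.generations, spec.replicates, rng, selection=s
        )
        # linked blocks: add rho * focal deviation to each neighbor, clipped
        linked_to = np.full(n, "", dtype=object)
        for locus in planted:
            if locus.block_halfwidth <= 0 or locus.rho == 0.0:
                continue
            i = planted_idx[locus.pos]
            focal_dev = traj[i] - traj[i, 0, :][None, :]  # (t+1, K)
            lo = int(np.searchsorted(pos, locus.pos - locus.block_halfwidth, "left"))
            hi = int(np.searchsorted(pos, locus.pos + locus.block_halfwidth, "right"))
            for j in range(lo, hi):
                if j == i or s[j] != 0.0:
                    continue
                traj[j] = np.clip(traj[j] + locus.rho * focal_dev, 0.0, 1.0)
                linked_to[j] = f"{locus.chrom}:{locus.pos}"

        a, r0 = observe_poolseq(traj[:, 0, :], spec.pool_size_founder, founder_cov, rng)
        c, rt = observe_poolseq(traj[:, -1, :], spec.pool_size_evolved, evolved_cov, rng)

        refs = np.array(["A", "C", "G", "T"])[rng.integers(0, 4, size=n)]
        for i in range(n):
            ref = str(refs[i])
            alt = _OTHER[ref]
            founder_sites.append(
                _site(chrom, int(pos[i]), ref, alt, a[i], r0[i] - a[i], f_labels)
            )
            evolved_sites.append(
                _site(chrom, int(pos[i]), ref, alt, c[i], rt[i] - c[i], e_labels)
            )
            row = {
                "chrom": chrom,
                "pos": int(pos[i]),
                "ref": ref,
                "alt": alt,
                "p0": p0[i],
                "s": s[i],
                "linked_to": linked_to[i],
            }
            for r in range(spec.replicates):
                row[f"true_final_freq_{r + 1}"] = traj[i, -1, r]
            truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    return SynthResult(
        founder_sites=founder_sites,
        evolved_sites=evolved_sites,
        truth=truth,
        blocks=blocks,
    )


def _draw_positions(rng, length: int, n: int, exclude: set[int]) -> np.ndarray:
    if n == 0:
        return np.array([], dtype=int)
    if n > length - len(exclude):
        raise ValueError(f"cannot place {n} SNPs on a {length}-bp chromosome")
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(1, length + 1, size=2 * (n - len(chosen)))
        for p in draw:
            p = int(p)
            if p not in exclude and p not in chosen:
                chosen.add(p)
                if len(chosen) == n:
                    break
    return np.array(sorted(chosen), dtype=int)


def _site(chrom, pos, ref, alt, focal_counts, other_counts, labels) -> AlleleCounts:
    idx = {"A": 0, "T": 1, "C": 2, "G": 3}
    samples = []
    for fc, oc in zip(focal_counts, other_counts):
        sextuple = [0, 0, 0, 0, 0, 0]
        sextuple[idx[ref]] = int(fc)
        sextuple[idx[alt]] = int(oc)
        samples.append(tuple(sextuple))
    return AlleleCounts(chrom, pos, ref, tuple(samples), tuple(labels))
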