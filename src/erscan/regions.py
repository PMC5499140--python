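"""Sliding-window averaging of candidate scores and selected-region merging.

Candidate SNPs' -log10 p values are averaged in 200-kb windows sliding every
100 kb; windows whose average exceeds the CMH cutoff are merged into
selected regions ("peaks").  Averages are taken on the -log10 scale: window
means of raw p-values near 1e-31 could never exceed a cutoff of 31.  Also
provides the allele-frequency-change summary of candidates (rising-allele
polarization, fixation fraction at major-allele frequency >= 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def window_scores(
    candidates: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 200_000,
    step: int = 100_000,
) -> pd.DataFrame:
    """Mean candidate -log10 p in sliding windows tiling each chromosome.

    Windows are 1-based inclusive, starting at 1 and advancing by ``step``;
    the final window may be shorter.  Windows without candidates carry a nan
    mean (never qualifying).  A candidate beyond its chromosome length is an
    error.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = candidates[candidates["chrom"] == chrom] if not candidates.empty else candidates
        if not sub.empty and int(sub["pos"].max()) > length:
            raise ValueError(
                f"candidate at {chrom}:{int(sub['pos'].max())} beyond chromosome "
                f"length {length}"
            )
        pos = sub["pos"].to_numpy() if not sub.empty else np.array([], dtype=int)
        score = sub["neg_log10_p"].to_numpy() if not sub.empty else np.array([])
        start = 1
        while start <= length:
            end = min(start + window - 1, length)
            inside = (pos >= start) & (pos <= end)
            n = int(inside.sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_candidates": n,
                    "mean_score": float(score[inside].mean()) if n else float("nan"),
                }
            )
            if end == length:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_candidates", "mean_score"])


@dataclass(frozen=True)
class RegionSummary:
    """Genome-fraction summary of the merged selected regions."""

    n_regions: int
    total_bp: int
    fraction_of_genome: float


def merge_regions(
    scores: pd.DataFrame,
    cutoff: float,
    chrom_lengths: dict[str, int] | None = None,
    candidates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, RegionSummary]:
    """Union overlapping/abutting windows whose mean score exceeds the cutoff.

    Qualification is strict (mean_score > cutoff); windows without
    candidates never qualify.  Regions are per-chromosome sorted and
    non-overlapping; the summary reports region count, unique bp, and — when
    chromosome lengths are given — the fraction of total genome length.
    """
    qual = scores[(scores["n_candidates"] > 0) & (scores["mean_score"] > cutoff)]
    regions = []
    for chrom, sub in qual.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        acc: list[pd.Series] = []

        def flush():
            if cur_start is None:
                return
            if candidates is not None and not candidates.empty:
                inside = candidates[
                    (candidates["chrom"] == chrom)
                    & (candidates["pos"] >= cur_start)
                    & (candidates["pos"] <= cur_end)
                ]
                n_cand = len(inside)
            else:
                # windows overlap, so the max over windows is the best
                # double-count-free figure without the candidate table
                n_cand = max(int(w["n_candidates"]) for w in acc)
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(cur_start),
                    "end": int(cur_end),
                    "n_windows": len(acc),
                    "n_candidates": n_cand,
                    "max_mean_score": float(max(w["mean_score"] for w in acc)),
                }
            )

        for _, w in sub.iterrows():
            if cur_start is None:
                cur_start, cur_end, acc = w["start"], w["end"], [w]
            elif w["start"] <= cur_end + 1:  # overlap or abut
                cur_end = max(cur_end, w["end"])
                acc.append(w)
            else:
                flush()
                cur_start, cur_end, acc = w["start"], w["end"], [w]
        flush()
    df = pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "n_windows", "n_candidates", "max_mean_score"],
    )
    total_bp = int((df["end"] - df["start"] + 1).sum()) if not df.empty else 0
    genome = sum(chrom_lengths.values()) if chrom_lengths else 0
    frac = total_bp / genome if genome else float("nan")
    return df, RegionSummary(n_regions=len(df), total_bp=total_bp, fraction_of_genome=frac)


def regions_to_bed(regions: pd.DataFrame, path) -> None:
    """Write merged regions as BED (0-based half-open)."""
    with open(path, "wt") as handle:
        for _, r in regions.iterrows():
            handle.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\n")


def afc_summary(
    candidates: pd.DataFrame,
    replicates: int,
    fixation_threshold: float = 0.9,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Allele-frequency-change summary of candidate SNPs.

    Per candidate, founder and evolved major-allele frequencies are averaged
    across replicates and re-polarized by the rising allele (the allele
    whose replicate-averaged change is positive).  Returns a per-candidate
    table (start/end frequency and change of the rising allele, final
    major-allele frequency) and summary statistics including the fixation
    fraction: the proportion of candidates whose final major-allele
    frequency reaches ``fixation_threshold``.
    """
    f_cols = [f"founder_freq_{r + 1}" for r in range(replicates)]
    e_cols = [f"evolved_freq_{r + 1}" for r in range(replicates)]
    if candidates.empty:
        table = pd.DataFrame(columns=["chrom", "pos", "start_freq", "end_freq", "change", "final_major_freq"])
        return table, {"n": 0, "fixation_fraction": float("nan"), "mean_change": float("nan")}
    f_mean = candidates[f_cols].mean(axis=1).to_numpy()
    e_mean = candidates[e_cols].mean(axis=1).to_numpy()
    rising = e_mean >= f_mean  # frequencies are of the founder major allele
    start = np.where(rising, f_mean, 1.0 - f_mean)
    end = np.where(rising, e_mean, 1.0 - e_mean)
    final_major = np.maximum(e_mean, 1.0 - e_mean)
    table = pd.DataFrame(
        {
            "chrom": candidates["chrom"].to_numpy(),
            "pos": candidates["pos"].to_numpy(),
            "start_freq": start,
            "end_freq": end,
            "change": end - start,
            "final_major_freq": final_major,
        }
    )
    stats = {
        "n": int(len(table)),
        "fixation_fraction": float(np.mean(final_major >= fixation_threshold)),
        "mean_change": float(np.mean(end - start)),
        "mean_start_freq": float(np.mean(start)),
        "mean_end_freq": float(np.mean(end)),
    }
    return table, stats
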