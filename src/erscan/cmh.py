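"""Cochran-Mantel-Haenszel test for replicated allele-frequency change.

Each SNP contributes one 2x2 table per replicate (allele x time point);
the CMH chi-square (1 df) asks whether the founder-vs-evolved frequency
shift is consistent across replicates.  Strata with a zero row or column
margin carry no information and are dropped from the sums rather than
failing the site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from erscan.sync_io import BiallelicSite

_LN10 = math.log(10.0)
#: smallest reportable p-value; ties at the floor keep their statistic
P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class CmhResult:
    """Outcome of one CMH test: chi-square statistic, p, and -log10 p."""

    statistic: float
    p_value: float
    neg_log10_p: float
    n_strata_used: int
    n_strata_skipped: int

    @property
    def undefined(self) -> bool:
        return self.n_strata_used == 0


def cmh_from_counts(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    continuity_correction: bool = True,
) -> dict[str, np.ndarray]:
    """Vectorized CMH over many SNPs at once.

    ``a``/``b`` are major/minor reads in the founder, ``c``/``d`` in the
    evolved sample, each shaped (n_sites, K).  Returns arrays: statistic,
    p_value (floored at the smallest positive float), neg_log10_p (computed
    from the chi-square log survival function, so it stays finite and exact
    past the p floor), strata used/skipped, and an ``undefined`` mask for
    sites where every stratum is degenerate.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    d = np.atleast_2d(np.asarray(d, dtype=float))
    n1 = a + b  # founder row margin
    n2 = c + d  # evolved row margin
    m1 = a + c  # major-allele column margin
    m2 = b + d  # minor-allele column margin
    t = n1 + n2
    valid = (n1 > 0) & (n2 > 0) & (m1 > 0) & (m2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(valid, n1 * m1 / t, 0.0)
        v = np.where(valid, n1 * n2 * m1 * m2 / (t * t * (t - 1.0)), 0.0)
    dev = np.where(valid, a - e, 0.0).sum(axis=1)
    var = v.sum(axis=1)
    n_used = valid.sum(axis=1)
    undefined = n_used == 0
    corr = 0.5 if continuity_correction else 0.0
    num = np.maximum(np.abs(dev) - corr, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = np.where(undefined, np.nan, num * num / np.where(var > 0, var, np.nan))
    # a zero variance with valid strata cannot occur (all margins positive)
    p = stats.chi2.sf(statistic, df=1)
    neg_log10 = -stats.chi2.logsf(statistic, df=1) / _LN10
    p = np.where(undefined, np.nan, np.maximum(p, P_FLOOR))
    neg_log10 = np.where(undefined, np.nan, neg_log10)
    return {
        "statistic": statistic,
        "p_value": p,
        "neg_log10_p": neg_log10,
        "n_strata_used": n_used,
        "n_strata_skipped": (~valid).sum(axis=1),
        "undefined": undefined,
    }


def cmh_test(
    a: Sequence[float],
    b: Sequence[float],
    c: Sequence[float],
    d: Sequence[float],
    continuity_correction: bool = True,
) -> CmhResult:
    """CMH test on a single 2x2xK table (per-replicate count vectors).

    ``a_k``/``b_k`` are major/minor founder reads and ``c_k``/``d_k`` the
    evolved reads in replicate k.  When every stratum has a zero margin the
    result is flagged undefined (nan statistic) for downstream exclusion.
    """
    res = cmh_from_counts(
        np.asarray(a)[None, :],
        np.asarray(b)[None, :],
        np.asarray(c)[None, :],
        np.asarray(d)[None, :],
        continuity_correction=continuity_correction,
    )
    return CmhResult(
        statistic=float(res["statistic"][0]),
        p_value=float(res["p_value"][0]),
        neg_log10_p=float(res["neg_log10_p"][0]),
        n_strata_used=int(res["n_strata_used"][0]),
        n_strata_skipped=int(res["n_strata_skipped"][0]),
    )


def cmh_scan(
    sites: Sequence[BiallelicSite],
    founder_labels: Sequence[str],
    evolved_labels: Sequence[str],
    continuity_correction: bool = True,
) -> pd.DataFrame:
    """Run the CMH test over a scan of polarized SNPs.

    Founder and evolved replicates are paired by position in the two label
    lists.  Returns one row per site: coordinates, alleles, per-replicate
    major-allele frequencies at both time points, statistic, p and -log10 p;
    undefined sites (all strata degenerate) carry nan and are counted.
    """
    if len(founder_labels) != len(evolved_labels):
        raise ValueError("founder and evolved label lists must pair one-to-one")
    sites = list(sites)
    if not sites:
        cols = ["chrom", "pos", "major", "minor", "statistic", "p_value", "neg_log10_p"]
        return pd.DataFrame(columns=cols)
    k = len(founder_labels)
    labels = sites[0].sample_labels
    f_idx = [labels.index(l) for l in founder_labels]
    e_idx = [labels.index(l) for l in evolved_labels]
    counts = np.array([s.counts for s in sites], dtype=float)  # (n, samples, 2)
    a = counts[:, f_idx, 0]
    b = counts[:, f_idx, 1]
    c = counts[:, e_idx, 0]
    d = counts[:, e_idx, 1]
    res = cmh_from_counts(a, b, c, d, continuity_correction=continuity_correction)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_freq = a / (a + b)
        e_freq = c / (c + d)
    data: dict[str, object] = {
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "major": [s.major for s in sites],
        "minor": [s.minor for s in sites],
    }
    for r in range(k):
        data[f"founder_freq_{r + 1}"] = f_freq[:, r]
        data[f"evolved_freq_{r + 1}"] = e_freq[:, r]
    data["statistic"] = res["statistic"]
    data["p_value"] = res["p_value"]
    data["neg_log10_p"] = res["neg_log10_p"]
    data["n_strata_skipped"] = res["n_strata_skipped"]
    df = pd.DataFrame(data)
    df.attrs["n_undefined"] = int(res["undefined"].sum())
    df.attrs["n_strata_skipped_total"] = int(res["n_strata_skipped"].sum())
    return df
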