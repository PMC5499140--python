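"""Empirical significance cutoff from a neutral cohort; candidate calling.

The CMH test does not account for drift, so nominal p-values are
anticonservative in an evolve-and-resequence design.  The cutoff is instead
taken from the order statistics of -log10 p in a matched neutral cohort at a
nominal false-positive rate (2% in the study); observed SNPs strictly above
the cutoff are candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CutoffResult:
    """An empirically calibrated -log10 p threshold."""

    fpr: float
    cutoff: float
    n_neutral: int
    realized_fpr_check: float | None = None


def empirical_cutoff(
    neutral_neg_log10_p,
    fpr: float = 0.02,
    holdout_neg_log10_p=None,
) -> CutoffResult:
    """Cutoff = smallest cohort value with at most ``fpr`` of the cohort
    strictly above it (nearest-rank from above).

    With an optional held-out neutral cohort the realized false-positive
    rate of the cutoff is reported alongside.
    """
    if not 0 < fpr < 1:
        raise ValueError(f"fpr must be in (0, 1), got {fpr}")
    scores = np.asarray(neutral_neg_log10_p, dtype=float)
    scores = scores[np.isfinite(scores)]
    n = scores.size
    if n == 0:
        raise ValueError("empty neutral cohort")
    if n < 50.0 / fpr:
        warnings.warn(
            f"neutral cohort of {n} is small for fpr={fpr}; cutoff will be noisy",
            stacklevel=2,
        )
    desc = np.sort(scores)[::-1]
    m = math.floor(fpr * n)
    cutoff = float(desc[min(m, n - 1)])
    realized = None
    if holdout_neg_log10_p is not None:
        holdout = np.asarray(holdout_neg_log10_p, dtype=float)
        holdout = holdout[np.isfinite(holdout)]
        realized = float(np.mean(holdout > cutoff))
    return CutoffResult(fpr=fpr, cutoff=cutoff, n_neutral=n, realized_fpr_check=realized)


def call_candidates(observed: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Subset observed CMH results to candidates: -log10 p strictly above
    the cutoff, genomic order preserved."""
    if observed.empty:
        return observed.copy()
    out = observed[observed["neg_log10_p"] > cutoff].copy()
    out.attrs["n_observed"] = len(observed)
    out.attrs["n_candidates"] = len(out)
    out.attrs["cutoff"] = float(cutoff)
    return out
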