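import numpy as np

from erscan.sync_io import AlleleCounts

_NUC_IDX = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4, "del": 5}


def make_site(chrom="2L", pos=100, ref="A", labels=("F1", "F2", "E1", "E2"), **per_sample):
    """Build an AlleleCounts from keyword counts like F1={'A': 10, 'T': 2}."""
    samples = []
    for label in labels:
        sextuple = [0] * 6
        for nuc, count in per_sample.get(label, {}).items():
            sextuple[_NUC_IDX[nuc]] = count
        samples.append(tuple(sextuple))
    return AlleleCounts(chrom, pos, ref, tuple(samples), tuple(labels))


def random_tables(rng: np.random.Generator, n: int, max_k: int = 5, low: int = 1, high: int = 50):
    """Random 2x2xK tables with strictly positive entries (no zero margins)."""
    out = []
    for _ in range(n):
        k = int(rng.integers(1, max_k + 1))
        out.append(rng.integers(low, high + 1, size=(4, k)))
    return out
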