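"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations — exhaustive enumeration and
direct probability sums — kept separate from the package code paths they
check.
"""

from __future__ import annotations

from scipy import stats

PAIRS = {("G", "C"): -3.0, ("C", "G"): -3.0,
         ("A", "T"): -2.0, ("T", "A"): -2.0,
         ("A", "U"): -2.0, ("U", "A"): -2.0,
         ("G", "T"): -1.0, ("T", "G"): -1.0,
         ("G", "U"): -1.0, ("U", "G"): -1.0}
MIN_LOOP = 3


def enumerate_structures(seq: str, i: int = 0, j: int | None = None):
    """Yield every pseudoknot-free pairing of seq[i:j] as a tuple of pairs."""
    if j is None:
        j = len(seq)
    if i >= j:
        yield ()
        return
    # position i unpaired
    for rest in enumerate_structures(seq, i + 1, j):
        yield rest
    # position i paired with k (hairpin loop >= MIN_LOOP unpaired bases)
    for k in range(i + MIN_LOOP + 1, j):
        if (seq[i], seq[k]) in PAIRS:
            for inner in enumerate_structures(seq, i + 1, k):
                for outer in enumerate_structures(seq, k + 1, j):
                    yield ((i, k),) + inner + outer


def brute_force_mfe(seq: str) -> float:
    """Minimum energy over all enumerated structures (0 if none pairs)."""
    best = 0.0
    for structure in enumerate_structures(seq.upper()):
        energy = sum(PAIRS[(seq[i], seq[j])] for i, j in structure)
        if energy < best:
            best = energy
    return best


def exact_p_enumeration(sum_a: int, sum_b: int, n_a: int, n_b: int,
                        phi: float) -> float:
    """Double-tail NB exact p by explicit enumeration over all splits."""
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)

    def pmf(k: int, n: int) -> float:
        if phi == 0:
            return float(stats.poisson.pmf(k, n * mu))
        size = n / phi
        return float(stats.nbinom.pmf(k, size, size / (size + n * mu)))

    probs = [pmf(k, n_a) * pmf(total - k, n_b) for k in range(total + 1)]
    z = sum(probs)
    probs = [p / z for p in probs]
    obs = probs[sum_a]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-9)))


def naive_site_count(pattern: str, text: str) -> int:
    """Overlapping substring count by sliding a window one base at a time."""
    return sum(text[i:i + len(pattern)] == pattern
               for i in range(len(text) - len(pattern) + 1))
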