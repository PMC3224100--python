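"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the production code paths: the SSR oracle scans every
(start, motif length) pair with plain substring comparisons, and the quality
oracle evaluates the two-hypothesis posterior with exact rational arithmetic.
"""

from fractions import Fraction

_ACGT = set("ACGT")


def _is_primitive(word: str) -> bool:
    n = len(word)
    for d in range(1, n):
        if n % d == 0 and word == word[:d] * (n // d):
            return False
    return True


def _canonical(word: str) -> str:
    root = word
    for d in range(1, len(word)):
        if len(word) % d == 0 and word == word[:d] * (len(word) // d):
            root = word[:d]
            break
    return min(root[i:] + root[:i] for i in range(len(root)))


def brute_force_ssrs(sequence: str, min_repeats=None, motif_lengths=(2, 3, 4, 5, 6)):
    """All maximal perfect repeat runs meeting class minima, then greedy
    overlap resolution (longest span, leftmost, shortest motif).

    Returns a set of (start, end, canonical_motif, repeats) tuples.
    """
    min_repeats = min_repeats or {2: 6, 3: 4, 4: 3, 5: 3, 6: 3}
    n = len(sequence)
    candidates = []
    for k in motif_lengths:
        minrep = min_repeats[k]
        for i in range(n - k * minrep + 1):
            word = sequence[i : i + k]
            if set(word) - _ACGT or not _is_primitive(word):
                continue
            # left-maximality: the periodic run must not extend left
            if i > 0 and sequence[i - 1] == sequence[i - 1 + k] and sequence[i - 1] in _ACGT:
                continue
            reps = 1
            while sequence[i + reps * k : i + (reps + 1) * k] == word:
                reps += 1
            if reps >= minrep:
                candidates.append((i, i + reps * k, k, _canonical(word), reps))
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen = []
    for c in candidates:
        if all(c[1] <= o[0] or o[1] <= c[0] for o in chosen):
            chosen.append(c)
    return {(s, e, m, r) for (s, e, _k, m, r) in chosen}


def exact_posterior(n_major: int, n_minor: int, error_rate=Fraction(1, 100)) -> Fraction:
    """Exact-rational posterior of the balanced-biallelic hypothesis.

    H0: monomorphic; a read shows the specific minor base at rate e/3.
    H1: balanced biallelic; a read shows either allele at rate (1-e)/2 + e/6.
    Equal priors; binomial coefficients shared, so they cancel.
    """
    e = Fraction(error_rate)
    l0 = (1 - e) ** n_major * (e / 3) ** n_minor
    p = (1 - e) / 2 + e / 6
    l1 = p ** (n_major + n_minor)
    return l1 / (l0 + l1)
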