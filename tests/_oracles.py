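"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive recursion/enumeration,
sharing no code with the implementation paths they check.
"""

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]
AA = dict(_TABLE.forward_table)
STOPS = set(_TABLE.stop_codons)


def recursive_global_score(a: str, b: str, match: float, mismatch: float, gap: float):
    """Linear-gap global alignment score by exhaustive recursion."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i == len(a):
            return gap * (len(b) - j)
        if j == len(b):
            return gap * (len(a) - i)
        diag = f(i + 1, j + 1) + (match if a[i] == b[j] else mismatch)
        return max(diag, f(i + 1, j) + gap, f(i, j + 1) + gap)

    return f(0, 0)


def ng86_codon_diff_oracle(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for a codon pair by enumerating every mutational pathway.

    Pathways visiting a stop codon at an intermediate step are excluded;
    when all are excluded, every pathway is used.
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in permutations(positions):
        cur = c1
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS and nxt != c2:
                blocked = True
            if cur in AA and nxt in AA and AA[cur] == AA[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        results.append((blocked, syn, non))
    usable = [(s, n) for b, s, n in results if not b]
    if not usable:
        usable = [(s, n) for _b, s, n in results]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def random_additive_tree(rng, n_taxa: int) -> str:
    """Random rooted binary tree over t1..tN with branch lengths in [0.1, 1]."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    rng.shuffle(labels)

    def build(group):
        if len(group) == 1:
            return group[0]
        k = int(rng.integers(1, len(group)))
        left, right = build(group[:k]), build(group[k:])
        bl = rng.uniform(0.1, 1.0)
        br = rng.uniform(0.1, 1.0)
        return f"({left}:{bl:.6f},{right}:{br:.6f})"

    return build(labels) + ";"
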