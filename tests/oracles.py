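"""Independent oracles used by the test suite.

These re-derive expected values by brute force or enumeration, through
code paths deliberately different from the package implementation.
"""

from __future__ import annotations

from functools import lru_cache

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

MIN_COUNT = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _primitive(motif: str) -> bool:
    for d in range(1, len(motif)):
        if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
            return False
    return True


def enumerate_ssrs(
    seq: str, min_count: dict[int, int] | None = None
) -> set[tuple[int, str, int]]:
    """Every maximal perfect SSR, by per-start substring comparison.

    A locus (start, motif, count) is emitted when the motif is primitive
    and N-free, the run cannot be extended one base leftwards while
    staying periodic, and the whole-copy count reaches the motif-length
    minimum.
    """
    min_count = min_count or MIN_COUNT
    n = len(seq)
    out: set[tuple[int, str, int]] = set()
    for m in range(1, 7):
        for a in range(n - 2 * m + 1):
            motif = seq[a : a + m]
            if "N" in motif or not _primitive(motif):
                continue
            if a >= 1 and seq[a - 1] == seq[a - 1 + m] and seq[a - 1] != "N":
                continue  # run extends leftwards: not a run start
            c = 1
            while seq[a + c * m : a + (c + 1) * m] == motif:
                c += 1
            if c >= min_count[m]:
                out.add((a, motif, c))
    return out


def affine_alignment_optimum(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Optimal global alignment score with affine gaps, by memoized
    recursion over (position, position, previous operation).

    A gap of length g scores gap_open + g * gap_extend.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = gap_extend + (gap_open if prev != "A" else 0)
            options.append(cost + best(i + 1, j, "A"))
        if j < len(b):  # gap in a
            cost = gap_extend + (gap_open if prev != "B" else 0)
            options.append(cost + best(i, j + 1, "B"))
        return max(options)

    return int(best(0, 0, "M"))
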