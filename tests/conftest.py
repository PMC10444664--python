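"""Shared fixtures and independent reference implementations.

The reference chainer here is deliberately naive -- no k-mer index, no
early exits beyond what the selection rule itself states -- so it can
serve as an independent oracle for the optimized chain implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

BASES = "ACGT"


def naive_chain(a: str, b: str, k: int) -> list[tuple[int, int]]:
    """Brute-force re-implementation of the greedy seed chaining rule.

    Scans every position of both sequences directly (quadratic) and
    applies: constant-time +1/+1 extension when the shifted windows
    match; otherwise the two-candidate scan with the distance-difference
    band |(i - i_prev) - (j - j_prev)| <= k, ties to the smaller
    position, and the step-3 comparison preferring the first-sequence
    candidate on <=.
    """
    seeds: list[tuple[int, int]] = []
    pi = pj = -1
    while True:
        nxt = None
        if seeds:
            i, j = pi + 1, pj + 1
            if (
                i + k <= len(a)
                and j + k <= len(b)
                and a[i : i + k] == b[j : j + k]
                and "N" not in a[i : i + k]
            ):
                nxt = (i, j)
        if nxt is None:
            c1 = None
            for i in range(pi + 1, len(a) - k + 1):
                km = a[i : i + k]
                if "N" in km:
                    continue
                best = None
                for j in range(pj + 1, len(b) - k + 1):
                    if b[j : j + k] == km:
                        d = abs((i - pi) - (j - pj))
                        if d <= k and (best is None or d < best[1]):
                            best = (j, d)
                if best is not None:
                    c1 = (i, best[0], best[1])
                    break
            c2 = None
            for j in range(pj + 1, len(b) - k + 1):
                km = b[j : j + k]
                if "N" in km:
                    continue
                best = None
                for i in range(pi + 1, len(a) - k + 1):
                    if a[i : i + k] == km:
                        d = abs((j - pj) - (i - pi))
                        if d <= k and (best is None or d < best[1]):
                            best = (i, d)
                if best is not None:
                    c2 = (best[0], j, best[1])
                    break
            if c1 is None and c2 is None:
                nxt = None
            elif c2 is None or (c1 is not None and c1[2] <= c2[2]):
                nxt = (c1[0], c1[1])
            else:
                nxt = (c2[0], c2[1])
        if nxt is None:
            break
        seeds.append(nxt)
        pi, pj = nxt
    return seeds


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[c] for c in rng.integers(0, 4, size=length))


@pytest.fixture
def worked_pair_a() -> tuple[str, str]:
    """Length-9 pair sharing 4 seeds at k=3."""
    return "ACGTAGTAG", "ACGAGTAGG"


@pytest.fixture
def worked_pair_b() -> tuple[str, str]:
    """Length-10 pair whose second chosen seed at k=3 is (4, 3)."""
    return "GCGTGATTCG", "GCGGATTGAG"
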