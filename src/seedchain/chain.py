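"""Greedy seed chaining and alignment-identity estimation for a fixed k.

Given two DNA sequences and a k-mer length ``k``, this module computes a
co-linear chain of *seeds* -- position pairs ``(i, j)`` at which the two
sequences carry the same k-mer -- and reads off the chain an estimate of
the number of substitutions, deletions and insertions (``GapAccount``)
separating the sequences.  The estimated alignment identity is then

    e = (|x| - (sub + del)) / (|x| + ins)

i.e. the number of matching alignment columns over the alignment length,
where ``x`` is the first sequence of the pair.  No dynamic-programming
alignment is performed here; the chain is built greedily in
O(k * (|x| + |y|)) time, which is the point of the method.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

__all__ = [
    "SequenceRecord",
    "Seed",
    "GapAccount",
    "ChainResult",
    "DUMMY_SEED",
    "index_kmers",
    "extend_seed",
    "next_seed",
    "chain_seeds",
    "account_gaps",
    "estimate_identity",
]

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence over {A, C, G, T, N}, uppercase, 0-based.

    Lowercase input is canonicalised to uppercase at construction time;
    any other letter raises ``ValueError``.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        seq = self.seq.upper()
        if not seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid letters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Seed:
    """A pair of start positions asserting equality of two k-mers.

    ``i`` indexes the first sequence, ``j`` the second; both 0-based.
    """

    i: int
    j: int


#: Virtual predecessor used to start a chain; covers nothing and ends
#: before position 0 of both sequences.
DUMMY_SEED = Seed(-1, -1)


@dataclass(frozen=True)
class GapAccount:
    """Estimated edit-operation counts read off a seed chain (in bases)."""

    subs: int = 0
    dels: int = 0
    ins: int = 0

    def __post_init__(self) -> None:
        if self.subs < 0 or self.dels < 0 or self.ins < 0:
            raise ValueError("gap counts must be non-negative")


@dataclass(frozen=True)
class ChainResult:
    """Seed chain for one (pair, k) plus its gap account and identity."""

    seeds: tuple[Seed, ...]
    k: int
    account: GapAccount
    identity: float

    @property
    def t(self) -> int:
        """Number of seeds in the chain."""
        return len(self.seeds)


def index_kmers(s: SequenceRecord | str, k: int) -> dict[str, list[int]]:
    """Map every k-mer of ``s`` to the sorted list of its start positions.

    k-mers containing ``N`` are excluded: an undefined base can never
    witness a seed.  ``k`` larger than the sequence yields an empty map
    (no seeds are possible), not an error.
    """
    seq = s.seq if isinstance(s, SequenceRecord) else s.upper()
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    index: dict[str, list[int]] = {}
    for p in range(len(seq) - k + 1):
        kmer = seq[p : p + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(p)
    return index


def extend_seed(prev: Seed, si: str, sj: str, k: int) -> Optional[Seed]:
    """Try the constant-time extension ``(i+1, j+1)`` of ``prev``.

    Returns the extended seed iff the shifted k-mer windows are equal,
    in range and free of N; ``None`` otherwise.
    """
    i, j = prev.i + 1, prev.j + 1
    if i + k > len(si) or j + k > len(sj):
        return None
    wi = si[i : i + k]
    if wi != sj[j : j + k] or "N" in wi:
        return None
    return Seed(i, j)


def _best_partner(
    occs: list[int], lo: int, target: int, k: int
) -> Optional[tuple[int, int]]:
    """Among occurrence positions ``> lo`` in a sorted list, find the one
    closest to ``target`` with |pos - target| <= k; ties prefer the
    smaller position.  Returns (position, |pos - target|) or None.
    """
    left = bisect_right(occs, lo)
    left = max(left, bisect_left(occs, target - k, left))
    right = bisect_right(occs, target + k, left)
    best: Optional[tuple[int, int]] = None
    for pos in occs[left:right]:
        d = abs(pos - target)
        if best is None or d < best[1]:
            best = (pos, d)
    return best


def _step_candidate(
    prev_a: int,
    prev_b: int,
    sa: str,
    idx_b: dict[str, list[int]],
    k: int,
) -> Optional[tuple[int, int, int]]:
    """Generic single-direction candidate scan.

    Walks positions of ``sa`` after ``prev_a`` in ascending order; at the
    first position whose k-mer also occurs in the other sequence after
    ``prev_b``, looks for the partner occurrence minimising the distance
    difference subject to the <= k band.  A position whose k-mer has
    occurrences but none inside the band is skipped and the scan
    continues (the chain is not silently truncated).

    Returns (pos_a, pos_b, distance_difference) or None.
    """
    for pa in range(prev_a + 1, len(sa) - k + 1):
        kmer = sa[pa : pa + k]
        if "N" in kmer:
            continue
        occs = idx_b.get(kmer)
        if not occs or occs[-1] <= prev_b:
            continue
        hit = _best_partner(occs, prev_b, prev_b + (pa - prev_a), k)
        if hit is not None:
            return pa, hit[0], hit[1]
    return None


def next_seed(
    prev: Seed,
    si: str,
    sj: str,
    k: int,
    idx_i: dict[str, list[int]],
    idx_j: dict[str, list[int]],
) -> Optional[Seed]:
    """Select the next seed after ``prev`` via the two-candidate rule.

    Step 1 scans the first sequence for the smallest position after
    ``prev.i`` whose k-mer recurs in the second sequence after ``prev.j``
    within a distance-difference band of width k; Step 2 is the mirror
    scan of the second sequence.  Step 3 keeps the Step-1 candidate when
    its distance difference is <= that of Step 2, otherwise the Step-2
    candidate.  ``prev`` may be the dummy seed (-1, -1).
    """
    c1 = _step_candidate(prev.i, prev.j, si, idx_j, k)
    c2 = _step_candidate(prev.j, prev.i, sj, idx_i, k)
    if c1 is None and c2 is None:
        return None
    if c2 is None or (c1 is not None and c1[2] <= c2[2]):
        return Seed(c1[0], c1[1])
    return Seed(c2[1], c2[0])


def chain_seeds(
    si: SequenceRecord | str, sj: SequenceRecord | str, k: int
) -> ChainResult:
    """Compute the full greedy seed chain between two sequences at ``k``.

    Starting from the dummy seed, the cheap +1/+1 extension is tried
    first after every selected seed; when it fails the two-candidate
    selection takes over, until no further seed qualifies.  The gap
    account and identity of the finished chain are filled in via
    :func:`account_gaps` and :func:`estimate_identity`.
    """
    a = si.seq if isinstance(si, SequenceRecord) else si.upper()
    b = sj.seq if isinstance(sj, SequenceRecord) else sj.upper()
    if not 1 <= k <= min(len(a), len(b)):
        raise ValueError(
            f"k={k} out of range for sequence lengths {len(a)}, {len(b)}"
        )
    idx_i = index_kmers(a, k)
    idx_j = index_kmers(b, k)

    seeds: list[Seed] = []
    prev = DUMMY_SEED
    while True:
        nxt = None
        if prev is not DUMMY_SEED:
            nxt = extend_seed(prev, a, b, k)
        if nxt is None:
            nxt = next_seed(prev, a, b, k, idx_i, idx_j)
        if nxt is None:
            break
        seeds.append(nxt)
        prev = nxt

    account = account_gaps(seeds, len(a), len(b), k)
    identity = estimate_identity(account, len(a))
    return ChainResult(tuple(seeds), k, account, identity)


def _gap_pair(gap_i: int, gap_j: int) -> tuple[int, int, int]:
    """min/diff rule: (subs, dels, ins) contributed by one inter-seed gap.

    Substitutions are the overlap of the two uncovered stretches, so a
    negative gap (overlapping seed windows) contributes none; the
    deletion/insertion charge is the *unclamped* difference gap_i -
    gap_j, i.e. the diagonal shift between the two seeds, which equals
    the net indel count between them even when the windows overlap.
    """
    subs = min(max(0, gap_i), max(0, gap_j))
    shift = gap_i - gap_j
    if shift > 0:
        return subs, shift, 0
    return subs, 0, -shift


def account_gaps(
    seeds: list[Seed] | tuple[Seed, ...], m: int, n: int, k: int
) -> GapAccount:
    """Estimate substitution/deletion/insertion counts from a seed chain.

    Between consecutive seeds the uncovered gap in each sequence is
    measured from the end of the previous k-mer window; the smaller gap
    is charged to substitutions and the excess to deletions (first
    sequence longer) or insertions (second longer).  The region before
    the first seed is charged against the virtual dummy seed ending at
    position -1, and the region after the last seed against the sequence
    ends, with the same rule.  Overlapping seeds (extension runs) have
    their substitution gaps clamped at zero, so overlapping matches are
    never double-penalised, but the diagonal shift between consecutive
    seeds is always charged in full to deletions or insertions.  An
    empty chain charges the whole shorter length to substitutions and
    the length difference to deletions/insertions.
    """
    end_i, end_j = 0, 0  # one past covered prefix of each sequence
    last_i, last_j = -1, -1
    subs = dels = ins = 0
    for s in seeds:
        if s.i <= last_i or s.j <= last_j:
            raise ValueError(
                "malformed chain: seeds must be strictly increasing "
                f"in both coordinates (got ({s.i}, {s.j}) after "
                f"({last_i}, {last_j}))"
            )
        a, d, i_ = _gap_pair(s.i - end_i, s.j - end_j)
        subs += a
        dels += d
        ins += i_
        end_i = s.i + k
        end_j = s.j + k
        last_i, last_j = s.i, s.j
    a, d, i_ = _gap_pair(m - end_i, n - end_j)
    subs += a
    dels += d
    ins += i_
    return GapAccount(subs, dels, ins)


def estimate_identity(account: GapAccount, m: int) -> float:
    """Alignment identity (|x| - (sub + del)) / (|x| + ins), clamped to [0, 1].

    ``m`` is the length of the first sequence of the pair; the formula is
    asymmetric in the two sequences because insertions extend the
    alignment beyond |x| while deletions do not.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if account.subs + account.dels > m:
        raise ValueError(
            f"inconsistent accounting: sub+del={account.subs + account.dels} > m={m}"
        )
    value = Fraction(m - (account.subs + account.dels), m + account.ins)
    return float(min(max(value, Fraction(0)), Fraction(1)))
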