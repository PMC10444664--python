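"""Per-pair k scan, (t, k) selection and minimizer-parameter aggregation.

For every sequence pair the chain estimator is run at every k in a user
range (default [3, 15]).  The selection rule then keeps the *largest* k
whose estimated identity is within ``delta`` of the best identity seen
over the scan: larger k-mers give more specific seeds, so among nearly
equivalent k values the largest is preferred.  Selected k values are
finally aggregated into a minimizer length kappa = ceil(mean k) and a
window size w = ceil(2 * kappa / 3), the parameter pair consumed by
minimizer-based aligners.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .chain import SequenceRecord, chain_seeds

__all__ = [
    "DEFAULT_MIN_K",
    "DEFAULT_MAX_K",
    "DEFAULT_DELTA",
    "KSelection",
    "MinimapParams",
    "scan_k",
    "select_k",
    "analyze_pair",
    "build_oseed",
    "aggregate_minimap_params",
]

DEFAULT_MIN_K = 3
#: Default upper bound of the scan; the default minimizer length of Minimap2.
DEFAULT_MAX_K = 15
DEFAULT_DELTA = 0.05


@dataclass
class KSelection:
    """Summary of the k scan for one sequence pair.

    ``per_k`` maps each scanned k to its (t, identity) estimate;
    ``e_best``/``k_best`` locate the identity maximum; ``k_delta`` is the
    selected k and ``t_out`` the seed count there.  ``in_oseed`` is set
    by :func:`build_oseed` once an identity threshold is chosen.
    """

    pair_ids: tuple[str, str]
    per_k: dict[int, tuple[int, float]]
    e_best: float
    k_best: int
    k_delta: int
    t_out: int
    in_oseed: bool | None = None

    @property
    def has_seeds(self) -> bool:
        """True if at least one scanned k produced a non-empty chain."""
        return any(t > 0 for t, _ in self.per_k.values())


@dataclass(frozen=True)
class MinimapParams:
    """Minimizer length and window size for a minimizer-based aligner."""

    kappa: int
    w: int

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.w != math.ceil(2 * self.kappa / 3):
            raise ValueError("w must equal ceil(2 * kappa / 3)")


def scan_k(
    si: SequenceRecord | str,
    sj: SequenceRecord | str,
    min_k: int = DEFAULT_MIN_K,
    max_k: int = DEFAULT_MAX_K,
) -> dict[int, tuple[int, float]]:
    """Run the chain estimator for every k in [min_k, max_k].

    k values exceeding the shorter sequence are skipped with a warning
    rather than failing the whole pair.
    """
    if min_k < 1 or min_k > max_k:
        raise ValueError(f"invalid k range [{min_k}, {max_k}]")
    shorter = min(
        len(si.seq) if isinstance(si, SequenceRecord) else len(si),
        len(sj.seq) if isinstance(sj, SequenceRecord) else len(sj),
    )
    if max_k > shorter:
        warnings.warn(
            f"k range truncated to [{min_k}, {shorter}]: "
            f"shorter sequence has length {shorter}",
            stacklevel=2,
        )
    per_k: dict[int, tuple[int, float]] = {}
    for k in range(min_k, min(max_k, shorter) + 1):
        result = chain_seeds(si, sj, k)
        per_k[k] = (result.t, result.identity)
    if not per_k:
        raise ValueError(
            f"no k in [{min_k}, {max_k}] fits sequences of length {shorter}"
        )
    return per_k


def select_k(
    per_k: dict[int, tuple[int, float]],
    delta: float = DEFAULT_DELTA,
    pair_ids: tuple[str, str] = ("x", "y"),
) -> KSelection:
    """Apply the e_best / delta rule to a completed k scan.

    ``k_best`` is the smallest k attaining the maximum identity (so the
    window [k_best, k_max] over which the delta rule searches is
    widest); ``k_delta`` is the largest scanned k in that window whose
    identity is within ``delta`` of the best.  ``delta`` = 0 selects
    k_best itself unless a larger k ties exactly.
    """
    if not per_k:
        raise ValueError("per_k must be non-empty")
    if not 0 <= delta <= 1:
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    ks = sorted(per_k)
    e_best = max(per_k[k][1] for k in ks)
    k_best = min(k for k in ks if per_k[k][1] == e_best)
    k_delta = max(
        k for k in ks if k >= k_best and e_best - per_k[k][1] <= delta
    )
    return KSelection(
        pair_ids=pair_ids,
        per_k=dict(per_k),
        e_best=e_best,
        k_best=k_best,
        k_delta=k_delta,
        t_out=per_k[k_delta][0],
    )


def analyze_pair(
    si: SequenceRecord,
    sj: SequenceRecord,
    min_k: int = DEFAULT_MIN_K,
    max_k: int = DEFAULT_MAX_K,
    delta: float = DEFAULT_DELTA,
) -> KSelection:
    """Scan k and apply the selection rule for one sequence pair.

    The first sequence plays the role of x in the identity formula.
    """
    per_k = scan_k(si, sj, min_k, max_k)
    return select_k(per_k, delta, pair_ids=(si.id, sj.id))


def build_oseed(
    selections: list[KSelection], e: float
) -> list[KSelection]:
    """Mark and return the selections whose best identity reaches ``e``.

    The returned list is the estimated positive set: the pairs reported,
    each carrying its (t, k) output.  Membership is monotone shrinking
    in ``e``.  Every selection's ``in_oseed`` flag is set in place.
    """
    if not 0 <= e <= 1:
        raise ValueError(f"identity threshold must be in [0, 1], got {e}")
    members = []
    for sel in selections:
        sel.in_oseed = sel.e_best >= e
        if sel.in_oseed:
            members.append(sel)
    return members


def aggregate_minimap_params(selections: list[KSelection]) -> MinimapParams:
    """Aggregate selected k values into (kappa, w).

    kappa is the ceiling of the mean ``k_delta`` over all pairs that
    produced at least one seed at some k; w = ceil(2 * kappa / 3),
    the ratio used by Minimap2's defaults.  Seedless pairs carry no
    k-mer information and are excluded with a warning.
    """
    contributing = [sel for sel in selections if sel.has_seeds]
    excluded = len(selections) - len(contributing)
    if excluded:
        warnings.warn(
            f"{excluded} pair(s) had no seeds at any k and were excluded "
            "from parameter aggregation",
            stacklevel=2,
        )
    if not contributing:
        raise ValueError("no pair produced seeds at any k; cannot aggregate")
    k_avg = sum(sel.k_delta for sel in contributing) / len(contributing)
    kappa = math.ceil(k_avg)
    return MinimapParams(kappa=kappa, w=math.ceil(2 * kappa / 3))
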