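"""Seeded generation of sequence pairs with controlled divergence.

Each pair is an i.i.d. uniform random DNA sequence of a chosen length
together with a mutated copy: round(divergence * length) edit
operations, each drawn uniformly among substitution, insertion and
deletion and applied at a uniformly chosen position of the evolving
sequence.  Substitutions always change the base, so every operation
costs at most one unit of edit distance and the realised optimal
divergence concentrates just below the nominal target (independent
operations can overlap or cancel).

Datasets are reproducible byte-for-byte from their ``GenSpec`` and can
be written as multiFASTA with a JSON sidecar recording the generating
parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .chain import SequenceRecord

__all__ = [
    "GenSpec",
    "random_sequence",
    "mutate",
    "generate_pair",
    "generate_dataset",
    "write_dataset",
]

_BASES = "ACGT"

#: Default operation mix: substitution, insertion, deletion.
_OP_PROBS = (1 / 3, 1 / 3, 1 / 3)


@dataclass(frozen=True)
class GenSpec:
    """Parameters of one synthetic dataset of sequence pairs."""

    n_pairs: int
    length: int
    divergence: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0, 1]")


def random_sequence(
    length: int, rng: np.random.Generator, id: str = "random"
) -> SequenceRecord:
    """Uniform i.i.d. DNA sequence of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    letters = rng.integers(0, 4, size=length)
    return SequenceRecord(id, "".join(_BASES[b] for b in letters))


def mutate(
    seq: SequenceRecord,
    divergence: float,
    rng: np.random.Generator,
    op_probs: tuple[float, float, float] = _OP_PROBS,
    id: str | None = None,
) -> SequenceRecord:
    """Apply round(divergence * |seq|) random edits to a copy of ``seq``.

    Operations are drawn per-edit with probabilities ``op_probs`` for
    (substitution, insertion, deletion) and applied sequentially to the
    evolving sequence; positions are uniform over the current length.
    A deletion on a length-1 sequence is skipped to keep the output
    non-empty.
    """
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    current = list(seq.seq)
    n_ops = round(divergence * len(seq.seq))
    for op in rng.choice(3, size=n_ops, p=op_probs):
        if op == 0:  # substitution: always a different base
            pos = int(rng.integers(0, len(current)))
            alternatives = _BASES.replace(current[pos], "") or _BASES
            current[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
        elif op == 1:  # insertion: any base, any of len+1 slots
            pos = int(rng.integers(0, len(current) + 1))
            current.insert(pos, _BASES[int(rng.integers(0, 4))])
        elif len(current) > 1:  # deletion
            pos = int(rng.integers(0, len(current)))
            del current[pos]
    return SequenceRecord(id or f"{seq.id}_mut", "".join(current))


def generate_pair(
    length: int, divergence: float, rng: np.random.Generator, label: str
) -> tuple[SequenceRecord, SequenceRecord]:
    """One (original, mutated) pair with ids ``<label>_ref`` / ``<label>_mut``."""
    ref = random_sequence(length, rng, id=f"{label}_ref")
    mut = mutate(ref, divergence, rng, id=f"{label}_mut")
    return ref, mut


def generate_dataset(
    spec: GenSpec,
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """All pairs of a dataset, deterministic under ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    return [
        generate_pair(spec.length, spec.divergence, rng, f"pair{i}")
        for i in range(spec.n_pairs)
    ]


def write_dataset(
    pairs: list[tuple[SequenceRecord, SequenceRecord]],
    spec: GenSpec,
    fasta_path: str | Path,
    line_width: int = 70,
) -> None:
    """Write pairs as multiFASTA plus a JSON sidecar recording the spec."""
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        for ref, mut in pairs:
            for rec in (ref, mut):
                fh.write(f">{rec.id}\n")
                for start in range(0, len(rec.seq), line_width):
                    fh.write(rec.seq[start : start + line_width] + "\n")
    sidecar = fasta_path.with_suffix(fasta_path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
        fh.write("\n")
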