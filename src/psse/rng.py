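"""48-bit LCG random number generation and Fisher-Yates permutation.

The permutation null needs thousands of independent, reproducible shuffles of
the subject sequence.  Each shuffle gets its own LCG stream: a master stream
seeded from the run seed emits one 31-bit seed per permutation, and each
permutation then draws from a fresh stream started at its own seed.  Any
single permutation can therefore be regenerated in isolation.

The generator is the POSIX ``lrand48`` linear congruential generator:

    state' = (a * state + c) mod 2**48,   a = 0x5DEECE66D, c = 11

seeded srand48-style (``state = (seed << 16) | 0x330E``) and returning the
top 31 bits of the successor state per draw.

The shuffle is the descending Durstenfeld/Fisher-Yates schedule: for
``i = n-1 .. 1``, ``j = draw mod (i+1)``, swap positions ``i`` and ``j``.
The ``mod`` reduction carries a modulo bias that is negligible for sequence
lengths far below 2**31 and keeps the per-step cost to one draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

LCG_MULTIPLIER = 25214903917  # 0x5DEECE66D
LCG_INCREMENT = 11
LCG_MODULUS = 1 << 48
_SEED_LOW_BITS = 0x330E
_STATE_MASK = LCG_MODULUS - 1


class Lrand48:
    """An lrand48-compatible 31-bit pseudorandom stream."""

    __slots__ = ("state",)

    def __init__(self, seed: int):
        if seed < 0:
            raise ValueError(f"seed must be nonnegative, got {seed}")
        self.state = (((seed % (1 << 32)) << 16) | _SEED_LOW_BITS) & _STATE_MASK

    def next(self) -> int:
        """Advance the state and return the top 31 bits (in [0, 2**31))."""
        self.state = (LCG_MULTIPLIER * self.state + LCG_INCREMENT) & _STATE_MASK
        return self.state >> 17


@dataclass(frozen=True)
class PermutationPlan:
    """Per-permutation seeds derived from one master seed."""

    master_seed: int
    n_permutations: int
    seeds: tuple

    def __post_init__(self):
        assert len(self.seeds) == self.n_permutations


def derive_permutation_seeds(master_seed: int, n_permutations: int) -> PermutationPlan:
    """Derive one independent 31-bit stream seed per permutation.

    Seed ``i`` is the ``i``-th draw of a master stream seeded with
    ``master_seed``, so plans are deterministic and any suffix of a longer
    plan extends a shorter one.
    """
    if n_permutations < 1:
        raise ValueError(f"need at least one permutation, got {n_permutations}")
    master = Lrand48(master_seed)
    seeds = tuple(master.next() for _ in range(n_permutations))
    return PermutationPlan(master_seed, n_permutations, seeds)


@njit(cache=True)
def _shuffle_codes(codes, seed):
    """Fisher-Yates shuffle of a uint8 code array driven by one LCG stream."""
    out = codes.copy()
    state = np.uint64((np.uint64(seed) << np.uint64(16)) | np.uint64(0x330E))
    mask = np.uint64(0xFFFFFFFFFFFF)
    a = np.uint64(25214903917)
    c = np.uint64(11)
    n = out.shape[0]
    for i in range(n - 1, 0, -1):
        state = (a * state + c) & mask
        draw = state >> np.uint64(17)
        j = int(draw % np.uint64(i + 1))
        tmp = out[i]
        out[i] = out[j]
        out[j] = tmp
    return out


def permute_codes(codes: np.ndarray, stream_seed: int) -> np.ndarray:
    """Shuffle an encoded sequence with a fresh stream seeded at ``stream_seed``."""
    return _shuffle_codes(
        np.ascontiguousarray(codes, dtype=np.uint8), stream_seed % (1 << 32)
    )


def permute_sequence(sequence, stream_seed: int):
    """Return a permuted copy of ``sequence`` (identical residue multiset)."""
    from .seq_io import Sequence, codes_to_residues

    shuffled = permute_codes(sequence.codes(), stream_seed)
    return Sequence(
        id=f"{sequence.id}|perm{stream_seed}",
        residues=codes_to_residues(shuffled),
    )
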