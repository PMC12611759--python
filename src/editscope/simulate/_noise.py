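"""Per-base sequencing noise: i.i.d. substitutions plus short indels.

The error model is intentionally simple — independent per-base
substitutions and 1-2 bp insertions/deletions (geometric length, capped
at 2) — enough to stress error-tolerant primer matching and size filters
without modelling homopolymer-dependent error.
"""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def add_noise(
    seq: str,
    rng: np.random.Generator,
    substitution_rate: float,
    indel_rate: float,
) -> str:
    """Apply substitutions then short indels to one sequence."""
    if substitution_rate <= 0 and indel_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    if substitution_rate > 0 and n:
        mask = rng.random(n) < substitution_rate
        n_sub = int(mask.sum())
        if n_sub:
            idx = _BASE_INDEX[arr[mask]].astype(np.int64)
            shift = rng.integers(1, 4, size=n_sub)
            arr[mask] = _BASES[(idx + shift) % 4]
    if indel_rate > 0 and n:
        positions = np.where(rng.random(n) < indel_rate)[0]
        if len(positions):
            is_ins = rng.random(len(positions)) < 0.5
            lengths = np.minimum(rng.geometric(0.5, size=len(positions)), 2)
            pieces: list[np.ndarray] = []
            cursor = 0
            for pos, ins, ln in zip(positions, is_ins, lengths):
                pos = int(pos)
                if pos < cursor:  # swallowed by a previous deletion
                    continue
                if ins:
                    pieces.append(arr[cursor:pos])
                    pieces.append(_BASES[rng.integers(0, 4, size=int(ln))])
                    cursor = pos
                else:
                    pieces.append(arr[cursor:pos])
                    cursor = min(n, pos + int(ln))
            pieces.append(arr[cursor:])
            arr = np.concatenate(pieces)
    return bytes(arr).decode()
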