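"""Small sequence/RNG helpers shared across modules."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte codes for A/C/G/T as stored in np.frombuffer of ASCII sequences
BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.int8) - 1
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """ASCII bytes of a sequence as a uint8 array (zero-copy view)."""
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def seq_codes(seq: str) -> np.ndarray:
    """Sequence as 0..3 base codes; -1 for non-ACGT."""
    return _CODE[seq_to_array(seq)]


def sample_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample generator derived by stable hashing of (master, sample id)."""
    tag = zlib.crc32(sample_id.encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag]))


def apply_errors(seqs: list[str], error_rate: float,
                 rng: np.random.Generator) -> list[str]:
    """Apply independent per-base substitution errors to a list of reads."""
    if error_rate <= 0.0 or not seqs:
        return list(seqs)
    out = []
    for seq in seqs:
        n = rng.binomial(len(seq), error_rate)
        if n == 0:
            out.append(seq)
            continue
        pos = rng.choice(len(seq), size=n, replace=False)
        chars = list(seq)
        for p in pos:
            alts = [b for b in "ACGT" if b != chars[p]]
            chars[p] = alts[rng.integers(3)]
        out.append("".join(chars))
    return out
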