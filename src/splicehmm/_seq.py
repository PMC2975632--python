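"""Nucleotide encoding helpers shared across modules.

Bases are encoded as small integers so that genome/read comparisons are plain
numpy equality tests:

* genome bases: A=0, C=1, G=2, T=3, N(and anything else)=4
* read bases:   A=0, C=1, G=2, T=3, N(and anything else)=5

A read 'N' (code 5) therefore mismatches every genome base, including genome
'N' (code 4), which is the policy for ambiguous calls.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# complement for codes; N-codes map to themselves
_COMP_CODE = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str, n_code: int = 4) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (see module docstring)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()
    if n_code != 4:
        arr[arr == 4] = n_code
    return arr


def encode_read(seq: str) -> np.ndarray:
    """Encode a read so ambiguous bases mismatch everything (N -> 5)."""
    return encode(seq, n_code=5)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return _COMP_CODE[arr][::-1]


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTNN"[c] for c in arr)
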