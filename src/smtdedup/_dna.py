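"""Small DNA-string helpers shared across modules.

Tags (SMTs) are frequently manipulated in bulk, so an integer packing
(2 bits per base, A=0 C=1 G=2 T=3) is provided alongside plain strings.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> 2-bit code lookup for fast bulk encoding
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def is_acgt(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq)


def encode_tag(tag: str) -> int:
    """Pack an ACGT string into an integer, 2 bits per base.

    Raises ValueError on any non-ACGT character (N tags are filtered
    upstream of any code path that packs).
    """
    code = 0
    for c in tag:
        v = _CODE[ord(c)]
        if v < 0:
            raise ValueError(f"non-ACGT base {c!r} in tag {tag!r}")
        code = (code << 2) | int(v)
    return code


def decode_tag(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def encode_tags(tags: np.ndarray | list[str]) -> np.ndarray:
    """Vectorised encode_tag for same-length ACGT strings."""
    arr = np.asarray(tags, dtype="U")
    if arr.size == 0:
        return np.empty(0, dtype=np.int64)
    length = len(arr.flat[0])
    mat = arr.view(np.uint32).reshape(arr.size, -1)[:, :length]
    codes_2bit = _CODE[np.minimum(mat, 255)]
    if (codes_2bit < 0).any():
        raise ValueError("non-ACGT base in tag set")
    weights = (4 ** np.arange(length - 1, -1, -1)).astype(np.int64)
    return (codes_2bit.astype(np.int64) * weights).sum(axis=1)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))
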