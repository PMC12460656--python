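"""Lempel–Ziv 1976 parsing complexity of a binary sequence.

The counter follows the Kaspar–Schuster pointer formulation of the
exhaustive-history parsing: scan the sequence, at each step finding the
longest prefix of the remaining suffix that already occurs in the text
seen so far (occurrences may run into the current word), and start a new
word one symbol beyond it.  The final, possibly incomplete, word is
counted.  Complexity is O(n·c) for a sequence of length n with c words.

The hot loop is JIT-compiled with numba when available; otherwise an
identical pure-Python loop is used.
"""

from __future__ import annotations

import numpy as np


def _lz76_py(b: np.ndarray) -> int:
    n = b.size
    if n < 2:
        return 0 if n == 0 else 1
    i = 0
    c = 1
    l = 1
    k = 1
    kmax = 1
    while True:
        if b[i + k - 1] == b[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > kmax:
                kmax = k
            i += 1
            if i == l:
                c += 1
                l += kmax
                if l + 1 > n:
                    break
                i = 0
                k = 1
                kmax = 1
            else:
                k = 1
    return c


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _lz76_jit = njit(cache=True)(_lz76_py)

    def _lz76_core(b: np.ndarray) -> int:
        return int(_lz76_jit(b))

except Exception:  # pragma: no cover
    _lz76_core = _lz76_py


def lz76_count(bits) -> int:
    """Number of words in the LZ76 exhaustive-history parsing of ``bits``.

    Parameters
    ----------
    bits : sequence of 0/1 (array, list, or string of '0'/'1')

    Returns
    -------
    int
        Word count, final incomplete word included.
    """
    if isinstance(bits, str):
        arr = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(bits)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("lz76_count expects a binary {0,1} sequence")
    if arr.size == 0:
        raise ValueError("empty sequence")
    if arr.size == 1:
        return 1
    return _lz76_core(np.ascontiguousarray(arr, dtype=np.uint8))
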