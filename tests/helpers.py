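"""Independent oracles used by the test suite."""

from __future__ import annotations


def _occurs_in_history(s: str, i: int, length: int) -> bool:
    """Does s[i:i+length] occur in s[0:i+length-1]? (explicit scan)"""
    word = s[i:i + length]
    window = s[:i + length - 1]
    for start in range(len(window) - length + 1):
        if window[start:start + length] == word:
            return True
    return False


def lz76_exhaustive_oracle(bits) -> int:
    """Brute-force exhaustive-history LZ76 word count.

    Each new word is the shortest substring starting at the current
    position that does not occur anywhere in the text seen so far
    (occurrences may run into the word, stopping one symbol short of
    its end); the final, possibly incomplete, word is counted.
    Occurrence is checked by explicit position-by-position scanning,
    independent of the production parser.
    """
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    count = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n and _occurs_in_history(s, i, length):
            length += 1
        count += 1  # complete word, or the final incomplete one
        i += length
    return count


def holm_oracle(pvals, alpha=0.05):
    """Step-down Holm decisions by direct enumeration.

    Returns booleans in input order: walk the sorted p-values,
    rejecting while p <= alpha / (m - rank), stopping at the first
    failure.
    """
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    reject = [False] * m
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject
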