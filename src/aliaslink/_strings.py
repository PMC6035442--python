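"""String comparators and phonetic codes used by the linkage engine.

Implements the Jaro and Jaro-Winkler similarities and American Soundex.
These are the standard comparators of probabilistic record linkage; they
are implemented here directly (pure Python, no third-party dependency)
and validated in the test suite against the classic worked examples
(MARTHA/MARHTA, DIXON/DICKSONX, ...).
"""

from __future__ import annotations

from functools import lru_cache

__all__ = ["jaro", "jaro_winkler", "soundex"]


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity in [0, 1].

    Characters match if equal and within ``floor(max(len)/2) - 1``
    positions of each other; the similarity combines the matched
    fraction of each string with the transposition count.
    """
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(len1, len2) // 2 - 1
    if window < 0:
        window = 0
    flags1 = [False] * len1
    flags2 = [False] * len2
    matches = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not flags2[j] and s2[j] == c:
                flags1[i] = True
                flags2[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # transpositions: matched characters out of order, counted in halves
    transpositions = 0
    j = 0
    for i in range(len1):
        if flags1[i]:
            while not flags2[j]:
                j += 1
            if s1[i] != s2[j]:
                transpositions += 1
            j += 1
    t = transpositions / 2
    m = matches
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler(s1: str, s2: str, prefix_scale: float = 0.1) -> float:
    """Jaro-Winkler similarity: Jaro boosted by shared prefix length.

    The boost is ``prefix_scale`` per shared leading character (maximum
    four), applied to the distance remaining above the Jaro score. The
    conventional scale 0.1 keeps the result within [0, 1].
    """
    j = jaro(s1, s2)
    prefix = 0
    for a, b in zip(s1[:4], s2[:4]):
        if a != b:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1.0 - j)


_SOUNDEX_CODES = {
    **dict.fromkeys("BFPV", "1"),
    **dict.fromkeys("CGJKQSXZ", "2"),
    **dict.fromkeys("DT", "3"),
    "L": "4",
    **dict.fromkeys("MN", "5"),
    "R": "6",
}


@lru_cache(maxsize=65536)
def soundex(name: str) -> str:
    """American Soundex code (letter + three digits), '' for empty input.

    H and W are transparent between consonants of equal code; vowels
    break runs. Used as a phonetic blocking key, not a comparator.
    """
    s = "".join(c for c in name.upper() if c.isalpha())
    if not s:
        return ""
    first = s[0]
    digits = [_SOUNDEX_CODES.get(first, "")]
    for c in s[1:]:
        if c in "HW":
            continue
        code = _SOUNDEX_CODES.get(c, "")
        if code and code != digits[-1]:
            digits.append(code)
        elif not code:
            digits.append("")  # vowel: breaks adjacency
    coded = [d for d in digits[1:] if d]
    return (first + "".join(coded)[:3]).ljust(4, "0")
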