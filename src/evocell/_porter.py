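"""Porter-family suffix-stripping stemmer.

Implements the classic Porter (1980) algorithm with one extension in step 1a:
the Greco-Latin endings ``-sis`` and ``-ses`` both reduce to ``-s``, so
singular/plural pairs such as "analysis"/"analyses" or "crisis"/"crises" map
to a single stem. Plain Porter sends them to different stems ("analysi" vs
"analys"), which defeats word-variant matching of publication titles.

Pure string function; no external models or wordlists.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        # y is a vowel when preceded by a consonant (or at a soft boundary)
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC blocks in the [C](VC)^m[V] decomposition."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        cons = _is_consonant(stem, i)
        if prev_vowel and cons:
            m += 1
        prev_vowel = not cons
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace_longest(word: str, rules: list[tuple[str, str]], min_m: int) -> str:
    """Apply the longest matching suffix rule, gated on measure(stem) > min_m.

    Porter semantics: the longest matching suffix decides which rule is in
    play; if its condition fails no rule in the step fires.
    """
    for suffix, repl in sorted(rules, key=lambda r: -len(r[0])):
        if word.endswith(suffix):
            stem = word[: len(word) - len(suffix)]
            if _measure(stem) > min_m:
                return stem + repl
            return word
    return word


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def stem(word: str) -> str:
    """Stem a single lowercase token."""
    w = word
    if len(w) <= 2:
        return w

    # Step 1a — plurals, with the -sis/-ses unification extension
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("sis"):
        w = w[:-2]
    elif w.endswith("ses"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b — -eed / -ed / -ing
    fired = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        w = w[:-2]
        fired = True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = w[:-3]
        fired = True
    if fired:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_consonant(w) and w[-1] not in "lsz":
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"

    # Step 1c — terminal y
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    w = _replace_longest(w, _STEP2, 0)
    w = _replace_longest(w, _STEP3, 0)

    # Step 4 — drop residual derivational suffixes when m > 1
    for suffix in sorted(_STEP4, key=len, reverse=True):
        if w.endswith(suffix):
            stem_ = w[: len(w) - len(suffix)]
            if _measure(stem_) > 1 and (suffix != "ion" or stem_.endswith(("s", "t"))):
                w = stem_
            break

    # Step 5a — terminal e
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _ends_cvc(w[:-1])):
            w = w[:-1]

    # Step 5b — terminal double l
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        w = w[:-1]

    return w
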