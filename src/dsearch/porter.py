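"""Classic Porter stemming algorithm (the original 1980 formulation).

The stemmer reduces inflected English word forms to a common stem
("expression" -> "express", "sequencing" -> "sequenc"). It is the
normalization step used throughout the engine, applied after lowercasing
and stopword removal. Only the original algorithm is implemented --
not the later "Porter2"/English revision -- because index terms, query
terms and any fixture vocabularies must all agree on one dialect.

Words of length <= 2 are returned unchanged. Input is assumed to be a
single lowercase token; digits are treated as consonants, which leaves
alphanumeric biomedical symbols ("tp53", "5s") untouched by the
letter-suffix rules.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        # y is a consonant at the start of a word or after a vowel
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions in the collapsed c/v form."""
    flags: list[bool] = []
    for i in range(len(stem)):
        c = _is_cons(stem, i)
        if not flags or flags[-1] != c:
            flags.append(c)
    return sum(1 for i in range(1, len(flags)) if flags[i] and not flags[i - 1])


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return len(word) >= 2 and word[-1] == word[-2] and _is_cons(word, len(word) - 1)


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant, where the final consonant is not w, x or y
    if len(word) < 3:
        return False
    n = len(word)
    return (
        _is_cons(word, n - 3)
        and not _is_cons(word, n - 2)
        and _is_cons(word, n - 1)
        and word[-1] not in "wxy"
    )


# (suffix, replacement) rule tables; within a step the longest matching
# suffix is selected first and is the only rule considered.
_STEP2 = (
    ("ization", "ize"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("ational", "ate"), ("tional", "tion"),
    ("biliti", "ble"), ("entli", "ent"), ("ousli", "ous"),
    ("ation", "ate"), ("alism", "al"), ("aliti", "al"), ("iviti", "ive"),
    ("enci", "ence"), ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
    ("alli", "al"), ("ator", "ate"), ("eli", "e"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ness", ""), ("ful", ""),
)

_STEP4 = (
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ion", "ism", "ate", "iti", "ous", "ive", "ize",
    "al", "er", "ic", "ou",
)


def _longest_suffix(word: str, suffixes) -> str | None:
    best = None
    for s in suffixes:
        if word.endswith(s) and (best is None or len(s) > len(best)):
            best = s
    return best


def stem(word: str) -> str:
    if len(word) <= 2:
        return word

    # Step 1a: plurals
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith("ies"):
        word = word[:-2]
    elif word.endswith("ss"):
        pass
    elif word.endswith("s"):
        word = word[:-1]

    # Step 1b: -ed / -ing
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            word = word[:-1]
    else:
        stripped = False
        if word.endswith("ed") and _has_vowel(word[:-2]):
            word = word[:-2]
            stripped = True
        elif word.endswith("ing") and _has_vowel(word[:-3]):
            word = word[:-3]
            stripped = True
        if stripped:
            if word.endswith(("at", "bl", "iz")):
                word += "e"
            elif _ends_double_cons(word) and word[-1] not in "lsz":
                word = word[:-1]
            elif _measure(word) == 1 and _ends_cvc(word):
                word += "e"

    # Step 1c: y -> i
    if word.endswith("y") and _has_vowel(word[:-1]):
        word = word[:-1] + "i"

    # Step 2
    sfx = _longest_suffix(word, [s for s, _ in _STEP2])
    if sfx is not None:
        rep = dict(_STEP2)[sfx]
        stem_part = word[: -len(sfx)]
        if _measure(stem_part) > 0:
            word = stem_part + rep

    # Step 3
    sfx = _longest_suffix(word, [s for s, _ in _STEP3])
    if sfx is not None:
        rep = dict(_STEP3)[sfx]
        stem_part = word[: -len(sfx)]
        if _measure(stem_part) > 0:
            word = stem_part + rep

    # Step 4
    sfx = _longest_suffix(word, _STEP4)
    if sfx is not None:
        stem_part = word[: -len(sfx)]
        if _measure(stem_part) > 1:
            if sfx != "ion" or (stem_part and stem_part[-1] in "st"):
                word = stem_part

    # Step 5a: final -e
    if word.endswith("e"):
        a = word[:-1]
        m = _measure(a)
        if m > 1 or (m == 1 and not _ends_cvc(a)):
            word = a

    # Step 5b: -ll -> -l
    if _measure(word) > 1 and _ends_double_cons(word) and word.endswith("l"):
        word = word[:-1]

    return word
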