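"""English (Porter2) Snowball stemmer.

A faithful implementation of the Snowball "english" stemming algorithm:
regions R1/R2, special-case words, and steps 0 through 5.  Word stems are
the feature unit for the bag-of-words representation, so inflections such
as "radiation" / "radiating" collapse to one column ("radiat").
"""

from __future__ import annotations

__all__ = ["stem"]

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDING = frozenset("cdeghkmnrt")

# Irregular forms handled before the algorithm proper.
_EXCEPTIONS = {
    "skis": "ski", "skies": "sky",
    "dying": "die", "lying": "lie", "tying": "tie",
    "idly": "idl", "gently": "gentl", "ugly": "ugli",
    "early": "earli", "only": "onli", "singly": "singl",
    "sky": "sky", "news": "news", "howe": "howe",
    "atlas": "atlas", "cosmos": "cosmos", "bias": "bias", "andes": "andes",
}

# Invariant after step 1a.
_EXCEPTIONS_1A = frozenset(
    {"inning", "outing", "canning", "herring", "earring", "proceed", "exceed", "succeed"}
)

_SPECIAL_PREFIXES = ("gener", "commun", "arsen")


def _is_vowel(word: str, i: int) -> bool:
    return word[i] in _VOWELS  # 'Y' (uppercase) marks a consonantal y


def _mark_consonant_y(word: str) -> str:
    chars = list(word)
    if chars[0] == "y":
        chars[0] = "Y"
    for i in range(1, len(chars)):
        if chars[i] == "y" and chars[i - 1] in _VOWELS:
            chars[i] = "Y"
    return "".join(chars)


def _region_after_vc(word: str, start: int) -> int:
    """Position after the first non-vowel following a vowel, from ``start``."""
    i = start
    n = len(word)
    while i < n and not _is_vowel(word, i):
        i += 1
    while i < n and _is_vowel(word, i):
        i += 1
    return min(i + 1, n) if i < n else n


def _r1(word: str) -> int:
    for prefix in _SPECIAL_PREFIXES:
        if word.startswith(prefix):
            return len(prefix)
    return _region_after_vc(word, 0)


def _r2(word: str, r1: int) -> int:
    return _region_after_vc(word, r1)


def _ends_short_syllable(word: str) -> bool:
    n = len(word)
    if n == 2:
        return _is_vowel(word, 0) and not _is_vowel(word, 1)
    if n < 3:
        return False
    return (
        not _is_vowel(word, n - 3)
        and _is_vowel(word, n - 2)
        and not _is_vowel(word, n - 1)
        and word[n - 1] not in "wxY"
    )


def _is_short(word: str) -> bool:
    return _ends_short_syllable(word) and _r1(word) >= len(word)


def _has_vowel(word: str) -> bool:
    return any(c in _VOWELS for c in word)


def _step0(word: str) -> str:
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            return word[: -len(suf)]
    return word


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith(("ied", "ies")):
        return word[:-2] if len(word) > 4 else word[:-1]
    if word.endswith(("us", "ss")):
        return word
    if word.endswith("s") and _has_vowel(word[:-2]):
        return word[:-1]
    return word


def _step1b(word: str, r1: int) -> str:
    for suf in ("eedly", "eed"):
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                return word[: -len(suf)] + "ee"
            return word
    for suf in ("ingly", "edly", "ing", "ed"):
        if word.endswith(suf):
            stem = word[: -len(suf)]
            if not _has_vowel(stem):
                return word
            if stem.endswith(("at", "bl", "iz")):
                return stem + "e"
            if stem.endswith(_DOUBLES):
                return stem[:-1]
            if _is_short(stem):
                return stem + "e"
            return stem
    return word


def _step1c(word: str) -> str:
    if len(word) > 2 and word[-1] in "yY" and not _is_vowel(word, len(word) - 2):
        return word[:-1] + "i"
    return word


_STEP2 = (
    ("ization", "ize"), ("ational", "ate"), ("fulness", "ful"), ("ousness", "ous"),
    ("iveness", "ive"), ("tional", "tion"), ("biliti", "ble"), ("lessli", "less"),
    ("entli", "ent"), ("ation", "ate"), ("alism", "al"), ("aliti", "al"),
    ("ousli", "ous"), ("iviti", "ive"), ("fulli", "ful"), ("enci", "ence"),
    ("anci", "ance"), ("abli", "able"), ("izer", "ize"), ("ator", "ate"),
    ("alli", "al"), ("bli", "ble"), ("ogi", "og"), ("li", ""),
)


def _step2(word: str, r1: int) -> str:
    for suf, repl in _STEP2:
        if word.endswith(suf):
            if len(word) - len(suf) < r1:
                return word
            if suf == "ogi":
                if word.endswith("logi"):
                    return word[:-3] + "og"
                return word
            if suf == "li":
                if len(word) >= 3 and word[-3] in _LI_ENDING:
                    return word[:-2]
                return word
            return word[: -len(suf)] + repl
    return word


_STEP3 = (
    ("ational", "ate"), ("tional", "tion"), ("alize", "al"), ("icate", "ic"),
    ("iciti", "ic"), ("ative", ""), ("ical", "ic"), ("ness", ""), ("ful", ""),
)


def _step3(word: str, r1: int, r2: int) -> str:
    for suf, repl in _STEP3:
        if word.endswith(suf):
            if len(word) - len(suf) < r1:
                return word
            if suf == "ative" and len(word) - len(suf) < r2:
                return word
            return word[: -len(suf)] + repl
    return word


_STEP4 = (
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ism", "ate", "iti", "ous", "ive", "ize",
    "ion", "al", "er", "ic",
)


def _step4(word: str, r2: int) -> str:
    for suf in _STEP4:
        if word.endswith(suf):
            if len(word) - len(suf) < r2:
                return word
            if suf == "ion":
                if len(word) >= 5 and word[-4] in "st":
                    return word[:-3]
                return word
            return word[: -len(suf)]
    return word


def _step5(word: str, r1: int, r2: int) -> str:
    if word.endswith("e"):
        if len(word) - 1 >= r2:
            return word[:-1]
        if len(word) - 1 >= r1 and not _ends_short_syllable(word[:-1]):
            return word[:-1]
        return word
    if word.endswith("l") and len(word) - 1 >= r2 and len(word) >= 2 and word[-2] == "l":
        return word[:-1]
    return word


def stem(word: str) -> str:
    """Return the Snowball English stem of ``word`` (lowercased)."""
    word = word.lower()
    if word.startswith("'"):
        word = word[1:]
    if len(word) <= 2:
        return word
    if word in _EXCEPTIONS:
        return _EXCEPTIONS[word]
    word = _mark_consonant_y(word)
    word = _step0(word)
    word = _step1a(word)
    if word in _EXCEPTIONS_1A:
        return word
    r1 = _r1(word)
    r2 = _r2(word, r1)
    word = _step1b(word, r1)
    word = _step1c(word)
    # regions are positions in the (possibly shortened) word; recompute so
    # later steps measure against the current form
    r1 = _r1(word)
    r2 = _r2(word, r1)
    word = _step2(word, r1)
    word = _step3(word, r1, r2)
    word = _step4(word, r2)
    word = _step5(word, r1, r2)
    return word.replace("Y", "y")
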