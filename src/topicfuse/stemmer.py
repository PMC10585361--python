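"""English Snowball (Porter2) stemmer.

A from-scratch implementation of the Porter2 algorithm, the English stemmer
of the Snowball project.  Only lowercase input is expected (the preprocessing
pipeline case-folds before stemming); uppercase ``Y`` is used internally to
mark consonant-y and is folded back before returning.
"""

from __future__ import annotations

__all__ = ["stem"]

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_VALID = frozenset("cdeghkmnrt")

# Irregular forms handled before the main algorithm.
_EXCEPTIONS_1 = {
    "skis": "ski",
    "skies": "sky",
    "dying": "die",
    "lying": "lie",
    "tying": "tie",
    "idly": "idl",
    "gently": "gentl",
    "ugly": "ugli",
    "early": "earli",
    "only": "onli",
    "singly": "singl",
    "sky": "sky",
    "news": "news",
    "howe": "howe",
    "atlas": "atlas",
    "cosmos": "cosmos",
    "bias": "bias",
    "andes": "andes",
}

# Invariant forms checked after step 1a.
_EXCEPTIONS_2 = frozenset(
    ["inning", "outing", "canning", "herring", "earring",
     "proceed", "exceed", "succeed"]
)

_SPECIAL_P1_PREFIXES = ("gener", "commun", "arsen")

_STEP2_RULES = [
    # (suffix, replacement); scanned longest-first; None replacement handled
    # separately ("ogi" and "li" have side conditions).
    ("ization", "ize"),
    ("ational", "ate"),
    ("fulness", "ful"),
    ("ousness", "ous"),
    ("iveness", "ive"),
    ("tional", "tion"),
    ("biliti", "ble"),
    ("lessli", "less"),
    ("entli", "ent"),
    ("ation", "ate"),
    ("alism", "al"),
    ("aliti", "al"),
    ("ousli", "ous"),
    ("iviti", "ive"),
    ("fulli", "ful"),
    ("enci", "ence"),
    ("anci", "ance"),
    ("abli", "able"),
    ("izer", "ize"),
    ("ator", "ate"),
    ("alli", "al"),
    ("bli", "ble"),
]

_STEP3_RULES = [
    ("ational", "ate"),
    ("tional", "tion"),
    ("alize", "al"),
    ("icate", "ic"),
    ("iciti", "ic"),
    ("ical", "ic"),
    ("ness", ""),
    ("ful", ""),
]

_STEP4_SUFFIXES = (
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ism", "ate", "iti", "ous", "ive", "ize",
    "al", "er", "ic",
)


def _is_vowel(ch: str) -> bool:
    return ch in _VOWELS


def _regions(word: str) -> tuple[int, int]:
    """Return (p1, p2): start offsets of regions R1 and R2.

    R1 is the region after the first non-vowel following a vowel; R2 is the
    same definition applied within R1.  Words beginning gener-/commun-/arsen-
    have R1 fixed after the prefix.
    """
    n = len(word)
    p1 = n
    for pre in _SPECIAL_P1_PREFIXES:
        if word.startswith(pre):
            p1 = len(pre)
            break
    else:
        for i in range(1, n):
            if not _is_vowel(word[i]) and _is_vowel(word[i - 1]):
                p1 = i + 1
                break
    p2 = n
    for i in range(p1 + 1, n):
        if not _is_vowel(word[i]) and _is_vowel(word[i - 1]):
            p2 = i + 1
            break
    return p1, p2


def _ends_short_syllable(word: str) -> bool:
    """True if the word ends in a short syllable.

    Either a vowel at the start followed by a non-vowel, or non-vowel,
    vowel, non-vowel(≠ w, x, Y) at the end.
    """
    n = len(word)
    if n == 2:
        return _is_vowel(word[0]) and not _is_vowel(word[1])
    if n >= 3:
        a, b, c = word[-3], word[-2], word[-1]
        return (not _is_vowel(a)) and _is_vowel(b) and (not _is_vowel(c)) \
            and c not in "wxY"
    return False


def _is_short(word: str, p1: int) -> bool:
    return p1 >= len(word) and _ends_short_syllable(word)


def _contains_vowel(s: str) -> bool:
    return any(_is_vowel(ch) for ch in s)


def stem(word: str) -> str:
    """Stem a single lowercase word with the Porter2 English algorithm."""
    if len(word) <= 2:
        return word
    if word.startswith("'"):
        word = word[1:]
    if word in _EXCEPTIONS_1:
        return _EXCEPTIONS_1[word]

    # Mark consonant y as Y: at the start, or after a vowel.
    if word.startswith("y"):
        word = "Y" + word[1:]
    chars = list(word)
    for i in range(1, len(chars)):
        if chars[i] == "y" and _is_vowel(chars[i - 1]):
            chars[i] = "Y"
    word = "".join(chars)

    p1, p2 = _regions(word)

    # Step 0: strip apostrophe suffixes.
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            word = word[: -len(suf)]
            break

    # Step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-3] + ("i" if len(word) > 4 else "ie")
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s"):
        # Delete if a vowel occurs anywhere before the penultimate letter.
        if _contains_vowel(word[:-2]):
            word = word[:-1]

    if word in _EXCEPTIONS_2:
        return word

    # Step 1b
    ed_ing = None
    for suf in ("ingly", "edly", "ing", "ed"):
        if word.endswith(suf):
            ed_ing = suf
            break
    if word.endswith(("eedly", "eed")):
        suf = "eedly" if word.endswith("eedly") else "eed"
        if len(word) - len(suf) >= p1:
            word = word[: -len(suf)] + "ee"
    elif ed_ing is not None:
        trunk = word[: -len(ed_ing)]
        if _contains_vowel(trunk):
            word = trunk
            if word.endswith(("at", "bl", "iz")):
                word += "e"
            elif word.endswith(_DOUBLES):
                word = word[:-1]
            elif _is_short(word, p1):
                word += "e"

    # Step 1c: y -> i after a non-vowel that is not the first letter.
    if len(word) > 2 and word[-1] in "yY" and not _is_vowel(word[-2]):
        word = word[:-1] + "i"

    # Step 2 (suffix must lie in R1)
    for suf, repl in _STEP2_RULES:
        if word.endswith(suf):
            if len(word) - len(suf) >= p1:
                word = word[: -len(suf)] + repl
            break
    else:
        if word.endswith("ogi"):
            if len(word) - 3 >= p1 and word.endswith("logi"):
                word = word[:-1]
        elif word.endswith("li"):
            if len(word) - 2 >= p1 and word[-3] in _LI_VALID:
                word = word[:-2]

    # Step 3 (suffix in R1; "ative" needs R2)
    if word.endswith("ative"):
        if len(word) - 5 >= p1 and len(word) - 5 >= p2:
            word = word[:-5]
    else:
        for suf, repl in _STEP3_RULES:
            if word.endswith(suf):
                if len(word) - len(suf) >= p1:
                    word = word[: -len(suf)] + repl
                break

    # Step 4 (suffix in R2)
    if word.endswith("ion"):
        if len(word) - 3 >= p2 and word[-4] in "st":
            word = word[:-3]
    else:
        for suf in _STEP4_SUFFIXES:
            if word.endswith(suf):
                if len(word) - len(suf) >= p2:
                    word = word[: -len(suf)]
                break

    # Step 5
    if word.endswith("e"):
        if len(word) - 1 >= p2:
            word = word[:-1]
        elif len(word) - 1 >= p1 and not _ends_short_syllable(word[:-1]):
            word = word[:-1]
    elif word.endswith("l"):
        if len(word) - 1 >= p2 and len(word) >= 2 and word[-2] == "l":
            word = word[:-1]

    return word.replace("Y", "y")
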