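"""Snowball English ("Porter2") stemming algorithm.

A self-contained implementation of the English stemmer from the Snowball
project.  The stemmer is the normalisation step that lets morphological
variants of a lay health term (``fatigue``, ``fatigues``, ``fatigued``,
``fatiguing``) collapse onto a single vocabulary entry (``fatigu``) so that
corpus statistics, ground-truth terms and lexicon insertions all live in the
same token space.

Only the English algorithm is provided; ``get_stemmer`` exists so that the
rest of the package refers to stemmers by identifier and alternative
algorithms can be registered later.
"""

from __future__ import annotations

from typing import Callable

__all__ = ["snowball_english", "get_stemmer", "UnknownStemmerError"]

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_VALID_LI = frozenset("cdeghkmnrt")

# Irregular forms handled before the algorithm proper.
_EXCEPTION1 = {
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

# Stems left alone after step 1a.
_EXCEPTION2 = frozenset(
    {"inning", "outing", "canning", "herring", "earring", "proceed", "exceed", "succeed"}
)

_STEP2_RULES = [
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
    ("ful", ""),
    ("ness", ""),
]

_STEP4_SUFFIXES = [
    "ement",
    "ance",
    "ence",
    "able",
    "ible",
    "ment",
    "ant",
    "ent",
    "ism",
    "ate",
    "iti",
    "ous",
    "ive",
    "ize",
    "ion",
    "al",
    "er",
    "ic",
]


def _is_vowel(word: str, i: int) -> bool:
    return word[i] in _VOWELS


def _compute_r1(word: str) -> int:
    # Special prefixes whose R1 is fixed regardless of vowel structure.
    for prefix in ("gener", "commun", "arsen"):
        if word.startswith(prefix):
            return len(prefix)
    for i in range(1, len(word)):
        if not _is_vowel(word, i) and _is_vowel(word, i - 1):
            return i + 1
    return len(word)


def _compute_r2(word: str, r1: int) -> int:
    for i in range(r1 + 1, len(word)):
        if not _is_vowel(word, i) and _is_vowel(word, i - 1):
            return i + 1
    return len(word)


def _ends_short_syllable(word: str) -> bool:
    n = len(word)
    if n == 2:
        return _is_vowel(word, 0) and not _is_vowel(word, 1)
    if n >= 3:
        # non-vowel, vowel, non-vowel other than w/x/Y
        return (
            not _is_vowel(word, n - 3)
            and _is_vowel(word, n - 2)
            and word[n - 1] not in _VOWELS
            and word[n - 1] not in "wxY"
        )
    return False


def _contains_vowel(word: str) -> bool:
    return any(c in _VOWELS for c in word)


def snowball_english(word: str) -> str:
    """Stem a single lowercase word with the Snowball English algorithm."""
    word = word.lower()
    if word.startswith("'"):
        word = word[1:]
    if len(word) <= 2:
        return word
    if word in _EXCEPTION1:
        return _EXCEPTION1[word]

    # Mark consonantal y as Y so it is not treated as a vowel.
    chars = list(word)
    if chars[0] == "y":
        chars[0] = "Y"
    for i in range(1, len(chars)):
        if chars[i] == "y" and chars[i - 1] in _VOWELS:
            chars[i] = "Y"
    word = "".join(chars)

    r1 = _compute_r1(word)
    r2 = _compute_r2(word, r1)

    # Step 0: strip possessive endings.
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            word = word[: -len(suf)]
            break

    # Step 1a.
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-2] if len(word) > 4 else word[:-1]
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s"):
        if any(c in _VOWELS for c in word[:-2]):
            word = word[:-1]

    if word in _EXCEPTION2:
        return word

    # Step 1b.
    step1b_deleted = False
    if word.endswith(("eedly", "eed")):
        suf = "eedly" if word.endswith("eedly") else "eed"
        if len(word) - len(suf) >= r1:
            word = word[: -len(suf)] + "ee"
    else:
        for suf in ("ingly", "edly", "ing", "ed"):
            if word.endswith(suf):
                stem = word[: -len(suf)]
                if _contains_vowel(stem):
                    word = stem
                    step1b_deleted = True
                break
    if step1b_deleted:
        if word.endswith(("at", "bl", "iz")):
            word += "e"
        elif word.endswith(_DOUBLES):
            word = word[:-1]
        elif r1 >= len(word) and _ends_short_syllable(word):
            word += "e"

    # Step 1c: y -> i after a non-vowel that is not word-initial.
    if (
        len(word) > 2
        and word[-1] in "yY"
        and word[-2] not in _VOWELS
    ):
        word = word[:-1] + "i"

    # Step 2.
    for suf, repl in _STEP2_RULES:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                word = word[: -len(suf)] + repl
            break
    else:
        if word.endswith("ogi"):
            if len(word) - 3 >= r1 and len(word) >= 4 and word[-4] == "l":
                word = word[:-1]
        elif word.endswith("li"):
            if len(word) - 2 >= r1 and len(word) >= 3 and word[-3] in _VALID_LI:
                word = word[:-2]

    # Step 3.
    for suf, repl in _STEP3_RULES:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                word = word[: -len(suf)] + repl
            break
    else:
        if word.endswith("ative"):
            if len(word) - 5 >= r1 and len(word) - 5 >= r2:
                word = word[:-5]

    # Step 4.
    for suf in _STEP4_SUFFIXES:
        if word.endswith(suf):
            if len(word) - len(suf) >= r2:
                if suf == "ion":
                    if len(word) >= 4 and word[-4] in "st":
                        word = word[:-3]
                else:
                    word = word[: -len(suf)]
            break

    # Step 5.
    if word.endswith("e"):
        if len(word) - 1 >= r2:
            word = word[:-1]
        elif len(word) - 1 >= r1 and not _ends_short_syllable(word[:-1]):
            word = word[:-1]
    elif word.endswith("l"):
        if len(word) - 1 >= r2 and len(word) >= 2 and word[-2] == "l":
            word = word[:-1]

    return word.replace("Y", "y")


_REGISTRY: dict[str, Callable[[str], str]] = {
    "snowball-english": snowball_english,
    "identity": lambda w: w,
}


class UnknownStemmerError(ValueError):
    """Raised when a stemmer identifier is not registered."""


def get_stemmer(stemmer_id: str) -> Callable[[str], str]:
    """Look up a stemming function by identifier.

    ``"snowball-english"`` is the pipeline default; ``"identity"`` disables
    stemming (useful for pre-stemmed or artificial corpora).
    """
    try:
        return _REGISTRY[stemmer_id]
    except KeyError:
        raise UnknownStemmerError(
            f"unknown stemmer {stemmer_id!r}; available: {sorted(_REGISTRY)}"
        ) from None
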