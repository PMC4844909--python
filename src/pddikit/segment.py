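"""Deterministic, abbreviation-aware sentence segmentation.

Drug label prose is segmented once, at corpus load, so that every annotation
source anchors PDDI mentions to the same sentence indices.  The splitter is
rule based: a sentence ends at ``.``, ``!`` or ``?`` followed by whitespace
and an upper-case letter, digit or end of text, unless the token ending at
the period is a known abbreviation (packaged list, e.g. "e.g.", "i.v.",
"Dr.").  Decimal points and offsets inside tokens never split.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

_TERMINATORS = ".!?"


@lru_cache(maxsize=1)
def default_abbreviations() -> frozenset[str]:
    """Lower-cased abbreviations (with trailing period) shipped with the package."""
    text = (
        resources.files("pddikit.data").joinpath("abbreviations.txt").read_text()
    )
    abbrevs = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            abbrevs.add(line.lower())
    return frozenset(abbrevs)


def _token_ending_at(text: str, end: int) -> str:
    """The whitespace-delimited token whose last character is ``text[end]``."""
    start = end
    while start > 0 and not text[start - 1].isspace():
        start -= 1
    return text[start : end + 1]


def segment_sentences(
    text: str, abbreviations: frozenset[str] | None = None
) -> list[tuple[int, int]]:
    """Split ``text`` into sorted, non-overlapping sentence intervals.

    Returns 0-based half-open ``(start, end)`` pairs.  Every non-whitespace
    character falls inside exactly one interval; whitespace between sentences
    is unassigned.  Empty or all-whitespace input yields ``[]``.
    """
    if abbreviations is None:
        abbreviations = default_abbreviations()
    boundaries: list[int] = []  # indices one past a sentence-final terminator
    n = len(text)
    i = 0
    while i < n:
        ch = text[i]
        if ch in _TERMINATORS:
            # absorb runs like "?!" or "..."
            j = i
            while j + 1 < n and text[j + 1] in _TERMINATORS:
                j += 1
            follows_ws = j + 1 >= n or text[j + 1].isspace()
            if follows_ws:
                nxt = j + 1
                while nxt < n and text[nxt].isspace():
                    nxt += 1
                next_ok = nxt >= n or text[nxt].isupper() or text[nxt].isdigit()
                token = _token_ending_at(text, j).lower()
                is_abbrev = ch == "." and token in abbreviations
                if next_ok and not is_abbrev:
                    boundaries.append(j + 1)
            i = j + 1
        else:
            i += 1
    if not boundaries or boundaries[-1] < n:
        boundaries.append(n)

    spans: list[tuple[int, int]] = []
    start = 0
    for b in boundaries:
        chunk = text[start:b]
        # trim unassigned whitespace from both ends
        lstrip = len(chunk) - len(chunk.lstrip())
        rstrip = len(chunk) - len(chunk.rstrip())
        s, e = start + lstrip, b - rstrip
        if s < e:
            spans.append((s, e))
        start = b
    return spans


_WORD_RE = re.compile(r"\S+")


def nonspace_coverage(text: str, spans: list[tuple[int, int]]) -> bool:
    """True iff every non-whitespace character lies inside one of ``spans``."""
    covered = set()
    for s, e in spans:
        covered.update(range(s, e))
    return all(
        i in covered
        for m in _WORD_RE.finditer(text)
        for i in range(m.start(), m.end())
    )
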