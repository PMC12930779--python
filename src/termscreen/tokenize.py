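"""Deterministic text normalization shared by documents and keywords.

The term score only consumes token counts, so tokenization is deliberately
simple: Unicode NFKC, lowercase, punctuation stripped, split on whitespace.
Keywords pass through the same pipeline at registry-insertion time, so phrase
and document tokens match by construction.  No stemming by default.
"""

from __future__ import annotations

import unicodedata
from typing import Callable, Optional

__all__ = ["tokenize_text", "normalize_phrase"]


def _strip_punct(text: str) -> str:
    # replace punctuation/symbol characters with spaces so "e.g.,word" splits
    return "".join(
        " " if unicodedata.category(ch)[0] in ("P", "S") else ch for ch in text
    )


def tokenize_text(text: Optional[str],
                  stemmer: Optional[Callable[[str], str]] = None) -> list[str]:
    """Tokenize free text into normalized word tokens.

    Absent text yields an empty list.  An optional ``stemmer`` hook is applied
    per token; it is off for all reference computations.
    """
    if not text:
        return []
    norm = unicodedata.normalize("NFKC", text).lower()
    tokens = _strip_punct(norm).split()
    if stemmer is not None:
        tokens = [stemmer(t) for t in tokens]
    return tokens


def normalize_phrase(phrase: str) -> str:
    """Normalize a keyword phrase to its canonical stored form."""
    return " ".join(tokenize_text(phrase))
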