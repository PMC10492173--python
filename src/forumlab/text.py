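"""Deterministic text normalization for the screening classifier.

Tokenizer rule (fixed and tested): lowercase; split on anything that is not
a letter or an in-number decimal point — so slashes split tokens and
``lh/fsh 2.2`` tokenizes to ``[lh, fsh, <NUM>]`` — and every numeral run
(with optional decimal part) becomes the number-class token ``<NUM>``.
"""
from __future__ import annotations

import re

NUM_TOKEN = "<NUM>"

_TOKEN_RE = re.compile(r"\d+(?:\.\d+)?|[a-zµ%]+")


def preprocess(text: str) -> list[str]:
    """Normalize raw post text into a token sequence."""
    tokens = []
    for tok in _TOKEN_RE.findall(text.lower()):
        tokens.append(NUM_TOKEN if tok[0].isdigit() else tok)
    return tokens
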