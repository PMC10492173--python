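"""Reading and writing the pipeline's standard formats.

Posts travel as JSON Lines in the Pushshift dialect (keys ``id``,
``author``, ``created_utc``, ``title``, ``selftext``); tables as TSV/CSV
with a header.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .types import ForumPost

log = logging.getLogger(__name__)


class DataError(ValueError):
    pass


def load_posts(path: str | Path, max_malformed_frac: float = 0.10) -> list[ForumPost]:
    """Load posts from JSONL, tolerant of extra keys and missing fields.

    Missing ``selftext``/``title`` become empty strings (with a warning);
    malformed lines are counted and reported; more than
    ``max_malformed_frac`` malformed lines is a hard error.
    """
    posts = []
    n_lines = 0
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            n_lines += 1
            try:
                raw = json.loads(line)
                if "title" not in raw or "selftext" not in raw:
                    log.warning("line %d: missing title/selftext, treated as empty",
                                lineno)
                posts.append(
                    ForumPost(
                        id=str(raw["id"]),
                        author=str(raw.get("author", "")),
                        created_utc=int(raw.get("created_utc", 0)),
                        title=str(raw.get("title", "") or ""),
                        selftext=str(raw.get("selftext", "") or ""),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                n_bad += 1
                log.warning("line %d: malformed (%s)", lineno, exc)
    if n_lines and n_bad / n_lines > max_malformed_frac:
        raise DataError(
            f"{n_bad}/{n_lines} malformed lines in {path} exceeds "
            f"{max_malformed_frac:.0%}"
        )
    return posts


def write_posts(posts: list[ForumPost], path: str | Path) -> None:
    with open(path, "w") as fh:
        for post in posts:
            fh.write(json.dumps(post.to_json_dict()) + "\n")


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    dialect: str = "tsv",
    decimals: int = 1,
    p_columns: tuple[str, ...] = ("p_tost", "p_directional", "p"),
) -> None:
    """Write a table as TSV/CSV with a header.

    Float columns print at ``decimals`` places (counts as whole numbers);
    p-value columns print at 4 places with the ``<.001`` convention.
    """
    if dialect not in ("tsv", "csv"):
        raise DataError(f"unknown dialect {dialect!r}")
    out = frame.copy()
    for col in out.columns:
        if col in p_columns:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else ("<.001" if v < 0.001 else f"{v:.3f}")
            )
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{decimals}f}"
            )
    out.to_csv(path, sep="\t" if dialect == "tsv" else ",", index=False)
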