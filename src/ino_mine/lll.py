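"""Summary statistics over an interaction-type annotation table.

The benchmark annotation of the LLL challenge corpus (one row per annotated
gene/protein interaction: sentence, entity pair, signalling keywords, and
the assigned interaction-type class) is distributed as supplementary
material and is *not* shipped here; this module parses any table in that
shape and computes the dataset-level statistics the benchmark is usually
summarized by: sentence and interaction counts, the single- vs
multi-keyword split, the two-keyword subset, and the number of distinct
interaction classes.
"""

from __future__ import annotations

from typing import IO

import pandas as pd

from .errors import InoMineError

__all__ = ["load_annotations", "summarize_annotations"]

REQUIRED_COLUMNS = ("sentence_id", "entity_a", "entity_b", "keywords", "ino_class")


def load_annotations(source: IO[str] | str) -> pd.DataFrame:
    """Read an annotation TSV with columns
    ``sentence_id  entity_a  entity_b  keywords  ino_class``
    (keywords ``//``-separated within the cell)."""
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise InoMineError(f"annotation table missing column(s): {sorted(missing)}")
    return df


def summarize_annotations(df: pd.DataFrame) -> dict[str, int]:
    """Dataset-level counts for an annotation table.

    ``n_keywords`` per interaction is the number of ``//``-separated
    keywords in its cell; interactions with an empty keyword cell count as
    zero-keyword and fall in neither the single- nor multi-keyword bucket.
    """
    n_kw = df["keywords"].map(
        lambda c: len([k for k in str(c).split("//") if k.strip()])
    )
    return {
        "sentences": int(df["sentence_id"].nunique()),
        "interactions": int(len(df)),
        "single_keyword_interactions": int((n_kw == 1).sum()),
        "multi_keyword_interactions": int((n_kw >= 2).sum()),
        "two_keyword_interactions": int((n_kw == 2).sum()),
        "distinct_classes": int(df.loc[df["ino_class"] != "", "ino_class"].nunique()),
    }
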