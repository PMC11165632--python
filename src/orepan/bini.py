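"""Biosynthetic Novelty Index (BiNI) scoring of strain BGC repertoires.

A strain's BiNI score is the mean nearest-gene-cluster-family distance of
its biosynthetic gene clusters, BiNI = sum(d) / n, where n is the total
number of clusters predicted for the strain and d is each cluster's
distance to its closest known gene cluster family.  Higher scores mean the
strain's biosynthetic repertoire sits farther from anything catalogued.  A
cluster whose distance exceeds 900 is individually flagged novel; distances
below the flag threshold still enter the sum (published per-strain scores
below 900 are only possible that way).  Missing distances contribute zero
to the sum but still count in n; per-strain coverage reports their impact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

NOVELTY_THRESHOLD = 900.0


def novelty_flag(d: float | None, threshold: float = NOVELTY_THRESHOLD) -> bool | None:
    """True iff a cluster's GCF distance strictly exceeds the threshold.

    A missing distance is unknown (``None``), never False.
    """
    if d is None or (isinstance(d, float) and math.isnan(d)):
        return None
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    return d > threshold


@dataclass(frozen=True)
class BiniRow:
    strain: str
    n: int            # total predicted clusters, with or without a distance
    sum_d: float
    score: float      # sum_d / n
    n_novel: int      # clusters with distance > threshold
    coverage: float   # fraction of clusters that have a distance


def read_bgc_table(path) -> pd.DataFrame:
    """Read a BGC TSV (strain, region, type, distance; distance may be empty)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("strain", "region", "type", "distance"):
        if col not in df.columns:
            raise ValueError(f"BGC table {path} is missing column {col!r}")
    dup = df.duplicated(subset=["strain", "region"])
    if dup.any():
        raise ValueError("duplicate (strain, region) rows in BGC table")
    if (df["distance"].dropna() < 0).any():
        raise ValueError("negative GCF distance in BGC table")
    return df


def bini_score(bgc_table: pd.DataFrame, strain: str,
               threshold: float = NOVELTY_THRESHOLD) -> BiniRow | None:
    """Score one strain: BiNI = sum of available distances / total cluster count."""
    rows = bgc_table[bgc_table["strain"] == strain]
    n = len(rows)
    if n == 0:
        logger.warning("strain %s has no clusters; skipped", strain)
        return None
    distances = rows["distance"].dropna()
    sum_d = float(distances.sum())
    n_novel = int((distances > threshold).sum())
    coverage = len(distances) / n
    if coverage == 0:
        logger.warning("strain %s has no cluster distances; score is 0", strain)
    return BiniRow(strain=strain, n=n, sum_d=sum_d, score=sum_d / n,
                   n_novel=n_novel, coverage=coverage)


def score_all(bgc_table: pd.DataFrame,
              threshold: float = NOVELTY_THRESHOLD) -> pd.DataFrame:
    """BiNI rows for every strain in the table, as a DataFrame."""
    rows = []
    for strain in sorted(bgc_table["strain"].unique()):
        row = bini_score(bgc_table, strain, threshold=threshold)
        if row is not None:
            rows.append(row.__dict__)
    return pd.DataFrame(rows, columns=["strain", "n", "sum_d", "score",
                                       "n_novel", "coverage"])


def rank_strains(scores: pd.DataFrame) -> pd.DataFrame:
    """Strains sorted by descending BiNI score, ties broken alphabetically."""
    if scores.empty:
        raise ValueError("no scored strains to rank")
    return scores.sort_values(["score", "strain"],
                              ascending=[False, True],
                              ignore_index=True)
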