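"""Taxon-KO abundance matrices from taxonomy and KO-annotation tables.

Consumes Bracken-style taxonomy reports and eggNOG-mapper-style KO annotation
tables and builds the normalized taxon-KO matrix: one row per
(dataset, KO) where a dataset is an environment x taxon-group combination
(e.g. ``PMT|Actinomycetota``), with raw query counts and counts-per-million
normalized against the dataset's mapped-read total.  Also provides taxon
relative-abundance summaries with a pooled "<1 %" bucket and the twofold
abundance screen used to contrast two environments.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BRACKEN_COLUMNS = [
    "name",
    "taxonomy_id",
    "taxonomy_lvl",
    "kraken_assigned_reads",
    "added_reads",
    "new_est_reads",
    "fraction_total_reads",
]

KO_PATTERN = re.compile(r"^K\d{5}$")

#: Annotation rows with this taxon-group label are excluded from the matrix.
EXCLUDED_GROUP = "Other"


@dataclass
class TaxonProfile:
    """A per-sample taxonomic abundance report (Bracken dialect)."""

    sample: str
    rows: pd.DataFrame  # columns: BRACKEN_COLUMNS

    def __post_init__(self) -> None:
        fr = self.rows["fraction_total_reads"].astype(float)
        if ((fr < 0) | (fr > 1)).any():
            bad = self.rows.loc[(fr < 0) | (fr > 1), "name"].tolist()
            raise ValueError(f"fraction_total_reads outside [0, 1] for {bad}")
        if (self.rows["new_est_reads"].astype(float) < 0).any():
            raise ValueError("negative estimated read counts")
        for lvl, grp in self.rows.groupby("taxonomy_lvl"):
            total = grp["fraction_total_reads"].astype(float).sum()
            if total > 1 + 1e-6:
                raise ValueError(f"fractions at rank {lvl!r} sum to {total} > 1")


def read_taxon_profile(path, sample: str | None = None) -> TaxonProfile:
    """Read a Bracken-report TSV into a :class:`TaxonProfile`.

    Raises a format error naming the first missing column.  An empty file
    yields an empty profile with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    for col in BRACKEN_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"taxonomy report {path} is missing column {col!r}")
    if df.empty:
        logger.warning("taxonomy report %s has no rows", path)
    name = sample if sample is not None else str(path)
    return TaxonProfile(sample=name, rows=df[BRACKEN_COLUMNS].copy())


def parse_ko_field(text: str) -> list[str]:
    """Split an eggNOG ``KEGG_ko`` cell into bare KO ids; ``-`` means none."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if text in ("", "-"):
        return []
    kos = []
    for token in text.split(","):
        ko = token.strip().removeprefix("ko:")
        if not KO_PATTERN.match(ko):
            raise ValueError(f"malformed KO identifier {token!r}")
        kos.append(ko)
    return kos


def read_annotations(path) -> pd.DataFrame:
    """Read an eggNOG-mapper-style annotation TSV.

    Uses the ``query`` and ``KEGG_ko`` columns plus a ``taxon_group`` column
    carrying the taxonomic bin of each query (``Actinomycetota``,
    ``Bacteria-other`` or ``Other``).  Comment lines starting with ``##``
    are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=_count_comment_lines(path))
    df.columns = [c.lstrip("#") for c in df.columns]
    for col in ("query", "KEGG_ko", "taxon_group"):
        if col not in df.columns:
            raise ValueError(f"annotation table {path} is missing column {col!r}")
    return df


def _count_comment_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                n += 1
            else:
                break
    return n


@dataclass
class TaxonKoMatrix:
    """Long-form taxon-KO matrix: counts and CPM per (dataset, KO).

    ``table`` columns: dataset, ko, raw, cpm.  ``mapped_totals`` holds the
    per-dataset mapped-read denominator used for CPM.
    """

    table: pd.DataFrame
    mapped_totals: dict[str, int] = field(default_factory=dict)

    @property
    def datasets(self) -> list[str]:
        return sorted(self.table["dataset"].unique())

    def ko_sets(self) -> dict[str, set[str]]:
        """Presence per dataset: a KO is present when its raw count is >= 1."""
        present = self.table[self.table["raw"] >= 1]
        sets = {d: set(g["ko"]) for d, g in present.groupby("dataset")}
        for d in self.datasets:
            sets.setdefault(d, set())
        return sets

    def check_cpm(self, tol: float = 1e-3) -> None:
        for dataset, grp in self.table.groupby("dataset"):
            if grp["raw"].sum() == 0:
                continue
            total = grp["cpm"].sum()
            if abs(total - 1e6) > tol:
                raise AssertionError(f"CPM of {dataset} sums to {total}, not 1e6")


def build_matrix(annotations: pd.DataFrame, group_by: dict[str, str] | None = None,
                 dataset_column: str = "dataset") -> TaxonKoMatrix:
    """Build the raw taxon-KO count matrix from annotation rows.

    Each annotation row carries a query id, its KO identifiers and a taxon
    group; rows labelled ``Other`` are excluded.  The dataset of a row is
    ``environment|taxon_group`` where the environment comes from
    ``group_by`` (mapping e.g. sample label -> environment) applied to the
    ``sample`` column, or from an explicit ``dataset`` column.  A query
    annotated with m KOs contributes one count to each of the m KOs.
    Duplicate query ids within a dataset raise (they would double count).
    """
    ann = annotations.copy()
    if dataset_column not in ann.columns:
        if group_by is None or "sample" not in ann.columns:
            raise ValueError("annotations need a 'dataset' column or group_by + 'sample'")
        ann[dataset_column] = (
            ann["sample"].map(group_by).str.cat(ann["taxon_group"], sep="|"))
    kept = ann[ann["taxon_group"] != EXCLUDED_GROUP]
    if kept.empty:
        logger.warning("all annotation rows excluded; matrix is empty")
        return TaxonKoMatrix(table=pd.DataFrame(columns=["dataset", "ko", "raw", "cpm"]))

    counts: dict[tuple[str, str], int] = {}
    rows_per_dataset: dict[str, int] = {}
    seen: dict[str, set[str]] = {}
    for dataset, query, ko_field in zip(
            kept[dataset_column], kept["query"], kept["KEGG_ko"]):
        if query in seen.setdefault(dataset, set()):
            raise ValueError(f"duplicate query id {query!r} in dataset {dataset!r}")
        seen[dataset].add(query)
        rows_per_dataset[dataset] = rows_per_dataset.get(dataset, 0) + 1
        for ko in parse_ko_field(ko_field):
            counts[(dataset, ko)] = counts.get((dataset, ko), 0) + 1

    table = pd.DataFrame(
        [{"dataset": d, "ko": k, "raw": c} for (d, k), c in sorted(counts.items())],
        columns=["dataset", "ko", "raw"])
    table["cpm"] = np.nan
    return TaxonKoMatrix(table=table, mapped_totals=dict(sorted(rows_per_dataset.items())))


def normalize_cpm(matrix: TaxonKoMatrix,
                  mapped_totals: dict[str, int] | None = None) -> TaxonKoMatrix:
    """Recompute CPM from raw counts: ``cpm = raw * 1e6 / mapped_total``.

    When no explicit totals are supplied, the per-dataset annotation-row
    counts recorded at matrix construction stand in for the mapped-read
    total.  Raw counts are never mutated.
    """
    totals = dict(mapped_totals) if mapped_totals is not None else dict(matrix.mapped_totals)
    table = matrix.table.copy()
    for dataset, grp in table.groupby("dataset"):
        raw_sum = grp["raw"].sum()
        total = totals.get(dataset, 0)
        if total <= 0:
            if raw_sum > 0:
                raise ValueError(f"dataset {dataset!r} has counts but mapped total {total}")
            continue
        table.loc[grp.index, "cpm"] = grp["raw"] * 1e6 / total
    return TaxonKoMatrix(table=table, mapped_totals=totals)


def write_matrix(matrix: TaxonKoMatrix, path) -> None:
    matrix.table.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> TaxonKoMatrix:
    table = pd.read_csv(path, sep="\t")
    return TaxonKoMatrix(table=table)


POOLED_LABEL_FMT = "<{:g} %"


def relative_abundance(profile: TaxonProfile, rank: str,
                       min_pct: float = 1.0) -> dict[str, float]:
    """Per-taxon percentage abundance at a rank, pooling rare taxa.

    Taxa whose estimated-read share falls below ``min_pct`` percent are
    pooled into a single ``"<min_pct %"`` bucket, as are unnamed/unknown
    taxa.  Percentages sum to 100.
    """
    rows = profile.rows[profile.rows["taxonomy_lvl"] == rank]
    if rows.empty:
        raise ValueError(f"no rows at rank {rank!r} in sample {profile.sample}")
    reads = rows.set_index("name")["new_est_reads"].astype(float)
    total = reads.sum()
    if total <= 0:
        raise ValueError(f"no reads at rank {rank!r} in sample {profile.sample}")
    pct = reads / total * 100.0
    pooled_label = POOLED_LABEL_FMT.format(min_pct)
    out: dict[str, float] = {}
    pooled = 0.0
    for name, p in pct.items():
        unknown = str(name).lower().startswith(("unknown", "unclassified"))
        if p < min_pct or unknown:
            pooled += p
        else:
            out[str(name)] = p
    if pooled > 0:
        out[pooled_label] = pooled
    return out


@dataclass(frozen=True)
class TwofoldResult:
    """Outcome of a twofold abundance screen between two conditions.

    ``flagged`` maps feature -> (ratio, direction) for features at least
    twofold different; ``exclusive_a``/``exclusive_b`` hold features with
    non-zero abundance on one side only (never ratio-flagged).
    """

    flagged: dict[str, tuple[float, str]]
    exclusive_a: frozenset[str]
    exclusive_b: frozenset[str]


def twofold_screen(a: dict[str, float], b: dict[str, float],
                   ratio: float = 2.0) -> TwofoldResult:
    """Features whose abundance differs at least ``ratio``-fold between a and b.

    The boundary is inclusive (exactly twofold is flagged).  Features absent
    (or zero) on one side are classed exclusive to the other rather than
    infinitely enriched.  Negative abundances are rejected.
    """
    for name, vals in (("a", a), ("b", b)):
        if any(v < 0 for v in vals.values()):
            raise ValueError(f"negative abundance in {name}")
    features = set(a) | set(b)
    flagged: dict[str, tuple[float, str]] = {}
    excl_a, excl_b = set(), set()
    for f in features:
        va, vb = a.get(f, 0.0), b.get(f, 0.0)
        if va > 0 and vb == 0:
            excl_a.add(f)
        elif vb > 0 and va == 0:
            excl_b.add(f)
        elif va > 0 and vb > 0:
            r = max(va, vb) / min(va, vb)
            if r >= ratio:
                flagged[f] = (r, "a" if va > vb else "b")
    return TwofoldResult(flagged=flagged,
                         exclusive_a=frozenset(excl_a),
                         exclusive_b=frozenset(excl_b))
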