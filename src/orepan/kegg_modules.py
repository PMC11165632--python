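"""Aggregation of the taxon-KO matrix into KEGG pathway/module abundances.

KOs are joined against a user-supplied map of KO -> (pathway, pathway
module).  Module relative abundance per environment is the share of that
environment's total weight (CPM by default, presence counts optionally)
carried by the module's member KOs; KOs missing from the map pool into an
``unmapped`` category so shares always sum to 100 %.  The same twofold
screen used for taxa applies at module level, and the unique (cloud) KOs of
an environment's dataset can be broken down into exclusive-pathway
proportions.
"""

from __future__ import annotations

import logging

import pandas as pd

from .ko_matrix import TaxonKoMatrix, TwofoldResult, twofold_screen
from .pan import PanPartition, unique_kos

logger = logging.getLogger(__name__)

UNMAPPED = "unmapped"


def read_module_map(path) -> pd.DataFrame:
    """Read a 3-column TSV (ko, pathway, module); duplicate (ko, pathway) rows reject."""
    df = pd.read_csv(path, sep="\t")
    for col in ("ko", "pathway", "module"):
        if col not in df.columns:
            raise ValueError(f"module map {path} is missing column {col!r}")
    dup = df.duplicated(subset=["ko", "pathway"])
    if dup.any():
        raise ValueError(f"duplicate (ko, pathway) rows in module map: "
                         f"{df.loc[dup, ['ko', 'pathway']].values.tolist()}")
    return df


def aggregate_by_module(matrix: TaxonKoMatrix, module_map: pd.DataFrame,
                        weight: str = "cpm", level: str = "module") -> pd.DataFrame:
    """Relative abundance (%) of each pathway module per dataset.

    ``weight`` is ``"cpm"`` (abundance-weighted) or ``"presence"`` (each
    present KO counts 1).  A KO mapped to k modules contributes its full
    weight to each, and such rows are flagged ``multi_module``; KOs absent
    from the map pool as ``unmapped``.  Returns a tidy frame
    (dataset, <level>, weight, percent, multi_module).
    """
    if module_map.empty:
        raise ValueError("module map is empty")
    if weight not in ("cpm", "presence"):
        raise ValueError(f"weight must be 'cpm' or 'presence', got {weight!r}")
    if level not in ("module", "pathway"):
        raise ValueError(f"level must be 'module' or 'pathway', got {level!r}")

    table = matrix.table[matrix.table["raw"] >= 1].copy()
    table["w"] = 1.0 if weight == "presence" else table["cpm"]
    mapped_kos = set(module_map["ko"])
    unmapped_kos = set(table["ko"]) - mapped_kos
    if unmapped_kos:
        logger.warning("%d KOs not covered by the module map", len(unmapped_kos))
    multiplicity = module_map.groupby("ko")[level].nunique()

    rows = []
    for dataset, grp in table.groupby("dataset"):
        total = grp["w"].sum()
        if total <= 0:
            continue
        merged = grp.merge(module_map, on="ko", how="left")
        merged[level] = merged[level].fillna(UNMAPPED)
        # a KO listed under k distinct groups keeps full weight in each
        agg = merged.drop_duplicates(["ko", level]).groupby(level)["w"].sum()
        for label, w in agg.items():
            members = set(merged.loc[merged[level] == label, "ko"])
            multi = any(multiplicity.get(ko, 0) > 1 for ko in members)
            rows.append({"dataset": dataset, level: label, "weight": w,
                         "percent": w / total * 100.0, "multi_module": multi})
    return pd.DataFrame(rows, columns=["dataset", level, "weight", "percent",
                                       "multi_module"])


def module_twofold(a: pd.DataFrame, b: pd.DataFrame,
                   level: str = "module", ratio: float = 2.0) -> TwofoldResult:
    """Twofold screen on module percentages of two single-dataset aggregates."""
    def as_dict(df: pd.DataFrame) -> dict[str, float]:
        if df["dataset"].nunique() > 1:
            raise ValueError("each side must cover a single dataset")
        return dict(zip(df[level], df["percent"]))
    return twofold_screen(as_dict(a), as_dict(b), ratio=ratio)


def exclusive_pathway_proportions(partition: PanPartition, module_map: pd.DataFrame,
                                  dataset: str, level: str = "pathway") -> dict[str, float]:
    """Pathway breakdown (%) of the KOs unique to one dataset.

    Uses the dataset's cloud KOs (present in it alone).  Each unique KO
    counts once per pathway it maps to; unmapped KOs report under
    ``unmapped``.  Percentages sum to 100; an empty unique set yields an
    empty dict with a warning.
    """
    uniques = unique_kos(partition, dataset)
    if not uniques:
        logger.warning("dataset %s has no unique KOs", dataset)
        return {}
    pairs: list[tuple[str, str]] = []
    mapped = module_map[module_map["ko"].isin(uniques)]
    for ko in uniques:
        labels = set(mapped.loc[mapped["ko"] == ko, level])
        if labels:
            pairs.extend((ko, lab) for lab in labels)
        else:
            pairs.append((ko, UNMAPPED))
    counts: dict[str, int] = {}
    for _, lab in pairs:
        counts[lab] = counts.get(lab, 0) + 1
    total = sum(counts.values())
    return {lab: c / total * 100.0 for lab, c in sorted(counts.items())}
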