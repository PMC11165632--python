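"""Pan-metagenome orthologue classification over four datasets.

Each KEGG orthologue (KO) observed in any of the four environment x
taxon-group datasets gets a 4-bit presence mask; the popcount of the mask
determines its pan class — present in all four datasets: *core*; exactly
three: *softcore*; exactly two: *shell*; one: *cloud*.  The same masks drive
the 15-region four-set Venn partition and the per-dataset unique-KO sets.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import pandas as pd

PAN_CLASSES = ("core", "softcore", "shell", "cloud")

_CLASS_BY_POPCOUNT = {4: "core", 3: "softcore", 2: "shell", 1: "cloud"}


def classify_pan(mask: tuple[bool, ...] | int) -> str:
    """Pan class of a 4-bit presence mask (tuple of 4 bools or an int 0-15)."""
    if isinstance(mask, int):
        bits = mask
    else:
        if len(mask) != 4:
            raise ValueError(f"presence mask must have 4 bits, got {len(mask)}")
        bits = sum(1 << i for i, b in enumerate(mask) if b)
    pop = bin(bits).count("1")
    if pop == 0:
        raise ValueError("KO absent from every dataset cannot be classified")
    if pop > 4:
        raise ValueError(f"mask {bits} has more than 4 bits set")
    return _CLASS_BY_POPCOUNT[pop]


@dataclass
class PanPartition:
    """Per-KO presence masks and pan classes over exactly four datasets."""

    datasets: tuple[str, str, str, str]
    masks: dict[str, tuple[bool, bool, bool, bool]]  # KO -> presence bits

    @property
    def classes(self) -> dict[str, str]:
        return {ko: classify_pan(m) for ko, m in self.masks.items()}

    def summary(self) -> dict[str, dict[str, float]]:
        """Class -> {count, fraction} over the union of the four KO sets."""
        counts = dict.fromkeys(PAN_CLASSES, 0)
        for cls in self.classes.values():
            counts[cls] += 1
        n = len(self.masks)
        return {cls: {"count": counts[cls],
                      "fraction": counts[cls] / n if n else 0.0}
                for cls in PAN_CLASSES}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"ko": ko,
                 "mask": "".join("1" if b else "0" for b in m),
                 "class": classify_pan(m)}
                for ko, m in sorted(self.masks.items())]
        return pd.DataFrame(rows, columns=["ko", "mask", "class"])


def pan_summary(ko_sets: dict[str, set[str]]) -> PanPartition:
    """Build the pan partition from four labelled KO presence sets."""
    if len(ko_sets) != 4:
        raise ValueError(f"pan classification is defined for 4 datasets, got {len(ko_sets)}")
    labels = tuple(sorted(ko_sets))
    union = set().union(*ko_sets.values())
    masks = {ko: tuple(ko in ko_sets[d] for d in labels) for ko in union}
    return PanPartition(datasets=labels, masks=masks)  # type: ignore[arg-type]


def unique_kos(partition: PanPartition, dataset: str) -> set[str]:
    """KOs present only in ``dataset`` (that dataset's cloud orthologues)."""
    if dataset not in partition.datasets:
        raise KeyError(f"unknown dataset {dataset!r}; have {partition.datasets}")
    idx = partition.datasets.index(dataset)
    return {ko for ko, m in partition.masks.items()
            if m[idx] and sum(m) == 1}


def venn_partition(ko_sets: dict[str, set[str]]) -> dict[frozenset[str], int]:
    """Counts for all 15 non-empty regions of the four-set Venn diagram.

    Region ``{A, B}`` counts KOs present in exactly A and B and no other
    set; regions are disjoint and sum to the size of the union.
    """
    if len(ko_sets) != 4:
        raise ValueError(f"Venn partition is defined for 4 sets, got {len(ko_sets)}")
    labels = sorted(ko_sets)
    regions: dict[frozenset[str], int] = {
        frozenset(combo): 0
        for r in range(1, 5)
        for combo in itertools.combinations(labels, r)
    }
    for ko in set().union(*ko_sets.values()):
        members = frozenset(d for d in labels if ko in ko_sets[d])
        regions[members] += 1
    return regions


def venn_to_frame(regions: dict[frozenset[str], int]) -> pd.DataFrame:
    rows = [{"region": "&".join(sorted(k)), "n_sets": len(k), "count": v}
            for k, v in regions.items()]
    return (pd.DataFrame(rows, columns=["region", "n_sets", "count"])
            .sort_values(["n_sets", "region"], ignore_index=True))


def write_summary_json(partition: PanPartition, path) -> None:
    payload = {
        "datasets": list(partition.datasets),
        "n_kos": len(partition.masks),
        "classes": partition.summary(),
        "unique": {d: len(unique_kos(partition, d)) for d in partition.datasets},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
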