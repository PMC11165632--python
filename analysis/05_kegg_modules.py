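"""Module-level metabolic profile: aggregation, twofold screen, exclusives.

Aggregates the taxon-KO matrix into pathway-module relative abundances per
dataset (CPM-weighted), screens the two Actinomycetota datasets for modules
at least twofold different between environments, and breaks the unique
(cloud) KOs of each Actinomycetota dataset into exclusive-pathway
proportions.
"""

import argparse
from pathlib import Path

from orepan.kegg_modules import (aggregate_by_module,
                                 exclusive_pathway_proportions,
                                 module_twofold, read_module_map)
from orepan.ko_matrix import read_matrix
from orepan.pan import pan_summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--matrix", default="results/matrix/taxon_ko_matrix.tsv")
    parser.add_argument("--map", dest="map_path",
                        default="results/simulated/module_map.tsv")
    parser.add_argument("--out", default="results/modules")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    matrix = read_matrix(args.matrix)
    module_map = read_module_map(args.map_path)
    agg = aggregate_by_module(matrix, module_map, weight="cpm")
    agg.to_csv(out / "module_abundance.tsv", sep="\t", index=False)

    acti = [d for d in matrix.datasets if d.endswith("|Actinomycetota")]
    if len(acti) == 2:
        a = agg[agg["dataset"] == acti[0]]
        b = agg[agg["dataset"] == acti[1]]
        screen = module_twofold(a, b)
        print(f"twofold screen {acti[0]} vs {acti[1]}: "
              f"{len(screen.flagged)} flagged, "
              f"{len(screen.exclusive_a) + len(screen.exclusive_b)} exclusive")
        for module, (ratio, side) in sorted(screen.flagged.items()):
            higher = acti[0] if side == "a" else acti[1]
            print(f"  {module}: {ratio:.2f}x higher in {higher}")

    partition = pan_summary(matrix.ko_sets())
    for dataset in acti:
        props = exclusive_pathway_proportions(partition, module_map, dataset)
        print(f"exclusive pathways of {dataset}: {len(props)} pathways over "
              f"the dataset's unique KOs")


if __name__ == "__main__":
    main()
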