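"""Build the CPM-normalized taxon-KO matrix from the simulated annotations.

Reads the eggNOG-style annotation table written by 01_simulate.py, counts
queries per (dataset, KO), normalizes to counts per million against each
dataset's mapped-read total and verifies that every dataset's CPM column
sums to one million.
"""

import argparse
from pathlib import Path

from orepan.ko_matrix import (build_matrix, normalize_cpm, read_annotations,
                              write_matrix)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--annotations", default="results/simulated/annotations.tsv")
    parser.add_argument("--out", default="results/matrix")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    matrix = normalize_cpm(build_matrix(read_annotations(args.annotations)))
    matrix.check_cpm()
    write_matrix(matrix, out / "taxon_ko_matrix.tsv")
    print(f"{len(matrix.table)} (dataset, KO) cells across "
          f"{len(matrix.datasets)} datasets; CPM sums verified at 1e6")
    for dataset, total in matrix.mapped_totals.items():
        print(f"  {dataset}: {total} mapped annotation rows")


if __name__ == "__main__":
    main()
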