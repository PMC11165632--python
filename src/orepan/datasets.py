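"""Published reference tables bundled as in-memory data.

Small tables transcribed from the source study of fluorite-mine soils:
the soil elemental analysis (concentrations in p.p.m. with ``"<N"``
censoring and the CRC crustal reference row) and the per-strain genome /
BGC summary of the six sequenced isolates.  They serve as worked-example
inputs for the geochemistry and BiNI stages.
"""

from __future__ import annotations

import pandas as pd

from .geochem import CRUSTAL_REFERENCE, Censored, GeochemTable, Value

_SOIL_ROWS: dict[str, dict[str, str | float]] = {
    # site: chloride, sulphate, nitrate, fluoride (p.p.m.), pH
    "Control":        {"chloride": "<50", "sulphate": "<50", "nitrate": "<10", "fluoride": "<10", "ph": 7.50},
    "Topaz Mountain": {"chloride": 2440, "sulphate": 5300,  "nitrate": 86,    "fluoride": 62,    "ph": 8.31},
    "Bell Hill":      {"chloride": 890,  "sulphate": 123,   "nitrate": 38,    "fluoride": 118,   "ph": 9.65},
    "Yellow Chief":   {"chloride": 185,  "sulphate": "<50", "nitrate": "<10", "fluoride": "<10", "ph": 8.48},
    "Minerva":        {"chloride": "<50", "sulphate": 752,  "nitrate": "<10", "fluoride": 44,    "ph": 7.31},
    "Hogg":           {"chloride": "<50", "sulphate": "<50", "nitrate": "<10", "fluoride": 99,   "ph": 7.03},
    "Spar pile":      {"chloride": "<50", "sulphate": "<50", "nitrate": "<10", "fluoride": 48,   "ph": 7.05},
    "PMT":            {"chloride": "<50", "sulphate": "<50", "nitrate": 22,   "fluoride": 18,    "ph": 8.33},
}


def soil_elemental_table(include_control: bool = False) -> GeochemTable:
    """The published soil elemental analysis as a :class:`GeochemTable`.

    ``include_control`` adds the potting-soil control row; by default only
    the mine sites are returned, matching the extreme-value annotations of
    the source table.
    """
    sites: list[str] = []
    values: dict[tuple[str, str], Value] = {}
    ph: dict[str, float] = {}
    for site, row in _SOIL_ROWS.items():
        if site == "Control" and not include_control:
            continue
        sites.append(site)
        for analyte in ("chloride", "sulphate", "nitrate", "fluoride"):
            cell = row[analyte]
            values[(site, analyte)] = (Censored(float(str(cell)[1:]))
                                       if isinstance(cell, str) else float(cell))
        ph[site] = float(row["ph"])
    return GeochemTable(sites=sites, values=values,
                        reference=dict(CRUSTAL_REFERENCE), ph=ph)


_STRAIN_ROWS = [
    # strain, environment, contigs, genome size (Mb), total BGCs, published BiNI
    ("BPP2",  "PMT",   64, 9.0,  32, 886.28),
    ("PMTA",  "PMT",   34, 8.1,  24, 951.0),
    ("PMTD",  "PMT",  155, 11.2, 39, 1002.0),
    ("PMTG",  "PMT",   37, 9.7,  42, 1304.71),
    ("S1A",   "Topaz",  6, 8.3,  32, 1086.43),
    ("BPT11", "Topaz", 82, 2.7,   6, 769.66),
]


def strain_summary() -> pd.DataFrame:
    """Genome and BGC summary of the six sequenced mine isolates.

    Columns: strain, environment, contigs, genome_mb, total_bgcs, and the
    published per-strain biosynthetic novelty score (``bini``), used as a
    ranking input in worked examples.
    """
    return pd.DataFrame(
        _STRAIN_ROWS,
        columns=["strain", "environment", "contigs", "genome_mb",
                 "total_bgcs", "bini"],
    )
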