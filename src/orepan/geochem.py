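"""Soil elemental-analysis tables: fold enrichment and extreme-value flags.

Concentrations (p.p.m.) of soluble anions (chloride, sulphate, nitrate,
fluoride) measured in mine soils are compared against average crustal
reference abundances.  Values below the instrument detection limit are
*censored* and rendered ``"<N"`` in CSV; censored cells never enter a fold
computation but do participate in "lowest value" flags.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field

import pandas as pd

ANALYTES = ("chloride", "sulphate", "nitrate", "fluoride")

#: Average abundance in the Earth's continental crust (p.p.m.), the
#: denominator used for soil fold-enrichment factors.
CRUSTAL_REFERENCE: dict[str, float] = {
    "chloride": 145.0,
    "sulphate": 350.0,
    "nitrate": 19.0,
    "fluoride": 585.0,
}


@dataclass(frozen=True)
class Censored:
    """A below-detection-limit measurement, e.g. ``Censored(50)`` for "<50"."""

    limit: float

    def __post_init__(self) -> None:
        if not self.limit > 0:
            raise ValueError(f"censoring limit must be positive, got {self.limit}")

    def __str__(self) -> str:  # CSV dialect of the source tables
        return f"<{self.limit:g}"


Value = float | Censored


def parse_value(text: str) -> Value:
    """Parse a concentration cell; ``"<N"`` (whitespace tolerated) is censored."""
    text = text.strip()
    if text.startswith("<"):
        return Censored(float(text[1:].strip()))
    value = float(text)
    if value < 0:
        raise ValueError(f"concentration must be non-negative, got {value}")
    return value


@dataclass
class GeochemTable:
    """Site x analyte concentrations plus per-analyte reference values.

    ``values`` maps ``(site, analyte)`` to a concentration or a
    :class:`Censored` limit; ``ph`` is optional per site.
    """

    sites: list[str]
    values: dict[tuple[str, str], Value]
    reference: dict[str, float] = field(default_factory=lambda: dict(CRUSTAL_REFERENCE))
    ph: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (site, analyte), v in self.values.items():
            if isinstance(v, float) and v < 0:
                raise ValueError(f"negative concentration at ({site}, {analyte})")
        for analyte in self.analytes():
            if analyte not in self.reference:
                raise ValueError(f"no reference value for analyte {analyte!r}")
            if not self.reference[analyte] > 0:
                raise ValueError(f"reference for {analyte!r} must be positive")

    def analytes(self) -> list[str]:
        seen: list[str] = []
        for _, analyte in self.values:
            if analyte not in seen:
                seen.append(analyte)
        return seen


def fold_enrichment(observed: Value, reference: float) -> float | None:
    """Fold enrichment of an observed concentration over a reference.

    Returns ``observed / reference`` rounded half-up to one decimal (the
    precision the source tables print, e.g. chloride 2440/145 -> 16.8).
    A censored observation is not computable and yields ``None``.
    """
    if isinstance(observed, Censored):
        return None
    if not reference > 0:
        raise ValueError(f"reference must be positive, got {reference}")
    if observed < 0:
        raise ValueError(f"observed must be non-negative, got {observed}")
    ratio = decimal.Decimal(observed) / decimal.Decimal(reference)
    return float(ratio.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def fold_table(table: GeochemTable) -> pd.DataFrame:
    """Fold enrichment for every (site, analyte); censored cells are NaN."""
    rows = []
    for site in table.sites:
        for analyte in table.analytes():
            if (site, analyte) not in table.values:
                continue
            fold = fold_enrichment(table.values[(site, analyte)], table.reference[analyte])
            rows.append({"site": site, "analyte": analyte,
                         "fold": math.nan if fold is None else fold})
    return pd.DataFrame(rows, columns=["site", "analyte", "fold"])


@dataclass(frozen=True)
class ExtremeFlags:
    """Per-analyte extreme sites: ``highest`` is None when every cell is censored."""

    highest: frozenset[str] | None
    lowest: frozenset[str]


def flag_extremes(table: GeochemTable) -> dict[str, ExtremeFlags]:
    """Flag the highest and lowest site(s) per analyte.

    The highest value is the maximum over uncensored cells.  Censored cells
    tie as joint lowest whenever their limit does not exceed the minimum
    uncensored value (a "<50" cell is below any measured 185); with no
    censored cells the minimum uncensored value is lowest.  Ties are
    reported as sets.
    """
    flags: dict[str, ExtremeFlags] = {}
    for analyte in table.analytes():
        cells = {s: table.values[(s, analyte)]
                 for s in table.sites if (s, analyte) in table.values}
        if not cells:
            continue
        uncensored = {s: v for s, v in cells.items() if isinstance(v, float)}
        censored = {s: v.limit for s, v in cells.items() if isinstance(v, Censored)}

        if uncensored:
            hi = max(uncensored.values())
            highest: frozenset[str] | None = frozenset(
                s for s, v in uncensored.items() if v == hi)
        else:
            highest = None

        min_unc = min(uncensored.values()) if uncensored else math.inf
        low_censored = {s for s, lim in censored.items() if lim <= min_unc}
        if low_censored:
            lowest = frozenset(low_censored)
        else:
            lowest = frozenset(s for s, v in uncensored.items() if v == min_unc)
        flags[analyte] = ExtremeFlags(highest=highest, lowest=lowest)
    return flags


def read_table(path, reference: dict[str, float] | None = None) -> GeochemTable:
    """Read a wide CSV (site, one column per analyte, optional pH).

    Censored cells are encoded ``"<N"``.  ``reference`` defaults to the
    crustal abundances; a row whose site is ``Reference`` overrides it.
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "site" not in df.columns:
        raise ValueError("geochemistry CSV must have a 'site' column")
    analytes = [c for c in df.columns if c in ANALYTES]
    ref = dict(reference or CRUSTAL_REFERENCE)

    sites: list[str] = []
    values: dict[tuple[str, str], Value] = {}
    ph: dict[str, float] = {}
    for _, row in df.iterrows():
        site = str(row["site"]).strip()
        if site.lower() == "reference":
            for analyte in analytes:
                if pd.notna(row[analyte]):
                    ref[analyte] = float(row[analyte])
            continue
        sites.append(site)
        for analyte in analytes:
            if pd.notna(row[analyte]) and str(row[analyte]).strip():
                values[(site, analyte)] = parse_value(str(row[analyte]))
        if "ph" in df.columns and pd.notna(row["ph"]):
            ph[site] = float(row["ph"])
    return GeochemTable(sites=sites, values=values, reference=ref, ph=ph)


def write_table(table: GeochemTable, path) -> None:
    """Write the wide CSV layout; censored cells round-trip as ``"<N"``."""
    analytes = table.analytes()
    rows = []
    for site in table.sites:
        row: dict[str, object] = {"site": site}
        for analyte in analytes:
            v = table.values.get((site, analyte))
            row[analyte] = "" if v is None else (str(v) if isinstance(v, Censored) else f"{v:g}")
        if site in table.ph:
            row["ph"] = table.ph[site]
        rows.append(row)
    cols = ["site", *analytes] + (["ph"] if table.ph else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
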