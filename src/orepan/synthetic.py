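"""Synthetic inputs with planted ground truth for every pipeline stage.

Emulates the four study conditions the pipeline consumes, with no external
data: (a) four taxon-KO count datasets (two environments x two taxon
groups) whose per-KO presence patterns realize configurable
core/softcore/shell/cloud fractions; (b) MS/MS spectrum collections with
planted compound families whose members share fragment ions; (c) per-strain
BGC tables with known gene-cluster-family distance distributions; (d) soil
geochemistry tables with known fold factors over crustal reference values.
Every generator is deterministic given a seed, and the planted truth is
returned alongside the data so downstream stages can be checked for exact
recovery in the noise-free regime.

Counts are drawn from an over-dispersed (negative-binomial) model shifted
to be strictly positive; downstream presence is binary, so the particular
count model only has to be positive and reproducible.  Planted fragment
m/z values sit on a 0.1 Da grid with disjoint blocks per compound family,
so a 0.03 Da matching tolerance can never cross-match fragments of
different families and ground-truth network edges are unambiguous.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geochem import Censored, GeochemTable
from .ko_matrix import BRACKEN_COLUMNS
from .network import Spectrum

logger = logging.getLogger(__name__)

ENVIRONMENTS = ("PMT", "Topaz")
TAXON_GROUPS = ("Actinomycetota", "Bacteria")
#: The four pan-metagenome datasets, in canonical order.
DATASETS = tuple(f"{env}|{grp}" for env in ENVIRONMENTS for grp in TAXON_GROUPS)

_CLASS_POPCOUNT = {"core": 4, "softcore": 3, "shell": 2, "cloud": 1}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the conditions the tests use."""

    seed: int = 0
    n_kos: int = 400
    target_fractions: dict[str, float] = field(
        default_factory=lambda: {"core": 0.25, "softcore": 0.25,
                                 "shell": 0.25, "cloud": 0.25})
    reads_per_dataset: int = 4000
    n_strains: int = 6
    n_compound_families: int = 3
    replicates_per_compound: int = 4
    peaks_per_spectrum: tuple[int, int] = (6, 10)
    mz_noise_sd: float = 0.0           # Da
    bgc_per_strain: tuple[int, int] = (6, 42)
    distance_range: tuple[float, float] = (600.0, 1400.0)
    geochem_folds: dict[str, float] = field(
        default_factory=lambda: {"chloride": 16.8, "sulphate": 15.1,
                                 "nitrate": 4.5, "fluoride": 0.1})
    count_mean: float = 10.0           # NB mean per present (dataset, KO) cell
    count_dispersion: float = 2.0      # NB size parameter r

    def __post_init__(self) -> None:
        total = sum(self.target_fractions.values())
        if any(f < 0 for f in self.target_fractions.values()):
            raise ValueError("target fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target fractions must sum to 1, got {total}")
        if set(self.target_fractions) != set(_CLASS_POPCOUNT):
            raise ValueError("target_fractions needs exactly the keys "
                             "core/softcore/shell/cloud")
        for name in ("n_kos", "reads_per_dataset", "n_strains",
                     "n_compound_families", "replicates_per_compound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.mz_noise_sd < 0:
            raise ValueError("mz_noise_sd must be non-negative")
        if self.peaks_per_spectrum[0] < 4:
            raise ValueError(
                "peaks_per_spectrum lower bound must be >= 4: families sharing "
                "fewer fragments cannot pass a 4-matched-ion network threshold")
        if self.distance_range[0] < 0 or self.distance_range[1] < self.distance_range[0]:
            raise ValueError("distance_range must be a non-negative ordered pair")
        if any(v <= 0 for v in self.geochem_folds.values()):
            raise ValueError("geochem folds must be positive")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, one entry per generated object."""

    ko_class: dict[str, str] = field(default_factory=dict)
    compound_family: dict[str, int] = field(default_factory=dict)
    strain_bini: dict[str, float] = field(default_factory=dict)
    geochem_fold: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "ko_class": self.ko_class,
            "compound_family": self.compound_family,
            "strain_bini": self.strain_bini,
            "geochem_fold": {f"{s}|{a}": v for (s, a), v in self.geochem_fold.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            ko_class=payload["ko_class"],
            compound_family={k: int(v) for k, v in payload["compound_family"].items()},
            strain_bini=payload["strain_bini"],
            geochem_fold={tuple(k.split("|", 1)): v
                          for k, v in payload["geochem_fold"].items()},
        )


def _class_counts(config: SyntheticConfig) -> dict[str, int]:
    """Integer KOs per pan class by largest-remainder apportionment."""
    raw = {c: config.n_kos * f for c, f in config.target_fractions.items()}
    counts = {c: math.floor(v) for c, v in raw.items()}
    for c, f in config.target_fractions.items():
        if f > 0 and raw[c] < 1:
            raise ValueError(
                f"class {c!r}: n_kos x fraction = {raw[c]:.3g} < 1; "
                "no KO can realize this class")
    remainder = config.n_kos - sum(counts.values())
    order = sorted(raw, key=lambda c: (raw[c] - counts[c], c), reverse=True)
    for c in order[:remainder]:
        counts[c] += 1
    return counts


def generate_ko_datasets(config: SyntheticConfig
                         ) -> tuple[dict[str, pd.DataFrame], PlantedTruth]:
    """Four taxon-KO count tables realizing the configured pan-class mix.

    Each KO is assigned a pan class (largest-remainder apportionment of the
    target fractions, so realized fractions deviate from targets by less
    than 1/n_kos) and a uniformly random presence mask of the matching
    popcount.  Present cells get strictly positive over-dispersed counts:
    ``1 + NegativeBinomial(r, r / (r + mean))``.  Returns
    {dataset label -> DataFrame(ko, count)} and the planted truth.
    """
    rng = np.random.default_rng(config.seed)
    counts_per_class = _class_counts(config)
    truth = PlantedTruth()
    tables: dict[str, list[tuple[str, int]]] = {d: [] for d in DATASETS}

    ko_ids = [f"K{i + 1:05d}" for i in range(config.n_kos)]
    classes = [c for c in ("core", "softcore", "shell", "cloud")
               for _ in range(counts_per_class[c])]
    r = config.count_dispersion
    p = r / (r + max(config.count_mean - 1.0, 0.1))
    for ko, cls in zip(ko_ids, classes):
        truth.ko_class[ko] = cls
        pop = _CLASS_POPCOUNT[cls]
        present = rng.choice(len(DATASETS), size=pop, replace=False)
        for idx in present:
            count = 1 + int(rng.negative_binomial(r, p))
            tables[DATASETS[idx]].append((ko, count))

    frames = {
        d: pd.DataFrame(rows, columns=["ko", "count"]).sort_values(
            "ko", ignore_index=True)
        for d, rows in tables.items()
    }
    return frames, truth


def ko_datasets_to_annotations(datasets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Expand count tables into eggNOG-mapper-style annotation rows.

    Each (dataset, KO, count) cell becomes ``count`` query rows annotated
    with that KO, so rebuilding the matrix from the annotations reproduces
    the counts exactly.  Dataset labels ``env|group`` populate the
    ``taxon_group`` and ``dataset`` columns.
    """
    rows = []
    for dataset, frame in datasets.items():
        _env, group = dataset.split("|", 1)
        q = 0
        for ko, count in zip(frame["ko"], frame["count"]):
            for _ in range(int(count)):
                rows.append({"query": f"{dataset}_q{q:06d}",
                             "KEGG_ko": f"ko:{ko}",
                             "taxon_group": group,
                             "dataset": dataset})
                q += 1
    return pd.DataFrame(rows, columns=["query", "KEGG_ko", "taxon_group", "dataset"])


_GENERA = ["Streptomyces", "Micrococcus", "Gordonia", "Actinomadura",
           "Nonomurea", "Conexibacter", "Rubrobacter", "Baekduia",
           "Modestobacter", "Frankia", "Amycolatopsis", "Actinoplanes"]


def generate_taxon_profiles(config: SyntheticConfig,
                            total_reads: int = 100_000) -> dict[str, pd.DataFrame]:
    """Bracken-style genus reports for the two environments.

    Genus shares come from a Dirichlet draw per environment; a trailing
    ``unknown`` bin absorbs leftover reads.  Returned frames have the
    seven-column Bracken layout.
    """
    rng = np.random.default_rng(config.seed + 1)
    profiles = {}
    for env in ENVIRONMENTS:
        shares = rng.dirichlet(np.full(len(_GENERA) + 1, 0.8))
        reads = np.floor(shares * total_reads).astype(int)
        rows = []
        names = _GENERA + ["unknown"]
        for i, (name, n) in enumerate(zip(names, reads)):
            assigned = int(n * 0.9)
            rows.append({
                "name": name, "taxonomy_id": 1000 + i, "taxonomy_lvl": "G",
                "kraken_assigned_reads": assigned, "added_reads": int(n) - assigned,
                "new_est_reads": int(n),
                "fraction_total_reads": n / total_reads,
            })
        profiles[env] = pd.DataFrame(rows, columns=BRACKEN_COLUMNS)
    return profiles


def _family_params(config: SyntheticConfig) -> list[dict]:
    """Per-compound-family parameters shared by spectra and library draws."""
    rng = np.random.default_rng(config.seed + 2)
    lo, hi = config.peaks_per_spectrum
    strains = [f"strain{i + 1:02d}" for i in range(config.n_strains)]
    block = hi + 2  # grid slots reserved per family; keeps blocks disjoint
    families = []
    for fam in range(config.n_compound_families):
        n_peaks = int(rng.integers(lo, hi + 1))
        grid_start = 100.0 + fam * block * 0.1
        positions = rng.choice(block, size=n_peaks, replace=False)
        families.append({
            "family": fam,
            "mzs": np.sort(grid_start + positions * 0.1),
            "base_intensity": rng.uniform(20.0, 100.0, size=n_peaks),
            "precursor": 300.0 + fam * 25.0,
            "strain": strains[fam % len(strains)],
        })
    return families


def generate_spectra(config: SyntheticConfig
                     ) -> tuple[list[Spectrum], PlantedTruth]:
    """MS/MS spectra with planted compound families.

    Family f gets a distinct precursor (spaced 25 Da apart) and a block of
    fragment m/z values on a 0.1 Da grid disjoint from every other
    family's block, so spectra of the same family share all their
    fragments and spectra of different families share none.  Each family
    is observed as ``replicates_per_compound`` replicate spectra from one
    strain, with Gaussian m/z noise of ``mz_noise_sd`` Da.
    """
    noise_rng = np.random.default_rng(config.seed + 4)
    truth = PlantedTruth()
    spectra: list[Spectrum] = []
    for fam in _family_params(config):
        n_peaks = len(fam["mzs"])
        for rep in range(config.replicates_per_compound):
            noisy_mz = fam["mzs"] + noise_rng.normal(
                0.0, config.mz_noise_sd, size=n_peaks)
            intensity = fam["base_intensity"] * noise_rng.uniform(
                0.8, 1.2, size=n_peaks)
            sid = f"fam{fam['family']}_rep{rep}"
            spectra.append(Spectrum(
                id=sid, precursor_mz=fam["precursor"], charge=1,
                peaks=np.column_stack([noisy_mz, intensity]),
                strain=fam["strain"]))
            truth.compound_family[sid] = fam["family"]
    return spectra, truth


def generate_library(config: SyntheticConfig,
                     covered_fraction: float = 0.5) -> list[Spectrum]:
    """Noise-free reference spectra for a fixed fraction of the families.

    The first ``round(covered_fraction x n_families)`` families get a
    library entry built from their exact planted fragments, so library
    search against it must match exactly that share of consensus nodes.
    """
    n_covered = round(config.n_compound_families * covered_fraction)
    library = []
    for fam in _family_params(config)[:n_covered]:
        library.append(Spectrum(
            id=f"lib_fam{fam['family']}", precursor_mz=fam["precursor"],
            charge=1,
            peaks=np.column_stack([fam["mzs"], fam["base_intensity"]])))
    return library


PATHWAY_MODULES = [
    "Carbohydrate metabolism", "Energy metabolism", "Lipid metabolism",
    "Nucleotide metabolism", "Amino acid metabolism",
    "Glycan metabolism", "Cofactor and vitamin metabolism",
    "Terpenoid and polyketide biosynthesis",
    "Biosynthesis of other secondary metabolites",
    "Xenobiotics biodegradation", "Genetic information processing",
    "Environmental information processing", "Cellular processes",
]
SIGNATURE_MODULES = ["Gene set", "Module set"]


def generate_module_map(config: SyntheticConfig,
                        n_pathways: int = 48) -> pd.DataFrame:
    """KO -> (pathway, module) map over the synthetic KO vocabulary.

    Pathways are assigned round-robin over ``n_pathways`` labels and each
    pathway belongs to one of the 13 pathway modules or 2 signature
    modules, mirroring the map shape used to organize functional
    orthologues.  Deterministic (no random draws).
    """
    modules = PATHWAY_MODULES + SIGNATURE_MODULES
    rows = []
    for i in range(config.n_kos):
        ko = f"K{i + 1:05d}"
        pathway_idx = i % n_pathways
        rows.append({"ko": ko,
                     "pathway": f"pathway{pathway_idx + 1:02d}",
                     "module": modules[pathway_idx % len(modules)]})
    return pd.DataFrame(rows, columns=["ko", "pathway", "module"])


_BGC_TYPES = ["NRPS", "T1PKS", "T2PKS", "terpene", "lanthipeptide", "siderophore"]


def generate_bgc_tables(config: SyntheticConfig
                        ) -> tuple[pd.DataFrame, PlantedTruth]:
    """Per-strain BGC tables with uniform GCF distances.

    Cluster counts are uniform over ``bgc_per_strain`` and distances
    uniform over ``distance_range``; the planted BiNI of each strain is
    computed from its own generated table (sum of distances / cluster
    count), so downstream scoring must recover it exactly.  A strain that
    draws zero clusters is excluded with a warning.
    """
    rng = np.random.default_rng(config.seed + 3)
    truth = PlantedTruth()
    rows = []
    lo, hi = config.bgc_per_strain
    for i in range(config.n_strains):
        strain = f"strain{i + 1:02d}"
        n = int(rng.integers(lo, hi + 1))
        if n == 0:
            logger.warning("strain %s drew no clusters; excluded", strain)
            continue
        distances = np.round(rng.uniform(*config.distance_range, size=n), 2)
        for j, d in enumerate(distances):
            rows.append({"strain": strain, "region": f"region{j + 1:03d}",
                         "type": _BGC_TYPES[int(rng.integers(len(_BGC_TYPES)))],
                         "distance": float(d)})
        truth.strain_bini[strain] = float(distances.sum() / n)
    return (pd.DataFrame(rows, columns=["strain", "region", "type", "distance"]),
            truth)


_SITE_MULTIPLIERS = {"site1": 1.0, "site2": 0.5, "site3": 2.0}


def generate_geochem(config: SyntheticConfig
                     ) -> tuple[GeochemTable, PlantedTruth]:
    """Geochemistry table with known fold factors over crustal references.

    Every uncensored cell is exactly ``reference x fold`` where the fold is
    the configured per-analyte factor times a fixed site multiplier,
    rounded to one decimal — the precision at which fold enrichment is
    reported, so recovery is exact.  A control site carries censored
    ``"<limit"`` cells.
    """
    from .geochem import CRUSTAL_REFERENCE

    truth = PlantedTruth()
    values: dict[tuple[str, str], float | Censored] = {}
    sites = list(_SITE_MULTIPLIERS)
    for site, mult in _SITE_MULTIPLIERS.items():
        for analyte, base in config.geochem_folds.items():
            fold = round(base * mult, 1)
            if fold <= 0:
                fold = 0.1
            # round away float dust so the concentration survives CSV round trips
            values[(site, analyte)] = round(CRUSTAL_REFERENCE[analyte] * fold, 6)
            truth.geochem_fold[(site, analyte)] = fold
    sites.append("control")
    for analyte in config.geochem_folds:
        values[("control", analyte)] = Censored(50.0)
    table = GeochemTable(sites=sites, values=values)
    return table, truth


def write_ko_dataset_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_annotation_tsv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def write_bracken_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_bgc_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def simulate_all(config: SyntheticConfig, outdir) -> PlantedTruth:
    """Generate and write every synthetic input under ``outdir``.

    Writes count tables and annotation TSVs per dataset, Bracken-style
    taxonomy reports, the spectra as MGF, the BGC table, the geochemistry
    CSV and the combined planted truth as JSON.
    """
    from pathlib import Path

    from . import geochem as _geochem
    from .network import write_mgf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    datasets, ko_truth = generate_ko_datasets(config)
    for label, frame in datasets.items():
        write_ko_dataset_tsv(frame, out / f"counts_{label.replace('|', '_')}.tsv")
    write_annotation_tsv(ko_datasets_to_annotations(datasets),
                         out / "annotations.tsv")
    for env, frame in generate_taxon_profiles(config).items():
        write_bracken_tsv(frame, out / f"bracken_{env}.tsv")

    generate_module_map(config).to_csv(out / "module_map.tsv", sep="\t", index=False)

    spectra, spec_truth = generate_spectra(config)
    write_mgf(spectra, out / "spectra.mgf")
    write_mgf(generate_library(config), out / "library.mgf")

    bgc, bgc_truth = generate_bgc_tables(config)
    write_bgc_tsv(bgc, out / "bgc.tsv")

    geo_table, geo_truth = generate_geochem(config)
    _geochem.write_table(geo_table, out / "geochem.csv")

    truth = PlantedTruth(
        ko_class=ko_truth.ko_class,
        compound_family=spec_truth.compound_family,
        strain_bini=bgc_truth.strain_bini,
        geochem_fold=geo_truth.geochem_fold,
    )
    truth.to_json(out / "truth.json")
    return truth
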