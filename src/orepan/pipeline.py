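"""End-to-end orchestration of the analysis stages from one config.

A run executes (subsets of) the stage chain

    simulate -> geochem -> matrix -> pan -> modules -> bini -> network

in dependency order, writing each stage's tables under the output
directory and collecting a machine-readable report: parameter echo,
per-file checksums and the headline summary numbers of every stage (pan
class fractions, unique-KO counts, BiNI table, network component count,
library match fraction).  Identical config + seed yields an identical
report apart from nothing — no timestamps are recorded.  A single seed
fans out to per-stage seeds through a fixed derivation so stages also
reproduce when run standalone.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import zlib
from pathlib import Path

import pandas as pd

from . import bini as _bini
from . import geochem as _geochem
from . import kegg_modules as _modules
from . import ko_matrix as _komat
from . import network as _net
from . import pan as _pan
from . import synthetic as _syn

logger = logging.getLogger(__name__)

STAGES = ("simulate", "geochem", "matrix", "pan", "modules", "bini", "network")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "orepan_run",
    "stages": {name: True for name in STAGES},
    "thresholds": {
        "twofold_ratio": 2.0,
        "bini_threshold": 900.0,
        "fragment_tol": 0.03,
        "edge_cosine": 0.65,
        "edge_matched": 4,
        "min_cluster_size": 3,
        "cluster_cosine": 0.7,
        "library_cosine": 0.5,
        "library_matched": 4,
    },
    "synthetic": {},   # overrides for SyntheticConfig fields
    "inputs": {        # external inputs, used when simulate is off
        "annotations": None,
        "module_map": None,
        "geochem": None,
        "bgc": None,
        "mgf": None,
        "library": None,
    },
}


class ConfigError(ValueError):
    """Invalid run configuration (unknown key or bad value)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2^31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults and path != "synthetic":
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(value, dict) and isinstance(defaults.get(key), dict):
            merged[key] = _merge(defaults[key], value, here)
        else:
            merged[key] = value
    return merged


def load_config(source: dict | str | Path) -> dict:
    """Validate a run config (dict or YAML path) against the schema."""
    import yaml

    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    config = _merge(DEFAULT_CONFIG, source)
    for name, value in config["thresholds"].items():
        if value <= 0:
            raise ConfigError(f"threshold {name!r} must be positive, got {value}")
    for name in config["stages"]:
        if name not in STAGES:
            raise ConfigError(f"unknown stage {name!r}")
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the enabled stages and return the report (also written as JSON).

    Raises :class:`StageError` naming the failing stage; outputs written
    before the failure are retained next to a ``FAILED`` marker file.
    """
    config = load_config(config)
    out = Path(config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    th = config["thresholds"]
    stages = config["stages"]
    report: dict = {"parameters": config, "stages": {}}
    files: dict[str, list[str]] = {}

    def record(stage: str, summary: dict, written: list[Path]) -> None:
        report["stages"][stage] = {
            "summary": summary,
            "outputs": {p.name: _sha256(p) for p in written},
        }
        files[stage] = [str(p) for p in written]

    try:
        syn_cfg = _syn.SyntheticConfig(
            seed=stage_seed(config["seed"], "simulate"),
            **config["synthetic"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid synthetic configuration: {exc}") from exc

    current = "?"
    try:
        sim_dir = out / "simulated"
        if stages.get("simulate"):
            current = "simulate"
            truth = _syn.simulate_all(syn_cfg, sim_dir)
            record("simulate",
                   {"n_kos": len(truth.ko_class),
                    "n_spectra": len(truth.compound_family),
                    "n_strains": len(truth.strain_bini)},
                   sorted(sim_dir.iterdir()))

        if stages.get("geochem"):
            current = "geochem"
            geo_path = config["inputs"]["geochem"] or sim_dir / "geochem.csv"
            table = _geochem.read_table(geo_path)
            folds = _geochem.fold_table(table)
            folds.to_csv(out / "fold_enrichment.csv", index=False)
            flags = _geochem.flag_extremes(table)
            record("geochem",
                   {"n_sites": len(table.sites),
                    "n_fold_values": int(folds["fold"].notna().sum()),
                    "highest": {a: sorted(f.highest) if f.highest else None
                                for a, f in flags.items()}},
                   [out / "fold_enrichment.csv"])

        matrix = None
        if stages.get("matrix"):
            current = "matrix"
            ann_path = config["inputs"]["annotations"] or sim_dir / "annotations.tsv"
            annotations = _komat.read_annotations(ann_path)
            matrix = _komat.build_matrix(annotations)
            matrix = _komat.normalize_cpm(matrix)
            matrix.check_cpm()
            _komat.write_matrix(matrix, out / "taxon_ko_matrix.tsv")
            record("matrix",
                   {"datasets": matrix.datasets,
                    "n_cells": len(matrix.table),
                    "mapped_totals": matrix.mapped_totals},
                   [out / "taxon_ko_matrix.tsv"])

        partition = None
        if stages.get("pan"):
            current = "pan"
            if matrix is None:
                raise ValueError("pan stage requires the matrix stage")
            partition = _pan.pan_summary(matrix.ko_sets())
            partition.to_frame().to_csv(out / "pan_classes.tsv", sep="\t", index=False)
            regions = _pan.venn_partition(matrix.ko_sets())
            _pan.venn_to_frame(regions).to_csv(out / "venn_regions.tsv",
                                               sep="\t", index=False)
            _pan.write_summary_json(partition, out / "pan_summary.json")
            record("pan",
                   {"classes": partition.summary(),
                    "unique": {d: len(_pan.unique_kos(partition, d))
                               for d in partition.datasets}},
                   [out / "pan_classes.tsv", out / "venn_regions.tsv",
                    out / "pan_summary.json"])

        if stages.get("modules"):
            current = "modules"
            if matrix is None or partition is None:
                raise ValueError("modules stage requires matrix and pan stages")
            map_path = config["inputs"]["module_map"] or sim_dir / "module_map.tsv"
            module_map = _modules.read_module_map(map_path)
            agg = _modules.aggregate_by_module(matrix, module_map)
            agg.to_csv(out / "module_abundance.tsv", sep="\t", index=False)
            per_ds = {d: agg[agg["dataset"] == d] for d in matrix.datasets}
            acti = [d for d in matrix.datasets if d.endswith("|Actinomycetota")]
            screens = {}
            if len(acti) == 2:
                res = _modules.module_twofold(per_ds[acti[0]], per_ds[acti[1]],
                                              ratio=th["twofold_ratio"])
                screens = {"flagged": sorted(res.flagged),
                           "exclusive": sorted(res.exclusive_a | res.exclusive_b)}
            record("modules",
                   {"n_modules": int(agg["module"].nunique()),
                    "twofold": screens},
                   [out / "module_abundance.tsv"])

        if stages.get("bini"):
            current = "bini"
            bgc_path = config["inputs"]["bgc"] or sim_dir / "bgc.tsv"
            bgc = _bini.read_bgc_table(bgc_path)
            scores = _bini.score_all(bgc, threshold=th["bini_threshold"])
            ranked = _bini.rank_strains(scores)
            ranked.to_csv(out / "bini_scores.tsv", sep="\t", index=False)
            record("bini",
                   {"scores": dict(zip(ranked["strain"], ranked["score"])),
                    "top_strain": ranked["strain"].iloc[0]},
                   [out / "bini_scores.tsv"])

        if stages.get("network"):
            current = "network"
            mgf_path = config["inputs"]["mgf"] or sim_dir / "spectra.mgf"
            spectra = _net.read_mgf(mgf_path)
            nodes = _net.cluster_spectra(
                spectra, precursor_tol=th["fragment_tol"],
                cosine_min=th["cluster_cosine"],
                min_cluster_size=int(th["min_cluster_size"]),
                fragment_tol=th["fragment_tol"])
            network = _net.build_network(
                nodes, tol=th["fragment_tol"], cosine_min=th["edge_cosine"],
                matched_min=int(th["edge_matched"]))
            network.edge_table().to_csv(out / "network_edges.tsv",
                                        sep="\t", index=False)
            lib_path = config["inputs"]["library"] or sim_dir / "library.mgf"
            hits, fraction = _net.library_match(
                nodes, _net.read_mgf(lib_path), tol=th["fragment_tol"],
                cosine_min=th["library_cosine"],
                matched_min=int(th["library_matched"]))
            pd.DataFrame(
                [{"node": n, "library_id": h[0] if h else None,
                  "cosine": h[1] if h else None,
                  "matched": h[2] if h else None} for n, h in hits.items()]
            ).to_csv(out / "library_hits.tsv", sep="\t", index=False)
            record("network",
                   {"n_nodes": len(nodes),
                    "n_edges": network.graph.number_of_edges(),
                    "n_components": len(network.components()),
                    "matched_fraction": fraction},
                   [out / "network_edges.tsv", out / "library_hits.tsv"])
    except Exception as exc:  # noqa: BLE001 - every stage failure is reported
        (out / "FAILED").write_text(f"stage {current} failed: {exc}\n")
        raise StageError(current, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
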