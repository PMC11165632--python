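"""Desk-scale classical molecular networking over tandem-MS spectra.

Replicate MS/MS spectra are first collapsed into consensus spectra by
greedy centroid clustering (clusters below a minimum member count are
discarded), consensus nodes are then connected by modified-cosine edges,
and connected components of the resulting network approximate compound
families.  The modified cosine allows fragment pairs to match either
directly or shifted by the precursor mass difference, with each peak used
at most once; the score is the optimum over all one-to-one peak matchings,
computed exactly as a maximum-weight bipartite assignment.  Consensus nodes
can additionally be searched against a spectral library and summarized into
per-strain chemical superclass compositions.

Default thresholds follow common practice for classical molecular
networking: fragment tolerance 0.03 Da, edge cosine 0.65 with at least 4
matched ions and a minimum cluster size of 3 spectra; library search at
cosine 0.5 with 4 matched peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from pyteomics import mgf as _mgf
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

FRAGMENT_TOL = 0.03      # Da
EDGE_COSINE_MIN = 0.65
EDGE_MATCHED_MIN = 4
MIN_CLUSTER_SIZE = 3
LIBRARY_COSINE_MIN = 0.5
LIBRARY_MATCHED_MIN = 4
NO_MATCH = "no match"


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor, charge and centroided fragment peaks."""

    id: str
    precursor_mz: float
    charge: int = 1
    peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # (mz, intensity)
    strain: str | None = None

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        if self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]
        if len(self.peaks) and (self.peaks[:, 0] <= 0).any():
            raise ValueError("fragment m/z values must be positive")
        if len(self.peaks) and (self.peaks[:, 1] < 0).any():
            raise ValueError("fragment intensities must be non-negative")

    @property
    def total_intensity(self) -> float:
        return float(self.peaks[:, 1].sum()) if len(self.peaks) else 0.0


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file; every block needs PEPMASS, TITLE carries the id."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params:
                raise ValueError(f"MGF block {i} in {path} is missing PEPMASS")
            charge = int(params["charge"][0]) if "charge" in params else 1
            spectra.append(Spectrum(
                id=str(params.get("title", f"scan{i}")),
                precursor_mz=float(params["pepmass"][0]),
                charge=abs(charge),
                peaks=np.column_stack([entry["m/z array"], entry["intensity array"]]),
                strain=params.get("strain"),
            ))
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.id, "pepmass": s.precursor_mz, "charge": s.charge}
        if s.strain is not None:
            params["strain"] = s.strain
        entries.append({"params": params,
                        "m/z array": s.peaks[:, 0],
                        "intensity array": s.peaks[:, 1]})
    _mgf.write(entries, str(path), file_mode="w")


def _weight_vector(peaks: np.ndarray, transform: str) -> np.ndarray:
    w = np.sqrt(peaks[:, 1]) if transform == "sqrt" else peaks[:, 1].astype(float)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def modified_cosine(a: Spectrum, b: Spectrum, tol: float = FRAGMENT_TOL,
                    transform: str = "sqrt") -> tuple[float, int]:
    """Modified cosine similarity and matched-peak count of two spectra.

    Peak i of ``a`` may pair with peak j of ``b`` when their m/z agree
    within ``tol`` either directly or after shifting by the precursor mass
    difference.  Intensities are square-root transformed (``transform=
    "linear"`` disables this) and unit-normalized per spectrum; the score
    is the maximum over all one-to-one peak matchings of the summed weight
    products, found exactly by linear assignment.  Symmetric in its
    arguments; bounded in [0, 1].
    """
    if len(a.peaks) == 0 or len(b.peaks) == 0:
        raise ValueError("modified cosine requires non-empty peak lists")
    wa = _weight_vector(a.peaks, transform)
    wb = _weight_vector(b.peaks, transform)
    delta = a.precursor_mz - b.precursor_mz
    mza = a.peaks[:, 0][:, None]
    mzb = b.peaks[:, 0][None, :]
    allowed = (np.abs(mza - mzb) <= tol) | (np.abs(mza - (mzb + delta)) <= tol)
    score_matrix = np.where(allowed, wa[:, None] * wb[None, :], 0.0)
    row, col = linear_sum_assignment(score_matrix, maximize=True)
    used = allowed[row, col]
    score = float(score_matrix[row, col].sum())
    return min(score, 1.0), int(used.sum())


@dataclass
class ConsensusNode:
    """Intensity-weighted merge of a cluster of near-identical spectra."""

    id: str
    precursor_mz: float
    charge: int
    peaks: np.ndarray
    members: list[str]
    strains: frozenset[str]

    @property
    def member_count(self) -> int:
        return len(self.members)

    def as_spectrum(self) -> Spectrum:
        return Spectrum(id=self.id, precursor_mz=self.precursor_mz,
                        charge=self.charge, peaks=self.peaks)


def _merge_peaks(members: list[Spectrum], tol: float) -> np.ndarray:
    stacked = np.vstack([s.peaks for s in members])
    stacked = stacked[np.argsort(stacked[:, 0], kind="stable")]
    merged = []
    start = 0
    for i in range(1, len(stacked) + 1):
        if i == len(stacked) or stacked[i, 0] - stacked[i - 1, 0] > tol:
            group = stacked[start:i]
            weights = group[:, 1]
            mz = (np.average(group[:, 0], weights=weights)
                  if weights.sum() > 0 else group[:, 0].mean())
            merged.append((mz, weights.sum() / len(members)))
            start = i
    return np.array(merged)


def cluster_spectra(spectra: list[Spectrum], precursor_tol: float = FRAGMENT_TOL,
                    cosine_min: float = 0.7, min_cluster_size: int = MIN_CLUSTER_SIZE,
                    fragment_tol: float = FRAGMENT_TOL) -> list[ConsensusNode]:
    """Greedy centroid clustering of replicate spectra into consensus nodes.

    Repeatedly seeds with the most intense unassigned spectrum and absorbs
    spectra whose precursor lies within ``precursor_tol`` and whose
    modified cosine against the seed reaches ``cosine_min``.  Consensus
    peaks are intensity-weighted merges of member peaks; clusters with
    fewer than ``min_cluster_size`` members are discarded (and logged), so
    compounds observed fewer than that many times never become nodes.
    """
    if not spectra:
        raise ValueError("no spectra to cluster")
    remaining = sorted(spectra, key=lambda s: (-s.total_intensity, s.id))
    nodes: list[ConsensusNode] = []
    n_discarded = 0
    while remaining:
        seed = remaining.pop(0)
        members = [seed]
        rest = []
        for s in remaining:
            if (abs(s.precursor_mz - seed.precursor_mz) <= precursor_tol
                    and modified_cosine(seed, s, tol=fragment_tol)[0] >= cosine_min):
                members.append(s)
            else:
                rest.append(s)
        remaining = rest
        if len(members) < min_cluster_size:
            n_discarded += 1
            continue
        weights = np.array([m.total_intensity for m in members])
        if weights.sum() == 0:
            weights = np.ones(len(members))
        precursor = float(np.average([m.precursor_mz for m in members], weights=weights))
        nodes.append(ConsensusNode(
            id=f"node{len(nodes)}",
            precursor_mz=precursor,
            charge=seed.charge,
            peaks=_merge_peaks(members, fragment_tol),
            members=[m.id for m in members],
            strains=frozenset(m.strain for m in members if m.strain is not None),
        ))
    if n_discarded:
        logger.info("discarded %d clusters below the minimum size of %d",
                    n_discarded, min_cluster_size)
    return nodes


@dataclass
class SpectralNetwork:
    """Consensus-spectrum graph: modified-cosine edges above thresholds."""

    graph: nx.Graph
    nodes: dict[str, ConsensusNode]

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def singletons(self) -> set[str]:
        return {n for n in self.graph if self.graph.degree[n] == 0}

    def edge_table(self):
        import pandas as pd
        rows = [{"node1": u, "node2": v, "cosine": d["cosine"], "matched": d["matched"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node1", "node2", "cosine", "matched"])


def build_network(nodes: list[ConsensusNode], tol: float = FRAGMENT_TOL,
                  cosine_min: float = EDGE_COSINE_MIN,
                  matched_min: int = EDGE_MATCHED_MIN) -> SpectralNetwork:
    """Connect consensus nodes whose modified cosine and matched-ion count
    pass both thresholds.  The graph keeps every node; unconnected nodes
    remain as singleton components."""
    if not nodes:
        raise ValueError("network requires at least one consensus node")
    graph = nx.Graph()
    for node in nodes:
        graph.add_node(node.id, precursor_mz=node.precursor_mz,
                       members=node.member_count)
    spectra = {n.id: n.as_spectrum() for n in nodes}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            score, matched = modified_cosine(spectra[u.id], spectra[v.id], tol=tol)
            if score >= cosine_min and matched >= matched_min:
                graph.add_edge(u.id, v.id, cosine=score, matched=matched)
    return SpectralNetwork(graph=graph, nodes={n.id: n for n in nodes})


def library_match(nodes: list[ConsensusNode], library: list[Spectrum],
                  tol: float = FRAGMENT_TOL, cosine_min: float = LIBRARY_COSINE_MIN,
                  matched_min: int = LIBRARY_MATCHED_MIN
                  ) -> tuple[dict[str, tuple[str, float, int] | None], float]:
    """Best library hit per node, plus the fraction of nodes with a hit.

    A hit must reach the library cosine and matched-peak thresholds; the
    best-scoring qualifying library spectrum wins, ties broken by library id.
    """
    if not library:
        raise ValueError("library is empty")
    hits: dict[str, tuple[str, float, int] | None] = {}
    for node in nodes:
        spec = node.as_spectrum()
        best: tuple[float, str, int] | None = None
        for lib in library:
            score, matched = modified_cosine(spec, lib, tol=tol)
            if score < cosine_min or matched < matched_min:
                continue
            if best is None or score > best[0] or (score == best[0] and lib.id < best[1]):
                best = (score, lib.id, matched)
        hits[node.id] = None if best is None else (best[1], best[0], best[2])
    fraction = sum(h is not None for h in hits.values()) / len(nodes) if nodes else 0.0
    return hits, fraction


def class_composition(network: SpectralNetwork,
                      node_classes: dict[str, str | None],
                      strains: list[str] | None = None):
    """Per-strain and overall chemical superclass percentages.

    ``node_classes`` may be partial; unlabelled nodes count as
    ``"no match"``.  A node contributes to every strain among its members.
    Percentages per strain (and overall) sum to 100.
    """
    import pandas as pd

    all_strains = strains if strains is not None else sorted(
        {s for n in network.nodes.values() for s in n.strains})
    rows = []
    groups: list[tuple[str, list[ConsensusNode]]] = [
        ("overall", list(network.nodes.values()))]
    for strain in all_strains:
        members = [n for n in network.nodes.values() if strain in n.strains]
        if not members:
            logger.warning("strain %s has no nodes in the network", strain)
            continue
        groups.append((strain, members))
    for label, members in groups:
        counts: dict[str, int] = {}
        for node in members:
            cls = node_classes.get(node.id) or NO_MATCH
            counts[cls] = counts.get(cls, 0) + 1
        total = sum(counts.values())
        for cls, c in sorted(counts.items()):
            rows.append({"strain": label, "superclass": cls,
                         "count": c, "percent": c / total * 100.0})
    return pd.DataFrame(rows, columns=["strain", "superclass", "count", "percent"])
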