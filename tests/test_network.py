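"""Modified cosine, consensus clustering, networking and library search."""

import itertools

import numpy as np
import pytest

from orepan import network as net
from orepan.network import (ConsensusNode, Spectrum, build_network,
                            class_composition, cluster_spectra, library_match,
                            modified_cosine, read_mgf, write_mgf)
from orepan.synthetic import SyntheticConfig, generate_library, generate_spectra


def spectrum(mzs, intensities, precursor=500.0, sid="s", strain=None):
    return Spectrum(id=sid, precursor_mz=precursor, charge=1,
                    peaks=np.column_stack([mzs, intensities]), strain=strain)


def brute_force_score(a: Spectrum, b: Spectrum, tol: float) -> float:
    """Exhaustive maximum over all one-to-one peak matchings."""
    wa = np.sqrt(a.peaks[:, 1]); wa /= np.linalg.norm(wa)
    wb = np.sqrt(b.peaks[:, 1]); wb /= np.linalg.norm(wb)
    delta = a.precursor_mz - b.precursor_mz
    allowed = [
        (i, j, wa[i] * wb[j])
        for i in range(len(wa)) for j in range(len(wb))
        if (abs(a.peaks[i, 0] - b.peaks[j, 0]) <= tol
            or abs(a.peaks[i, 0] - (b.peaks[j, 0] + delta)) <= tol)
    ]
    best = 0.0
    n = len(wa)

    def recurse(pairs, used_a, used_b, acc):
        nonlocal best
        best = max(best, acc)
        for k, (i, j, w) in enumerate(pairs):
            if i in used_a or j in used_b:
                continue
            recurse(pairs[k + 1:], used_a | {i}, used_b | {j}, acc + w)

    recurse(allowed, frozenset(), frozenset(), 0.0)
    return min(best, 1.0)


class TestModifiedCosine:
    def test_identity_scores_one(self, rng):
        mzs = np.sort(rng.uniform(100, 500, size=12))
        s = spectrum(mzs, rng.uniform(1, 100, size=12))
        score, matched = modified_cosine(s, s, tol=0.03)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert matched == 12

    def test_disjoint_spectra_score_zero(self):
        a = spectrum([100.0, 110.0, 120.0, 130.0], [1, 1, 1, 1], precursor=500.0)
        b = spectrum([105.0, 115.0, 125.0, 135.0], [1, 1, 1, 1], precursor=500.0)
        score, matched = modified_cosine(a, b, tol=0.03)
        assert score == 0.0
        assert matched == 0

    def test_precursor_shift_enables_matches(self):
        # b's fragments are a's shifted by the precursor difference of 14 Da
        a = spectrum([100.0, 150.0, 200.0, 250.0], [5, 4, 3, 2], precursor=400.0)
        b = spectrum([114.0, 164.0, 214.0, 264.0], [5, 4, 3, 2], precursor=414.0)
        score, matched = modified_cosine(b, a, tol=0.01)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert matched == 4

    def test_symmetry(self, rng):
        for _ in range(20):
            na, nb = rng.integers(2, 8, size=2)
            a = spectrum(np.sort(rng.uniform(100, 110, size=na)),
                         rng.uniform(1, 100, size=na),
                         precursor=float(rng.uniform(300, 310)))
            b = spectrum(np.sort(rng.uniform(100, 110, size=nb)),
                         rng.uniform(1, 100, size=nb),
                         precursor=float(rng.uniform(300, 310)))
            sab, mab = modified_cosine(a, b, tol=0.3)
            sba, mba = modified_cosine(b, a, tol=0.3)
            assert sab == pytest.approx(sba, abs=1e-9)
            assert mab == mba

    def test_matches_exhaustive_oracle_on_random_pairs(self, rng):
        """Assignment-based score equals the exhaustive optimum over all
        one-to-one matchings for 100 random pairs of <= 8-peak spectra."""
        tol = 0.3
        for _ in range(100):
            na, nb = rng.integers(2, 9, size=2)
            a = spectrum(np.sort(rng.uniform(100, 104, size=na)),
                         rng.uniform(1, 100, size=na),
                         precursor=float(rng.uniform(300, 302)))
            b = spectrum(np.sort(rng.uniform(100, 104, size=nb)),
                         rng.uniform(1, 100, size=nb),
                         precursor=float(rng.uniform(300, 302)))
            score, matched = modified_cosine(a, b, tol=tol)
            assert score == pytest.approx(brute_force_score(a, b, tol), abs=1e-9)
            assert 0.0 <= score <= 1.0
            assert matched <= min(na, nb)

    def test_empty_peak_list_rejected(self):
        a = spectrum([100.0], [1.0])
        with pytest.raises(ValueError):
            modified_cosine(a, Spectrum(id="e", precursor_mz=100.0), tol=0.03)


class TestMgfRoundTrip:
    def test_round_trip(self, tmp_path, config):
        spectra, _ = generate_spectra(config)
        path = tmp_path / "spectra.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == len(spectra)
        for orig, rt in zip(spectra, back):
            assert rt.id == orig.id
            assert rt.strain == orig.strain
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-4)
            np.testing.assert_allclose(rt.peaks[:, 0], orig.peaks[:, 0], atol=1e-4)
            np.testing.assert_allclose(rt.peaks[:, 1], orig.peaks[:, 1], rtol=1e-3)

    def test_two_block_toy(self, tmp_path):
        path = tmp_path / "toy.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=one\nPEPMASS=300.0\nCHARGE=1+\n"
            "100.1 5\n200.2 7\nEND IONS\n"
            "BEGIN IONS\nTITLE=two\nPEPMASS=310.0\nCHARGE=1+\n"
            "110.1 3\nEND IONS\n")
        spectra = read_mgf(path)
        assert [s.id for s in spectra] == ["one", "two"]

    def test_unsorted_peaks_sorted_on_load(self):
        s = spectrum([300.0, 100.0, 200.0], [1, 2, 3])
        assert list(s.peaks[:, 0]) == [100.0, 200.0, 300.0]


class TestClustering:
    def test_identical_spectra_one_node(self):
        spectra = [spectrum([100.0, 110.0, 120.0, 130.0], [5, 4, 3, 2],
                            sid=f"s{i}") for i in range(5)]
        nodes = cluster_spectra(spectra)
        assert len(nodes) == 1
        assert nodes[0].member_count == 5

    def test_two_replicates_discarded_by_min_cluster(self):
        spectra = [spectrum([100.0, 110.0, 120.0, 130.0], [5, 4, 3, 2],
                            sid=f"s{i}") for i in range(2)]
        assert cluster_spectra(spectra, min_cluster_size=3) == []

    def test_consensus_merges_peaks_within_tolerance(self):
        spectra = [
            spectrum([100.00, 110.0, 120.0, 130.0], [4, 4, 4, 4], sid="a"),
            spectrum([100.02, 110.0, 120.0, 130.0], [4, 4, 4, 4], sid="b"),
            spectrum([100.01, 110.0, 120.0, 130.0], [4, 4, 4, 4], sid="c"),
        ]
        nodes = cluster_spectra(spectra, fragment_tol=0.03)
        assert len(nodes) == 1
        assert len(nodes[0].peaks) == 4
        assert nodes[0].peaks[0, 0] == pytest.approx(100.01, abs=0.011)


class TestPlantedRecovery:
    def test_components_equal_planted_families_at_zero_noise(self):
        cfg = SyntheticConfig(seed=5, n_compound_families=3,
                              replicates_per_compound=4, mz_noise_sd=0.0)
        spectra, truth = generate_spectra(cfg)
        nodes = cluster_spectra(spectra, min_cluster_size=3)
        network = build_network(nodes, tol=0.03, cosine_min=0.65, matched_min=4)
        components = network.components()
        assert len(components) == 3
        node_by_id = {n.id: n for n in nodes}
        for comp in components:
            families = {truth.compound_family[m]
                        for nid in comp for m in node_by_id[nid].members}
            assert len(families) == 1

    def test_two_replicates_yield_empty_node_set(self):
        cfg = SyntheticConfig(seed=5, n_compound_families=3,
                              replicates_per_compound=2)
        spectra, _ = generate_spectra(cfg)
        assert cluster_spectra(spectra, min_cluster_size=3) == []

    def test_impossible_cosine_threshold_gives_no_edges(self):
        cfg = SyntheticConfig(seed=5)
        spectra, _ = generate_spectra(cfg)
        nodes = cluster_spectra(spectra)
        network = build_network(nodes, cosine_min=1.01)
        assert network.graph.number_of_edges() == 0


class TestLibraryMatch:
    def test_identical_library_spectrum_scores_one(self):
        s = spectrum([100.0, 110.0, 120.0, 130.0], [5, 4, 3, 2])
        node = ConsensusNode(id="n0", precursor_mz=500.0, charge=1,
                             peaks=s.peaks, members=["s"], strains=frozenset())
        lib = [spectrum([100.0, 110.0, 120.0, 130.0], [5, 4, 3, 2], sid="lib1")]
        hits, fraction = library_match([node], lib)
        assert hits["n0"][0] == "lib1"
        assert hits["n0"][1] == pytest.approx(1.0, abs=1e-9)
        assert fraction == 1.0

    def test_half_covered_synthetic_library(self):
        cfg = SyntheticConfig(seed=5, n_compound_families=4)
        spectra, _ = generate_spectra(cfg)
        nodes = cluster_spectra(spectra)
        _, fraction = library_match(nodes, generate_library(cfg, 0.5))
        assert fraction == pytest.approx(0.5)

    def test_no_shared_fragments_no_match(self):
        node = ConsensusNode(
            id="n0", precursor_mz=500.0, charge=1,
            peaks=np.array([[100.0, 1.0], [110.0, 1.0], [120.0, 1.0], [130.0, 1.0]]),
            members=["s"], strains=frozenset())
        lib = [spectrum([105.0, 115.0, 125.0, 135.0], [1, 1, 1, 1], precursor=500.0)]
        hits, fraction = library_match([node], lib)
        assert hits["n0"] is None
        assert fraction == 0.0


class TestClassComposition:
    @staticmethod
    def toy_network():
        nodes = [
            ConsensusNode(id=i, precursor_mz=300.0 + k * 100, charge=1,
                          peaks=np.array([[100.0 + k, 1.0], [110.0 + k, 1.0],
                                          [120.0 + k, 1.0], [130.0 + k, 1.0]]),
                          members=[f"{i}_m"], strains=frozenset({"X"}))
            for k, i in enumerate("abcd")
        ]
        return build_network(nodes)

    def test_half_unlabelled_is_half_no_match(self):
        network = self.toy_network()
        comp = class_composition(network, {"a": "organic acids", "b": "lipids",
                                           "c": None, "d": None})
        overall = comp[comp.strain == "overall"].set_index("superclass")["percent"]
        assert overall["no match"] == pytest.approx(50.0)
        assert overall["organic acids"] == pytest.approx(25.0)

    def test_all_unlabelled(self):
        network = self.toy_network()
        comp = class_composition(network, {})
        overall = comp[comp.strain == "overall"]
        assert overall["superclass"].tolist() == ["no match"]
        assert overall["percent"].iloc[0] == pytest.approx(100.0)

    def test_percentages_sum_to_100_per_strain(self):
        network = self.toy_network()
        comp = class_composition(network, {"a": "lipids"})
        for _, grp in comp.groupby("strain"):
            assert grp["percent"].sum() == pytest.approx(100.0)


def test_edge_symmetry_no_duplicates():
    cfg = SyntheticConfig(seed=5)
    spectra, _ = generate_spectra(cfg)
    network = build_network(cluster_spectra(spectra))
    edges = {frozenset(e) for e in network.graph.edges()}
    assert len(edges) == network.graph.number_of_edges()
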