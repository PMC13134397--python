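"""Spectral cosine, clustering, network construction, mass-shift table."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycopop as gp
from conftest import make_spectrum


def brute_force_cosine(a, b, frag_tol):
    """Exhaustive best one-to-one matching over all peak subsets."""
    wa, wb = np.sqrt(a.intensity), np.sqrt(b.intensity)
    candidates = [
        (i, j)
        for i in range(a.n_peaks)
        for j in range(b.n_peaks)
        if abs(a.mz[i] - b.mz[j]) <= frag_tol
    ]
    best = 0.0
    best_n = 0
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            rows = [i for i, _ in subset]
            cols = [j for _, j in subset]
            if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
                continue
            dot = sum(wa[i] * wb[j] for i, j in subset)
            if dot > best:
                best, best_n = dot, r
    norm = np.linalg.norm(wa) * np.linalg.norm(wb)
    return min(best / norm, 1.0), best_n


small_spectra = st.lists(
    st.tuples(st.floats(100.0, 110.0), st.floats(1.0, 100.0)),
    min_size=1,
    max_size=6,
)


class TestCosine:
    def test_identity_scores_one(self, toy_spectrum):
        score, matched = gp.cosine_similarity(toy_spectrum, toy_spectrum)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == toy_spectrum.n_peaks

    def test_disjoint_spectra_score_zero(self):
        a = make_spectrum("a", 800.0, [(100.0, 10.0), (200.0, 10.0)])
        b = make_spectrum("b", 800.0, [(150.0, 10.0), (250.0, 10.0)])
        assert gp.cosine_similarity(a, b) == (0.0, 0)

    def test_empty_spectrum_rejected(self, toy_spectrum):
        empty = make_spectrum("e", 800.0, [])
        with pytest.raises(ValueError):
            gp.cosine_similarity(toy_spectrum, empty)

    def test_three_peak_pair_matches_brute_force(self):
        a = make_spectrum("a", 800.0, [(100.000, 50.0), (100.015, 20.0), (200.0, 30.0)])
        b = make_spectrum("b", 800.0, [(100.010, 40.0), (100.025, 60.0), (200.005, 30.0)])
        score, matched = gp.cosine_similarity(a, b, 0.02)
        bscore, bmatched = brute_force_cosine(a, b, 0.02)
        assert score == pytest.approx(bscore, abs=1e-12)

    @given(small_spectra, small_spectra, st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_random_small_spectra(self, pa, pb, _):
        a = make_spectrum("a", 800.0, [(m, i) for m, i in pa])
        b = make_spectrum("b", 800.0, [(m, i) for m, i in pb])
        score, _ = gp.cosine_similarity(a, b, 0.02)
        bscore, _ = brute_force_cosine(a, b, 0.02)
        assert score == pytest.approx(bscore, abs=1e-9)

    def test_symmetric_and_scale_invariant(self, toy_spectrum):
        other = make_spectrum("o", 800.0, [(204.088, 5.0), (366.141, 80.0), (900.0, 3.0)])
        s1, m1 = gp.cosine_similarity(toy_spectrum, other)
        s2, m2 = gp.cosine_similarity(other, toy_spectrum)
        assert s1 == pytest.approx(s2, abs=1e-12) and m1 == m2
        scaled = make_spectrum("s", 800.0, list(zip(other.mz, other.intensity * 37.0)))
        s3, _ = gp.cosine_similarity(toy_spectrum, scaled)
        assert s3 == pytest.approx(s1, abs=1e-12)


class TestClustering:
    def test_duplicates_merge_into_one_node(self, toy_spectrum):
        dup = make_spectrum("dup", toy_spectrum.precursor_mz,
                            list(zip(toy_spectrum.mz, toy_spectrum.intensity)))
        nodes = gp.cluster_spectra([toy_spectrum, dup])
        assert len(nodes) == 1
        assert nodes[0].n_members == 2

    def test_distant_precursors_stay_separate(self, toy_spectrum):
        shifted = make_spectrum("far", toy_spectrum.precursor_mz + 1.0,
                                list(zip(toy_spectrum.mz, toy_spectrum.intensity)))
        nodes = gp.cluster_spectra([toy_spectrum, shifted])
        assert len(nodes) == 2

    def test_members_within_precursor_tolerance_of_consensus(self, sim_config):
        panel = gp.sample_population(sim_config)
        run, truth = gp.simulate_dda_run(panel, sim_config)
        nodes = gp.cluster_spectra([gp.preprocess_peaks(s) for s in run.ms2()])
        member_mz = {s.scan_id: s.precursor_mz for s in run.ms2()}
        for n in nodes:
            for sid in n.member_scan_ids:
                assert abs(member_mz[sid] - n.precursor_mz) <= 0.02 + 1e-9

    def test_replicate_panel_recovers_one_node_per_glycoform(self, sim_config):
        panel = gp.sample_population(sim_config).head(10)
        panel = panel.assign(proportion=panel["proportion"] / panel["proportion"].sum())
        run, truth = gp.simulate_dda_run(panel, sim_config)
        nodes = gp.cluster_spectra([gp.preprocess_peaks(s) for s in run.ms2()])
        assert len(nodes) == 10
        assert all(n.n_members == sim_config.scans_per_glycoform for n in nodes)


class TestNetwork:
    def _ladder_nodes(self):
        """Consensus nodes for glycoforms differing by one Hex each."""
        nodes = []
        pep = "EEQYNSTYR"
        for k in range(4):
            g = gp.GlycanComposition(HexNAc=2, Hex=3 + k)
            ion = gp.GlycopeptideIon(pep, g, charge=2)
            mz, inten = gp.theoretical_fragments(ion, "stepped")
            s = gp.Spectrum(scan_id=f"l{k}", precursor_mz=ion.mz(), precursor_charge=2,
                            mz=mz, intensity=inten)
            nodes.append(gp.ConsensusSpectrum(
                node_id=f"n{k}", member_scan_ids=[f"l{k}"], precursor_mz=ion.mz(),
                precursor_charge=2, retention_time=17.0, mz=s.mz, intensity=s.intensity))
        return nodes

    def test_thresholds_respected(self):
        a = make_spectrum("a", 800.0, [(100.0 + i, 10.0) for i in range(7)])
        b = make_spectrum("b", 800.3, [(100.0 + i, 10.0) for i in range(7)])
        na = gp.ConsensusSpectrum("na", ["a"], 800.0, 2, 1.0, a.mz, a.intensity)
        nb = gp.ConsensusSpectrum("nb", ["b"], 800.3, 2, 1.0, b.mz, b.intensity)
        net = gp.build_network([na, nb], min_cosine=0.7, min_matched=6)
        assert net.has_edge("na", "nb")
        # same pair but only 5 shared peaks -> no edge
        b5 = make_spectrum("b", 800.3, [(100.0 + i, 10.0) for i in range(5)] + [(300.0, 10.0), (310.0, 10.0)])
        nb5 = gp.ConsensusSpectrum("nb", ["b"], 800.3, 2, 1.0, b5.mz, b5.intensity)
        net5 = gp.build_network([na, nb5], min_cosine=0.7, min_matched=6)
        assert not net5.has_edge("na", "nb")

    def test_hexose_ladder_forms_connected_path_with_hex_deltas(self):
        net = gp.build_network(self._ladder_nodes())
        import networkx as nx
        assert nx.is_connected(net)
        hex_mass_over_z = 162.0528 / 2
        consecutive = [(f"n{k}", f"n{k+1}") for k in range(3)]
        for u, v in consecutive:
            assert net.has_edge(u, v)
            assert abs(abs(net.edges[u, v]["delta"]) - hex_mass_over_z) < 0.01

    def test_result_invariant_to_node_order(self):
        nodes = self._ladder_nodes()
        net1 = gp.build_network(nodes)
        net2 = gp.build_network(list(reversed(nodes)))
        assert set(net1.edges) == set(net2.edges)
        for e in net1.edges:
            assert net1.edges[e]["cosine"] == pytest.approx(net2.edges[e]["cosine"], abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gp.build_network([])


class TestMassShiftHistogram:
    def test_single_hex_edge_annotated(self):
        nodes = TestNetwork()._ladder_nodes()[:2]
        net = gp.build_network(nodes)
        hist = gp.mass_shift_histogram(net)
        assert len(hist) == 1
        # m/z delta at z=2 is half a hexose; annotation works on the m/z axis
        assert hist["count"].iloc[0] == 1

    def test_neutral_mass_deltas_annotated_as_hexose(self):
        # singly charged ladder: precursor m/z deltas equal residue masses
        pep = "EEQYNSTYR"
        nodes = []
        for k in range(3):
            g = gp.GlycanComposition(HexNAc=2, Hex=3 + k)
            ion = gp.GlycopeptideIon(pep, g, charge=1)
            mz, inten = gp.theoretical_fragments(ion, "stepped")
            nodes.append(gp.ConsensusSpectrum(
                node_id=f"n{k}", member_scan_ids=[f"s{k}"], precursor_mz=ion.mz(),
                precursor_charge=1, retention_time=17.0, mz=mz, intensity=inten))
        net = gp.build_network(nodes, min_matched=4)
        hist = gp.mass_shift_histogram(net)
        hex_rows = hist[hist["annotation"].str.contains("Hex", na=False)]
        assert not hex_rows.empty

    def test_edgeless_network_rejected(self, toy_spectrum):
        n = gp.ConsensusSpectrum("solo", ["toy"], 800.0, 2, 1.0,
                                 toy_spectrum.mz, toy_spectrum.intensity)
        net = gp.build_network([n])
        with pytest.raises(ValueError):
            gp.mass_shift_histogram(net)
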