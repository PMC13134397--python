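"""Seeding, proton transfer and annotation propagation on toy networks."""

import numpy as np
import pytest

import glycopop as gp
from glycopop.networking import ConsensusSpectrum

PEP = "EEQYNSTYR"


def chain_network(compositions, charge=1, extra_edges=(), node_ids=None):
    """A path network of glycopeptide nodes in the given order."""
    import networkx as nx

    nodes = []
    for k, comp in enumerate(compositions):
        ion = gp.GlycopeptideIon(PEP, comp, charge=charge)
        mz, inten = gp.theoretical_fragments(ion, "stepped")
        nid = node_ids[k] if node_ids else f"n{k}"
        nodes.append(
            ConsensusSpectrum(
                node_id=nid,
                member_scan_ids=[f"scan{k}"],
                precursor_mz=ion.mz(),
                precursor_charge=charge,
                retention_time=17.0,
                mz=mz,
                intensity=inten,
            )
        )
    g = nx.Graph()
    for n in nodes:
        g.add_node(n.node_id, consensus=n)
    for a, b in zip(nodes, nodes[1:]):
        g.add_edge(a.node_id, b.node_id, cosine=0.9, matched=10,
                   delta=b.precursor_mz - a.precursor_mz)
    for a, b in extra_edges:
        g.add_edge(a, b, cosine=0.9, matched=10,
                   delta=g.nodes[b]["consensus"].precursor_mz - g.nodes[a]["consensus"].precursor_mz)
    return g


def hex_chain(n=5):
    return [gp.GlycanComposition(HexNAc=2, Hex=3 + k) for k in range(n)]


class TestSeeding:
    def test_matching_psm_seeds_node(self):
        net = chain_network(hex_chain(2))
        psm = gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)
        rep = gp.seed_nodes(net, [psm])
        assert rep.n_seeded == 1
        ann = gp.annotations(net)["n0"]
        assert ann.source == "seed" and ann.glycan == hex_chain(1)[0]

    def test_one_proton_discrepancy_still_seeds(self):
        net = chain_network(hex_chain(1))
        c = net.nodes["n0"]["consensus"]
        c.precursor_mz += gp.PROTON_MASS  # looks 1 Da heavier than the PSM mass
        rep = gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)])
        assert rep.n_seeded == 1

    def test_three_dalton_error_not_seeded(self):
        net = chain_network(hex_chain(1))
        net.nodes["n0"]["consensus"].precursor_mz += 3.0
        rep = gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)])
        assert rep.n_seeded == 0

    def test_low_score_psm_ignored(self):
        net = chain_network(hex_chain(1))
        rep = gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 50.0)])
        assert rep.n_seeded == 0

    def test_conflicting_psms_resolved_by_score(self):
        net = chain_network(hex_chain(1))
        right = gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 500.0)
        wrong_but_isobaric = gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0] + gp.GlycanComposition(), 200.0)
        gp.seed_nodes(net, [wrong_but_isobaric, right])
        assert gp.annotations(net)["n0"].mass_error <= 0.1

    def test_unknown_scan_skipped_with_warning(self):
        net = chain_network(hex_chain(1))
        rep = gp.seed_nodes(net, [gp.SeedAnnotation("ghost", PEP, hex_chain(1)[0], 300.0)])
        assert rep.n_seeded == 0
        assert any("ghost" in c for c in rep.conflicts)

    def test_psm_tsv_round_trip(self, tmp_path):
        psms = [gp.SeedAnnotation("s1", PEP, gp.parse_composition("HexNAc(4)Hex(5)Fuc(1)"), 250.0)]
        p = tmp_path / "psms.tsv"
        gp.write_psm_tsv(psms, p)
        back = gp.read_psm_tsv(p)
        assert back == psms


class TestProtonTransfer:
    def _net_with_proton_neighbor(self, offset):
        comps = hex_chain(2)
        net = chain_network(comps)
        # make n1 an ionization variant of n0 instead of a Hex addition
        ion0 = gp.GlycopeptideIon(PEP, comps[0], charge=1)
        net.nodes["n1"]["consensus"].precursor_mz = ion0.mz() + offset
        return net

    def test_neighbor_one_dalton_away_gets_identical_annotation(self):
        net = self._net_with_proton_neighbor(gp.PROTON_MASS)
        gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)])
        n = gp.proton_transfer(net)
        assert n == 1
        ann = gp.annotations(net)["n1"]
        assert ann.source == "proton-transfer"
        assert ann.glycan == hex_chain(1)[0] and ann.peptide == PEP

    def test_neighbor_at_2_5_da_unchanged(self):
        net = self._net_with_proton_neighbor(2.5)
        gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)])
        assert gp.proton_transfer(net) == 0
        assert "n1" not in gp.annotations(net)

    def test_competing_transfers_set_ambiguity_flag(self):
        """Two annotated neighbors each 1 Da from one target, with
        different glycans: the target must be flagged ambiguous."""
        from glycopop.network_walk import NodeAnnotation

        comps = [gp.GlycanComposition(HexNAc=2, Hex=3)] * 3
        net = chain_network(comps, extra_edges=[("n0", "n2")])
        # target n1 sits one proton above n0 and one below n2
        base = net.nodes["n0"]["consensus"].precursor_mz
        net.nodes["n1"]["consensus"].precursor_mz = base + gp.PROTON_MASS
        net.nodes["n2"]["consensus"].precursor_mz = base + 2 * gp.PROTON_MASS
        net.remove_edge("n0", "n2")
        net.add_edge("n1", "n2", cosine=0.9, matched=10, delta=gp.PROTON_MASS)
        g_a = comps[0]
        g_b = gp.GlycanComposition(HexNAc=2, Hex=3, Fuc=1)
        net.nodes["n0"]["annotation"] = NodeAnnotation("n0", PEP, g_a, "seed", 1)
        net.nodes["n2"]["annotation"] = NodeAnnotation("n2", PEP, g_b, "seed", 1)
        assert gp.proton_transfer(net) == 1
        ann = gp.annotations(net)["n1"]
        assert ann.source == "proton-transfer"
        assert ann.ambiguous
        assert len(ann.alternatives) == 1


class TestPropagation:
    def test_hexose_neighbor_annotated_via_delta(self):
        net = chain_network(hex_chain(2))
        gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)])
        rep = gp.propagate(net)
        ann = gp.annotations(net)["n1"]
        assert ann.source == "propagated"
        assert ann.glycan == gp.GlycanComposition(HexNAc=2, Hex=4)
        assert dict(ann.delta.counts) == {"Hex": 1}

    def test_unexplainable_delta_stays_unannotated(self):
        net = chain_network(hex_chain(2))
        net.nodes["n1"]["consensus"].precursor_mz = (
            net.nodes["n0"]["consensus"].precursor_mz + 50.0
        )
        net.edges["n0", "n1"]["delta"] = 50.0
        gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)])
        gp.propagate(net)
        assert "n1" not in gp.annotations(net)

    def test_negative_count_candidates_rejected(self):
        # neighbor at +15.995 (=-Fuc+Hex) of a fucose-free seed: no valid glycan
        comps = [gp.GlycanComposition(HexNAc=2, Hex=3)] * 2
        net = chain_network(comps)
        ion = gp.GlycopeptideIon(PEP, comps[0], charge=1)
        net.nodes["n1"]["consensus"].precursor_mz = ion.mz() + 15.995
        gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, comps[0], 300.0)])
        gp.propagate(net)
        ann = gp.annotations(net).get("n1")
        # the -Fuc+Hex route is impossible; any annotation must use another
        # decomposition (-NeuAc+NeuGc is equally impossible without NeuAc)
        assert ann is None

    def test_chain_fully_annotated_with_hop_counts(self):
        net = chain_network(hex_chain(5))
        gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)])
        rep = gp.propagate(net)
        ann = gp.annotations(net)
        assert len(ann) == 5
        assert [ann[f"n{k}"].hop for k in range(5)] == [0, 1, 2, 3, 4]
        assert ann["n4"].glycan == gp.GlycanComposition(HexNAc=2, Hex=7)

    def test_termination_and_monotone_growth(self):
        net = chain_network(hex_chain(5))
        gp.seed_nodes(net, [gp.SeedAnnotation("scan2", PEP, hex_chain(3)[2], 300.0)])
        rep = gp.propagate(net)
        assert rep.n_iterations < 10
        again = gp.propagate(net)
        assert again.n_propagated == 0  # fixed point

    def test_peptide_backbone_never_changes(self):
        net = chain_network(hex_chain(5))
        gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)])
        gp.propagate(net)
        assert all(a.peptide == PEP for a in gp.annotations(net).values())

    def test_seeds_immutable(self):
        net = chain_network(hex_chain(3))
        gp.seed_nodes(net, [
            gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0),
            gp.SeedAnnotation("scan2", PEP, hex_chain(3)[2], 300.0),
        ])
        before = {k: a.glycan for k, a in gp.annotations(net).items() if a.source == "seed"}
        gp.propagate(net)
        after = {k: a.glycan for k, a in gp.annotations(net).items() if gp.annotations(net)[k].source == "seed"}
        assert before == after

    def test_result_invariant_to_node_relabeling(self):
        """Visitation order must not change the outcome."""
        comps = hex_chain(5)
        base = None
        for labels in (["n0", "n1", "n2", "n3", "n4"], ["z9", "a1", "m5", "b2", "k7"]):
            net = chain_network(comps, node_ids=labels)
            gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, comps[0], 300.0)])
            gp.propagate(net)
            ann = gp.annotations(net)
            result = {i: (str(ann[l].glycan), ann[l].hop) for i, l in enumerate(labels)}
            if base is None:
                base = result
            else:
                assert result == base

    def test_provenance_chains_terminate_at_seed(self):
        net = chain_network(hex_chain(4))
        gp.seed_nodes(net, [gp.SeedAnnotation("scan0", PEP, hex_chain(1)[0], 300.0)])
        gp.propagate(net)
        ann = gp.annotations(net)
        for nid, a in ann.items():
            cur = a
            for _ in range(10):
                if cur.source == "seed":
                    break
                cur = ann[cur.origin]
            assert cur.source == "seed"


class TestRecovery:
    def test_synthetic_dda_recovery_at_30pct_seeding(self):
        """End-to-end: filter -> cluster -> network -> walk on one DDA run."""
        cfg = gp.SimulationConfig(seed=1)
        panel = gp.sample_population(cfg)
        run, truth = gp.simulate_dda_run(panel, cfg)
        spectra = [gp.preprocess_peaks(s) for s in gp.oxonium_filter(run.ms2())]
        nodes = gp.cluster_spectra(spectra)
        net = gp.build_network(nodes)
        node_truth = {
            n.node_id: {truth.scan_truth[s] for s in n.member_scan_ids} for n in nodes
        }
        pure = sum(1 for v in node_truth.values() if len(v) == 1)
        assert pure / len(nodes) >= 0.95  # composition-pure nodes

        keys = sorted({k for v in node_truth.values() for k in v})
        rng = np.random.default_rng(5)
        seed_keys = {keys[i] for i in rng.choice(len(keys), size=int(0.3 * len(keys)), replace=False)}
        by_g = {}
        for sid, k in sorted(truth.scan_truth.items()):
            by_g.setdefault(k, []).append(sid)
        psms = [gp.SeedAnnotation(by_g[k][0], k[0], gp.parse_composition(k[1]), 300.0)
                for k in sorted(seed_keys)]
        gp.walk(net, psms)
        ann = gp.annotations(net)
        unseeded = [nid for nid, v in node_truth.items() if next(iter(v)) not in seed_keys]
        recovered = sum(
            1 for nid in unseeded
            if nid in ann and (ann[nid].peptide, str(ann[nid].glycan)) == next(iter(node_truth[nid]))
        )
        assert recovered / len(unseeded) >= 0.8
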