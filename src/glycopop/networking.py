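"""Spectral clustering and molecular-network construction.

Glycopeptide MS/MS scans that pass the oxonium filter are clustered
into consensus spectra (precursor tolerance 0.02 Da, fragment
tolerance 0.02 Da), and consensus nodes are connected by edges when
their spectral cosine similarity reaches 0.7 with at least 6 matched
fragment ions.  Edges carry the precursor m/z difference, which for
glycopeptides sharing a peptide backbone corresponds to monosaccharide
mass differences — the signal the network walk exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment as _linear_sum_assignment

from .glycan_model import (
    DEFAULT_TABLE,
    CompositionDelta,
    MonosaccharideTable,
    _signed_count_vectors,
)
from .spectra_io import Spectrum


def _best_peak_matching(
    mz_a: np.ndarray,
    int_a: np.ndarray,
    mz_b: np.ndarray,
    int_b: np.ndarray,
    frag_tol: float,
) -> List[Tuple[int, int]]:
    """Optimal one-to-one peak matching within ``frag_tol``.

    Maximizes the total intensity product over all one-to-one
    matchings of peaks within tolerance.  Candidate pairs form a
    bipartite graph that is nearly always a set of trivial one-edge
    components (peaks rarely have two partners within 0.02 Da); each
    ambiguous component is solved exactly by the Hungarian algorithm,
    so the result equals exhaustive best matching.
    """
    candidates: List[Tuple[int, int]] = []
    for i in range(mz_a.size):
        lo = np.searchsorted(mz_b, mz_a[i] - frag_tol, side="left")
        hi = np.searchsorted(mz_b, mz_a[i] + frag_tol, side="right")
        candidates.extend((i, j) for j in range(lo, hi))
    if not candidates:
        return []
    # connected components of the bipartite candidate graph
    parent: Dict[Tuple[str, int], Tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i, j in candidates:
        union(("a", i), ("b", j))
    comps: Dict[Tuple[str, int], List[Tuple[int, int]]] = {}
    for i, j in candidates:
        comps.setdefault(find(("a", i)), []).append((i, j))
    pairs: List[Tuple[int, int]] = []
    for edges in comps.values():
        if len(edges) == 1:
            pairs.append(edges[0])
            continue
        rows = sorted({i for i, _ in edges})
        cols = sorted({j for _, j in edges})
        cost = np.zeros((len(rows), len(cols)))
        ri = {r: k for k, r in enumerate(rows)}
        cj = {c: k for k, c in enumerate(cols)}
        for i, j in edges:
            cost[ri[i], cj[j]] = -(int_a[i] * int_b[j])
        r_idx, c_idx = _linear_sum_assignment(cost)
        for r, c in zip(r_idx, c_idx):
            if cost[r, c] < 0 and (rows[r], cols[c]) in set(edges):
                pairs.append((rows[r], cols[c]))
    pairs.sort()
    return pairs


def cosine_similarity(
    a: Spectrum, b: Spectrum, frag_tol: float = 0.02
) -> Tuple[float, int]:
    """Spectral cosine with square-root intensity weighting.

    Returns (score in [0, 1], number of matched peaks).  The score is
    the normalized dot product over the best one-to-one matching of
    peaks within ``frag_tol``; it is symmetric and invariant to uniform
    intensity scaling of either spectrum.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("cosine similarity undefined for an empty spectrum")
    wa, wb = np.sqrt(a.intensity), np.sqrt(b.intensity)
    pairs = _best_peak_matching(a.mz, wa, b.mz, wb, frag_tol)
    if not pairs:
        return 0.0, 0
    dot = sum(wa[i] * wb[j] for i, j in pairs)
    score = dot / (np.linalg.norm(wa) * np.linalg.norm(wb))
    return float(min(score, 1.0)), len(pairs)


@dataclass
class ConsensusSpectrum:
    """A cluster of near-identical scans merged into one spectrum."""

    node_id: str
    member_scan_ids: List[str]
    precursor_mz: float
    precursor_charge: Optional[int]
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def n_members(self) -> int:
        return len(self.member_scan_ids)

    def as_spectrum(self) -> Spectrum:
        return Spectrum(
            scan_id=self.node_id,
            precursor_mz=self.precursor_mz,
            precursor_charge=self.precursor_charge,
            retention_time=self.retention_time,
            mz=self.mz,
            intensity=self.intensity,
        )


def _merge_peaks(
    members: Sequence[Spectrum], frag_tol: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Pool member peaks and collapse groups within ``frag_tol``.

    Groups are formed by single linkage along the sorted m/z axis; each
    group becomes one consensus peak at the intensity-weighted mean m/z
    with the mean (per member) summed intensity.
    """
    mz = np.concatenate([s.mz for s in members])
    inten = np.concatenate([s.intensity for s in members])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if mz.size == 0:
        return mz, inten
    breaks = np.nonzero(np.diff(mz) > frag_tol)[0] + 1
    out_mz, out_int = [], []
    n = len(members)
    for grp_mz, grp_int in zip(np.split(mz, breaks), np.split(inten, breaks)):
        total = grp_int.sum()
        out_mz.append(float((grp_mz * grp_int).sum() / total) if total > 0 else float(grp_mz.mean()))
        out_int.append(float(total / n))
    return np.array(out_mz), np.array(out_int)


def cluster_spectra(
    spectra: Sequence[Spectrum],
    prec_tol: float = 0.02,
    frag_tol: float = 0.02,
    cluster_min_cosine: float = 0.7,
) -> List[ConsensusSpectrum]:
    """Greedy clustering of scans into consensus spectra.

    Scans are processed in (precursor m/z, scan id) order, which makes
    the result independent of input order.  A scan joins the first
    existing cluster whose consensus precursor is within ``prec_tol``
    and whose consensus spectrum matches at cosine >=
    ``cluster_min_cosine``; otherwise it founds a new cluster.
    """
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.scan_id))
    clusters: List[Dict] = []  # each: {'members': [Spectrum], 'consensus': Spectrum-like fields}
    for s in ordered:
        placed = False
        for c in clusters:
            if abs(c["precursor_mz"] - s.precursor_mz) > prec_tol:
                continue
            consensus = Spectrum(
                scan_id="consensus",
                precursor_mz=c["precursor_mz"],
                mz=c["mz"],
                intensity=c["intensity"],
            )
            score, _ = cosine_similarity(consensus, s, frag_tol)
            if score >= cluster_min_cosine:
                c["members"].append(s)
                mzs = np.array([m.precursor_mz for m in c["members"]])
                c["precursor_mz"] = float(mzs.mean())
                c["mz"], c["intensity"] = _merge_peaks(c["members"], frag_tol)
                placed = True
                break
        if not placed:
            clusters.append(
                {
                    "members": [s],
                    "precursor_mz": s.precursor_mz,
                    "mz": s.mz.copy(),
                    "intensity": s.intensity.copy(),
                }
            )
    out = []
    for k, c in enumerate(clusters):
        members = c["members"]
        charges = {m.precursor_charge for m in members if m.precursor_charge}
        charge = charges.pop() if len(charges) == 1 else None
        out.append(
            ConsensusSpectrum(
                node_id=f"node{k}",
                member_scan_ids=[m.scan_id for m in members],
                precursor_mz=c["precursor_mz"],
                precursor_charge=charge,
                retention_time=float(np.mean([m.retention_time for m in members])),
                mz=c["mz"],
                intensity=c["intensity"],
            )
        )
    return out


def build_network(
    nodes: Sequence[ConsensusSpectrum],
    min_cosine: float = 0.7,
    min_matched: int = 6,
    frag_tol: float = 0.02,
    top_k: Optional[int] = None,
) -> nx.Graph:
    """Score all node pairs and keep edges passing both thresholds.

    Returns an undirected networkx graph whose nodes carry their
    :class:`ConsensusSpectrum` under the ``consensus`` attribute and
    whose edges carry ``cosine``, ``matched`` and the signed precursor
    m/z difference ``delta`` (m/z of the higher-id node minus the
    lower).  With ``top_k`` set, each node keeps only its ``top_k``
    highest-cosine edges (an edge survives if either endpoint ranks it).
    """
    if not nodes:
        raise ValueError("cannot build a network from zero nodes")
    ordered = sorted(nodes, key=lambda n: (n.precursor_mz, n.node_id))
    g = nx.Graph()
    for n in ordered:
        g.add_node(n.node_id, consensus=n)
    specs = {n.node_id: n.as_spectrum() for n in ordered}
    edges = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            score, matched = cosine_similarity(specs[a.node_id], specs[b.node_id], frag_tol)
            if score >= min_cosine and matched >= min_matched:
                edges.append((a.node_id, b.node_id, score, matched, b.precursor_mz - a.precursor_mz))
    if top_k is not None:
        ranked: Dict[str, List[Tuple[float, Tuple]]] = {n.node_id: [] for n in ordered}
        for e in edges:
            ranked[e[0]].append((-e[2], e))
            ranked[e[1]].append((-e[2], e))
        keep = set()
        for node_id, lst in ranked.items():
            lst.sort(key=lambda t: (t[0], t[1][0], t[1][1]))
            for _, e in lst[:top_k]:
                keep.add((e[0], e[1]))
        edges = [e for e in edges if (e[0], e[1]) in keep]
    for u, v, score, matched, delta in edges:
        g.add_edge(u, v, cosine=score, matched=matched, delta=delta)
    return g


def mass_shift_histogram(
    net: nx.Graph,
    bin_width: float = 0.01,
    annotation_tol: float = 0.1,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> pd.DataFrame:
    """Histogram of absolute precursor m/z differences over edges.

    Each populated bin is annotated with the nearest single- or
    di-residue mass combination within ``annotation_tol`` Da (e.g. a
    162.05 shift annotates as Hex; 365.13 as Hex+HexNAc).
    """
    deltas = [abs(d["delta"]) for _, _, d in net.edges(data=True)]
    if not deltas:
        raise ValueError("network has no edges")
    # candidate annotation masses: all positive 1- and 2-residue sums
    combos = {}
    for vec in _signed_count_vectors(table.symbols, 2):
        if not vec or any(c < 0 for c in vec.values()):
            continue
        d = CompositionDelta.from_counts(vec, table)
        combos[d] = d.net_mass
    rows: Dict[float, int] = {}
    for d in deltas:
        rows[round(d / bin_width) * bin_width] = rows.get(round(d / bin_width) * bin_width, 0) + 1
    records = []
    for center in sorted(rows):
        best_name, best_err = "", None
        for combo, m in combos.items():
            err = abs(m - center)
            if err <= annotation_tol and (best_err is None or err < best_err):
                best_name, best_err = str(combo), err
        records.append({"delta": center, "count": rows[center], "annotation": best_name})
    return pd.DataFrame.from_records(records)


def network_tables(net: nx.Graph) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables in a Cytoscape-importable CSV layout."""
    node_rows = []
    for node_id, data in net.nodes(data=True):
        c: ConsensusSpectrum = data["consensus"]
        row = {
            "node_id": node_id,
            "precursor_mz": c.precursor_mz,
            "precursor_charge": c.precursor_charge,
            "retention_time": c.retention_time,
            "n_members": c.n_members,
            "member_scan_ids": ";".join(c.member_scan_ids),
        }
        ann = data.get("annotation")
        if ann is not None:
            row.update(
                peptide=ann.peptide, glycan=str(ann.glycan), source=ann.source,
                hop=ann.hop, mass_error=ann.mass_error, ambiguous=ann.ambiguous,
            )
        node_rows.append(row)
    edge_rows = [
        {"source": u, "target": v, "cosine": d["cosine"], "matched": d["matched"], "delta": d["delta"]}
        for u, v, d in net.edges(data=True)
    ]
    return pd.DataFrame(node_rows), pd.DataFrame(edge_rows)


def write_graphml(net: nx.Graph, path) -> None:
    """GraphML export with consensus objects flattened to attributes."""
    g = nx.Graph()
    for node_id, data in net.nodes(data=True):
        c: ConsensusSpectrum = data["consensus"]
        attrs = {
            "precursor_mz": c.precursor_mz,
            "retention_time": c.retention_time,
            "n_members": c.n_members,
        }
        if c.precursor_charge is not None:
            attrs["precursor_charge"] = c.precursor_charge
        ann = data.get("annotation")
        if ann is not None:
            attrs.update(peptide=ann.peptide, glycan=str(ann.glycan), source=ann.source)
        g.add_node(node_id, **attrs)
    for u, v, d in net.edges(data=True):
        g.add_edge(u, v, cosine=d["cosine"], matched=d["matched"], delta=d["delta"])
    nx.write_graphml(g, str(path))
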