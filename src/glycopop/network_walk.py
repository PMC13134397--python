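"""Annotation propagation over glycopeptide spectral networks.

Database-search identifications seed the network; annotations then
spread outward along edges whose precursor mass difference can be
explained as a combination of at most two added/removed monosaccharide
residues (within 0.1 Da).  A +15.995 Da shift, for example, transfers
an annotation with one fucose (−146.058) swapped for one hexose
(+162.053).  Neighbors exactly one proton apart receive the identical
annotation (ionization differences).  The walk iterates until no new
node can be annotated.

All mass comparisons happen in neutral monoisotopic mass space.  When
a node's consensus charge is unknown, charges 1-4 are tried and the
best-matching interpretation is kept.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .glycan_model import (
    DEFAULT_TABLE,
    PROTON_MASS,
    CompositionDelta,
    GlycanComposition,
    GlycopeptideIon,
    MonosaccharideTable,
    delta_decompositions,
    neutral_from_mz,
    parse_composition,
)
from .networking import ConsensusSpectrum

DEFAULT_SEED_SCORE = 100.0  # search-engine score acceptance threshold
_CANDIDATE_CHARGES = (1, 2, 3, 4)


@dataclass(frozen=True)
class SeedAnnotation:
    """A glycopeptide-spectrum match accepted from a database search."""

    scan_id: str
    peptide: str
    glycan: GlycanComposition
    score: float


def read_psm_tsv(path, table: MonosaccharideTable = DEFAULT_TABLE) -> List[SeedAnnotation]:
    """Read a PSM table: TSV with columns scan_id, peptide, glycan, score."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                SeedAnnotation(
                    scan_id=row["scan_id"],
                    peptide=row["peptide"],
                    glycan=parse_composition(row["glycan"], table),
                    score=float(row["score"]),
                )
            )
    return out


def write_psm_tsv(psms: Sequence[SeedAnnotation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["scan_id", "peptide", "glycan", "score"])
        for p in psms:
            writer.writerow([p.scan_id, p.peptide, str(p.glycan), p.score])


@dataclass
class NodeAnnotation:
    """Annotation state of a network node, with provenance."""

    node_id: str
    peptide: str
    glycan: GlycanComposition
    source: str  # seed | propagated | proton-transfer
    charge: int
    origin: Optional[str] = None  # node the annotation came from
    delta: Optional[CompositionDelta] = None
    mass_error: float = 0.0  # cumulative |Da| along the provenance chain
    hop: int = 0
    ambiguous: bool = False
    alternatives: Tuple[str, ...] = ()


@dataclass
class WalkReport:
    """Bookkeeping from one complete network walk."""

    n_seeded: int = 0
    n_proton_transfer: int = 0
    n_propagated: int = 0
    n_iterations: int = 0
    n_scans_annotated: int = 0
    conflicts: List[str] = field(default_factory=list)


def _node_mass_interpretations(c: ConsensusSpectrum) -> List[Tuple[float, int]]:
    """Neutral-mass hypotheses for a consensus node.

    One hypothesis per charge: the known consensus charge if present,
    otherwise charges 1-4.
    """
    charges = (c.precursor_charge,) if c.precursor_charge else _CANDIDATE_CHARGES
    return [(neutral_from_mz(c.precursor_mz, z), z) for z in charges]


def seed_nodes(
    net: nx.Graph,
    psms: Sequence[SeedAnnotation],
    tol: float = 0.1,
    min_score: float = DEFAULT_SEED_SCORE,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> WalkReport:
    """Attach search identifications to network nodes.

    A node is seeded when one of its member scans carries a PSM whose
    glycopeptide neutral mass matches a node mass hypothesis within
    ``tol`` Da, allowing an extra ±1 proton discrepancy (ionization
    artifacts).  Conflicting PSMs on one node resolve to the highest
    search score.  PSMs whose scan id appears in no node are skipped.
    """
    report = WalkReport()
    scan_to_node: Dict[str, str] = {}
    for node_id, data in net.nodes(data=True):
        for sid in data["consensus"].member_scan_ids:
            scan_to_node[sid] = node_id
    best: Dict[str, Tuple[float, SeedAnnotation, int, float]] = {}
    for psm in psms:
        if psm.score <= min_score:
            continue
        node_id = scan_to_node.get(psm.scan_id)
        if node_id is None:
            report.conflicts.append(f"PSM scan {psm.scan_id!r} matches no node; skipped")
            continue
        gp_mass = GlycopeptideIon(psm.peptide, psm.glycan, charge=1).neutral_mass(table)
        consensus = net.nodes[node_id]["consensus"]
        for node_mass, z in _node_mass_interpretations(consensus):
            errors = [abs(node_mass - gp_mass)]
            errors.append(abs(node_mass - gp_mass - PROTON_MASS))
            errors.append(abs(node_mass - gp_mass + PROTON_MASS))
            err = min(errors)
            if err <= tol:
                cur = best.get(node_id)
                if cur is None or psm.score > cur[0]:
                    best[node_id] = (psm.score, psm, z, err)
                break
    for node_id, (score, psm, z, err) in best.items():
        net.nodes[node_id]["annotation"] = NodeAnnotation(
            node_id=node_id,
            peptide=psm.peptide,
            glycan=psm.glycan,
            source="seed",
            charge=z,
            mass_error=err,
        )
        report.n_seeded += 1
    return report


def _annotated(net: nx.Graph) -> Dict[str, NodeAnnotation]:
    return {
        n: d["annotation"] for n, d in net.nodes(data=True) if d.get("annotation")
    }


def proton_transfer(net: nx.Graph, tol: float = 0.1) -> int:
    """Copy annotations to neighbors exactly one proton apart.

    Neighboring nodes whose neutral masses (under some charge
    hypothesis pair) differ by 1.00728 Da within ``tol`` receive the
    identical peptide+glycan annotation, tagged ``proton-transfer``.
    Seeds are never overwritten.  Competing sources with different
    annotations mark the target ambiguous.  Returns the number of
    nodes annotated.
    """
    proposals: Dict[str, List[NodeAnnotation]] = {}
    for node_id, ann in sorted(_annotated(net).items()):
        origin_mass = neutral_from_mz(
            net.nodes[node_id]["consensus"].precursor_mz, ann.charge
        )
        for nbr in sorted(net.neighbors(node_id)):
            if net.nodes[nbr].get("annotation") is not None:
                continue
            for nbr_mass, z in _node_mass_interpretations(net.nodes[nbr]["consensus"]):
                err = abs(abs(nbr_mass - origin_mass) - PROTON_MASS)
                if err <= tol:
                    proposals.setdefault(nbr, []).append(
                        NodeAnnotation(
                            node_id=nbr,
                            peptide=ann.peptide,
                            glycan=ann.glycan,
                            source="proton-transfer",
                            charge=z,
                            origin=node_id,
                            mass_error=ann.mass_error + err,
                            hop=ann.hop + 1,
                        )
                    )
                    break
    n_new = 0
    for nbr, cands in proposals.items():
        cands.sort(key=lambda a: (a.hop, a.mass_error, a.origin))
        chosen = cands[0]
        distinct = {(a.peptide, a.glycan) for a in cands}
        if len(distinct) > 1:
            chosen = replace(
                chosen,
                ambiguous=True,
                alternatives=tuple(
                    sorted(f"{p}+{g}" for p, g in distinct if (p, g) != (chosen.peptide, chosen.glycan))
                ),
            )
        net.nodes[nbr]["annotation"] = chosen
        n_new += 1
    return n_new


def _delta_candidates(
    origin: NodeAnnotation,
    origin_mass: float,
    nbr_consensus: ConsensusSpectrum,
    max_changes: int,
    tol: float,
    table: MonosaccharideTable,
) -> Optional[NodeAnnotation]:
    """Best propagated annotation for one neighbor, or None."""
    best: Optional[Tuple[Tuple, NodeAnnotation]] = None
    for nbr_mass, z in _node_mass_interpretations(nbr_consensus):
        mass_delta = nbr_mass - origin_mass
        for cand in delta_decompositions(mass_delta, max_changes, tol, table):
            new_glycan = cand.apply(origin.glycan)
            if new_glycan is None:
                continue
            ann = NodeAnnotation(
                node_id=nbr_consensus.node_id,
                peptide=origin.peptide,
                glycan=new_glycan,
                source="propagated",
                charge=z,
                origin=origin.node_id,
                delta=cand,
                mass_error=origin.mass_error + cand.error,
                hop=origin.hop + 1,
            )
            key = (cand.n_changes, cand.error, str(new_glycan))
            if best is None or key < best[0]:
                best = (key, ann)
    return best[1] if best else None


def propagate(
    net: nx.Graph,
    max_changes: int = 2,
    tol: float = 0.1,
    max_hops: Optional[int] = None,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> WalkReport:
    """Breadth-first annotation propagation until a fixed point.

    Each iteration first applies the exact one-proton transfer rule,
    then offers every unannotated neighbor of an annotated node the
    annotation implied by decomposing the neutral-mass difference into
    at most ``max_changes`` residue additions/removals within ``tol``
    Da, rejecting any candidate that would drive a residue count
    negative.  Proposals for one target are resolved by (hop count,
    cumulative |mass error|); competing distinct annotations set the
    ambiguity flag.  Frontiers are committed level-by-level, which
    makes the result independent of neighbor visitation order.
    """
    report = WalkReport()
    if not _annotated(net):
        return report
    while True:
        report.n_iterations += 1
        n_pt = proton_transfer(net, tol)
        report.n_proton_transfer += n_pt
        frontier = _annotated(net)
        proposals: Dict[str, List[NodeAnnotation]] = {}
        for node_id, ann in sorted(frontier.items()):
            if max_hops is not None and ann.hop >= max_hops:
                continue
            origin_mass = neutral_from_mz(
                net.nodes[node_id]["consensus"].precursor_mz, ann.charge
            )
            for nbr in sorted(net.neighbors(node_id)):
                if net.nodes[nbr].get("annotation") is not None:
                    continue
                cand = _delta_candidates(
                    ann, origin_mass, net.nodes[nbr]["consensus"], max_changes, tol, table
                )
                if cand is not None:
                    proposals.setdefault(nbr, []).append(cand)
        n_new = 0
        for nbr in sorted(proposals):
            cands = proposals[nbr]
            cands.sort(key=lambda a: (a.hop, a.mass_error, str(a.glycan), a.origin))
            chosen = cands[0]
            distinct = {(a.peptide, a.glycan) for a in cands}
            if len(distinct) > 1:
                chosen = replace(
                    chosen,
                    ambiguous=True,
                    alternatives=tuple(
                        sorted(
                            f"{p}+{g}"
                            for p, g in distinct
                            if (p, g) != (chosen.peptide, chosen.glycan)
                        )
                    ),
                )
                report.conflicts.append(
                    f"node {nbr}: {len(distinct)} competing annotations"
                )
            net.nodes[nbr]["annotation"] = chosen
            n_new += 1
        report.n_propagated += n_new
        if n_new == 0 and n_pt == 0:
            break
    report.n_scans_annotated = sum(
        net.nodes[n]["consensus"].n_members for n in _annotated(net)
    )
    return report


def walk(
    net: nx.Graph,
    psms: Sequence[SeedAnnotation],
    max_changes: int = 2,
    tol: float = 0.1,
    min_score: float = DEFAULT_SEED_SCORE,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> WalkReport:
    """Seed, then propagate to convergence; merged report."""
    seed_report = seed_nodes(net, psms, tol=tol, min_score=min_score, table=table)
    prop_report = propagate(net, max_changes=max_changes, tol=tol, table=table)
    prop_report.n_seeded = seed_report.n_seeded
    prop_report.conflicts = seed_report.conflicts + prop_report.conflicts
    return prop_report


def annotations(net: nx.Graph) -> Dict[str, NodeAnnotation]:
    """All current node annotations keyed by node id."""
    return _annotated(net)
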