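"""Composition-level N-glycan biosynthesis rules and substructure networks.

Observed glycoform compositions are closed downward to the trimannosyl
core (HexNAc(2)Hex(3)) by single-residue removals, adding only
intermediates a mammalian N-glycosylation pathway could produce.  The
resulting acyclic substructure graph — observed nodes plus inferred
intermediates — is the basis of the theoretical transition library:
any fragment of any member glycoform is a node of this network.

Rules operate at composition resolution only (Hex, not Man/Gal), which
matches the resolution of database-search output.  The rule set is a
configurable predicate table; the defaults encode the coarse
constraints of the complex/hybrid/high-mannose pathway plus an
optional endoglycosidase-truncation class (HexNAc(1) ± core fucose)
for infection samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .glycan_model import (
    DEFAULT_TABLE,
    GlycanComposition,
    GlycopeptideIon,
    MonosaccharideTable,
    format_composition,
)

TRIMANNOSYL_CORE = GlycanComposition(HexNAc=2, Hex=3)


@dataclass(frozen=True)
class BiosynthesisRules:
    """Predicate set deciding which compositions are pathway-valid.

    Defaults: at least the chitobiose+trimannosyl core (HexNAc >= 2,
    Hex >= 3; Hex >= 2 when the paucimannose exception is on); sialic
    acids capped by available antennae (NeuAc+NeuGc <= HexNAc-2) and
    requiring galactosylation capacity (Hex > 3); at most 2 fucoses.
    With ``allow_truncated`` on, the endoglycosidase product class
    HexNAc(1) with at most one fucose and nothing else is also valid.
    """

    min_hexnac: int = 2
    min_hex: int = 3
    paucimannose: bool = False  # relaxes min_hex to 2
    max_fuc: int = 2
    sialic_requires_hex_gt: int = 3
    allow_truncated: bool = False
    root: GlycanComposition = TRIMANNOSYL_CORE
    max_counts: Tuple[Tuple[str, int], ...] = (
        ("HexNAc", 8), ("Hex", 12), ("Fuc", 2), ("NeuAc", 4), ("NeuGc", 4),
    )

    def __post_init__(self):
        ok, violated = self.validate(self.root)
        if not ok:
            raise ValueError(f"root composition violates rules: {violated}")

    def _is_truncation_product(self, g: GlycanComposition) -> bool:
        return (
            g["HexNAc"] == 1
            and g["Fuc"] <= 1
            and g.total == g["HexNAc"] + g["Fuc"]
        )

    def validate(self, g: GlycanComposition) -> Tuple[bool, List[str]]:
        """Check every predicate; returns (valid, names of violated rules)."""
        if self.allow_truncated and self._is_truncation_product(g):
            return True, []
        violated = []
        min_hex = 2 if self.paucimannose else self.min_hex
        if g["HexNAc"] < self.min_hexnac:
            violated.append("core_hexnac")
        if g["Hex"] < min_hex:
            violated.append("core_hex")
        sia = g["NeuAc"] + g["NeuGc"]
        if sia > max(0, g["HexNAc"] - 2):
            violated.append("sialic_per_antenna")
        if sia > 0 and g["Hex"] <= self.sialic_requires_hex_gt:
            violated.append("sialic_requires_galactose")
        if g["Fuc"] > self.max_fuc:
            violated.append("max_fucose")
        for sym, cap in self.max_counts:
            if g[sym] > cap:
                violated.append(f"max_{sym.lower()}")
        return not violated, violated


DEFAULT_RULES = BiosynthesisRules()


def is_valid_nglycan(
    g: GlycanComposition, rules: BiosynthesisRules = DEFAULT_RULES
) -> Tuple[bool, List[str]]:
    """True iff the composition satisfies all biosynthesis predicates."""
    return rules.validate(g)


def _children(g: GlycanComposition) -> Iterable[GlycanComposition]:
    """All compositions one residue smaller."""
    for sym in sorted(g):
        counts = dict(g)
        counts[sym] -= 1
        yield GlycanComposition(counts)


def infer_substructure_network(
    observed: Iterable[GlycanComposition],
    rules: BiosynthesisRules = DEFAULT_RULES,
    root: Optional[GlycanComposition] = None,
) -> nx.DiGraph:
    """Close an observed composition set downward to the root.

    Starting from the observed glycoforms, single-residue removals are
    applied repeatedly; every rule-valid intermediate (and the root)
    joins the network.  Directed edges run parent -> child, child being
    one residue smaller.  Nodes carry ``observed`` (bool) and
    ``reachable`` (whether a path to the root exists); unreachable
    observed nodes are kept as isolated flagged nodes rather than
    silently dropped.
    """
    root = root if root is not None else rules.root
    observed = list(observed)
    for g in observed:
        ok, violated = rules.validate(g)
        if not ok:
            raise ValueError(
                f"observed composition {format_composition(g)} violates rules: {violated}"
            )
    g_net = nx.DiGraph()

    def node_key(c: GlycanComposition) -> str:
        return format_composition(c) or "(empty)"

    def ensure_node(c: GlycanComposition, obs: bool):
        key = node_key(c)
        if key not in g_net:
            g_net.add_node(key, composition=c, observed=obs)
        elif obs:
            g_net.nodes[key]["observed"] = True

    ensure_node(root, False)
    frontier = list(dict.fromkeys(observed))
    for c in frontier:
        ensure_node(c, True)
    seen: Set[GlycanComposition] = set(frontier) | {root}
    while frontier:
        nxt = []
        for parent in frontier:
            if parent == root:
                continue
            for child in _children(parent):
                valid, _ = rules.validate(child)
                if not (valid or child == root):
                    continue
                ensure_node(child, False)
                g_net.add_edge(node_key(parent), node_key(child))
                if child not in seen:
                    seen.add(child)
                    nxt.append(child)
        frontier = nxt
    # reachability: a node reaches the root iff root is a descendant
    root_key = node_key(root)
    ancestors = nx.ancestors(g_net, root_key) | {root_key}
    for key in g_net.nodes:
        g_net.nodes[key]["reachable"] = key in ancestors
    return g_net


def substructure_table(net: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {
            "composition": key,
            "observed": d["observed"],
            "inferred": not d["observed"],
            "reachable": d["reachable"],
            "n_residues": d["composition"].total,
        }
        for key, d in net.nodes(data=True)
    ]
    return pd.DataFrame(rows).sort_values(["n_residues", "composition"]).reset_index(drop=True)


def curate_precursor_list(
    compositions: Iterable[GlycanComposition],
    peptides: Sequence[str],
    charges: Sequence[int] = (1, 2, 3, 4),
    rules: BiosynthesisRules = DEFAULT_RULES,
    mz_range: Tuple[float, float] = (100.0, 1800.0),
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> pd.DataFrame:
    """Rule-valid composition x peptide x charge precursor table.

    Invalid compositions are dropped (with the violated rule recorded
    in the returned frame's ``attrs['rejected']``); precursors outside
    the instrument scan range are filtered out.
    """
    rows = []
    rejected = []
    lo, hi = mz_range
    for comp in compositions:
        ok, violated = rules.validate(comp)
        if not ok:
            rejected.append((format_composition(comp), ";".join(violated)))
            continue
        for pep in peptides:
            for z in charges:
                ion = GlycopeptideIon(pep, comp, charge=z)
                mz = ion.mz(table)
                if lo <= mz <= hi:
                    rows.append(
                        {
                            "peptide": pep,
                            "glycan": format_composition(comp),
                            "charge": z,
                            "neutral_mass": ion.neutral_mass(table),
                            "mz": mz,
                        }
                    )
    df = pd.DataFrame(rows, columns=["peptide", "glycan", "charge", "neutral_mass", "mz"])
    df.attrs["rejected"] = rejected
    return df
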