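"""Precursor and fragment transition libraries for wide-window DIA.

Two library flavours are built from a curated precursor table:

* **precursor transitions** — 3 isotope peaks per glycopeptide
  precursor, for MS1 quantification of individual glycoforms;
* **fragment transitions** — oxonium ions of glycan sub-units and the
  Y ladder (sequential monosaccharide losses down to Y1), for MS2
  extraction from wide DIA windows.

Fragment transitions are then *collapsed into feature superclasses*
(fucosylation, galactosylation, sialylation, high-mannose): each
feature collects every fragment ion, from any precursor, whose glycan
composition satisfies the feature's criterion.  A member transition is
flagged *specific* when no fragment anywhere in the library within the
m/z tolerance violates the criterion; only specific transitions should
be used for feature quantification (the ubiquitous HexNAc oxonium at
204.09, for instance, is never specific).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .glycan_model import (
    DEFAULT_TABLE,
    ISOTOPE_SPACING,
    GlycanComposition,
    GlycopeptideIon,
    MonosaccharideTable,
    format_composition,
    oxonium_mz,
    parse_composition,
    sub_compositions,
    y_ion_ladder,
)

MZ_RANGE = (100.0, 1800.0)


@dataclass(frozen=True)
class Transition:
    """One extractable ion: precursor context + product m/z."""

    entry_id: str
    precursor_name: str  # "peptide+glycan" or a feature superclass tag
    precursor_mz: float
    precursor_charge: int
    product_mz: float
    product_charge: int
    kind: str  # oxonium | Y | precursor-isotope
    composition: Optional[str] = None  # glycan composition of the fragment
    isotope: int = 0
    water_losses: int = 0


def _in_range(mz: float, mz_range: Tuple[float, float] = MZ_RANGE) -> bool:
    return mz_range[0] <= mz <= mz_range[1]


def build_precursor_transitions(
    precursors: Sequence[GlycopeptideIon],
    n_isotopes: int = 3,
    mz_range: Tuple[float, float] = MZ_RANGE,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> List[Transition]:
    """MS1 isotope transitions: ``n_isotopes`` peaks spaced 1.00336/z."""
    out = []
    for ion in precursors:
        m0 = ion.mz(table)
        name = f"{ion.peptide}+{format_composition(ion.glycan)}"
        for k in range(n_isotopes):
            mz = m0 + k * ISOTOPE_SPACING / ion.charge
            if _in_range(mz, mz_range):
                out.append(
                    Transition(
                        entry_id=f"{name}/{ion.charge}+ M+{k}",
                        precursor_name=name,
                        precursor_mz=m0,
                        precursor_charge=ion.charge,
                        product_mz=mz,
                        product_charge=ion.charge,
                        kind="precursor-isotope",
                        composition=format_composition(ion.glycan),
                        isotope=k,
                    )
                )
    return out


def build_fragment_transitions(
    precursors: Sequence[GlycopeptideIon],
    ladder_policy: str = "lattice",
    oxonium_max_residues: int = 3,
    water_losses: Sequence[int] = (0, 1),
    fragment_charges: Sequence[int] = (1,),
    mz_range: Tuple[float, float] = MZ_RANGE,
    dedup_tol: float = 1e-4,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> List[Transition]:
    """Oxonium + Y-ladder transitions for each precursor.

    Oxonium ions are generated for every sub-unit of the precursor's
    glycan of up to ``oxonium_max_residues`` residues (so a sialylated
    complex glycan yields 204.09, 292.10, 366.14, 657.24, ...), with
    the configured water losses.  Y ions come from
    :func:`glycopop.glycan_model.y_ion_ladder`.  Transitions are
    deduplicated per precursor at ``dedup_tol`` Th.
    """
    out = []
    for ion in precursors:
        name = f"{ion.peptide}+{format_composition(ion.glycan)}"
        prec_mz = ion.mz(table)
        seen: List[float] = []

        def add(t: Transition):
            for m in seen:
                if abs(m - t.product_mz) < dedup_tol:
                    return
            seen.append(t.product_mz)
            out.append(t)

        for sub in sub_compositions(ion.glycan, include_full=ion.glycan.total <= oxonium_max_residues):
            if sub.total > oxonium_max_residues:
                continue
            for wl in water_losses:
                mz = oxonium_mz(sub, wl, table)
                if _in_range(mz, mz_range):
                    add(
                        Transition(
                            entry_id=f"{name} ox:{format_composition(sub)}-{wl}w",
                            precursor_name=name,
                            precursor_mz=prec_mz,
                            precursor_charge=ion.charge,
                            product_mz=mz,
                            product_charge=1,
                            kind="oxonium",
                            composition=format_composition(sub),
                            water_losses=wl,
                        )
                    )
        for y in y_ion_ladder(ion, charges=tuple(fragment_charges), policy=ladder_policy, table=table):
            for z, mz in y.mz_by_charge.items():
                if _in_range(mz, mz_range):
                    add(
                        Transition(
                            entry_id=f"{name} Y:{format_composition(y.composition)}/{z}+",
                            precursor_name=name,
                            precursor_mz=prec_mz,
                            precursor_charge=ion.charge,
                            product_mz=mz,
                            product_charge=z,
                            kind="Y",
                            composition=format_composition(y.composition),
                        )
                    )
    return out


@dataclass(frozen=True)
class FeatureCriterion:
    """Predicate over fragment glycan compositions defining a feature.

    ``any_of`` is a list of minimum-count requirements; a composition
    matches when it meets every minimum in at least one requirement
    set.  ``exclusive`` additionally demands that no residues outside
    the listed symbols are present (used for the Hex-only high-mannose
    proxy).
    """

    name: str
    any_of: Tuple[Tuple[Tuple[str, int], ...], ...]
    exclusive: Optional[Tuple[str, ...]] = None
    kinds: Optional[Tuple[str, ...]] = None  # restrict to fragment kinds

    @classmethod
    def make(
        cls,
        name: str,
        any_of: Sequence[Mapping[str, int]],
        exclusive: Optional[Sequence[str]] = None,
        kinds: Optional[Sequence[str]] = None,
    ) -> "FeatureCriterion":
        return cls(
            name=name,
            any_of=tuple(tuple(sorted(req.items())) for req in any_of),
            exclusive=tuple(exclusive) if exclusive else None,
            kinds=tuple(kinds) if kinds else None,
        )

    def admits_kind(self, kind: str) -> bool:
        return self.kinds is None or kind in self.kinds

    def matches(self, g: GlycanComposition) -> bool:
        if self.exclusive is not None:
            if any(g[sym] for sym in g if sym not in self.exclusive):
                return False
        return any(all(g[sym] >= n for sym, n in req) for req in self.any_of)


def default_feature_criteria() -> List[FeatureCriterion]:
    """Composition-level proxies for the four canonical glycan features.

    Composition strings cannot distinguish galactose from mannose, so
    galactosylation is proxied by sialic-acid-free Hex+HexNAc fragments
    (the 366.14 oxonium series; sialylated antenna ions such as 657.24
    are sialylation markers, not galactose readouts) and high-mannose
    by Hex-only fragments (the 163.06 / 145.05 series).  Both are
    restricted to oxonium (B-type) ions: every Y ion beyond Y1 retains
    the Hex+HexNAc trimannosyl core, so Y ions satisfy those count
    predicates without carrying any antenna information.  These are
    proxies, not structure-level assignments.
    """
    return [
        FeatureCriterion.make("fucosylation", [{"Fuc": 1}]),
        FeatureCriterion.make(
            "galactosylation",
            [{"Hex": 1, "HexNAc": 1}],
            exclusive=("Hex", "HexNAc", "Fuc"),
            kinds=("oxonium",),
        ),
        FeatureCriterion.make("sialylation", [{"NeuAc": 1}, {"NeuGc": 1}]),
        FeatureCriterion.make(
            "high-mannose", [{"Hex": 1}], exclusive=("Hex",), kinds=("oxonium",)
        ),
    ]


@dataclass
class FeatureLibraryEntry:
    """A feature superclass: member transitions with specificity flags."""

    feature: str
    transitions: List[Transition]
    specific: List[bool]

    def specific_transitions(self) -> List[Transition]:
        return [t for t, s in zip(self.transitions, self.specific) if s]


def build_feature_library(
    transitions: Sequence[Transition],
    criteria: Optional[Sequence[FeatureCriterion]] = None,
    specificity_tol_ppm: float = 10.0,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> List[FeatureLibraryEntry]:
    """Collapse fragment transitions into feature superclass entries.

    Membership: the fragment's glycan composition satisfies the
    criterion.  Specificity: no transition anywhere in the library
    whose composition *fails* the criterion lies within the ppm
    tolerance of the member's m/z.  Precursor-isotope transitions are
    not collapsed (they quantify individual glycoforms, not features).
    """
    if criteria is None:
        criteria = default_feature_criteria()
    if not criteria:
        raise ValueError("criteria must be non-empty")
    frags = [t for t in transitions if t.kind in ("oxonium", "Y") and t.composition is not None]
    comps = [parse_composition(t.composition, table) for t in frags]
    entries = []
    for crit in criteria:
        member_idx = [
            i
            for i, c in enumerate(comps)
            if crit.matches(c) and crit.admits_kind(frags[i].kind)
        ]
        if not member_idx:
            warnings.warn(f"feature criterion {crit.name!r} matched no transitions")
            entries.append(FeatureLibraryEntry(crit.name, [], []))
            continue
        violating_mz = sorted(
            t.product_mz for i, t in enumerate(frags) if not crit.matches(comps[i])
        )
        members, flags = [], []
        seen_mz: List[float] = []
        for i in member_idx:
            t = frags[i]
            if any(abs(m - t.product_mz) < 1e-6 for m in seen_mz):
                continue
            seen_mz.append(t.product_mz)
            tol = t.product_mz * specificity_tol_ppm * 1e-6
            specific = not any(abs(v - t.product_mz) <= tol for v in violating_mz)
            members.append(t)
            flags.append(specific)
        entries.append(FeatureLibraryEntry(crit.name, members, flags))
    return entries


# ---------------------------------------------------------------------------
# Export

SKYLINE_COLUMNS = [
    "Molecule List Name",
    "Precursor Name",
    "Precursor m/z",
    "Precursor Charge",
    "Product m/z",
    "Product Charge",
    "Explicit Retention Time",
    "Explicit Retention Time Window",
    "Note",
]


def transitions_to_skyline(
    transitions: Sequence[Transition],
    molecule_list: str = "glycopop",
    rt: Optional[float] = None,
    rt_window: Optional[float] = None,
) -> pd.DataFrame:
    """Transition list in the Skyline small-molecule CSV dialect."""
    rows = [
        {
            "Molecule List Name": molecule_list,
            "Precursor Name": t.precursor_name,
            "Precursor m/z": round(t.precursor_mz, 5),
            "Precursor Charge": t.precursor_charge,
            "Product m/z": round(t.product_mz, 5),
            "Product Charge": t.product_charge,
            "Explicit Retention Time": rt,
            "Explicit Retention Time Window": rt_window,
            "Note": f"{t.kind}:{t.composition or ''}",
        }
        for t in transitions
    ]
    return pd.DataFrame(rows, columns=SKYLINE_COLUMNS)


def library_to_json(entries: Sequence[FeatureLibraryEntry], path) -> None:
    payload = [
        {
            "feature": e.feature,
            "transitions": [
                {**t.__dict__, "specific": s} for t, s in zip(e.transitions, e.specific)
            ],
        }
        for e in entries
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def library_from_json(path) -> List[FeatureLibraryEntry]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for rec in payload:
        trans, flags = [], []
        for t in rec["transitions"]:
            t = dict(t)
            flags.append(t.pop("specific"))
            trans.append(Transition(**t))
        out.append(FeatureLibraryEntry(rec["feature"], trans, flags))
    return out
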