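"""Glycan composition algebra and glycopeptide mass arithmetic.

Everything downstream — spectral networking, annotation propagation,
transition-library construction, DIA feature quantification — works in
terms of *compositions*: multisets of monosaccharide residues such as
``HexNAc(4)Hex(5)Fuc(1)NeuAc(1)`` (the Byonic dialect).  This module
provides the composition type, the monosaccharide residue-mass table,
theoretical oxonium and Y-ion fragments, and the decomposition of a
precursor mass difference into signed combinations of residues (the
arithmetic behind the network walk).

Compositions are linkage-blind: ``Hex`` does not distinguish mannose
from galactose, and no topology is modelled.  That matches the
resolution of glycopeptide database-search output, which is the input
to every pipeline stage here.
"""

from __future__ import annotations

import csv
import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

from pyteomics import mass as _pymass

# Physical constants (Da).
PROTON_MASS = 1.00727646688
WATER_MASS = 18.0105646863
ISOTOPE_SPACING = 1.00335483507  # 13C - 12C

# Common peptide modifications (Da).
CARBAMIDOMETHYL = 57.02146
MET_OXIDATION = 15.994915


class GlycanParseError(ValueError):
    """Raised when a composition string cannot be interpreted."""


@dataclass(frozen=True)
class Monosaccharide:
    """A residue symbol with its elemental formula and monoisotopic mass."""

    symbol: str
    formula: str
    residue_mass: float


class MonosaccharideTable:
    """Registry of monosaccharide residues keyed by symbol.

    The default table covers the residues seen on mammalian N-glycans
    (human + murine plasma IgG): Hex, HexNAc, Fuc, NeuAc and NeuGc.
    Residue masses are derived from the elemental residue formulas and
    checked against any explicitly supplied mass to 1e-4 Da.
    """

    _DEFAULT_FORMULAS = {
        "Hex": "C6H10O5",
        "HexNAc": "C8H13NO5",
        "Fuc": "C6H10O4",
        "NeuAc": "C11H17NO8",
        "NeuGc": "C11H17NO9",
    }

    def __init__(self, residues: Iterable[Monosaccharide]):
        self._residues: Dict[str, Monosaccharide] = {}
        for r in residues:
            if r.symbol in self._residues:
                raise ValueError(f"duplicate monosaccharide symbol {r.symbol!r}")
            formula_mass = _pymass.calculate_mass(formula=r.formula)
            if abs(formula_mass - r.residue_mass) > 1e-4:
                raise ValueError(
                    f"{r.symbol}: residue_mass {r.residue_mass} disagrees with "
                    f"formula {r.formula} ({formula_mass:.6f}) by more than 1e-4 Da"
                )
            self._residues[r.symbol] = r

    @classmethod
    def default(cls) -> "MonosaccharideTable":
        residues = [
            Monosaccharide(sym, f, _pymass.calculate_mass(formula=f))
            for sym, f in cls._DEFAULT_FORMULAS.items()
        ]
        return cls(residues)

    @classmethod
    def from_csv(cls, path) -> "MonosaccharideTable":
        """Load a table from CSV with columns symbol, formula, residue_mass."""
        residues = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                residues.append(
                    Monosaccharide(
                        row["symbol"].strip(),
                        row["formula"].strip(),
                        float(row["residue_mass"]),
                    )
                )
        return cls(residues)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["symbol", "formula", "residue_mass"])
            for r in self._residues.values():
                writer.writerow([r.symbol, r.formula, f"{r.residue_mass:.6f}"])

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._residues

    def __getitem__(self, symbol: str) -> Monosaccharide:
        return self._residues[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._residues)

    @property
    def symbols(self) -> Tuple[str, ...]:
        return tuple(self._residues)

    def mass(self, symbol: str) -> float:
        try:
            return self._residues[symbol].residue_mass
        except KeyError:
            raise GlycanParseError(f"unknown monosaccharide symbol {symbol!r}") from None


DEFAULT_TABLE = MonosaccharideTable.default()

# Canonical display order for formatting (Byonic convention); other
# symbols follow alphabetically.
_CANONICAL_ORDER = ("HexNAc", "Hex", "Fuc", "NeuAc", "NeuGc")

_COMPOSITION_TOKEN = re.compile(r"\s*([A-Za-z][A-Za-z0-9]*)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)")


class GlycanComposition(Mapping[str, int]):
    """An immutable multiset of monosaccharide residues.

    Counts are strictly positive; absent symbols read as zero.  Supports
    addition, subtraction (raising on negative results), containment
    (``a <= b`` count-wise) and mass evaluation against a residue table.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Optional[Mapping[str, int]] = None, **kw: int):
        merged: Dict[str, int] = {}
        for src in (counts or {}), kw:
            for sym, n in src.items():
                merged[sym] = merged.get(sym, 0) + int(n)
        for sym, n in list(merged.items()):
            if n < 0:
                raise ValueError(f"negative count for {sym}: {n}")
            if n == 0:
                del merged[sym]
        object.__setattr__(self, "_counts", dict(sorted(merged.items())))
        object.__setattr__(self, "_hash", hash(tuple(self._counts.items())))

    def __setattr__(self, *a):  # immutability guard
        raise AttributeError("GlycanComposition is immutable")

    def __getitem__(self, symbol: str) -> int:
        return self._counts.get(symbol, 0)

    def get(self, symbol: str, default: int = 0) -> int:
        return self._counts.get(symbol, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other) -> bool:
        if isinstance(other, GlycanComposition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        counts = dict(self._counts)
        for sym, n in other.items():
            counts[sym] = counts.get(sym, 0) + n
        return GlycanComposition(counts)

    def __sub__(self, other: "GlycanComposition") -> "GlycanComposition":
        counts = dict(self._counts)
        for sym, n in other.items():
            counts[sym] = counts.get(sym, 0) - n
        return GlycanComposition(counts)  # raises on negative

    def contains(self, other: "GlycanComposition") -> bool:
        """True when *other* is a count-wise sub-composition of self."""
        return all(self[sym] >= n for sym, n in other.items())

    @property
    def total(self) -> int:
        """Total residue count."""
        return sum(self._counts.values())

    def mass(self, table: MonosaccharideTable = DEFAULT_TABLE) -> float:
        return sum(n * table.mass(sym) for sym, n in self._counts.items())

    def __str__(self) -> str:
        return format_composition(self)

    def __repr__(self) -> str:
        return f"GlycanComposition({format_composition(self)!r})"


EMPTY_COMPOSITION = GlycanComposition()


def parse_composition(
    text: str, table: MonosaccharideTable = DEFAULT_TABLE
) -> GlycanComposition:
    """Parse a Byonic-style composition string, e.g. ``HexNAc(4)Hex(5)Fuc(1)``.

    Whitespace between tokens is tolerated; an empty string yields the
    empty composition.  Unknown symbols and negative or non-integer
    counts raise :class:`GlycanParseError`.
    """
    counts: Dict[str, int] = {}
    pos = 0
    stripped = text.strip()
    while pos < len(stripped):
        m = _COMPOSITION_TOKEN.match(stripped, pos)
        if not m:
            raise GlycanParseError(
                f"malformed composition string at position {pos}: {stripped!r}"
            )
        sym, raw_count = m.group(1), m.group(2)
        if sym not in table:
            raise GlycanParseError(f"unknown monosaccharide symbol {sym!r}")
        try:
            n = int(raw_count)
        except ValueError:
            raise GlycanParseError(
                f"non-integer count {raw_count!r} for {sym}"
            ) from None
        if n < 0:
            raise GlycanParseError(f"negative count {n} for {sym}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return GlycanComposition(counts)


def format_composition(g: GlycanComposition) -> str:
    """Render a composition in canonical Byonic order; '' for empty."""
    parts = []
    seen = set()
    for sym in _CANONICAL_ORDER:
        if g[sym]:
            parts.append(f"{sym}({g[sym]})")
            seen.add(sym)
    for sym in sorted(g):
        if sym not in seen and g[sym]:
            parts.append(f"{sym}({g[sym]})")
    return "".join(parts)


def composition_mass(
    g: GlycanComposition, table: MonosaccharideTable = DEFAULT_TABLE
) -> float:
    """Monoisotopic residue-mass sum of a composition (Da)."""
    return g.mass(table)


def peptide_mass(
    sequence: str,
    *,
    carbamidomethyl_cys: bool = True,
    extra_mod_masses: Sequence[float] = (),
) -> float:
    """Neutral monoisotopic mass of a peptide backbone (residues + water).

    Cysteines carry fixed carbamidomethylation by default, mirroring
    standard iodoacetamide alkylation; additional variable-modification
    masses (e.g. Met oxidation, +15.994915) are added verbatim.
    """
    m = _pymass.calculate_mass(sequence=sequence)
    if carbamidomethyl_cys:
        m += CARBAMIDOMETHYL * sequence.count("C")
    return m + sum(extra_mod_masses)


@dataclass(frozen=True)
class GlycopeptideIon:
    """A glycopeptide precursor: peptide backbone + glycan + charge."""

    peptide: str
    glycan: GlycanComposition
    charge: int = 2
    modification_masses: Tuple[float, ...] = ()
    carbamidomethyl_cys: bool = True

    def __post_init__(self):
        if not 1 <= self.charge <= 8:
            raise ValueError(f"unreasonable charge state {self.charge}")

    @property
    def peptide_mass(self) -> float:
        return peptide_mass(
            self.peptide,
            carbamidomethyl_cys=self.carbamidomethyl_cys,
            extra_mod_masses=self.modification_masses,
        )

    def neutral_mass(self, table: MonosaccharideTable = DEFAULT_TABLE) -> float:
        return self.peptide_mass + self.glycan.mass(table)

    def mz(self, table: MonosaccharideTable = DEFAULT_TABLE) -> float:
        return (self.neutral_mass(table) + self.charge * PROTON_MASS) / self.charge

    def __str__(self) -> str:
        return f"{self.peptide}+{format_composition(self.glycan) or 'unglycosylated'}/{self.charge}+"


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    return (neutral_mass + charge * PROTON_MASS) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    return mz * charge - charge * PROTON_MASS


def oxonium_mz(
    g: GlycanComposition,
    water_losses: int = 0,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> float:
    """m/z of the singly charged oxonium ion of a glycan sub-unit.

    The oxonium ion of composition ``g`` is the protonated residue sum,
    optionally minus one or two waters (e.g. Hex gives 163.06 and, with
    one water loss, 145.05).
    """
    if g.total == 0:
        raise ValueError("oxonium ion undefined for the empty composition")
    if not 0 <= water_losses <= 2:
        raise ValueError("water_losses must be 0, 1 or 2")
    return g.mass(table) + PROTON_MASS - water_losses * WATER_MASS


def sub_compositions(
    g: GlycanComposition,
    *,
    min_counts: Optional[Mapping[str, int]] = None,
    include_full: bool = True,
    include_empty: bool = False,
) -> List[GlycanComposition]:
    """Enumerate the count-wise sub-composition lattice of ``g``."""
    floors = dict(min_counts or {})
    symbols = sorted(g)
    ranges = [range(floors.get(s, 0), g[s] + 1) for s in symbols]
    out = []
    for combo in itertools.product(*ranges):
        sub = GlycanComposition(dict(zip(symbols, combo)))
        if sub.total == 0 and not include_empty:
            continue
        if sub == g and not include_full:
            continue
        out.append(sub)
    return out


@dataclass(frozen=True)
class YIon:
    """A glycopeptide Y ion: intact peptide retaining a glycan remnant."""

    composition: GlycanComposition
    neutral_mass: float
    mz_by_charge: Mapping[int, float]
    n_lost: int  # residues removed from the precursor glycan

    @property
    def is_y1(self) -> bool:
        return self.composition.total == 1 and self.composition["HexNAc"] == 1


def y_ion_ladder(
    gp: GlycopeptideIon,
    charges: Sequence[int] = (1,),
    policy: str = "lattice",
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> List[YIon]:
    """Theoretical Y ions from sequential monosaccharide losses down to Y1.

    Y ions keep the peptide intact and shed glycan residues; Y1 is the
    peptide plus a single core HexNAc.  The ``lattice`` policy
    enumerates every sub-composition retaining >=1 HexNAc (the losses
    need not follow one linear order); ``linear`` produces a single
    path removing NeuGc/NeuAc, then Fuc, then Hex, then HexNAc.  The
    intact precursor composition itself is excluded unless the glycan
    already is Y1-sized.  Fragments are deduplicated by composition and
    sorted by descending remnant mass.
    """
    if gp.glycan["HexNAc"] < 1:
        raise ValueError("Y1 undefined: glycan contains no HexNAc")
    if policy == "lattice":
        subs = sub_compositions(gp.glycan, min_counts={"HexNAc": 1}, include_full=False)
        if not subs:  # glycan is already a single HexNAc (+ nothing)
            subs = [gp.glycan]
    elif policy == "linear":
        order = ["NeuGc", "NeuAc", "Fuc", "Hex", "HexNAc"]
        subs = []
        current = dict(gp.glycan)
        while True:
            for sym in order:
                if current.get(sym, 0) > (1 if sym == "HexNAc" else 0):
                    current = dict(current)
                    current[sym] -= 1
                    break
            else:
                break
            subs.append(GlycanComposition(current))
        if not subs:
            subs = [gp.glycan]
    else:
        raise ValueError(f"unknown ladder policy {policy!r}")

    pep = gp.peptide_mass
    out = []
    for sub in sorted(set(subs), key=lambda s: (-s.mass(table), str(s))):
        neutral = pep + sub.mass(table)
        out.append(
            YIon(
                composition=sub,
                neutral_mass=neutral,
                mz_by_charge={z: mz_from_neutral(neutral, z) for z in charges},
                n_lost=gp.glycan.total - sub.total,
            )
        )
    return out


@dataclass(frozen=True)
class CompositionDelta:
    """A signed residue-count change between two compositions."""

    counts: Tuple[Tuple[str, int], ...]  # (symbol, signed count), nonzero only
    net_mass: float
    error: float = 0.0  # |net_mass - requested delta| when produced by a search

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        table: MonosaccharideTable = DEFAULT_TABLE,
        error: float = 0.0,
    ) -> "CompositionDelta":
        nz = tuple(sorted((s, c) for s, c in counts.items() if c))
        net = sum(c * table.mass(s) for s, c in nz)
        return cls(counts=nz, net_mass=net, error=error)

    @property
    def n_changes(self) -> int:
        return sum(abs(c) for _, c in self.counts)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def apply(self, g: GlycanComposition) -> Optional[GlycanComposition]:
        """Apply to a composition; None when any count would go negative."""
        counts = dict(g)
        for sym, c in self.counts:
            counts[sym] = counts.get(sym, 0) + c
            if counts[sym] < 0:
                return None
        return GlycanComposition(counts)

    def __str__(self) -> str:
        if not self.counts:
            return "(no change)"
        return "".join(f"{'+' if c > 0 else '-'}{sym}({abs(c)})" for sym, c in self.counts)


def _signed_count_vectors(symbols: Sequence[str], max_changes: int):
    """All signed count vectors with L1 norm <= max_changes."""

    def rec(i: int, budget: int, acc: Dict[str, int]):
        if i == len(symbols):
            yield dict(acc)
            return
        for c in range(-budget, budget + 1):
            if c:
                acc[symbols[i]] = c
            yield from rec(i + 1, budget - abs(c), acc)
            acc.pop(symbols[i], None)

    yield from rec(0, max_changes, {})


def delta_decompositions(
    delta: float,
    max_changes: int = 2,
    tol: float = 0.1,
    table: MonosaccharideTable = DEFAULT_TABLE,
) -> List[CompositionDelta]:
    """Signed residue combinations whose net mass matches ``delta``.

    Enumerates every combination of at most ``max_changes`` added or
    removed residues (mixed signs allowed: a +15.995 shift decomposes
    as one fucose removed and one hexose added) and keeps those whose
    net mass lies within ``tol`` of the target.  Results are sorted by
    (number of changes, |mass error|), so the most parsimonious
    explanation comes first.
    """
    if max_changes < 1:
        raise ValueError("max_changes must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    out = []
    for vec in _signed_count_vectors(table.symbols, max_changes):
        d = CompositionDelta.from_counts(vec, table)
        err = abs(d.net_mass - delta)
        if err <= tol:
            out.append(CompositionDelta(counts=d.counts, net_mass=d.net_mass, error=err))
    out.sort(key=lambda d: (d.n_changes, d.error, str(d)))
    # deduplicate (the empty vector is produced once; others are unique)
    return out
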