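"""Glycan composition grammar, monoisotopic mass calculus, and glycan-class typing.

A glycan is represented purely compositionally — a multiset of monosaccharide
residues such as ``HexNAc(2)Hex(9)`` — with no topology or linkage information.
This is the standard granularity for high-throughput intact glycopeptide work,
where fragmentation rarely determines branching.

Monosaccharide symbols form a closed table of residue (i.e. dehydrated)
monoisotopic masses.  Mannose-6-phosphate is encoded as a ``Phospho(1)`` count
alongside the Hex counts, e.g. ``HexNAc(2)Hex(7)Phospho(1)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "MONOSACCHARIDES",
    "SYMBOL_ORDER",
    "GlycanComposition",
    "GlycanClass",
    "GlycanParseError",
    "parse_composition",
    "composition_mass",
    "classify_glycan",
    "load_glycan_database",
    "default_glycan_database",
    "ClassificationConfig",
]

#: Residue monoisotopic masses (Da), i.e. the monosaccharide minus one water.
MONOSACCHARIDES: dict[str, float] = {
    "HexNAc": 203.079373,
    "Hex": 162.052824,
    "Fuc": 146.057909,
    "NeuAc": 291.095417,
    "Phospho": 79.966331,
}

#: Canonical symbol order used in composition strings.
SYMBOL_ORDER: tuple[str, ...] = ("HexNAc", "Hex", "Fuc", "NeuAc", "Phospho")

PROTON: float = 1.007276
WATER: float = 18.010565


class GlycanParseError(ValueError):
    """Raised when a composition string cannot be parsed."""


@dataclass(frozen=True)
class GlycanComposition:
    """A multiset of monosaccharide residues.

    Equality and hashing are by counts, so compositions can key dictionaries
    and index matrices.  ``str()`` gives the canonical text, with symbols in
    the fixed order ``HexNAc, Hex, Fuc, NeuAc, Phospho`` and zero counts
    omitted.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for sym, n in self.counts.items():
            if sym not in MONOSACCHARIDES:
                raise GlycanParseError(f"unknown monosaccharide symbol: {sym!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise GlycanParseError(f"non-integer count for {sym}: {n!r}")
            if n < 0:
                raise GlycanParseError(f"negative count for {sym}: {n}")
            if n > 0:
                clean[sym] = n
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __len__(self) -> int:
        """Total residue count."""
        return sum(self.counts.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, GlycanComposition):
            return NotImplemented
        return self.counts == other.counts

    def __hash__(self) -> int:
        return hash(tuple(self[s] for s in SYMBOL_ORDER))

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        merged = {s: self[s] + other[s] for s in SYMBOL_ORDER if self[s] + other[s]}
        return GlycanComposition(merged)

    def contains(self, other: "GlycanComposition") -> bool:
        """True if *other* is a sub-multiset of self."""
        return all(self[s] >= other[s] for s in SYMBOL_ORDER)

    @property
    def canonical_text(self) -> str:
        return "".join(f"{s}({self[s]})" for s in SYMBOL_ORDER if self[s])

    def __str__(self) -> str:
        return self.canonical_text

    def __repr__(self) -> str:
        return f"GlycanComposition({self.canonical_text!r})"

    @property
    def mass(self) -> float:
        return composition_mass(self)


_TOKEN_RE = re.compile(r"([A-Za-z0-9]+)\(([^)]*)\)")


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string like ``"HexNAc(2)Hex(9)"``.

    Raises :class:`GlycanParseError` naming the offending token for unknown
    symbols, malformed parentheses, or non-positive-integer counts.
    """
    if not text or not text.strip():
        raise GlycanParseError("empty composition string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise GlycanParseError(
                f"malformed composition near {text[pos:m.start()]!r} in {text!r}"
            )
        sym, num = m.group(1), m.group(2)
        if sym not in MONOSACCHARIDES:
            raise GlycanParseError(f"unknown monosaccharide symbol: {sym!r}")
        try:
            n = int(num)
        except ValueError:
            raise GlycanParseError(f"non-integer count {num!r} for {sym}") from None
        if n < 0:
            raise GlycanParseError(f"negative count {n} for {sym}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(text):
        raise GlycanParseError(f"malformed composition near {text[pos:]!r} in {text!r}")
    return GlycanComposition(counts)


def composition_mass(comp: GlycanComposition | Mapping[str, int]) -> float:
    """Monoisotopic residue mass of a composition (Da).

    Additive over composition union: ``mass(a + b) == mass(a) + mass(b)``.
    """
    if not isinstance(comp, GlycanComposition):
        comp = GlycanComposition(dict(comp))
    return sum(n * MONOSACCHARIDES[s] for s, n in comp.counts.items())


GLYCAN_TYPES: tuple[str, ...] = (
    "paucimannose",
    "high_mannose",
    "complex_hybrid",
    "fucosylated",
    "sialylated",
    "M6P",
)


@dataclass(frozen=True)
class ClassificationConfig:
    """Boundaries of the exclusive N-glycan classes.

    High mannose means the chitobiose core (HexNAc exactly 2) carrying five or
    more hexoses; paucimannose is the same core with at most four hexoses and
    optionally a core fucose.  Anything with NeuAc is sialylated; anything
    phosphorylated is M6P.  These boundaries are conventions of the field,
    exposed here so they can be revised.
    """

    high_mannose_min_hex: int = 5
    paucimannose_max_hex: int = 4
    paucimannose_max_fuc: int = 1


@dataclass(frozen=True)
class GlycanClass:
    """Exclusive class plus independent multi-label flags.

    ``exclusive_class`` follows the precedence M6P > sialylated > fucosylated
    > high_mannose > paucimannose > complex_hybrid, so every composition lands
    in exactly one bucket (the grouping used for network node coloring).
    ``multilabel_flags`` are orthogonal: e.g. a fucosylated sialylated glycan
    carries both flags, matching the counting rule in which a paucimannose or
    sialylated glycan with fucose is also counted as fucosylated.
    """

    exclusive_class: str
    multilabel_flags: frozenset[str]


def classify_glycan(
    comp: GlycanComposition, config: ClassificationConfig | None = None
) -> GlycanClass:
    """Assign a composition to its glycan class.

    Deterministic and pure: the same counts always yield the same class.
    """
    cfg = config or ClassificationConfig()
    hexnac, hexose = comp["HexNAc"], comp["Hex"]
    fuc, neuac, phos = comp["Fuc"], comp["NeuAc"], comp["Phospho"]

    is_high_mannose = (
        hexnac == 2 and hexose >= cfg.high_mannose_min_hex
        and fuc == 0 and neuac == 0 and phos == 0
    )
    is_pauci = (
        hexnac == 2 and hexose <= cfg.paucimannose_max_hex
        and fuc <= cfg.paucimannose_max_fuc and neuac == 0 and phos == 0
    )

    flags = set()
    if neuac >= 1:
        flags.add("sialylated")
    if fuc >= 1:
        flags.add("fucosylated")
    if phos >= 1:
        flags.add("M6P")
    if is_high_mannose:
        flags.add("high_mannose")

    if phos >= 1:
        exclusive = "M6P"
    elif neuac >= 1:
        exclusive = "sialylated"
    elif fuc >= 1 and not is_pauci:
        exclusive = "fucosylated"
    elif is_high_mannose:
        exclusive = "high_mannose"
    elif is_pauci and fuc >= 1:
        # paucimannose core with core fucose: counted as fucosylated
        exclusive = "fucosylated"
    elif is_pauci:
        exclusive = "paucimannose"
    else:
        exclusive = "complex_hybrid"
    return GlycanClass(exclusive, frozenset(flags))


def load_glycan_database(path) -> list[GlycanComposition]:
    """Load a glycan composition database from a TSV file.

    The file must have a header with columns ``id`` and ``composition``
    (optional ``label``).  Row order is preserved; duplicate compositions are
    rejected, and unparseable rows raise an error with the line number.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "composition"):
        if col not in df.columns:
            raise ValueError(f"glycan database missing required column {col!r}")
    comps: list[GlycanComposition] = []
    seen: set[GlycanComposition] = set()
    for i, text in enumerate(df["composition"]):
        try:
            comp = parse_composition(text)
        except GlycanParseError as exc:
            raise GlycanParseError(f"line {i + 2}: {exc}") from exc
        if comp in seen:
            raise ValueError(
                f"line {i + 2}: duplicate composition {comp.canonical_text}"
            )
        seen.add(comp)
        comps.append(comp)
    return comps


def default_glycan_database() -> list[GlycanComposition]:
    """The packaged default database of 117 N-glycan compositions.

    Synthetic fixture: a deterministic enumeration of plausible mammalian
    brain N-glycans (high mannose, paucimannose, complex/hybrid, fucosylated,
    sialylated, and mannose-6-phosphate series), size-matched to the 117
    compositions typical of large-scale brain glycoproteome studies.  It is
    not a copy of any published supplementary table.
    """
    ref = resources.files("glycoscape.data").joinpath("glycan_db_117.tsv")
    with resources.as_file(ref) as path:
        return load_glycan_database(path)


def _enumerate_default_database() -> list[tuple[str, str]]:
    """Deterministic enumeration behind the packaged 117-entry fixture.

    Returns (composition, class label) pairs; used once to write the TSV and
    kept so the fixture is reproducible from source.
    """
    entries: list[GlycanComposition] = []

    def add(**counts):
        entries.append(GlycanComposition(counts))

    for hexose in range(5, 13):                      # high mannose: 8
        add(HexNAc=2, Hex=hexose)
    for hexose in range(1, 5):                       # paucimannose ± core Fuc: 8
        add(HexNAc=2, Hex=hexose)
        add(HexNAc=2, Hex=hexose, Fuc=1)
    for hexose in range(4, 10):                      # M6P: 9
        add(HexNAc=2, Hex=hexose, Phospho=1)
    for hexose in range(6, 9):
        add(HexNAc=2, Hex=hexose, Phospho=2)
    for hexnac in range(3, 7):                       # complex/hybrid: 20
        for hexose in range(3, 8):
            add(HexNAc=hexnac, Hex=hexose)
    for hexnac in range(3, 7):                       # fucosylated complex: 20
        for hexose in range(3, 8):
            add(HexNAc=hexnac, Hex=hexose, Fuc=1)
    for hexose in range(5, 8):                       # fucosylated hybrid: 3
        add(HexNAc=2, Hex=hexose, Fuc=1)
    for hexnac in range(3, 6):                       # sialylated: 24
        for hexose in range(4, 8):
            for neuac in (1, 2):
                add(HexNAc=hexnac, Hex=hexose, NeuAc=neuac)
    for hexnac in range(3, 6):                       # sialylated + fucose: 12
        for hexose in range(4, 8):
            add(HexNAc=hexnac, Hex=hexose, Fuc=1, NeuAc=1)
    for hexnac in (5, 6):                            # trisialylated: 6
        for hexose in range(6, 9):
            add(HexNAc=hexnac, Hex=hexose, NeuAc=3)
    for hexnac in range(4, 7):                       # difucosylated: 7
        for hexose in (5, 6):
            add(HexNAc=hexnac, Hex=hexose, Fuc=2)
    add(HexNAc=6, Hex=7, Fuc=2)

    assert len(entries) == len(set(entries)) == 117
    return [(c.canonical_text, classify_glycan(c).exclusive_class) for c in entries]
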