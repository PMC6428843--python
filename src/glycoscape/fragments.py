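"""Theoretical fragment ions for intact glycopeptides.

Electron-driven dissociation of a glycopeptide cleaves the peptide backbone
(c/z•-type ions, some y) while concurrent vibrational activation cleaves the
labile glycosidic bonds, yielding Y-ions (intact peptide retaining part of the
glycan) and low-mass B/oxonium ions.  This module enumerates all of these:

* backbone ions (b/y/c/z) in three glycan-retention modes — ``intact`` (the
  whole glycan rides on the fragment), ``stub`` (a single HexNAc remains), and
  ``none`` (the bare backbone fragment, printed with a "~" in annotated
  spectra);
* the Y-ion ladder over the composition lattice of the glycan (Y0 = bare
  peptide, Y1 = peptide + one HexNAc, ...);
* oxonium/B ions from a configurable catalog.

No glycan topology is assumed: the Y ladder enumerates sub-compositions,
constrained so that a nonempty retained composition keeps at least one HexNAc
(the peptide-proximal core residue is lost last).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

from .glycans import (
    PROTON,
    SYMBOL_ORDER,
    WATER,
    GlycanComposition,
    composition_mass,
    parse_composition,
)

__all__ = [
    "AA_MASSES",
    "Glycopeptide",
    "FragmentIon",
    "OxoniumEntry",
    "DEFAULT_OXONIUM_CATALOG",
    "peptide_mass",
    "backbone_fragments",
    "y_ion_ladder",
    "oxonium_ions",
    "precursor_mz",
    "theoretical_fragments",
    "load_oxonium_catalog",
]

#: Monoisotopic residue masses for the 20 canonical amino acids.
AA_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa]
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}

NH3 = 17.026549
#: z-radical (z•) neutral offset relative to the summed C-terminal residues:
#: water minus NH2 (the y-ion minus NH3, plus the transferred hydrogen).
Z_DOT_OFFSET = WATER - 16.018724

#: Neutral-mass offset of each backbone series relative to summed residues.
SERIES_OFFSETS: dict[str, float] = {
    "b": 0.0,
    "y": WATER,
    "c": NH3,
    "z": Z_DOT_OFFSET,
}

N_TERMINAL_SERIES = frozenset("bc")
C_TERMINAL_SERIES = frozenset("yz")

CARBAMIDOMETHYL = 57.021464

#: Default m/z ceiling above which fragments are flagged out-of-range
#: (typical MS/MS scan upper bound).
DEFAULT_MZ_CEILING = 2000.0


@dataclass(frozen=True)
class Glycopeptide:
    """A peptide bearing exactly one N-glycan.

    Parameters
    ----------
    sequence : str
        Amino-acid sequence over the 20 canonical residues.
    glycosite : int
        1-based position of the modified asparagine.
    glycan : GlycanComposition
        The attached glycan composition.
    fixed_mods : mapping residue -> mass delta
        Applied to every occurrence; default carbamidomethyl on Cys.
    variable_mods : sequence of (position, mass delta)
        1-based positions.
    """

    sequence: str
    glycosite: int
    glycan: GlycanComposition
    fixed_mods: Mapping[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )
    variable_mods: tuple = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - set(AA_MASSES)
        if bad:
            raise ValueError(f"unknown residue(s): {sorted(bad)}")
        if not 1 <= self.glycosite <= len(self.sequence):
            raise ValueError(
                f"glycosite {self.glycosite} outside 1..{len(self.sequence)}"
            )
        if self.sequence[self.glycosite - 1] != "N":
            raise ValueError(
                f"residue at glycosite {self.glycosite} is "
                f"{self.sequence[self.glycosite - 1]!r}, expected 'N'"
            )
        object.__setattr__(self, "variable_mods", tuple(self.variable_mods))

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_masses(self) -> list[float]:
        """Per-residue masses including fixed and variable modifications."""
        masses = [AA_MASSES[aa] + self.fixed_mods.get(aa, 0.0) for aa in self.sequence]
        for pos, delta in self.variable_mods:
            masses[pos - 1] += delta
        return masses

    @property
    def peptide_mass(self) -> float:
        """Neutral peptide monoisotopic mass (glycan excluded)."""
        return sum(self.residue_masses()) + WATER


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment ion.

    ``index`` is the ordinal within the series: for backbone ions the number
    of residues in the fragment (c3 = first three residues), for Y ions the
    number of retained glycan residues, for B ions the catalog entry name.
    ``bond`` is the cleaved backbone bond (1..L-1) for backbone ions, used for
    coverage accounting.  ``retention`` applies only to backbone series whose
    fragment carries the glycosite: ``intact``, ``stub`` or ``none``;
    otherwise ``n/a``.
    """

    series: str
    index: object
    charge: int
    mz: float
    retention: str = "n/a"
    bond: int | None = None
    composition_retained: GlycanComposition | None = None
    in_range: bool = True

    @property
    def label(self) -> str:
        ret = {"intact": "+glycan", "stub": "+HexNAc", "none": "~"}.get(
            self.retention, ""
        )
        return f"{self.series}{self.index}{ret}^{self.charge}"


def peptide_mass(
    sequence: str,
    fixed_mods: Mapping[str, float] | None = None,
    variable_mods: Iterable[tuple[int, float]] = (),
) -> float:
    """Neutral monoisotopic peptide mass: summed residues + water + mods."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    bad = set(sequence) - set(AA_MASSES)
    if bad:
        raise ValueError(f"unknown residue(s): {sorted(bad)}")
    fixed = fixed_mods or {}
    total = sum(AA_MASSES[aa] + fixed.get(aa, 0.0) for aa in sequence) + WATER
    total += sum(delta for _, delta in variable_mods)
    return total


def _mz(neutral: float, charge: int) -> float:
    return (neutral + charge * PROTON) / charge


_STUB_MASS = 203.079373  # one HexNAc


def backbone_fragments(
    gp: Glycopeptide,
    series: Iterable[str] = ("c", "z"),
    retention_modes: Iterable[str] = ("intact", "stub", "none"),
    max_charge: int = 1,
    mz_ceiling: float = DEFAULT_MZ_CEILING,
) -> list[FragmentIon]:
    """Backbone fragment ions for every cleavable bond.

    For each bond i (1..L-1), each requested series, each applicable retention
    mode and each charge 1..max_charge, one :class:`FragmentIon` is produced.
    Retention modes apply only when the glycosite lies on the fragment's side
    of the bond; fragments without the glycosite are emitted once per charge
    with ``retention='n/a'``.  Ions above *mz_ceiling* are kept but flagged
    ``in_range=False``.
    """
    series = tuple(series)
    retention_modes = tuple(retention_modes)
    unknown = set(series) - set(SERIES_OFFSETS)
    if unknown:
        raise ValueError(f"unknown series: {sorted(unknown)}")
    bad_modes = set(retention_modes) - {"intact", "stub", "none"}
    if bad_modes:
        raise ValueError(f"unknown retention modes: {sorted(bad_modes)}")
    if max_charge < 1:
        raise ValueError("max charge must be >= 1")

    res = gp.residue_masses()
    L = len(gp)
    prefix = list(itertools.accumulate(res))
    glycan_mass = composition_mass(gp.glycan)
    out: list[FragmentIon] = []
    for bond in range(1, L):
        for ser in series:
            if ser in N_TERMINAL_SERIES:
                n_res = bond
                frag_res_mass = prefix[bond - 1]
                has_site = gp.glycosite <= bond
            else:
                n_res = L - bond
                frag_res_mass = prefix[-1] - prefix[bond - 1]
                has_site = gp.glycosite > bond
            neutral = frag_res_mass + SERIES_OFFSETS[ser]
            if has_site:
                variants = [
                    (mode, {"intact": glycan_mass, "stub": _STUB_MASS, "none": 0.0}[mode])
                    for mode in retention_modes
                ]
            else:
                variants = [("n/a", 0.0)]
            for mode, extra in variants:
                for z in range(1, max_charge + 1):
                    mz = _mz(neutral + extra, z)
                    out.append(
                        FragmentIon(
                            series=ser,
                            index=n_res,
                            charge=z,
                            mz=mz,
                            retention=mode,
                            bond=bond,
                            in_range=mz <= mz_ceiling,
                        )
                    )
    return out


def _sub_compositions(glycan: GlycanComposition) -> list[GlycanComposition]:
    """All sub-compositions that are empty or retain >= 1 HexNAc, full excluded."""
    ranges = [range(glycan[s] + 1) for s in SYMBOL_ORDER]
    subs = []
    for combo in itertools.product(*ranges):
        comp = GlycanComposition(
            {s: n for s, n in zip(SYMBOL_ORDER, combo) if n}
        )
        if comp == glycan:
            continue
        if comp and comp["HexNAc"] == 0 and glycan["HexNAc"] > 0:
            continue
        subs.append(comp)
    return subs


def y_ion_ladder(
    gp: Glycopeptide,
    max_charge: int = 1,
    require_core_hexnac: bool = True,
    mz_ceiling: float = DEFAULT_MZ_CEILING,
) -> list[FragmentIon]:
    """Y-ion ladder: intact peptide plus every partial glycan composition.

    Y0 is the bare peptide; Y1 the peptide plus one HexNAc.  The full
    composition (the precursor itself) is excluded.  With
    ``require_core_hexnac`` (default), a nonempty retained composition must
    contain at least one HexNAc, encoding the N-glycan core attachment.
    """
    if not gp.glycan:
        raise ValueError("glycopeptide has an empty glycan")
    if max_charge < 1:
        raise ValueError("max charge must be >= 1")
    pmass = gp.peptide_mass
    if require_core_hexnac:
        subs = _sub_compositions(gp.glycan)
    else:
        ranges = [range(gp.glycan[s] + 1) for s in SYMBOL_ORDER]
        subs = [
            GlycanComposition({s: n for s, n in zip(SYMBOL_ORDER, combo) if n})
            for combo in itertools.product(*ranges)
        ]
        subs = [c for c in subs if c != gp.glycan]
    out = []
    for comp in subs:
        neutral = pmass + composition_mass(comp)
        for z in range(1, max_charge + 1):
            mz = _mz(neutral, z)
            out.append(
                FragmentIon(
                    series="Y",
                    index=len(comp),
                    charge=z,
                    mz=mz,
                    retention="n/a",
                    composition_retained=comp,
                    in_range=mz <= mz_ceiling,
                )
            )
    return out


@dataclass(frozen=True)
class OxoniumEntry:
    """One oxonium/B-ion catalog entry: a composition and a water-loss count."""

    name: str
    composition: GlycanComposition
    water_losses: int = 0

    @property
    def mz(self) -> float:
        return composition_mass(self.composition) + PROTON - self.water_losses * WATER


DEFAULT_OXONIUM_CATALOG: tuple[OxoniumEntry, ...] = (
    OxoniumEntry("HexNAc", GlycanComposition({"HexNAc": 1})),
    OxoniumEntry("Hex", GlycanComposition({"Hex": 1})),
    OxoniumEntry("NeuAc", GlycanComposition({"NeuAc": 1})),
    OxoniumEntry("NeuAc-H2O", GlycanComposition({"NeuAc": 1}), water_losses=1),
    OxoniumEntry("HexNAcHex", GlycanComposition({"HexNAc": 1, "Hex": 1})),
    OxoniumEntry(
        "HexNAcHexNeuAc", GlycanComposition({"HexNAc": 1, "Hex": 1, "NeuAc": 1})
    ),
)


def load_oxonium_catalog(path) -> tuple[OxoniumEntry, ...]:
    """Read an oxonium catalog TSV with columns name, composition, water_losses."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"name": str, "composition": str})
    return tuple(
        OxoniumEntry(
            row["name"],
            parse_composition(row["composition"]),
            int(row.get("water_losses", 0) or 0),
        )
        for _, row in df.iterrows()
    )


def oxonium_ions(
    comp: GlycanComposition,
    catalog: Sequence[OxoniumEntry] = DEFAULT_OXONIUM_CATALOG,
) -> list[FragmentIon]:
    """B/oxonium ions for every catalog entry available within *comp*."""
    out = []
    for entry in catalog:
        if not comp.contains(entry.composition):
            continue
        out.append(
            FragmentIon(
                series="B",
                index=entry.name,
                charge=1,
                mz=entry.mz,
                retention="n/a",
                composition_retained=entry.composition,
            )
        )
    return out


def precursor_mz(gp: Glycopeptide, charge: int) -> float:
    """Precursor m/z of the intact glycopeptide at the given charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return _mz(gp.peptide_mass + composition_mass(gp.glycan), charge)


def theoretical_fragments(
    gp: Glycopeptide,
    series: Iterable[str] = ("c", "z"),
    retention_modes: Iterable[str] = ("intact", "stub", "none"),
    max_charge: int = 2,
    include_y_ladder: bool = True,
    include_oxonium: bool = True,
    oxonium_catalog: Sequence[OxoniumEntry] = DEFAULT_OXONIUM_CATALOG,
    mz_ceiling: float = DEFAULT_MZ_CEILING,
) -> list[FragmentIon]:
    """Full theoretical ion list for annotation: backbone + Y ladder + oxonium."""
    ions = backbone_fragments(gp, series, retention_modes, max_charge, mz_ceiling)
    if include_y_ladder and gp.glycan:
        ions += y_ion_ladder(gp, max_charge, mz_ceiling=mz_ceiling)
    if include_oxonium and gp.glycan:
        ions += oxonium_ions(gp.glycan, oxonium_catalog)
    return ions
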