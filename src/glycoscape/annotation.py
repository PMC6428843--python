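"""Peak matching and spectrum-level quality metrics for glycopeptide MS/MS.

Given a centroid peak list and the theoretical ion list of a glycopeptide,
this module computes the figures of merit used to judge glycopeptide spectra:

* peptide backbone coverage — the percentage of the L-1 inter-residue bonds
  evidenced by at least one matched b/y/c/z ion of any charge or glycan
  retention;
* glycan coverage — the percentage of glycan residues evidenced by the ladder
  of Y-ion depths observed (counting Y0, the bare peptide);
* explained ion current, partitioned over five fragment classes: plain
  backbone ions, backbone ions retaining the intact glycan, backbone ions
  retaining a HexNAc stub, Y ions, and B/oxonium ions;
* diagnostic oxonium intensity ratios — the GlcNAc/GalNAc isomer ratio and
  the Neu5Ac/HexNAc sialylation check.

Matching is ppm-based (default 20 ppm for products).  When one peak matches
several theoretical ions it is classified once, by the priority
backbone_plain > backbone_intact_glycan > backbone_stub > Y > oxonium, which
prevents double counting of ion current and favors the information-richer
assignment.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fragments import FragmentIon, Glycopeptide
from .glycans import GlycanComposition

__all__ = [
    "Spectrum",
    "AnnotationResult",
    "match_peaks",
    "coverage_metrics",
    "explained_ion_current",
    "intensity_ratio",
    "classify_hexnac_isomer",
    "flag_sialylation",
    "GLCNAC_GALNAC_DEFAULT",
    "HEXNAC_OXONIUM_MZ",
    "NEUAC_H2O_MZ",
]

PEAK_CLASSES = (
    "backbone_plain",
    "backbone_intact_glycan",
    "backbone_stub",
    "Y",
    "oxonium",
)

#: Diagnostic m/z values (singly protonated).
HEXNAC_OXONIUM_MZ = 204.086649
NEUAC_H2O_MZ = 274.092128

#: Default HexNAc-fragment ion sets for the GlcNAc/GalNAc intensity ratio
#: (numerator favors GlcNAc-diagnostic fragments).  These follow common
#: practice in oxonium-ratio work and are configuration, not fixed science.
GLCNAC_GALNAC_DEFAULT = (
    (126.0550, 138.0550),
    (144.0655, 168.0655),
)


@dataclass(frozen=True)
class Spectrum:
    """A centroid MS/MS peak list.

    Peaks are stored sorted by m/z.  ``scan_low``/``scan_high`` bound the
    acquired m/z range; peaks below ``scan_low`` are never matched.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple  # of (mz, intensity)
    scan_low: float = 115.0
    scan_high: float = 2000.0

    def __post_init__(self):
        if self.scan_low >= self.scan_high:
            raise ValueError("scan_low must be < scan_high")
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValueError("negative peak intensity")
        object.__setattr__(self, "peaks", pk)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    @property
    def total_intensity(self) -> float:
        return float(sum(i for _, i in self.peaks))


def _fragment_class(ion: FragmentIon) -> str:
    if ion.series in ("b", "y", "c", "z"):
        if ion.retention == "intact":
            return "backbone_intact_glycan"
        if ion.retention == "stub":
            return "backbone_stub"
        return "backbone_plain"
    if ion.series == "Y":
        return "Y"
    return "oxonium"


@dataclass
class AnnotationResult:
    """Matched-fragment bookkeeping for one spectrum.

    ``matches`` holds (ion, peak index, ppm error) triples; ``class_of_peak``
    assigns each matched peak exactly one class.  Metrics are filled by
    :func:`coverage_metrics` and :func:`explained_ion_current` (or all at once
    by :func:`match_peaks` when a glycopeptide is supplied).
    """

    spectrum: Spectrum
    matches: list = field(default_factory=list)
    class_of_peak: dict = field(default_factory=dict)
    backbone_coverage_pct: float = 0.0
    glycan_coverage_pct: float = 0.0
    eic_fractions: dict = field(default_factory=dict)
    explained_fraction_of_total: float = 0.0

    @property
    def matched_ions(self) -> list[FragmentIon]:
        return [ion for ion, _, _ in self.matches]


def _nearest_peak(mzs: Sequence[float], target: float, tol_ppm: float) -> tuple[int, float] | None:
    """Index and ppm error of the peak nearest *target* within tolerance."""
    lo = bisect.bisect_left(mzs, target * (1 - tol_ppm * 1e-6))
    hi = bisect.bisect_right(mzs, target * (1 + tol_ppm * 1e-6))
    best = None
    for idx in range(lo, hi):
        ppm = (mzs[idx] - target) / target * 1e6
        if best is None or abs(ppm) < abs(best[1]):
            best = (idx, ppm)
    return best


def match_peaks(
    spec: Spectrum,
    theoretical: Sequence[FragmentIon],
    tol_ppm: float = 20.0,
    gp: Glycopeptide | None = None,
) -> AnnotationResult:
    """Match theoretical ions to observed peaks within a ppm tolerance.

    Each theoretical ion is matched to the nearest peak within *tol_ppm*;
    each matched peak gets one class by the documented priority.  An empty
    spectrum yields a result with all-zero metrics.  If *gp* is given, the
    coverage and ion-current metrics are computed as well.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not theoretical:
        raise ValueError("theoretical ion list is empty")

    res = AnnotationResult(spectrum=spec)
    mzs = [m for m, _ in spec.peaks]
    priority = {cls: k for k, cls in enumerate(PEAK_CLASSES)}
    for ion in theoretical:
        if ion.mz < spec.scan_low:
            continue
        hit = _nearest_peak(mzs, ion.mz, tol_ppm)
        if hit is None:
            continue
        idx, ppm = hit
        res.matches.append((ion, idx, ppm))
        cls = _fragment_class(ion)
        cur = res.class_of_peak.get(idx)
        if cur is None or priority[cls] < priority[cur]:
            res.class_of_peak[idx] = cls

    if gp is not None:
        res.backbone_coverage_pct, res.glycan_coverage_pct = coverage_metrics(res, gp)
    res.eic_fractions, res.explained_fraction_of_total = explained_ion_current(res)
    return res


def coverage_metrics(res: AnnotationResult, gp: Glycopeptide) -> tuple[float, float]:
    """Backbone and glycan coverage percentages.

    Backbone coverage counts the inter-residue bonds evidenced by any matched
    b/y/c/z ion over the L-1 possible bonds.  Glycan coverage counts the
    distinct retained-residue depths among matched Y ions (Y0 included) over
    the total number of glycan residues.
    """
    L = len(gp)
    bonds = {ion.bond for ion in res.matched_ions if ion.series in "bycz"}
    bonds.discard(None)
    backbone = 100.0 * len(bonds) / (L - 1) if L > 1 else 0.0

    n_glycan = len(gp.glycan)
    if n_glycan:
        depths = {ion.index for ion in res.matched_ions if ion.series == "Y"}
        glycan = 100.0 * len(depths) / n_glycan
    else:
        glycan = 0.0
    return backbone, glycan


def explained_ion_current(res: AnnotationResult) -> tuple[dict, float]:
    """Ion-current fractions per fragment class.

    Fractions are over the matched intensity, so they sum to 1 whenever at
    least one peak matched; ``explained_fraction_of_total`` relates matched to
    total spectral intensity.
    """
    intens = [i for _, i in res.spectrum.peaks]
    per_class = {cls: 0.0 for cls in PEAK_CLASSES}
    for idx, cls in res.class_of_peak.items():
        per_class[cls] += intens[idx]
    matched = sum(per_class.values())
    total = sum(intens)
    if matched > 0:
        fractions = {cls: v / matched for cls, v in per_class.items()}
    else:
        fractions = {cls: 0.0 for cls in PEAK_CLASSES}
    explained = matched / total if total > 0 else 0.0
    return fractions, explained


def _sum_matched(spec: Spectrum, targets: Iterable[float], tol_ppm: float) -> float:
    mzs = [m for m, _ in spec.peaks]
    intens = [i for _, i in spec.peaks]
    seen: set[int] = set()
    total = 0.0
    for t in targets:
        if t < spec.scan_low:
            continue
        hit = _nearest_peak(mzs, t, tol_ppm)
        if hit is not None and hit[0] not in seen:
            seen.add(hit[0])
            total += intens[hit[0]]
    return total


def intensity_ratio(
    spec: Spectrum,
    numerator_mzs: Iterable[float],
    denominator_mzs: Iterable[float],
    tol_ppm: float = 20.0,
) -> float | None:
    """Summed-intensity ratio between two diagnostic ion sets.

    Returns ``None`` (undefined) when no denominator ion is found, 0.0 when
    the denominator is present but the numerator is absent.
    """
    numerator_mzs = tuple(numerator_mzs)
    denominator_mzs = tuple(denominator_mzs)
    if not numerator_mzs or not denominator_mzs:
        raise ValueError("ion sets must be nonempty")
    den = _sum_matched(spec, denominator_mzs, tol_ppm)
    if den == 0:
        return None
    num = _sum_matched(spec, numerator_mzs, tol_ppm)
    return num / den


def classify_hexnac_isomer(ratio: float | None) -> str:
    """Interpret a GlcNAc/GalNAc oxonium ratio.

    A ratio below 1 indicates GalNAc, above 2 indicates GlcNAc; values in
    [1, 2] (or an undefined ratio) are ambiguous.
    """
    if ratio is None:
        return "ambiguous"
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio < 1:
        return "GalNAc"
    if ratio > 2:
        return "GlcNAc"
    return "ambiguous"


def flag_sialylation(
    spec: Spectrum, tol_ppm: float = 20.0, threshold: float = 0.1
) -> bool:
    """True if the Neu5Ac/HexNAc oxonium intensity ratio exceeds *threshold*.

    The ratio of the m/z 274.0921 ion (NeuAc - H2O) to the HexNAc oxonium at
    m/z 204.0867 controls for spurious sialic-acid signals; strictly greater
    than 0.1 flags a genuinely sialylated precursor.
    """
    ratio = intensity_ratio(spec, (NEUAC_H2O_MZ,), (HEXNAC_OXONIUM_MZ,), tol_ppm)
    return ratio is not None and ratio > threshold
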