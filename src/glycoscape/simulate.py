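"""Seeded generators for every input the pipeline consumes.

Raw glycoproteomics inputs (instrument files and search-engine exports) are
large and instrument-bound, so this module emulates their structure with known
ground truth: a glycoproteome with planted N-X-S/T sequons, domain spans and
GO cellular-component labels; site-glycan assignment tables with tunable
microheterogeneity; PSM tables containing target and decoy hits with
configurable score distributions and planted per-step filter violators; and
glycopeptide MS/MS peak lists with controllable fragment-detection probability,
ppm jitter and noise.

Defaults emulate the structure of a large-scale brain N-glycoproteome
experiment: ~60% of occupied glycosites carry more than one glycan, roughly
four PSMs per unique glycopeptide, a 20-ppm-compatible mass accuracy (5 ppm
jitter), and a 115-2000 Th scan range.  All randomness flows through a single
``numpy`` generator seeded from the config, so equal seeds give byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Spectrum
from .fragments import FragmentIon, Glycopeptide, precursor_mz, theoretical_fragments
from .glycans import GlycanComposition, default_glycan_database

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_glycoproteome",
    "generate_assignments",
    "generate_psm_table",
    "generate_spectrum",
    "simulate_study",
    "truncated_geometric_pmf",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Domain catalog: name -> (min length, max length).
DEFAULT_DOMAIN_CATALOG: dict[str, tuple[int, int]] = {
    "Ig-like": (70, 110),
    "EGF-like": (30, 45),
    "Fibronectin type-III": (80, 100),
    "Sushi": (55, 70),
    "CUB": (100, 120),
    "Cadherin": (90, 110),
    "Sema": (400, 450),
    "Laminin EGF-like": (50, 65),
    "Peptidase S1": (210, 250),
    "Lectin C-type": (110, 130),
}

#: GO cellular-component term catalog sampled for protein annotations.
DEFAULT_CC_CATALOG: tuple[str, ...] = (
    "plasma membrane",
    "integral component of membrane",
    "synaptic vesicle membrane",
    "synapse",
    "axon",
    "neuronal cell body",
    "myelin sheath",
    "Golgi apparatus",
    "endoplasmic reticulum",
    "cell surface",
    "lysosome",
    "extracellular space",
    "transport vesicle",
    "cytoplasm",
    "nucleus",
)


@dataclass
class SimulationConfig:
    """Tunable knobs of the synthetic study; see module docstring for defaults."""

    seed: int = 0
    n_proteins: int = 50
    protein_length: tuple[int, int] = (250, 500)
    sequon_density: float = 0.01          # planted sequons per residue
    domain_catalog: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_CATALOG)
    )
    domains_per_protein: tuple[int, int] = (1, 3)
    cc_catalog: Sequence[str] = DEFAULT_CC_CATALOG
    cc_multi_label_prob: float = 0.4
    cc_terms_max: int = 4
    glycan_database: Sequence[GlycanComposition] | None = None
    site_occupancy: float = 0.85
    multi_glycan_prob: float = 0.6        # truncated-geometric continuation q
    max_glycans_per_site: int = 20
    psm_rate: float = 3.3                 # PSMs per site-glycan pair = 1 + Poisson(rate)
    decoy_fraction: float = 0.10
    false_target_fraction: float = 0.0
    violators: Mapping[str, int] = field(default_factory=dict)
    # score distributions: (mean, sd); two_d is the FDR-ranking score
    target_two_d: tuple[float, float] = (4.0, 1.0)
    null_two_d: tuple[float, float] = (0.0, 1.0)
    target_byonic: tuple[float, float] = (350.0, 80.0)
    target_log_prob: tuple[float, float] = (3.0, 1.0)
    target_delta_mod: tuple[float, float] = (30.0, 10.0)
    # spectra
    n_spectra: int = 25
    fragment_detection_p: float = 0.7
    series: tuple[str, ...] = ("c", "z")
    retention_modes: tuple[str, ...] = ("intact", "stub", "none")
    max_fragment_charge: int = 2
    include_y_ladder: bool = True
    include_oxonium: bool = True
    ppm_jitter_sigma: float = 5.0
    n_noise_peaks: int = 50
    noise_intensity_scale: float = 50.0
    scan_low: float = 115.0
    scan_high: float = 2000.0

    def __post_init__(self):
        for p in (self.site_occupancy, self.multi_glycan_prob,
                  self.fragment_detection_p, self.cc_multi_label_prob,
                  self.decoy_fraction, self.false_target_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_proteins < 0 or self.n_spectra < 0 or self.n_noise_peaks < 0:
            raise ValueError("counts must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def glycans(self) -> list[GlycanComposition]:
        if self.glycan_database is not None:
            return list(self.glycan_database)
        return default_glycan_database()


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    assignments: pd.DataFrame            # protein_accession, protein_site, glycan
    glycans_per_site: dict               # k -> number of sites
    psm_labels: pd.DataFrame | None = None   # spectrum_id, is_correct, planted_violation
    planted_fragments: dict = field(default_factory=dict)  # spectrum_id -> [FragmentIon]

    def to_json(self) -> dict:
        obj = {
            "assignments": self.assignments.to_dict(orient="records"),
            "glycans_per_site": {str(k): int(v) for k, v in self.glycans_per_site.items()},
        }
        if self.psm_labels is not None:
            obj["psm_labels"] = self.psm_labels.to_dict(orient="records")
        return obj


def truncated_geometric_pmf(q: float, kmax: int) -> np.ndarray:
    """PMF of the glycans-per-site count k = 1..kmax.

    Geometric with continuation probability *q* truncated at *kmax*;
    the untruncated P(k > 1) equals q.
    """
    k = np.arange(1, kmax + 1)
    pmf = (1 - q) * q ** (k - 1)
    return pmf / pmf.sum()


def generate_glycoproteome(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Random glycoproteome: sequences with planted sequons, domains, CC terms.

    Returns ``(fasta, candidate_sites, cc_df, domain_df, domain_counts)`` where
    *fasta* maps accession to sequence and *candidate_sites* is a list of
    (accession, 1-based position) pairs, every one of which satisfies the
    N-X-S/T (X != P) sequon by construction.
    """
    rng = rng or cfg.rng()
    fasta: dict[str, str] = {}
    candidates: list[tuple[str, int]] = []
    cc_rows, dom_rows = [], []
    aa = np.array(list(AA_ALPHABET))
    x_pool = np.array([c for c in AA_ALPHABET if c != "P"])

    for i in range(cfg.n_proteins):
        acc = f"SYN{i:04d}"
        length = int(rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1))
        seq = rng.choice(aa, size=length)
        n_sequons = int(round(cfg.sequon_density * length))
        if n_sequons * 3 > length:
            raise ValueError(
                f"sequon density {cfg.sequon_density} infeasible for length {length}"
            )
        if n_sequons:
            # non-overlapping triplet anchors, kept >= 3 apart
            positions: list[int] = []
            tries = 0
            while len(positions) < n_sequons and tries < 1000:
                pos = int(rng.integers(1, length - 2))  # 0-based anchor, room for +2
                if all(abs(pos - p) >= 3 for p in positions):
                    positions.append(pos)
                tries += 1
            for pos in sorted(positions):
                seq[pos] = "N"
                seq[pos + 1] = rng.choice(x_pool)
                seq[pos + 2] = "S" if rng.random() < 0.41 else "T"
                candidates.append((acc, pos + 1))
        # guard: strip accidental Ns that would form unplanned sequons?  Not
        # needed: downstream only uses planted candidates.
        fasta[acc] = "".join(seq)

        n_terms = 1 + int(
            rng.binomial(cfg.cc_terms_max - 1, cfg.cc_multi_label_prob)
        )
        terms = rng.choice(len(cfg.cc_catalog), size=min(n_terms, len(cfg.cc_catalog)),
                           replace=False)
        for t in sorted(terms):
            cc_rows.append((acc, cfg.cc_catalog[int(t)]))

        names = list(cfg.domain_catalog)
        n_dom = int(rng.integers(cfg.domains_per_protein[0],
                                 cfg.domains_per_protein[1] + 1))
        cursor = 1
        for _ in range(n_dom):
            name = names[int(rng.integers(len(names)))]
            lo, hi = cfg.domain_catalog[name]
            span = int(rng.integers(lo, hi + 1))
            if cursor + span > length:
                break
            start = cursor + int(rng.integers(0, max(1, (length - cursor - span) // 3 + 1)))
            end = min(start + span - 1, length)
            dom_rows.append((acc, name, start, end))
            cursor = end + 1

    cc_df = pd.DataFrame(cc_rows, columns=["accession", "go_cc_term"])
    dom_df = pd.DataFrame(dom_rows, columns=["protein_accession", "domain", "start", "end"])
    counts = dom_df["domain"].value_counts().rename_axis("domain").rename("count")
    domain_counts = counts.reset_index()
    return fasta, candidates, cc_df, dom_df, domain_counts


def generate_assignments(
    candidates: Sequence[tuple[str, int]],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw site-glycan assignments with a truncated-geometric heterogeneity law."""
    rng = rng or cfg.rng()
    glycans = cfg.glycans()
    kmax = min(cfg.max_glycans_per_site, len(glycans))
    if cfg.max_glycans_per_site > len(glycans):
        import warnings

        warnings.warn("max glycans per site capped at database size", stacklevel=2)
    pmf = truncated_geometric_pmf(cfg.multi_glycan_prob, kmax)
    rows = []
    hist: dict[int, int] = {}
    for acc, site in candidates:
        if rng.random() > cfg.site_occupancy:
            continue
        k = int(rng.choice(np.arange(1, kmax + 1), p=pmf))
        chosen = rng.choice(len(glycans), size=k, replace=False)
        hist[k] = hist.get(k, 0) + 1
        for gi in sorted(chosen):
            rows.append((acc, site, str(glycans[int(gi)])))
    df = pd.DataFrame(rows, columns=["protein_accession", "protein_site", "glycan"])
    truth = GroundTruth(assignments=df.copy(), glycans_per_site=hist)
    return df, truth


def _draw(rng, params, size=None, floor=0.0):
    return np.maximum(rng.normal(params[0], params[1], size=size), floor)


def _peptide_window(
    seq: str, site: int, rng: np.random.Generator, min_len: int = 6
) -> tuple[str, int]:
    """Peptide substring around a 1-based protein site; returns (peptide, site-in-peptide)."""
    before = int(rng.integers(2, 9))
    after = int(rng.integers(4, 12))
    start = max(0, site - 1 - before)
    end = min(len(seq), site + after)
    if end - start < min_len:
        end = min(len(seq), start + min_len)
    return seq[start:end], site - start


def generate_psm_table(
    assignments: pd.DataFrame,
    fasta: Mapping[str, str],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSM table with targets, decoys, optional false targets and planted violators.

    Returns ``(psms, labels)`` where *labels* carries per-row ground truth:
    ``is_correct`` (False for decoys and null-score targets) and
    ``planted_violation`` (the cascade step a violator row was built to fail,
    empty otherwise).
    """
    rng = rng or cfg.rng()
    rows: list[dict] = []
    labels: list[dict] = []
    sid = 0

    def emit(acc, peptide, gpos, psite, glycan, correct, violation, decoy=False,
             overrides=None):
        nonlocal sid
        sid += 1
        good = correct and not decoy
        t = "target" if good else "null"
        # the ranking score (two_d) separates correct targets from decoys and
        # false targets; the remaining quality scores are target-like for all
        # emitted rows and truncated to the passing side of each threshold, so
        # cascade removals beyond the q-value step are attributable solely to
        # planted violators (the generator's contract)
        byonic = max(float(_draw(rng, cfg.target_byonic)), 160.0)
        log_prob = max(float(_draw(rng, cfg.target_log_prob)), 1.2)
        delta = max(float(_draw(rng, cfg.target_delta_mod)), 12.0)
        if good:
            two_d = max(float(rng.normal(*cfg.target_two_d)), 2.5)
        else:
            two_d = min(float(rng.normal(*cfg.null_two_d)), 2.0)
        row = {
            "spectrum_id": f"scan{sid:06d}",
            "peptide": peptide,
            "protein_accession": acc,
            "is_decoy": decoy,
            "glycosite_position": gpos,
            "protein_site": psite,
            "glycan": glycan,
            "n_glycosites": 1 if glycan else 0,
            "byonic_score": byonic,
            "two_d_score": two_d,
            "log_prob_abs": log_prob,
            "delta_mod": delta,
            "precursor_mz": float(rng.uniform(700, 1600)),
            "charge": int(rng.integers(2, 5)),
            "dissociation": "AI-ETD" if rng.random() < 0.7 else "HCD",
        }
        if overrides:
            row.update(overrides)
        rows.append(row)
        labels.append(
            {"spectrum_id": row["spectrum_id"], "is_correct": bool(correct and not decoy),
             "planted_violation": violation}
        )

    n_true = 0
    for _, a in assignments.iterrows():
        acc, psite, glycan = a["protein_accession"], int(a["protein_site"]), a["glycan"]
        peptide, gpos = _peptide_window(fasta[acc], psite, rng)
        n_psm = 1 + int(rng.poisson(cfg.psm_rate))
        for _ in range(n_psm):
            emit(acc, peptide, gpos, psite, glycan, True, "")
            n_true += 1

    glycan_pool = [str(g) for g in cfg.glycans()]
    accs = list(fasta)

    n_false = int(round(cfg.false_target_fraction * n_true))
    for _ in range(n_false):
        acc = accs[int(rng.integers(len(accs)))]
        peptide, gpos = _peptide_window(fasta[acc], 1 + int(
            rng.integers(3, max(4, len(fasta[acc]) - 12))), rng)
        glycan = glycan_pool[int(rng.integers(len(glycan_pool)))]
        emit(acc, peptide, min(gpos, len(peptide)), None, glycan, False, "")

    n_decoy = int(round(cfg.decoy_fraction * n_true))
    for _ in range(n_decoy):
        acc = accs[int(rng.integers(len(accs)))]
        peptide = "".join(
            rng.choice(list(AA_ALPHABET), size=int(rng.integers(8, 16)))
        )
        glycan = glycan_pool[int(rng.integers(len(glycan_pool)))]
        emit("rev_" + acc, peptide, 1, None, glycan, False, "", decoy=True,
             overrides={"glycosite_position": None})

    # planted violators: pass everything except exactly one step
    clean_template = assignments.iloc[0] if len(assignments) else None
    for step, count in cfg.violators.items():
        for _ in range(int(count)):
            if clean_template is None:
                break
            acc = clean_template["protein_accession"]
            psite = int(clean_template["protein_site"])
            glycan = clean_template["glycan"]
            peptide, gpos = _peptide_window(fasta[acc], psite, rng)
            overrides = {}
            if step == "psm_fdr":
                overrides["two_d_score"] = float(
                    rng.normal(*cfg.null_two_d) - 5.0
                )
            elif step == "byonic_score":
                overrides["byonic_score"] = float(rng.uniform(20, 140))
            elif step == "peptide_length":
                peptide, gpos = "GNST", 2
            elif step == "log_prob":
                overrides["log_prob_abs"] = float(rng.uniform(0.0, 0.9))
            elif step == "single_glycosite":
                overrides["n_glycosites"] = 2
            elif step == "delta_mod":
                overrides["delta_mod"] = float(rng.uniform(0, 9))
            else:
                raise ValueError(f"unknown violator step {step!r}")
            # force the non-violated score fields comfortably past thresholds
            base = {
                "byonic_score": 400.0,
                "log_prob_abs": 3.0,
                "delta_mod": 30.0,
            }
            base.update(overrides)
            emit(acc, peptide, gpos, psite, glycan, True, step, overrides=base)

    psms = pd.DataFrame(rows)
    label_df = pd.DataFrame(labels)
    return psms, label_df


def generate_spectrum(
    gp: Glycopeptide,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    spectrum_id: str = "sim0001",
) -> tuple[Spectrum, list[FragmentIon]]:
    """Simulate one MS/MS spectrum of a glycopeptide.

    Theoretical fragments within the scan range are each retained with
    probability ``fragment_detection_p``, their m/z jittered with Gaussian ppm
    noise; class-dependent log-normal intensities and uniform noise peaks are
    added.  Returns the spectrum and the list of planted fragments.
    """
    rng = rng or cfg.rng()
    theo = theoretical_fragments(
        gp,
        series=cfg.series,
        retention_modes=cfg.retention_modes,
        max_charge=cfg.max_fragment_charge,
        include_y_ladder=cfg.include_y_ladder,
        include_oxonium=cfg.include_oxonium,
        mz_ceiling=cfg.scan_high,
    )
    in_window = [
        ion for ion in theo if cfg.scan_low <= ion.mz <= cfg.scan_high
    ]
    intensity_mu = {"b": 4.0, "y": 4.0, "c": 5.0, "z": 5.0, "Y": 5.5, "B": 6.5}
    peaks = []
    planted = []
    for ion in in_window:
        if rng.random() > cfg.fragment_detection_p:
            continue
        mz = ion.mz * (1 + rng.normal(0, cfg.ppm_jitter_sigma) * 1e-6)
        inten = float(rng.lognormal(intensity_mu[ion.series], 0.5))
        peaks.append((mz, inten))
        planted.append(ion)
    for _ in range(cfg.n_noise_peaks):
        peaks.append(
            (
                float(rng.uniform(cfg.scan_low, cfg.scan_high)),
                float(rng.exponential(cfg.noise_intensity_scale)),
            )
        )
    charge = max(2, cfg.max_fragment_charge)
    spec = Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz(gp, charge),
        precursor_charge=charge,
        peaks=tuple(peaks),
        scan_low=cfg.scan_low,
        scan_high=cfg.scan_high,
    )
    return spec, planted


def simulate_study(cfg: SimulationConfig, outdir) -> GroundTruth:
    """Run the full generator and write every pipeline input to *outdir*.

    Emits proteome.fasta, cc_terms.tsv, domains.tsv, domain_counts.tsv,
    psms.tsv, spectra.mgf, glycan_db.tsv and truth.json.  Deterministic under
    the config seed.
    """
    from pathlib import Path

    from . import io as gio
    from .fragments import Glycopeptide
    from .glycans import parse_composition

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()

    fasta, candidates, cc_df, dom_df, dom_counts = generate_glycoproteome(cfg, rng)
    assignments, truth = generate_assignments(candidates, cfg, rng)
    psms, labels = generate_psm_table(assignments, fasta, cfg, rng)
    truth.psm_labels = labels

    spectra = []
    glyco_targets = psms[(~psms["is_decoy"]) & (psms["glycan"] != "")]
    n_spec = min(cfg.n_spectra, len(glyco_targets))
    for i in range(n_spec):
        row = glyco_targets.iloc[i]
        try:
            gp = Glycopeptide(
                sequence=row["peptide"],
                glycosite=int(row["glycosite_position"]),
                glycan=parse_composition(row["glycan"]),
            )
        except ValueError:
            continue
        spec, planted = generate_spectrum(
            gp, cfg, rng, spectrum_id=row["spectrum_id"]
        )
        spectra.append(spec)
        truth.planted_fragments[row["spectrum_id"]] = planted

    gio.write_fasta(fasta, outdir / "proteome.fasta")
    gio.write_tsv(cc_df, outdir / "cc_terms.tsv")
    gio.write_tsv(dom_df, outdir / "domains.tsv")
    gio.write_tsv(dom_counts, outdir / "domain_counts.tsv")
    gio.write_tsv(psms, outdir / "psms.tsv")
    gio.write_mgf(spectra, outdir / "spectra.mgf")
    glydb = pd.DataFrame(
        {
            "id": range(1, len(cfg.glycans()) + 1),
            "composition": [str(g) for g in cfg.glycans()],
        }
    )
    gio.write_tsv(glydb, outdir / "glycan_db.tsv")
    gio.write_json(truth.to_json(), outdir / "truth.json")
    return truth
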