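"""Target-decoy FDR and the six-step post-search filter cascade.

Search-engine exports retain many marginal glycopeptide-spectrum matches, so
identifications are post-processed by (1) filtering to 1% FDR at the PSM level
using a target-decoy q-value over the ranking score, (2) removing search
scores below 150, (3) requiring peptide length >= 5, (4) requiring
|log10 protein p-value| > 1, (5) discarding peptides carrying more than one
glycosite, and (6) requiring a modification-localization (DeltaMod) score of
at least 10.  A glyco-specific FDR is then estimated by counting decoy and
target hits that are glycopeptides, excluding non-modified sequences.

PSM tables are pandas DataFrames with the columns in :data:`PSM_COLUMNS`
(column order free, extra columns ignored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PSM_COLUMNS",
    "FilterConfig",
    "FilterReport",
    "compute_qvalues",
    "apply_filter_cascade",
    "estimate_glyco_fdr",
    "validate_sequon",
    "build_focused_database",
]

#: Required columns of a PSM table.
PSM_COLUMNS = (
    "spectrum_id",
    "peptide",
    "protein_accession",
    "is_decoy",
    "glycosite_position",   # 1-based within peptide; NaN for non-glyco PSMs
    "glycan",               # composition string; empty for non-glyco PSMs
    "n_glycosites",
    "byonic_score",
    "two_d_score",          # ranking score used for PSM-level FDR
    "log_prob_abs",         # |log10 protein p-value|
    "delta_mod",
    "precursor_mz",
    "charge",
    "dissociation",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the six-step cascade (defaults follow common practice)."""

    psm_fdr: float = 0.01
    min_byonic_score: float = 150.0
    min_peptide_length: int = 5
    min_log_prob_abs: float = 1.0
    max_glycosites: int = 1
    min_delta_mod: float = 10.0
    require_sequon: bool = True

    def __post_init__(self):
        for name, val in asdict(self).items():
            if name != "require_sequon" and val < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: Mapping) -> "FilterConfig":
        return cls(**obj)


@dataclass
class FilterReport:
    """Per-step survivor accounting for one cascade run.

    ``steps`` is a list of dicts with keys step, input, removed, survivors;
    counts telescope (survivors of step k = input of step k+1).
    """

    steps: list = field(default_factory=list)
    survivors: pd.DataFrame | None = None
    glyco_fdr_estimate: float | None = None
    decoys_remaining: int = 0

    def add_step(self, name: str, n_in: int, n_out: int) -> None:
        self.steps.append(
            {"step": name, "input": n_in, "removed": n_in - n_out, "survivors": n_out}
        )

    def removed(self, step_name: str) -> int:
        for s in self.steps:
            if s["step"] == step_name:
                return s["removed"]
        raise KeyError(step_name)

    def to_json(self) -> dict:
        return {
            "steps": self.steps,
            "n_survivors": 0 if self.survivors is None else len(self.survivors),
            "glyco_fdr_estimate": self.glyco_fdr_estimate,
            "decoys_remaining": self.decoys_remaining,
        }

    def log_lines(self) -> list[str]:
        lines = []
        for s in self.steps:
            lines.append(
                f"{s['step']}: {s['input']} in, {s['removed']} removed, "
                f"{s['survivors']} survive"
            )
        fdr = (
            "undefined"
            if self.glyco_fdr_estimate is None
            else f"{100 * self.glyco_fdr_estimate:.2f}%"
        )
        lines.append(
            f"glyco FDR estimate: {fdr} ({self.decoys_remaining} decoys remaining)"
        )
        return lines


def compute_qvalues(
    psms: pd.DataFrame, score_field: str = "two_d_score"
) -> pd.DataFrame:
    """Target-decoy q-values over *score_field* (higher score = better).

    At each threshold t, FDR(t) = (#decoys >= t) / (#targets >= t); the
    q-value is the running minimum of FDR over decreasing score, and tied
    scores share a q-value.  Returns a copy with a ``q_value`` column.

    Raises if there are no target records; with no decoys, all q-values are 0
    and a warning is emitted.
    """
    if score_field not in psms.columns:
        raise ValueError(f"score field {score_field!r} missing from PSM table")
    if "is_decoy" not in psms.columns:
        raise ValueError("PSM table lacks 'is_decoy' column")
    out = psms.copy()
    n_targets = int((~out["is_decoy"].astype(bool)).sum())
    if n_targets == 0:
        raise ValueError("PSM table contains no target records")
    if len(out) == 0:
        out["q_value"] = pd.Series(dtype=float)
        return out
    if out["is_decoy"].astype(bool).sum() == 0:
        warnings.warn("no decoy records: all q-values set to 0", stacklevel=2)
        out["q_value"] = 0.0
        return out

    scores = out[score_field].to_numpy(dtype=float)
    decoy = out["is_decoy"].to_numpy(dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = decoy[order]
    cum_decoys = np.cumsum(d_sorted)
    cum_targets = np.cumsum(~d_sorted)
    with np.errstate(divide="ignore"):
        fdr = np.where(cum_targets > 0, cum_decoys / np.maximum(cum_targets, 1), np.inf)
    # ties share the FDR computed at the last index of the tie block
    for i in range(len(s_sorted) - 2, -1, -1):
        if s_sorted[i] == s_sorted[i + 1]:
            fdr[i] = fdr[i + 1]
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    qvals = np.empty_like(q)
    qvals[order] = q
    out["q_value"] = qvals
    return out


def _require_columns(psms: pd.DataFrame, cols: Iterable[str]) -> None:
    for col in cols:
        if col not in psms.columns:
            raise ValueError(f"PSM table missing required column {col!r}")
        if psms[col].isna().all() and len(psms):
            continue


def apply_filter_cascade(
    psms: pd.DataFrame,
    cfg: FilterConfig | None = None,
    protein_context: Mapping[str, str] | None = None,
) -> FilterReport:
    """Run the six-step cascade and return a :class:`FilterReport`.

    Steps, in order: q-value <= psm_fdr; byonic_score >= min; peptide length
    >= min; log_prob_abs > min; n_glycosites <= max; delta_mod >= min; then an
    optional sequon check on glyco PSMs (protein context, keyed by accession,
    resolves sequons spanning the peptide C-terminus).
    Requires a ``q_value`` column (see :func:`compute_qvalues`).
    """
    cfg = cfg or FilterConfig()
    if "q_value" not in psms.columns:
        raise ValueError("q-values not computed; run compute_qvalues first")
    _require_columns(
        psms,
        ("peptide", "byonic_score", "log_prob_abs", "n_glycosites", "delta_mod",
         "is_decoy"),
    )
    for col in ("byonic_score", "log_prob_abs", "delta_mod", "q_value"):
        bad = psms.index[psms[col].isna()]
        if len(bad):
            raise ValueError(f"missing {col!r} on row {bad[0]}")

    report = FilterReport()
    cur = psms

    def step(name: str, mask: pd.Series) -> None:
        nonlocal cur
        n_in = len(cur)
        cur = cur[mask]
        report.add_step(name, n_in, len(cur))

    step("psm_fdr", cur["q_value"] <= cfg.psm_fdr)
    step("byonic_score", cur["byonic_score"] >= cfg.min_byonic_score)
    step("peptide_length", cur["peptide"].str.len() >= cfg.min_peptide_length)
    step("log_prob", cur["log_prob_abs"] > cfg.min_log_prob_abs)
    step("single_glycosite", cur["n_glycosites"] <= cfg.max_glycosites)
    step("delta_mod", cur["delta_mod"] >= cfg.min_delta_mod)

    if cfg.require_sequon:
        ctx = protein_context or {}

        def _ok(row) -> bool:
            if not row["n_glycosites"]:
                return True
            pos = row["glycosite_position"]
            if pd.isna(pos):
                return False
            downstream = ""
            acc = row.get("protein_accession")
            if acc in ctx:
                seq = ctx[acc]
                start = seq.find(row["peptide"])
                if start >= 0:
                    downstream = seq[start + len(row["peptide"]):]
            try:
                return validate_sequon(row["peptide"], int(pos), downstream)
            except ValueError:
                return False

        step("sequon", cur.apply(_ok, axis=1) if len(cur) else pd.Series(dtype=bool))

    report.survivors = cur.reset_index(drop=True)
    report.decoys_remaining = int(cur["is_decoy"].astype(bool).sum())
    report.glyco_fdr_estimate = estimate_glyco_fdr(cur)
    return report


def estimate_glyco_fdr(psms: pd.DataFrame) -> float | None:
    """Glycopeptide-level FDR: decoy glyco PSMs / target glyco PSMs.

    Only records with at least one glycosite count; returns ``None``
    (undefined) when no target glyco PSMs remain.
    """
    if len(psms) == 0:
        return None
    glyco = psms[psms["n_glycosites"].fillna(0).astype(int) >= 1]
    decoys = int(glyco["is_decoy"].astype(bool).sum())
    targets = len(glyco) - decoys
    if targets == 0:
        return None
    return decoys / targets


def validate_sequon(
    peptide: str, glycosite_position: int, protein_context: str = ""
) -> bool:
    """Check the N-glycosylation sequon N-X-S/T (X any residue but proline).

    *glycosite_position* is 1-based within *peptide* and must index an N.
    *protein_context* supplies the residues following the peptide in the
    parent protein, used when the sequon spans the peptide C-terminus; without
    context a terminal N fails the check.
    """
    if not 1 <= glycosite_position <= len(peptide):
        raise ValueError(
            f"glycosite position {glycosite_position} outside 1..{len(peptide)}"
        )
    if peptide[glycosite_position - 1] != "N":
        raise ValueError(
            f"residue at position {glycosite_position} is "
            f"{peptide[glycosite_position - 1]!r}, expected 'N'"
        )
    extended = peptide + protein_context
    i = glycosite_position - 1
    if i + 2 >= len(extended):
        return False
    x, third = extended[i + 1], extended[i + 2]
    return x != "P" and third in ("S", "T")


def build_focused_database(
    deglyco_psms: pd.DataFrame, fasta: Mapping[str, str]
) -> dict[str, str]:
    """Subset a FASTA to proteins evidenced by de-glycosylated peptides.

    PNGaseF treatment converts a formerly glycosylated asparagine to
    aspartate, observed as a deamidation; a protein is retained when at least
    one of its peptides carries a deamidated N inside a valid N-X-S/T sequon.

    *deglyco_psms* needs columns ``protein_accession``, ``peptide`` and
    ``deamidated_positions`` (comma-separated 1-based peptide positions; empty
    for none).  Accessions absent from *fasta* are skipped with a warning.
    """
    kept: dict[str, str] = {}
    for _, row in deglyco_psms.iterrows():
        acc = row["protein_accession"]
        if acc in kept:
            continue
        if acc not in fasta:
            warnings.warn(f"accession {acc!r} absent from FASTA; row skipped",
                          stacklevel=2)
            continue
        raw = row.get("deamidated_positions", "")
        if pd.isna(raw) or not str(raw).strip():
            continue
        peptide = row["peptide"]
        seq = fasta[acc]
        start = seq.find(peptide)
        downstream = seq[start + len(peptide):] if start >= 0 else ""
        for tok in str(raw).split(","):
            pos = int(tok)
            if not (1 <= pos <= len(peptide)) or peptide[pos - 1] != "N":
                continue
            if validate_sequon(peptide, pos, downstream):
                kept[acc] = seq
                break
    return kept
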