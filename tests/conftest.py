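import numpy as np
import pandas as pd
import pytest

from glycoscape.fragments import Glycopeptide
from glycoscape.glycans import parse_composition


@pytest.fixture
def high_mannose_gp():
    """The worked-example glycopeptide: TN*SSFIQGFVDHVKEDCDR + HexNAc(2)Hex(9),
    carbamidomethyl on the cysteine (fixed by default)."""
    return Glycopeptide(
        sequence="TNSSFIQGFVDHVKEDCDR",
        glycosite=2,
        glycan=parse_composition("HexNAc(2)Hex(9)"),
    )


def make_psm_frame(rows):
    """Build a PSM table from partial dicts, filling passing defaults."""
    defaults = {
        "spectrum_id": None,
        "peptide": "TNSSFK",
        "protein_accession": "P1",
        "is_decoy": False,
        "glycosite_position": 2,
        "protein_site": 10,
        "glycan": "HexNAc(2)Hex(9)",
        "n_glycosites": 1,
        "byonic_score": 300.0,
        "two_d_score": 5.0,
        "log_prob_abs": 3.0,
        "delta_mod": 20.0,
        "precursor_mz": 900.0,
        "charge": 2,
        "dissociation": "AI-ETD",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["spectrum_id"] = f"s{i:04d}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def psm_factory():
    return make_psm_frame
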