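"""Target-decoy q-values, the six-step cascade, glyco FDR, sequon checks."""

import numpy as np
import pandas as pd
import pytest

from glycoscape.filtering import (
    FilterConfig,
    apply_filter_cascade,
    build_focused_database,
    compute_qvalues,
    estimate_glyco_fdr,
    validate_sequon,
)


def test_qvalue_worked_example(psm_factory):
    """Targets 300/250/200 with one decoy at 220: q(200) = 1/3."""
    df = psm_factory(
        [
            {"two_d_score": 300.0},
            {"two_d_score": 250.0},
            {"two_d_score": 220.0, "is_decoy": True},
            {"two_d_score": 200.0},
        ]
    )
    q = compute_qvalues(df)
    by_score = q.set_index("two_d_score")["q_value"]
    assert by_score[200.0] == pytest.approx(1 / 3)
    assert by_score[300.0] == 0.0
    assert by_score[250.0] == 0.0


def test_qvalue_ties_share_value(psm_factory):
    df = psm_factory(
        [
            {"two_d_score": 250.0},
            {"two_d_score": 200.0},
            {"two_d_score": 200.0, "is_decoy": True},
            {"two_d_score": 100.0},
        ]
    )
    q = compute_qvalues(df)
    tied = q[q["two_d_score"] == 200.0]["q_value"]
    assert tied.nunique() == 1
    # FDR at threshold 200 is 1/2, but accepting down to 100 gives 1/3 with
    # more targets, so the running-minimum q-value at the tie is 1/3
    assert tied.iloc[0] == pytest.approx(1 / 3)
    assert q.set_index("two_d_score")["q_value"][100.0] == pytest.approx(1 / 3)


def test_qvalue_degenerate_inputs(psm_factory):
    with pytest.raises(ValueError, match="no target"):
        compute_qvalues(psm_factory([{"is_decoy": True}]))
    with pytest.warns(UserWarning, match="no decoy"):
        q = compute_qvalues(psm_factory([{}, {}]))
    assert (q["q_value"] == 0).all()


def test_qvalue_monotone_in_score(psm_factory):
    rng = np.random.default_rng(2)
    rows = [{"two_d_score": float(rng.normal(3, 1))} for _ in range(200)]
    rows += [{"two_d_score": float(rng.normal(0, 1)), "is_decoy": True}
             for _ in range(50)]
    q = compute_qvalues(psm_factory(rows)).sort_values("two_d_score")
    assert (np.diff(q["q_value"].to_numpy()) <= 1e-12).all()


def _cascade_table(psm_factory):
    rows = [{} for _ in range(20)]                       # clean survivors
    rows += [{"byonic_score": 149.0}] * 3                # step 2 violators
    rows += [{"peptide": "GNST", "glycosite_position": 2}] * 2   # step 3
    rows += [{"log_prob_abs": 1.0}] * 4                  # step 4 (strict >)
    rows += [{"n_glycosites": 2}] * 2                    # step 5
    rows += [{"delta_mod": 9.9}] * 5                     # step 6
    rows += [{"two_d_score": -10.0}] * 2                 # q-value casualties
    rows += [{"two_d_score": float(-5 - i), "is_decoy": True} for i in range(3)]
    return psm_factory(rows)


def test_cascade_per_step_counts(psm_factory):
    df = compute_qvalues(_cascade_table(psm_factory))
    report = apply_filter_cascade(df, FilterConfig(require_sequon=False))
    # independent recount: decoys and the two sunk targets exceed q 0.01
    q_removed = int((df["q_value"] > 0.01).sum())
    assert report.removed("psm_fdr") == q_removed
    assert report.removed("byonic_score") == 3
    assert report.removed("peptide_length") == 2
    assert report.removed("log_prob") == 4
    assert report.removed("single_glycosite") == 2
    assert report.removed("delta_mod") == 5
    assert len(report.survivors) == 20
    # counts telescope
    for prev, nxt in zip(report.steps, report.steps[1:]):
        assert prev["survivors"] == nxt["input"]


def test_cascade_monotone_in_thresholds(psm_factory):
    df = compute_qvalues(_cascade_table(psm_factory))
    base = apply_filter_cascade(df, FilterConfig(require_sequon=False))
    tighter = apply_filter_cascade(
        df,
        FilterConfig(min_byonic_score=400, min_delta_mod=25, require_sequon=False),
    )
    assert len(tighter.survivors) <= len(base.survivors)


def test_cascade_order_invariance_of_survivors(psm_factory):
    """All predicates are record-local, so the survivor set is order-free."""
    df = compute_qvalues(_cascade_table(psm_factory))
    report = apply_filter_cascade(df, FilterConfig(require_sequon=False))
    cfg = FilterConfig(require_sequon=False)
    direct = df[
        (df["q_value"] <= cfg.psm_fdr)
        & (df["byonic_score"] >= cfg.min_byonic_score)
        & (df["peptide"].str.len() >= cfg.min_peptide_length)
        & (df["log_prob_abs"] > cfg.min_log_prob_abs)
        & (df["n_glycosites"] <= cfg.max_glycosites)
        & (df["delta_mod"] >= cfg.min_delta_mod)
    ]
    assert set(direct["spectrum_id"]) == set(report.survivors["spectrum_id"])


def test_cascade_requires_qvalues(psm_factory):
    with pytest.raises(ValueError, match="q-values"):
        apply_filter_cascade(psm_factory([{}]))


def test_cascade_missing_field_named(psm_factory):
    df = compute_qvalues(psm_factory([{}, {"delta_mod": np.nan}]))
    with pytest.raises(ValueError, match="delta_mod"):
        apply_filter_cascade(df)


def test_glyco_fdr_estimate(psm_factory):
    rows = [{} for _ in range(300)]
    rows += [{"is_decoy": True}]
    rows += [{"glycan": "", "n_glycosites": 0, "glycosite_position": None}] * 10
    df = psm_factory(rows)
    est = estimate_glyco_fdr(df)
    assert est == pytest.approx(1 / 300)
    # non-glyco rows are excluded from both counts
    no_decoys = psm_factory([{} for _ in range(5)])
    assert estimate_glyco_fdr(no_decoys) == 0.0
    all_decoy = psm_factory([{"is_decoy": True}])
    assert estimate_glyco_fdr(all_decoy) is None


@pytest.mark.parametrize(
    "peptide,pos,context,expected",
    [
        ("TNSSF", 2, "", True),     # N-S-S
        ("TNPTF", 2, "", False),    # X = P
        ("TNSTF", 2, "", True),
        ("TNSAF", 2, "", False),    # third residue not S/T
        ("GGN", 3, "", False),      # terminal N, no context
        ("GGN", 3, "AT", True),     # context completes N-A-T
        ("GGN", 3, "PT", False),
        ("GGNA", 3, "T", True),
    ],
)
def test_validate_sequon(peptide, pos, context, expected):
    assert validate_sequon(peptide, pos, context) is expected


def test_validate_sequon_errors():
    with pytest.raises(ValueError):
        validate_sequon("TNSS", 9)
    with pytest.raises(ValueError, match="expected 'N'"):
        validate_sequon("TNSS", 1)


def test_sequon_step_in_cascade(psm_factory):
    rows = [
        {"peptide": "TNSSF", "glycosite_position": 2},
        {"peptide": "TNPSF", "glycosite_position": 2},  # N-P-S fails
        {"peptide": "AAAAA", "glycan": "", "n_glycosites": 0,
         "glycosite_position": None},                    # non-glyco passes
    ]
    df = compute_qvalues(psm_factory(rows + [{"is_decoy": True,
                                              "two_d_score": -9.0}]))
    report = apply_filter_cascade(df, FilterConfig(require_sequon=True))
    assert report.removed("sequon") == 1
    assert set(report.survivors["peptide"]) == {"TNSSF", "AAAAA"}


def test_fdr_calibration_on_null_decoys(psm_factory):
    """With decoy scores drawn from the null distribution, realized FDP at
    q <= 0.01 averages <= 0.02 over repeated tables."""
    rng = np.random.default_rng(17)
    fdps = []
    for _ in range(100):
        true = [{"two_d_score": float(rng.normal(4, 1))} for _ in range(150)]
        false = [{"two_d_score": float(rng.normal(0, 1))} for _ in range(50)]
        decoy = [{"two_d_score": float(rng.normal(0, 1)), "is_decoy": True}
                 for _ in range(50)]
        df = psm_factory(true + false + decoy)
        labels = np.array([True] * 150 + [False] * 50 + [False] * 50)
        q = compute_qvalues(df)
        accepted = (q["q_value"] <= 0.01).to_numpy() & ~q["is_decoy"].to_numpy()
        n_acc = accepted.sum()
        fdps.append(((accepted & ~labels).sum() / n_acc) if n_acc else 0.0)
    assert np.mean(fdps) <= 0.02


def test_build_focused_database():
    fasta = {
        "P1": "MKTNSTGGAAAKR",       # deamidated N in N-S-T sequon
        "P2": "MKGNPSGGAAAKR",       # N-P-S: fails
        "P3": "MKAAAGGAAAKR",
    }
    psms = pd.DataFrame(
        [
            {"protein_accession": "P1", "peptide": "TNSTGGAAAK",
             "deamidated_positions": "2"},
            {"protein_accession": "P2", "peptide": "GNPSGGAAAK",
             "deamidated_positions": "2"},
            {"protein_accession": "P3", "peptide": "AAAGGAAAK",
             "deamidated_positions": ""},
            {"protein_accession": "MISSING", "peptide": "TNSTK",
             "deamidated_positions": "2"},
        ]
    )
    with pytest.warns(UserWarning, match="MISSING"):
        db = build_focused_database(psms, fasta)
    assert set(db) == {"P1"}
    assert build_focused_database(psms.iloc[0:0], fasta) == {}
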