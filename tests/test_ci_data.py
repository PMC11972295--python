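"""CI-matrix data model: parsing, masking, I/O, counting, cohort filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from organotrope.ci_data import (
    ACROCENTRIC_SHORT,
    CIEvent,
    CIMatrix,
    CIMatrixParseError,
    CohortTable,
    DEFAULT_MASK,
    call_arm_events,
    parse_event,
    read_ci_matrix,
    read_cytoband,
    read_seg,
    select_one_met_per_patient,
    summarize_ci,
)


def make_matrix(samples, labels, values):
    return CIMatrix(samples, [parse_event(l) for l in labels],
                    np.asarray(values))


def make_meta(rows):
    return CohortTable(
        pd.DataFrame(rows, columns=["sample", "patient", "site", "timing"])
    )


# ---------------------------------------------------------------------------
# event parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "label, chrom, arm, direction, bands, amp",
    [
        ("+7p", "7", "p", "gain", None, False),
        ("-18q", "18", "q", "loss", None, False),
        ("+12p amp", "12", "p", "gain", None, True),
        ("+8q23-q24", "8", "q", "gain", "23-q24", False),
        ("-1p32", "1", "p", "loss", "32", False),
        ("+Xq", "X", "q", "gain", None, False),
    ],
)
def test_event_parse_roundtrip(label, chrom, arm, direction, bands, amp):
    ev = parse_event(label)
    assert (ev.chromosome, ev.arm, ev.direction) == (chrom, arm, direction)
    assert ev.band_interval == bands
    assert ev.high_level is amp
    assert ev.canonical() == label


@pytest.mark.parametrize("label", ["7p", "+23q", "gain7p", "+7r", "-18q amp"])
def test_event_parse_rejects_malformed(label):
    with pytest.raises((CIMatrixParseError, ValueError)):
        parse_event(label)


# ---------------------------------------------------------------------------
# exclusion mask
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "label, excluded",
    [
        ("-13p", True),       # acrocentric short arm
        ("-14p", True),
        ("-1p32", True),      # 1p32 -> pter region
        ("-1p36", True),
        ("-1p21", False),     # proximal 1p band is fine
        ("-1p", False),       # whole-arm 1p events are reported in cohorts
        ("-1q12", True),      # heterochromatic block
        ("-9q12", True),
        ("-9q22", False),
        ("+8q24-qter", True),  # telomeric
        ("+7p", False),
        ("-18q", False),
    ],
)
def test_default_mask_rules(label, excluded):
    assert DEFAULT_MASK.excludes(parse_event(label)) is excluded


def test_mask_application_is_idempotent():
    m = make_matrix(["S1"], ["+7p", "-18q", "-13p"], [[1, 1, 1]])
    once = m.apply_mask(DEFAULT_MASK)
    twice = once.apply_mask(DEFAULT_MASK)
    assert once.event_labels == twice.event_labels == ["+7p", "-18q"]
    assert np.array_equal(once.values, twice.values)


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------


def test_read_ci_matrix_direct_roundtrip(tmp_path):
    path = tmp_path / "ci.tsv"
    path.write_text("sample\t+13q\t-18q\nS1\t1\t1\nS2\t0\t1\n")
    m = read_ci_matrix(path)
    assert m.samples == ["S1", "S2"]
    assert m.event_labels == ["+13q", "-18q"]
    assert np.array_equal(m.values, [[1, 1], [0, 1]])


def test_write_read_roundtrip_canonical_dialect(tmp_path):
    m = make_matrix(["S1", "S2"], ["+13q", "-18q", "+12p"],
                    [[1, 1, 2], [0, 1, 0]])
    path = tmp_path / "ci.tsv"
    m.write(path)
    back = read_ci_matrix(path)
    assert back.event_labels == m.event_labels
    assert np.array_equal(back.values, m.values)
    # raw file uses the signed dialect for losses
    assert "\t-1" in path.read_text()


def test_read_drops_masked_event_with_warning(tmp_path, caplog):
    path = tmp_path / "ci.tsv"
    path.write_text("sample\t+7p\t-1p32\nS1\t1\t1\n")
    with caplog.at_level("WARNING", logger="organotrope.ci_data"):
        m = read_ci_matrix(path)
    assert m.event_labels == ["+7p"]
    assert sum("masked" in r.message for r in caplog.records) == 1


def test_read_rejects_out_of_alphabet_code(tmp_path):
    path = tmp_path / "ci.tsv"
    path.write_text("sample\t+13q\nS1\t3\n")
    with pytest.raises(CIMatrixParseError, match=r"S1.*\+13q|\+13q.*S1"):
        read_ci_matrix(path)


def test_read_rejects_duplicate_sample(tmp_path):
    path = tmp_path / "ci.tsv"
    path.write_text("sample\t+13q\nS1\t1\nS1\t0\n")
    with pytest.raises(CIMatrixParseError, match="duplicate"):
        read_ci_matrix(path)


def test_read_splits_unsigned_arm_columns(tmp_path):
    path = tmp_path / "ci.tsv"
    path.write_text("sample\t13q\nS1\t1\nS2\t-1\nS3\t0\n")
    m = read_ci_matrix(path)
    assert set(m.event_labels) == {"+13q", "-13q"}
    frame = m.to_frame()
    assert frame.loc["S1", "+13q"] == 1 and frame.loc["S1", "-13q"] == 0
    assert frame.loc["S2", "-13q"] == 1 and frame.loc["S2", "+13q"] == 0


def test_gain_column_rejects_negative_code(tmp_path):
    path = tmp_path / "ci.tsv"
    path.write_text("sample\t+13q\nS1\t-1\n")
    with pytest.raises(CIMatrixParseError):
        read_ci_matrix(path)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_summarize_counts_arm_vs_focal():
    m = make_matrix(["S1"], ["+13q", "-18q", "+8q23-q24"], [[1, 1, 1]])
    s = summarize_ci(m).loc["S1"]
    assert s["n_arm_aneuploidies"] == 2
    assert s["n_focal"] == 1
    assert s["n_gains"] == 2
    assert s["n_losses"] == 1
    assert s["n_total"] == 3


def test_summarize_acrocentric_short_arm_not_aneuploidy():
    m = CIMatrix(["S1"], [CIEvent("13", "p", "loss")], np.array([[1]]))
    s = summarize_ci(m).loc["S1"]
    assert s["n_arm_aneuploidies"] == 0
    assert s["n_total"] == 1  # still a CI, bucketed as focal


def test_summarize_empty_sample_and_amp_counts_once():
    m = make_matrix(["S1", "S2"], ["+12p"], [[0], [2]])
    s = summarize_ci(m)
    assert (s.loc["S1"] == 0).all()
    assert s.loc["S2", "n_gains"] == 1
    assert s.loc["S2", "n_total"] == 1


@given(
    st.integers(2, 6).flatmap(
        lambda n_ev: st.lists(
            st.lists(st.sampled_from([0, 0, 0, 1, 1, 2]),
                     min_size=n_ev, max_size=n_ev),
            min_size=1, max_size=8,
        )
    )
)
def test_summarize_conservation(rows):
    """Sum of per-sample totals equals the number of nonzero cells."""
    n_ev = len(rows[0])
    labels = [f"+{c}q" for c in range(2, 2 + n_ev)]
    m = make_matrix([f"S{i}" for i in range(len(rows))], labels, rows)
    s = summarize_ci(m)
    assert s["n_total"].sum() == (np.asarray(rows) > 0).sum()
    assert (s["n_total"] == s["n_gains"] + s["n_losses"]).all()
    assert (s["n_total"] == s["n_arm_aneuploidies"] + s["n_focal"]).all()


# ---------------------------------------------------------------------------
# one-metastasis-per-patient filter
# ---------------------------------------------------------------------------


def _met_fixture():
    m = make_matrix(
        ["P1-li", "P1-br", "P2-li1", "P2-li2", "P3-lu", "P4-pr"],
        ["+7p", "-18q", "+13q", "+20q"],
        [
            [1, 1, 1, 1],  # P1 liver: 4 CIs
            [1, 0, 0, 0],  # P1 brain: 1 CI
            [1, 1, 1, 0],  # P2 liver #1: 3 CIs
            [1, 0, 0, 0],  # P2 liver #2: 1 CI
            [0, 1, 0, 0],  # P3 lung
            [1, 1, 0, 0],  # P4 primary only
        ],
    )
    meta = make_meta(
        [
            ("P1-li", "P1", "liver", "synchronous"),
            ("P1-br", "P1", "brain", "metachronous"),
            ("P2-li1", "P2", "liver", "synchronous"),
            ("P2-li2", "P2", "liver", "synchronous"),
            ("P3-lu", "P3", "lung", "metachronous"),
            ("P4-pr", "P4", "primary", "primary"),
        ]
    )
    return m, meta


def test_one_met_priority_brain_over_liver():
    m, meta = _met_fixture()
    sel = select_one_met_per_patient(m, meta)
    assert sel.table.set_index("patient").loc["P1", "sample"] == "P1-br"


def test_one_met_lowest_ci_within_site():
    m, meta = _met_fixture()
    sel = select_one_met_per_patient(m, meta)
    assert sel.table.set_index("patient").loc["P2", "sample"] == "P2-li2"


def test_one_met_identity_and_primary_only_excluded(caplog):
    m, meta = _met_fixture()
    with caplog.at_level("WARNING", logger="organotrope.ci_data"):
        sel = select_one_met_per_patient(m, meta)
    assert sel.table.set_index("patient").loc["P3", "sample"] == "P3-lu"
    assert "P4" not in set(sel.table["patient"])
    assert any("P4" in r.message for r in caplog.records)
    assert sel.table["patient"].is_unique


def test_one_met_tie_breaks_by_sample_id():
    m = make_matrix(["P1-b", "P1-a"], ["+7p"], [[1], [1]])
    meta = make_meta(
        [("P1-b", "P1", "liver", "synchronous"),
         ("P1-a", "P1", "liver", "synchronous")]
    )
    sel = select_one_met_per_patient(m, meta)
    assert sel.table["sample"].iloc[0] == "P1-a"


def test_cohort_table_site_timing_consistency():
    with pytest.raises(ValueError, match="site=primary iff timing=primary"):
        make_meta([("S1", "P1", "primary", "synchronous")])


# ---------------------------------------------------------------------------
# arm-level calling from segments
# ---------------------------------------------------------------------------


def _seg_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "seg_mean"])


def test_arm_call_whole_arm_gain(cytoband_file):
    arms = read_cytoband(cytoband_file)
    seg = _seg_frame([("T1", "8", 40_000_000, 140_000_000, 0.5)])
    matrix, flags = call_arm_events(seg, arms)
    assert matrix.to_frame().loc["T1", "+8q"] == 1


def test_arm_call_below_coverage_emits_no_call(cytoband_file):
    arms = read_cytoband(cytoband_file)
    seg = _seg_frame([("T1", "8", 40_000_000, 80_000_000, 0.5)])  # 40% of 8q
    matrix, flags = call_arm_events(seg, arms)
    assert "+8q" not in matrix.event_labels
    assert flags["8q"] == "uncovered"


def test_arm_call_weighted_alteration_fraction(cytoband_file):
    """80% of covered length gained at +0.3, 20% neutral -> +1, not +2."""
    arms = read_cytoband(cytoband_file)
    seg = _seg_frame(
        [
            ("T1", "8", 40_000_000, 120_000_000, 0.3),   # 80 Mb gained
            ("T1", "8", 120_000_000, 140_000_000, 0.0),  # 20 Mb neutral
        ]
    )
    matrix, _ = call_arm_events(seg, arms)
    assert matrix.to_frame().loc["T1", "+8q"] == 1


def test_arm_call_high_level_amplification(cytoband_file):
    arms = read_cytoband(cytoband_file)
    seg = _seg_frame([("T1", "8", 40_000_000, 140_000_000, 1.4)])
    matrix, _ = call_arm_events(seg, arms)
    assert matrix.to_frame().loc["T1", "+8q"] == 2


def test_arm_call_monotone_in_alteration_min(cytoband_file, rng):
    """Raising alteration_min never converts a no-call into a call."""
    arms = read_cytoband(cytoband_file)
    for _ in range(20):
        cuts = np.sort(rng.choice(
            np.arange(40_000_000, 140_000_001, 10_000_000), 3, replace=False))
        rows = []
        prev = 40_000_000
        for cut in list(cuts) + [140_000_000]:
            if cut > prev:
                rows.append(("T1", "8", prev, cut,
                             float(rng.choice([-0.5, 0.0, 0.5]))))
                prev = cut
        seg = _seg_frame(rows)
        lo, _ = call_arm_events(seg, arms, alteration_min=0.5)
        hi, _ = call_arm_events(seg, arms, alteration_min=0.8)
        lo_calls = set(lo.event_labels)
        hi_calls = set(hi.event_labels)
        assert hi_calls <= lo_calls


def test_arm_call_rejects_stray_segments(cytoband_file):
    arms = read_cytoband(cytoband_file)
    with pytest.raises(ValueError, match="unknown chromosome"):
        call_arm_events(_seg_frame([("T1", "99", 0, 10, 0.5)]), arms)
    with pytest.raises(ValueError, match="non-positive length"):
        call_arm_events(
            _seg_frame([("T1", "8", 50_000_000, 50_000_000, 0.5)]), arms)


def test_read_seg_converts_to_half_open(tmp_path):
    path = tmp_path / "calls.seg"
    path.write_text(
        "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
        "T1\tchr8\t40000001\t140000000\t500\t0.5\n"
    )
    seg = read_seg(path)
    assert seg.loc[0, "start"] == 40_000_000
    assert seg.loc[0, "end"] == 140_000_000
    assert seg.loc[0, "chrom"] == "8"


def test_read_cytoband_merges_bands(cytoband_file):
    arms = {(a.chromosome, a.arm): a for a in read_cytoband(cytoband_file)}
    assert arms[("8", "q")].start == 40_000_000
    assert arms[("8", "q")].end == 140_000_000
    assert arms[("13", "p")].acrocentric_short
    assert not arms[("8", "q")].acrocentric_short
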