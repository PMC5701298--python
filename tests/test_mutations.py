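import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scith import mutations as mut

SAMPLES = ["A", "B", "C", "D"]


def make_table(rows, caller, samples=SAMPLES, blood=True):
    """rows: list of dicts with chrom,pos,ref,alt,qual,vafs (sample->vaf or None)."""
    out = []
    for r in rows:
        rec = {
            "CHROM": r.get("chrom", "chr1"),
            "POS": r["pos"],
            "REF": r.get("ref", "C"),
            "ALT": r.get("alt", "T"),
            "GENE": r.get("gene", ""),
            "EFFECT": r.get("effect", "nonsynonymous"),
            "QUAL": r.get("qual", 60.0),
            "IS_INDEL": r.get("is_indel", False),
            "CALLER": caller,
        }
        for s in samples:
            rec[s] = r.get("vafs", {}).get(s, np.nan)
        if blood:
            rec["blood"] = r.get("blood", np.nan)
        out.append(rec)
    cols = ["CHROM", "POS", "REF", "ALT", "GENE", "EFFECT", "QUAL", "IS_INDEL", "CALLER"]
    cols += samples + (["blood"] if blood else [])
    return pd.DataFrame(out, columns=cols)


# -------------------------------------------------------------- consensus_calls


def test_consensus_both_callers_one_region():
    rows = [{"pos": 100, "vafs": {"A": 0.3}}]
    calls = mut.consensus_calls(make_table(rows, "a"), make_table(rows, "b"))
    assert calls.presence.loc["chr1:100:C>T"].tolist() == [True, False, False, False]


def test_single_caller_everywhere_excluded():
    rows = [{"pos": 100, "vafs": {"A": 0.3, "B": 0.4}}]
    calls = mut.consensus_calls(make_table(rows, "a"), make_table([], "b"))
    assert len(calls.meta) == 0


def test_pos_zero_rejected():
    rows = [{"pos": 0, "vafs": {"A": 0.3}}]
    with pytest.raises(ValueError, match="1-based"):
        mut.consensus_calls(make_table(rows, "a"), make_table(rows, "b"))


def test_consensus_fuzz_matches_set_intersection_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = 25
        positions = rng.choice(np.arange(100, 100_000, 100), size=n, replace=False)
        rows_a, rows_b = [], []
        truth_a, truth_b = set(), set()
        for pos in positions:
            va = {s: 0.3 for s in SAMPLES if rng.random() < 0.5}
            vb = {s: 0.3 for s in SAMPLES if rng.random() < 0.5}
            if va:
                rows_a.append({"pos": int(pos), "vafs": va})
                truth_a |= {(int(pos), s) for s in va}
            if vb:
                rows_b.append({"pos": int(pos), "vafs": vb})
                truth_b |= {(int(pos), s) for s in vb}
        calls = mut.consensus_calls(make_table(rows_a, "a"), make_table(rows_b, "b"))
        got = {
            (int(calls.meta.loc[k, "POS"]), s)
            for k in calls.presence.index
            for s in SAMPLES
            if calls.presence.loc[k, s]
        }
        assert got == truth_a & truth_b  # brute-force per-(variant, sample) intersection


# -------------------------------------------------------- apply_quality_filters


def consensus_of(rows, **kw):
    return mut.consensus_calls(make_table(rows, "a"), make_table(rows, "b"), **kw)


@pytest.mark.parametrize("qual,kept", [(29.0, False), (30.0, True)])
def test_quality_boundary(qual, kept):
    calls = consensus_of([{"pos": 100, "qual": qual, "vafs": {"A": 0.3}}])
    out = mut.apply_quality_filters(calls)
    assert (len(out.meta) == 1) == kept


@pytest.mark.parametrize("pos2,kept", [(110, False), (115, True)])
def test_spacing_boundary_drops_both(pos2, kept):
    calls = consensus_of(
        [{"pos": 100, "vafs": {"A": 0.3}}, {"pos": pos2, "vafs": {"A": 0.3}}]
    )
    out = mut.apply_quality_filters(calls)
    assert len(out.meta) == (2 if kept else 0)


def test_spacing_only_within_chromosome():
    calls = consensus_of(
        [
            {"pos": 100, "chrom": "chr1", "vafs": {"A": 0.3}},
            {"pos": 105, "chrom": "chr2", "vafs": {"A": 0.3}},
        ]
    )
    assert len(mut.apply_quality_filters(calls).meta) == 2


def test_germline_subtraction():
    calls = consensus_of(
        [
            {"pos": 100, "vafs": {"A": 0.3}, "blood": 0.5},
            {"pos": 200, "vafs": {"A": 0.3}},
        ]
    )
    out = mut.apply_quality_filters(calls)
    assert list(out.meta.index) == ["chr1:200:C>T"]


def test_missing_blood_rejected():
    a = make_table([{"pos": 100, "vafs": {"A": 0.3}}], "a", blood=False)
    b = make_table([{"pos": 100, "vafs": {"A": 0.3}}], "b", blood=False)
    calls = mut.consensus_calls(a, b)
    with pytest.raises(ValueError, match="blood"):
        mut.apply_quality_filters(calls)


def test_filter_idempotent():
    rng = np.random.default_rng(5)
    rows = [
        {"pos": int(p), "qual": float(rng.integers(20, 70)), "vafs": {"A": 0.3}}
        for p in rng.choice(np.arange(100, 10_000, 7), 50, replace=False)
    ]
    calls = consensus_of(rows)
    once = mut.apply_quality_filters(calls)
    twice = mut.apply_quality_filters(once)
    assert list(once.meta.index) == list(twice.meta.index)


def spacing_oracle(positions_by_chrom, min_spacing=15):
    """O(n^2) all-pairs spacing filter: drop both members of close pairs."""
    dropped = set()
    for chrom, positions in positions_by_chrom.items():
        for p, q in itertools.combinations(positions, 2):
            if abs(p - q) < min_spacing:
                dropped.add((chrom, p))
                dropped.add((chrom, q))
    return dropped


def test_spacing_fuzz_matches_all_pairs_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        rows = []
        by_chrom = {}
        for chrom in ("chr1", "chr2"):
            positions = sorted(
                int(p) for p in rng.choice(np.arange(100, 2000), 40, replace=False)
            )
            by_chrom[chrom] = positions
            rows += [{"pos": p, "chrom": chrom, "vafs": {"A": 0.3}} for p in positions]
        calls = consensus_of(rows)
        out = mut.apply_quality_filters(calls)
        dropped = spacing_oracle(by_chrom)
        expected = {
            (c, p)
            for c, ps in by_chrom.items()
            for p in ps
            if (c, p) not in dropped
        }
        got = {(row["CHROM"], int(row["POS"])) for _, row in out.meta.iterrows()}
        assert got == expected


# ----------------------------------------------------------------- rescue


def two_caller_tables(rows_a, rows_b):
    return mut.consensus_calls(make_table(rows_a, "a"), make_table(rows_b, "b"))


@pytest.mark.parametrize("vaf,rescued", [(0.25, True), (0.20, False)])
def test_rescue_boundary(vaf, rescued):
    rows_a = [{"pos": 100, "vafs": {"A": vaf, "B": 0.4}}]
    rows_b = [{"pos": 100, "vafs": {"B": 0.4}}]
    calls = two_caller_tables(rows_a, rows_b)
    out = mut.rescue_low_vaf(calls)
    assert out.presence.loc["chr1:100:C>T", "A"] == rescued
    assert out.presence.loc["chr1:100:C>T", "B"]


def test_rescue_requires_consensus_somewhere():
    # single-caller everywhere: variant never entered the candidate set
    rows_a = [{"pos": 100, "vafs": {"A": 0.5, "B": 0.5}}]
    calls = two_caller_tables(rows_a, [])
    assert len(calls.meta) == 0


def test_rescue_monotone_in_threshold():
    rng = np.random.default_rng(11)
    rows_a, rows_b = [], []
    for pos in range(100, 4100, 40):
        vafs_a = {s: round(float(rng.uniform(0, 0.5)), 3) for s in SAMPLES if rng.random() < 0.7}
        vafs_b = {s: vafs_a[s] for s in vafs_a if rng.random() < 0.7}
        if vafs_a:
            rows_a.append({"pos": pos, "vafs": vafs_a})
        if vafs_b:
            rows_b.append({"pos": pos, "vafs": vafs_b})
    calls = two_caller_tables(rows_a, rows_b)
    prev = None
    for thr in (0.1, 0.2, 0.3, 0.4):
        total = mut.rescue_low_vaf(calls, thr).presence.to_numpy().sum()
        if prev is not None:
            assert total <= prev
        prev = total


def rescue_oracle(calls, thr=0.2):
    out = calls.presence.copy()
    for v in calls.meta.index:
        if not calls.presence.loc[v].any():
            continue
        for s in calls.samples:
            one_caller = bool(calls.called_a.loc[v, s]) != bool(calls.called_b.loc[v, s])
            if one_caller and calls.vaf.loc[v, s] > thr:
                out.loc[v, s] = True
    return out


def test_rescue_fuzz_matches_rule_replay_oracle():
    rng = np.random.default_rng(13)
    for _ in range(20):
        rows_a, rows_b = [], []
        for pos in range(100, 1700, 40):
            vafs = {s: round(float(rng.uniform(0, 0.5)), 3) for s in SAMPLES}
            sub_a = {s: v for s, v in vafs.items() if rng.random() < 0.6}
            sub_b = {s: v for s, v in vafs.items() if rng.random() < 0.6}
            if sub_a:
                rows_a.append({"pos": pos, "vafs": sub_a})
            if sub_b:
                rows_b.append({"pos": pos, "vafs": sub_b})
        calls = two_caller_tables(rows_a, rows_b)
        got = mut.rescue_low_vaf(calls).presence
        pd.testing.assert_frame_equal(got, rescue_oracle(calls))


# ----------------------------------------------------------------- merge_indels


def test_merge_zero_indels_identity():
    calls = consensus_of([{"pos": 100, "vafs": {"A": 0.3}}])
    out = mut.merge_indels(calls, None)
    assert list(out.meta.index) == list(calls.meta.index)


def test_merge_private_indel():
    calls = consensus_of([{"pos": 100, "vafs": {"A": 0.3}}])
    indels = make_table(
        [{"pos": 500, "ref": "AT", "alt": "A", "is_indel": True, "vafs": {"C": 0.4}}], "a"
    )
    out = mut.merge_indels(calls, indels)
    assert out.presence.loc["chr1:500:AT>A"].tolist() == [False, False, True, False]


def test_merge_duplicate_keeps_max_quality():
    calls = consensus_of([{"pos": 100, "vafs": {"A": 0.3}}])
    indels = make_table(
        [
            {"pos": 500, "ref": "AT", "alt": "A", "is_indel": True, "qual": 40, "vafs": {"C": 0.4}},
            {"pos": 500, "ref": "AT", "alt": "A", "is_indel": True, "qual": 55, "vafs": {"D": 0.4}},
        ],
        "a",
    )
    out = mut.merge_indels(calls, indels)
    assert out.meta.loc["chr1:500:AT>A", "QUAL"] == 55


def test_merge_cardinality_set_oracle():
    rng = np.random.default_rng(17)
    for _ in range(10):
        snv_pos = rng.choice(np.arange(100, 5000, 20), 30, replace=False)
        indel_pos = rng.choice(np.arange(100, 5000, 20), 15, replace=False)
        calls = consensus_of([{"pos": int(p), "vafs": {"A": 0.3}} for p in snv_pos])
        indels = make_table(
            [
                {"pos": int(p), "ref": "AT", "alt": "A", "is_indel": True, "vafs": {"B": 0.3}}
                for p in indel_pos
            ],
            "a",
        )
        out = mut.merge_indels(calls, indels)
        snv_keys = {f"chr1:{p}:C>T" for p in snv_pos}
        indel_keys = {f"chr1:{p}:AT>A" for p in indel_pos}
        assert len(out.meta) == len(snv_keys | indel_keys)


def test_germline_indels_dropped_with_warning():
    calls = consensus_of([{"pos": 100, "vafs": {"A": 0.3}}])
    indels = make_table(
        [{"pos": 500, "ref": "AT", "alt": "A", "is_indel": True, "vafs": {"C": 0.4}, "blood": 0.5}],
        "a",
    )
    with pytest.warns(UserWarning, match="germline"):
        out = mut.merge_indels(calls, indels)
    assert "chr1:500:AT>A" not in out.meta.index


# ---------------------------------------------------------- categorize_mutations


def matrix_from_presence(presence: pd.DataFrame) -> mut.MutationMatrix:
    meta = pd.DataFrame(
        {
            "CHROM": "chr1",
            "POS": np.arange(1, len(presence) + 1) * 100,
            "REF": "C",
            "ALT": "T",
            "GENE": "",
            "EFFECT": "nonsynonymous",
            "QUAL": 60.0,
            "IS_INDEL": False,
        },
        index=presence.index,
    )
    return mut.MutationMatrix(meta, presence, presence.astype(float) * 0.3)


def test_pde11a_style_case_is_shared():
    presence = pd.DataFrame(
        [[False, True, True, True, False]],
        index=["v1"],
        columns=["A", "B", "C", "D", "E"],
    )
    m = matrix_from_presence(presence)
    assert mut.categorize_mutations(m)["v1"] == "shared"


def test_private_single_region():
    presence = pd.DataFrame([[False, False, True, False]], index=["v"], columns=SAMPLES)
    assert mut.categorize_mutations(matrix_from_presence(presence))["v"] == "private"


def test_ubiquitous_all_regions():
    presence = pd.DataFrame([[True] * 4], index=["v"], columns=SAMPLES)
    assert mut.categorize_mutations(matrix_from_presence(presence))["v"] == "ubiquitous"


def test_single_region_degenerate_all_ubiquitous():
    presence = pd.DataFrame([[True], [True]], index=["v1", "v2"], columns=["A"])
    cat = mut.categorize_mutations(matrix_from_presence(presence))
    assert (cat == "ubiquitous").all()


def test_all_false_row_rejected():
    presence = pd.DataFrame([[False] * 4], index=["v"], columns=SAMPLES)
    with pytest.raises(ValueError, match="all-false"):
        mut.categorize_mutations(matrix_from_presence(presence))


def test_categorize_fuzz_matches_count_oracle():
    rng = np.random.default_rng(19)
    for _ in range(25):
        n_regions = int(rng.integers(2, 7))
        cols = [f"R{i}" for i in range(n_regions)]
        rows = rng.random((40, n_regions)) < 0.5
        rows[rows.sum(axis=1) == 0, 0] = True
        presence = pd.DataFrame(rows, index=[f"v{i}" for i in range(40)], columns=cols)
        cat = mut.categorize_mutations(matrix_from_presence(presence))
        for v in presence.index:
            k = int(presence.loc[v].sum())
            expected = "ubiquitous" if k == n_regions else ("private" if k == 1 else "shared")
            assert cat[v] == expected
        # partition property
        assert cat.isin(["ubiquitous", "shared", "private"]).all()


# ------------------------------------------------------------ mutation_spectrum


def test_g_to_a_collapses_to_c_to_t():
    presence = pd.DataFrame([[True] * 4], index=["v"], columns=SAMPLES)
    m = matrix_from_presence(presence)
    m.meta.loc["v", ["REF", "ALT"]] = ["G", "A"]
    spec = mut.mutation_spectrum(m)
    assert spec.loc["A", "C>T"] == 1
    assert spec.loc["A"].sum() == 1


def test_empty_spectrum_all_zero():
    presence = pd.DataFrame(columns=SAMPLES, dtype=bool)
    m = matrix_from_presence(presence)
    spec = mut.mutation_spectrum(m)
    assert (spec.to_numpy() == 0).all()


def test_non_acgt_warned_and_skipped():
    presence = pd.DataFrame([[True] * 4], index=["v"], columns=SAMPLES)
    m = matrix_from_presence(presence)
    m.meta.loc["v", ["REF", "ALT"]] = ["N", "A"]
    with pytest.warns(UserWarning, match="non-ACGT"):
        spec = mut.mutation_spectrum(m)
    assert (spec.to_numpy() == 0).all()


SPECTRUM_LOOKUP = {
    ("C", "A"): "C>A", ("C", "G"): "C>G", ("C", "T"): "C>T",
    ("T", "A"): "T>A", ("T", "C"): "T>C", ("T", "G"): "T>G",
    ("G", "T"): "C>A", ("G", "C"): "C>G", ("G", "A"): "C>T",
    ("A", "T"): "T>A", ("A", "G"): "T>C", ("A", "C"): "T>G",
}


def test_spectrum_fuzz_matches_lookup_oracle():
    rng = np.random.default_rng(23)
    bases = np.array(list("ACGT"))
    for _ in range(6):
        n = 100
        refs = rng.choice(bases, n)
        alts = np.array([rng.choice([b for b in bases if b != r]) for r in refs])
        presence = pd.DataFrame(
            rng.random((n, 4)) < 0.6, index=[f"v{i}" for i in range(n)], columns=SAMPLES
        )
        presence.iloc[presence.sum(axis=1) == 0, 0] = True
        m = matrix_from_presence(presence)
        m.meta["REF"], m.meta["ALT"] = refs, alts
        spec = mut.mutation_spectrum(m)
        for s in SAMPLES:
            expected = {c: 0 for c in mut.SPECTRUM_CLASSES}
            for i in range(n):
                if presence.iloc[i][s]:
                    expected[SPECTRUM_LOOKUP[(refs[i], alts[i])]] += 1
            assert spec.loc[s].to_dict() == expected
        # conservation: class counts sum to SNVs present per group
        assert (spec.sum(axis=1) == presence.sum(axis=0)).all()


# --------------------------------------------------------------- spectrum_test


def test_fisher_diagonal_p_one():
    counts = pd.DataFrame([[1, 0], [0, 1]], index=["g1", "g2"], columns=["C>T", "T>A"])
    _, p = mut.spectrum_test(counts, "fisher", focal_class="C>T", focal_group="g1")
    assert p == pytest.approx(1.0)


def test_chi2_identical_rows():
    counts = pd.DataFrame([[10, 5, 3], [10, 5, 3]], index=["g1", "g2"],
                          columns=["C>A", "C>G", "C>T"])
    stat, p = mut.spectrum_test(counts, "chi2")
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: stats.hypergeom.pmf(x, n, col1, row1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def test_fisher_fuzz_matches_enumeration_oracle():
    rng = np.random.default_rng(29)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 9, 4)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        counts = pd.DataFrame([[a, b], [c, d]], index=["g1", "g2"], columns=["X", "Y"])
        _, p = mut.spectrum_test(counts, "fisher", focal_class="X", focal_group="g1")
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d), abs=1e-10)


def test_negative_counts_rejected():
    counts = pd.DataFrame([[1, -1], [0, 1]], columns=["X", "Y"])
    with pytest.raises(ValueError):
        mut.spectrum_test(counts, "chi2")
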