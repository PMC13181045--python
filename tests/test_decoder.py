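"""Tag-file decoding: parsing, LQ screening, segmentation, time reconstruction."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from divetherm import (
    DiveProfile,
    DiveRejection,
    decode_tag_file,
    filter_fixes,
    parse_tag_file,
    reconstruct_dive_profile,
    segment_dives,
)
from divetherm.decoder import TagFileParseError, coherent_subsequence
from divetherm.synthetic import TAG_FILE_COLUMNS

HEADER = ",".join(TAG_FILE_COLUMNS)
FIX_T = dt.datetime(2021, 6, 1, 12, 0)


def fix_row(lq="0", lat="41.2", lon="17.2", utc=None, tag="T1"):
    utc = (utc or FIX_T).isoformat()
    return f"{tag},FIX,{utc},{lat},{lon},{lq},,,,,,,,,,,,,,,"


def dive_row(pairs, dt_min, tag="T1", sst="20.0", sst_t="60"):
    cells = []
    for d, t in pairs:
        cells += [str(d), str(t)]
    cells += [""] * (12 - len(cells))
    return f"{tag},DIVE,,,,,{sst},{sst_t}," + ",".join(cells) + f",{dt_min}"


def diag_row(tag="T1"):
    return f"{tag},DIAG,,,,,,,,,,,,,,,,,,,"


def write(tmp_path, lines, name="tag.csv"):
    p = tmp_path / name
    p.write_text("\n".join([HEADER] + lines) + "\n")
    return p


PAIRS4 = [(10.0, 18.0), (20.0, 17.0), (20.0, 17.1), (10.0, 18.1)]
PAIRS6 = [(5.0, 19.0), (10.0, 18.5), (15.0, 18.0), (20.0, 17.5), (15.0, 18.1), (10.0, 18.6)]


class TestParse:
    def test_diag_rows_dropped(self, tmp_path):
        lines = [fix_row() for _ in range(3)] + [dive_row(PAIRS4, 30) for _ in range(5)] + [diag_row()] * 2
        records = parse_tag_file(write(tmp_path, lines))
        assert len(records) == 8
        assert all(r.row_type in ("FIX", "DIVE") for r in records)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        assert parse_tag_file(p) == []

    def test_text_in_depth_field_names_line(self, tmp_path):
        bad = dive_row([("abc", 18.0)], 30)
        p = write(tmp_path, [fix_row(), bad])
        with pytest.raises(TagFileParseError, match="line 3"):
            parse_tag_file(p)

    def test_wrong_arity_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(HEADER + "\nT1,FIX,2021-06-01T12:00:00\n")
        with pytest.raises(TagFileParseError, match="line 2"):
            parse_tag_file(p)


class TestFilterFixes:
    def test_only_lq0_kept_by_default(self, tmp_path):
        lines = [
            fix_row(lq="3"), dive_row(PAIRS4, 30),
            fix_row(lq="0"), dive_row(PAIRS4, 30),
            fix_row(lq="B"), dive_row(PAIRS4, 30),
        ]
        records = parse_tag_file(write(tmp_path, lines))
        kept = filter_fixes(records)
        assert [r.row_type for r in kept] == ["FIX", "DIVE"]
        assert kept[0].lq == "0"

    def test_wider_filter_keeps_more(self, tmp_path):
        lines = [fix_row(lq=c) for c in ("3", "0", "B")]
        records = parse_tag_file(write(tmp_path, lines))
        kept = filter_fixes(records, allowed_lq={"0", "1", "2", "3"})
        assert len(kept) == 2

    def test_fix_without_latitude_removed(self, tmp_path):
        records = parse_tag_file(write(tmp_path, [fix_row(lq="0", lat=""), dive_row(PAIRS4, 30)]))
        assert filter_fixes(records) == []

    def test_unknown_lq_symbol_rejected(self, tmp_path):
        records = parse_tag_file(write(tmp_path, [fix_row(lq="Q")]))
        with pytest.raises(ValueError, match="unknown LQ"):
            filter_fixes(records)

    @given(allowed=st.sets(st.sampled_from(["Z", "B", "A", "0", "1", "2", "3"]), min_size=1))
    def test_filter_monotone_in_allowed_set(self, allowed):
        # enlarging the allowed set never decreases the number of kept fixes
        from divetherm.decoder import RawRecord

        records = [
            RawRecord(tag_id="T", row_type="FIX", line_no=i, utc=FIX_T, lat=41.0, lon=17.0, lq=c)
            for i, c in enumerate(("Z", "B", "A", "0", "1", "2", "3"))
        ]
        n_small = len(filter_fixes(records, allowed_lq=allowed))
        n_big = len(filter_fixes(records, allowed_lq=allowed | {"0", "3"}))
        assert n_big >= n_small


class TestSegmentDives:
    def _groups(self, tmp_path, lines):
        return segment_dives(filter_fixes(parse_tag_file(write(tmp_path, lines))))

    def test_contiguous_records_one_dive(self, tmp_path):
        groups = self._groups(tmp_path, [fix_row(), dive_row(PAIRS6, 30), dive_row(PAIRS6, 60)])
        assert len(groups) == 1
        assert len(groups[0].rows) == 2
        profile = reconstruct_dive_profile(groups[0])
        assert isinstance(profile, DiveProfile)
        assert len(profile.samples) == 12

    def test_gap_splits_dives(self, tmp_path):
        groups = self._groups(tmp_path, [fix_row(), dive_row(PAIRS6, 30), dive_row(PAIRS6, 120)])
        assert len(groups) == 2

    def test_single_row_single_dive(self, tmp_path):
        groups = self._groups(tmp_path, [fix_row(), dive_row(PAIRS4, 30)])
        assert len(groups) == 1

    def test_orphan_dive_rows_dropped(self, tmp_path):
        groups = self._groups(tmp_path, [dive_row(PAIRS4, 30), fix_row(), dive_row(PAIRS4, 30)])
        assert len(groups) == 1


class TestReconstruct:
    def test_retroactive_times(self, tmp_path):
        """Fix at 12:00, DTtime 30, 4 pairs → 11:15, 11:20, 11:25, 11:30."""
        groups = segment_dives(filter_fixes(parse_tag_file(write(tmp_path, [fix_row(), dive_row(PAIRS4, 30)]))))
        profile = reconstruct_dive_profile(groups[0])
        times = [t for t, _, _ in profile.samples]
        assert times == [dt.datetime(2021, 6, 1, 11, m) for m in (15, 20, 25, 30)]
        # most recent pair (last slot) carries the time closest to the fix
        assert [d for _, d, _ in profile.samples] == [p[0] for p in PAIRS4]

    def test_truncation_drops_incoherent_sample(self):
        """Merged offsets [−40, −35, −45, −30] keep [−40, −35, −30]."""
        keep = coherent_subsequence([-40, -35, -45, -30])
        assert keep == [0, 1, 3]

    def test_truncation_prefix_variant(self):
        keep = coherent_subsequence([-40, -35, -45, -30], anchor="prefix")
        assert keep == [0, 1, 3]
        assert coherent_subsequence([-30, -45], anchor="prefix") == [0]
        assert coherent_subsequence([-30, -45], anchor="suffix") == [1]

    def test_duplicate_times_truncated(self):
        assert coherent_subsequence([-40, -35, -35, -30]) in ([0, 1, 3], [0, 2, 3])
        times = coherent_subsequence([-40, -35, -35, -30])
        assert len(times) == 3

    def test_zero_depth_samples_discarded(self, tmp_path):
        pairs = [(0.0, 21.0), (3.2, 19.0), (7.5, 18.0), (0.0, 21.5)]
        groups = segment_dives(filter_fixes(parse_tag_file(write(tmp_path, [fix_row(), dive_row(pairs, 30)]))))
        profile = reconstruct_dive_profile(groups[0])
        assert [d for _, d, _ in profile.samples] == [3.2, 7.5]

    def test_missing_depth_rejected_with_reason(self, tmp_path):
        pairs = [(10.0, 18.0), ("", 17.0)]
        groups = segment_dives(filter_fixes(parse_tag_file(write(tmp_path, [fix_row(), dive_row(pairs, 30)]))))
        res = reconstruct_dive_profile(groups[0])
        assert isinstance(res, DiveRejection)
        assert res.reason == "missing_depth"

    def test_missing_dttime_rejected(self, tmp_path):
        groups = segment_dives(filter_fixes(parse_tag_file(write(tmp_path, [fix_row(), dive_row(PAIRS4, "")]))))
        res = reconstruct_dive_profile(groups[0])
        assert isinstance(res, DiveRejection)
        assert res.reason == "missing_time"

    def test_all_surfacing_rejected(self, tmp_path):
        pairs = [(0.0, 21.0), (0.0, 21.1)]
        groups = segment_dives(filter_fixes(parse_tag_file(write(tmp_path, [fix_row(), dive_row(pairs, 30)]))))
        res = reconstruct_dive_profile(groups[0])
        assert isinstance(res, DiveRejection)
        assert res.reason == "empty_after_filtering"

    @given(st.lists(st.integers(-240, 0), min_size=1, max_size=25))
    def test_coherence_invariants(self, offsets):
        keep = coherent_subsequence(offsets)
        vals = [offsets[i] for i in keep]
        assert keep[-1] == len(offsets) - 1  # anchored at the most recent sample
        assert all(b > a for a, b in zip(vals, vals[1:]))  # strictly increasing
        assert keep == sorted(keep)  # a subsequence


class TestFileAccounting:
    def test_conservation_per_file(self, tmp_path):
        lines = [
            fix_row(lq="0"), dive_row(PAIRS6, 30), dive_row(PAIRS6, 120),  # 2 dives
            diag_row(),
            fix_row(lq="3"), dive_row(PAIRS4, 30),  # dropped by LQ filter
            fix_row(lq="0"), dive_row([(0.0, 21.0)], 30),  # rejected: all surfacing
        ]
        res = decode_tag_file(write(tmp_path, lines))
        c = res.counts
        assert c["n_dive_groups"] == c["n_profiles"] + c["n_rejected"]
        assert c["n_profiles"] == 2
        assert c["n_rejected"] == 1
        assert c["n_diag_dropped"] == 1
        assert c["rejection_reasons"] == {"empty_after_filtering": 1}

    def test_every_profile_satisfies_invariants(self, clean_dives, tmp_path):
        from divetherm import encode_tag_file

        p = tmp_path / "all.csv"
        encode_tag_file(clean_dives, p)
        res = decode_tag_file(p, allowed_lq=set("ZBA0123"))
        assert res.profiles
        for prof in res.profiles:
            prof.validate()  # strict monotone times, positive depths
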