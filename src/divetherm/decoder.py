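"""Decode tag CSV files into quality-controlled vertical temperature profiles.

The decoding chain mirrors how transmitted dive records are turned into
profiles: diagnostic rows are discarded, fixes are screened by Argos location
quality (by default only LQ class 0 is retained, the class whose ~1,500 m
precision matches a ~4-km model grid), dive records are grouped into dive
events by temporal contiguity, sample times are reconstructed retroactively
from each record's DTtime by stepping back in 5-min intervals from the
transmission time, temporally incoherent samples are truncated away, and
surfacing samples (exactly 0 m, where the sensor may read air temperature)
are dropped. Structurally deficient dives are rejected with a reason code and
counted so that ``n_dive_groups == n_profiles + n_rejected`` holds per file.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .params import LQ_CLASSES, SAMPLE_INTERVAL_MIN

logger = logging.getLogger(__name__)


class TagFileParseError(ValueError):
    """Malformed row in a tag CSV file; message names the line number."""


@dataclass
class RawRecord:
    """One parsed FIX or DIVE row."""

    tag_id: str
    row_type: str  # "FIX" or "DIVE"
    line_no: int
    utc: dt.datetime | None = None
    lat: float | None = None
    lon: float | None = None
    lq: str | None = None
    sst: float | None = None
    sst_time_min: float | None = None
    pairs: list[tuple[float | None, float | None]] = field(default_factory=list)
    dt_time_min: float | None = None


@dataclass
class DiveProfile:
    """Reconstructed chronological profile of one dive event."""

    tag_id: str
    dive_id: str
    fix_utc: dt.datetime
    lat: float
    lon: float
    lq: str
    samples: list[tuple[dt.datetime, float, float]]  # (utc, depth m, temp °C)
    sst: float | None = None
    sst_time_min: float | None = None

    @property
    def mid_time(self) -> dt.datetime:
        t0, t1 = self.samples[0][0], self.samples[-1][0]
        return t0 + (t1 - t0) / 2

    def validate(self) -> None:
        times = [t for t, _, _ in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times not strictly increasing")
        if any(d <= 0 for _, d, _ in self.samples):
            raise ValueError("non-positive sample depth")


@dataclass
class DiveRejection:
    tag_id: str
    dive_id: str
    reason: str


@dataclass
class DecodeResult:
    profiles: list[DiveProfile]
    rejections: list[DiveRejection]
    counts: dict


def _num(s: str, what: str, line_no: int) -> float | None:
    s = s.strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise TagFileParseError(f"line {line_no}: unparseable {what}: {s!r}") from None


def parse_tag_file(path) -> list[RawRecord]:
    """Parse one tag CSV file, dropping DIAG rows; file order preserved.

    Raises :class:`TagFileParseError` naming the line for rows with wrong
    arity or unparseable numbers/dates.
    """
    records: list[RawRecord] = []
    n_diag = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            logger.warning("empty tag file %s", path)
            return []
        n_cols = len(header)
        for line_no, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != n_cols:
                raise TagFileParseError(f"line {line_no}: expected {n_cols} fields, got {len(row)}")
            tag_id, row_type = row[0].strip(), row[1].strip().upper()
            if row_type == "DIAG":
                n_diag += 1
                continue
            if row_type not in ("FIX", "DIVE"):
                raise TagFileParseError(f"line {line_no}: unknown row_type {row[1]!r}")
            rec = RawRecord(tag_id=tag_id, row_type=row_type, line_no=line_no)
            if row_type == "FIX":
                utc = row[2].strip()
                if utc:
                    try:
                        rec.utc = dt.datetime.fromisoformat(utc)
                    except ValueError:
                        raise TagFileParseError(f"line {line_no}: unparseable UTC time: {utc!r}") from None
                rec.lat = _num(row[3], "latitude", line_no)
                rec.lon = _num(row[4], "longitude", line_no)
                rec.lq = row[5].strip() or None
            else:
                rec.sst = _num(row[6], "SST", line_no)
                rec.sst_time_min = _num(row[7], "SSTtime", line_no)
                pairs = []
                for i in range(6):
                    d = _num(row[8 + 2 * i], "depth", line_no)
                    t = _num(row[9 + 2 * i], "temperature", line_no)
                    if d is None and t is None:
                        continue
                    pairs.append((d, t))
                if not pairs:
                    raise TagFileParseError(f"line {line_no}: DIVE row with no depth-temperature pairs")
                rec.pairs = pairs
                rec.dt_time_min = _num(row[20], "DTtime", line_no)
            records.append(rec)
    if not records:
        logger.warning("tag file %s contains no FIX/DIVE rows", path)
    if n_diag:
        logger.info("%s: dropped %d diagnostic rows", path, n_diag)
    parse_tag_file._last_diag_count = n_diag  # inspected by decode_tag_file
    return records


def filter_fixes(records: list[RawRecord], allowed_lq: set[str] = frozenset({"0"})) -> list[RawRecord]:
    """Keep only fixes with valid coordinates and an allowed LQ class, plus the
    DIVE rows attributed to them (rows following a fix up to the next fix).

    Raises ``ValueError`` on an LQ symbol outside {Z, B, A, 0, 1, 2, 3}.
    """
    for lq in allowed_lq:
        if lq not in LQ_CLASSES:
            raise ValueError(f"unknown LQ class in filter: {lq!r}")
    out: list[RawRecord] = []
    keep_current = False
    seen_fix = False
    for rec in records:
        if rec.row_type == "FIX":
            seen_fix = True
            if rec.lq is not None and rec.lq not in LQ_CLASSES:
                raise ValueError(f"line {rec.line_no}: unknown LQ symbol {rec.lq!r}")
            valid = rec.lat is not None and rec.lon is not None and rec.lq is not None and rec.utc is not None
            keep_current = valid and rec.lq in allowed_lq
            if keep_current:
                out.append(rec)
        elif keep_current or not seen_fix:
            # rows before any FIX stay for segment_dives to drop loudly;
            # rows under a rejected FIX are removed together with it
            out.append(rec)
    return out


@dataclass
class DiveGroup:
    fix: RawRecord
    rows: list[RawRecord]  # file order: most recent record first


def _record_span(rec: RawRecord) -> tuple[float, float] | None:
    """(start, end) of a record in minutes before the fix (start ≥ end)."""
    if rec.dt_time_min is None:
        return None
    n = len(rec.pairs)
    return (rec.dt_time_min + SAMPLE_INTERVAL_MIN * (n - 1), rec.dt_time_min)


def segment_dives(records: list[RawRecord]) -> list[DiveGroup]:
    """Group DIVE rows under their governing FIX and split them into dive
    events wherever consecutive records are not temporally contiguous.

    Records of one dive abut on the 5-min lattice: with rows ordered most
    recent first, the next (older) record's DTtime must equal the current
    record's DTtime + 5·(its number of pairs); a gap beyond one sample
    interval starts a new dive. Overlaps/inversions are kept within the dive
    for the truncation rule to resolve. DIVE rows with no preceding FIX are
    dropped with a warning.
    """
    groups: list[DiveGroup] = []
    fix: RawRecord | None = None
    current: list[RawRecord] = []
    n_orphans = 0

    def flush():
        nonlocal current
        if fix is not None and current:
            groups.append(DiveGroup(fix=fix, rows=current))
        current = []

    for rec in records:
        if rec.row_type == "FIX":
            flush()
            fix = rec
            continue
        if fix is None:
            n_orphans += 1
            continue
        if current:
            prev = current[-1]
            prev_span = _record_span(prev)
            this_span = _record_span(rec)
            if prev_span is not None and this_span is not None:
                gap = this_span[1] - prev_span[0]  # older end minus newer start
                if gap > SAMPLE_INTERVAL_MIN:
                    flush()
        current.append(rec)
    flush()
    if n_orphans:
        logger.warning("dropped %d DIVE rows with no preceding FIX", n_orphans)
    segment_dives._last_orphan_count = n_orphans
    return groups


def coherent_subsequence(times: list, anchor: str = "suffix") -> list[int]:
    """Indices of the longest strictly increasing subsequence of ``times``
    anchored at the most recent sample (``anchor="suffix"``, the last element)
    or at the earliest (``anchor="prefix"``, the first element).

    This is the temporal-coherence truncation rule: samples breaking strict
    monotonicity (including duplicated timestamps) are discarded, keeping as
    much of the record nearest the anchor as possible. Ties between equally
    long subsequences prefer later (more recently acquired) samples.
    """
    n = len(times)
    if n == 0:
        return []
    if anchor == "prefix":
        rev = [-_t_key(t) for t in reversed(times)]
        idx = coherent_subsequence(rev, anchor="suffix")
        return sorted(n - 1 - i for i in idx)
    if anchor != "suffix":
        raise ValueError("anchor must be 'suffix' or 'prefix'")
    keys = [_t_key(t) for t in times]
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            # >= prefers the later predecessor on equal-length ties
            if keys[j] < keys[i] and best_len[j] + 1 >= best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    out = []
    i = n - 1
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def _t_key(t):
    if isinstance(t, dt.datetime):
        return t.timestamp()
    return float(t)


def reconstruct_dive_profile(group: DiveGroup, truncate: str = "suffix") -> DiveProfile | DiveRejection:
    """Rebuild one dive's chronological (time, depth, temperature) samples.

    Within each record the most recent pair is the last populated slot; its
    acquisition time is ``fix_utc − DTtime`` and earlier pairs step back in
    5-min intervals. Records are merged oldest-first, the temporal-coherence
    truncation applied, and 0-m surfacing samples discarded. Structural
    deficiencies return a :class:`DiveRejection` with a reason code instead of
    raising.
    """
    fix = group.fix
    dive_id = f"{fix.utc.isoformat()}#{group.rows[0].line_no}"
    if not group.rows:
        return DiveRejection(fix.tag_id, dive_id, "no_records")
    samples: list[tuple[dt.datetime, float, float]] = []
    for rec in reversed(group.rows):  # oldest record first → chronological
        if rec.dt_time_min is None:
            return DiveRejection(fix.tag_id, dive_id, "missing_time")
        n = len(rec.pairs)
        for j, (depth, temp) in enumerate(rec.pairs):
            if depth is None:
                return DiveRejection(fix.tag_id, dive_id, "missing_depth")
            if temp is None:
                return DiveRejection(fix.tag_id, dive_id, "missing_temperature")
            ts = fix.utc - dt.timedelta(minutes=rec.dt_time_min + SAMPLE_INTERVAL_MIN * (n - 1 - j))
            samples.append((ts, depth, temp))
    if not samples:
        return DiveRejection(fix.tag_id, dive_id, "no_samples")

    keep = coherent_subsequence([s[0] for s in samples], anchor=truncate)
    if len(keep) < len(samples):
        logger.debug("dive %s: truncated %d temporally incoherent samples", dive_id, len(samples) - len(keep))
    samples = [samples[i] for i in keep]
    samples = [s for s in samples if s[1] != 0.0]  # discard surfacing samples
    if not samples:
        return DiveRejection(fix.tag_id, dive_id, "empty_after_filtering")
    if any(s[1] < 0 for s in samples):
        return DiveRejection(fix.tag_id, dive_id, "negative_depth")

    profile = DiveProfile(
        tag_id=fix.tag_id,
        dive_id=dive_id,
        fix_utc=fix.utc,
        lat=fix.lat,
        lon=fix.lon,
        lq=fix.lq,
        samples=samples,
        sst=group.rows[0].sst,
        sst_time_min=group.rows[0].sst_time_min,
    )
    profile.validate()
    return profile


def decode_tag_file(path, allowed_lq: set[str] = frozenset({"0"}), truncate: str = "suffix") -> DecodeResult:
    """Full decoding chain for one tag file, with per-stage accounting."""
    records = parse_tag_file(path)
    n_diag = getattr(parse_tag_file, "_last_diag_count", 0)
    filtered = filter_fixes(records, allowed_lq=allowed_lq)
    groups = segment_dives(filtered)
    n_orphans = getattr(segment_dives, "_last_orphan_count", 0)
    profiles: list[DiveProfile] = []
    rejections: list[DiveRejection] = []
    for g in groups:
        res = reconstruct_dive_profile(g, truncate=truncate)
        if isinstance(res, DiveProfile):
            profiles.append(res)
        else:
            rejections.append(res)
    counts = {
        "path": str(path),
        "n_records": len(records),
        "n_diag_dropped": n_diag,
        "n_fix_parsed": sum(r.row_type == "FIX" for r in records),
        "n_fix_kept": sum(r.row_type == "FIX" for r in filtered),
        "n_dive_rows_parsed": sum(r.row_type == "DIVE" for r in records),
        "n_dive_rows_kept": sum(r.row_type == "DIVE" for r in filtered),
        "n_orphan_dive_rows": n_orphans,
        "n_dive_groups": len(groups),
        "n_profiles": len(profiles),
        "n_rejected": len(rejections),
        "rejection_reasons": dict(Counter(r.reason for r in rejections)),
    }
    assert counts["n_dive_groups"] == counts["n_profiles"] + counts["n_rejected"]
    return DecodeResult(profiles=profiles, rejections=rejections, counts=counts)


def decode_directory(tags_dir, allowed_lq: set[str] = frozenset({"0"}), truncate: str = "suffix") -> DecodeResult:
    """Decode every ``*.csv`` under ``tags_dir`` and pool the results."""
    profiles, rejections, per_file = [], [], []
    for p in sorted(Path(tags_dir).glob("*.csv")):
        res = decode_tag_file(p, allowed_lq=allowed_lq, truncate=truncate)
        profiles += res.profiles
        rejections += res.rejections
        per_file.append(res.counts)
    totals = {
        k: sum(c[k] for c in per_file)
        for k in ("n_records", "n_diag_dropped", "n_dive_groups", "n_profiles", "n_rejected")
    }
    totals["files"] = per_file
    return DecodeResult(profiles=profiles, rejections=rejections, counts=totals)


def profiles_to_frame(profiles: list[DiveProfile]) -> pd.DataFrame:
    """Long table, one row per sample: the decoder's interchange output."""
    rows = []
    for p in profiles:
        for ts, depth, temp in p.samples:
            rows.append((p.tag_id, p.dive_id, ts.isoformat(), p.lat, p.lon, p.lq, depth, temp))
    return pd.DataFrame(rows, columns=["tag_id", "dive_id", "utc", "lat", "lon", "lq", "depth_m", "temp_c"])
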