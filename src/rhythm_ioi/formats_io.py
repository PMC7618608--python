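"""Readers and writers for every external representation the pipeline touches.

* Praat TextGrid interval tiers — both the "long" (named fields) and the
  "short" (bare values) text dialects, in UTF-8 or UTF-16 (Praat writes
  either, with a BOM for UTF-16);
* delimited element tables (CSV/TSV) with configurable column names;
* WAV audio (integer PCM or float, any sample rate) via scipy;
* the analysis results document: a JSON file holding every scalar and array
  of a :class:`~rhythm_ioi.inference.RhythmTestResult`, with companion flat
  CSV tables of the grid-wise arrays and the peak list.

Class labels are opaque case-sensitive strings throughout; an absent label
maps to the sentinel class ``"unlabeled"``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import FormatError, TierNotFoundError, ValidationError
from .inference import (DeviationProfile, InferenceConfig, PeakCall,
                        RhythmTestResult)
from .sequence_model import UNLABELED, AnnotationSet, ElementRecord

__all__ = [
    "read_textgrid",
    "write_textgrid",
    "read_element_table",
    "write_element_table",
    "read_wav",
    "write_wav",
    "write_results",
    "read_results",
]


# --------------------------------------------------------------------- #
# TextGrid
# --------------------------------------------------------------------- #
def _decode_textgrid(path: Path) -> str:
    raw = path.read_bytes()
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    if raw.startswith(b"\xef\xbb\xbf"):
        return raw.decode("utf-8-sig")
    return raw.decode("utf-8")


def _tokenize_textgrid(text: str) -> list[str]:
    """Reduce both TextGrid dialects to a flat stream of value tokens.

    Long-format lines carry ``name = value`` pairs (or structural headers
    like ``item [1]:``); short-format lines are bare values.  Quoted strings
    may span lines and escape embedded quotes by doubling them.
    """
    tokens: list[str] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.startswith("File type") or line.startswith("Object class"):
            continue
        if "=" in line and not line.startswith('"'):
            value = line.split("=", 1)[1].strip()
        elif line.startswith("tiers?"):
            value = line.split("?", 1)[1].strip()
        else:
            # structural header: item []: / item [1]: / intervals [1]:
            if line.endswith(":") and "[" in line and "=" not in line:
                continue
            value = line
        if value.startswith('"'):
            # re-join if the quoted string continues on following lines
            while not _closed_quote(value) and i < len(lines):
                value += "\n" + lines[i]
                i += 1
            value = value.strip()
            tokens.append('"' + value[1:-1].replace('""', '"') + '"')
        elif value:
            tokens.append(value)
    return tokens


def _closed_quote(s: str) -> bool:
    return len(s) >= 2 and s.count('"') % 2 == 0


class _TokenStream:
    def __init__(self, tokens: list[str]):
        self._tokens = tokens
        self._pos = 0

    def next(self) -> str:
        if self._pos >= len(self._tokens):
            raise FormatError("truncated TextGrid file")
        tok = self._tokens[self._pos]
        self._pos += 1
        return tok

    def next_float(self) -> float:
        tok = self.next()
        try:
            return float(tok)
        except ValueError:
            raise FormatError(f"expected a number, got {tok!r}") from None

    def next_int(self) -> int:
        return int(self.next_float())

    def next_str(self) -> str:
        tok = self.next()
        if tok.startswith('"') and tok.endswith('"'):
            return tok[1:-1]
        return tok


def _parse_textgrid(text: str) -> list[dict]:
    """All tiers of a TextGrid as dicts with name/class/entries."""
    if "ooTextFile" not in text.split("\n", 1)[0] and \
            "ooTextFile" not in text[:200]:
        raise FormatError("not a Praat TextGrid (missing ooTextFile header)")
    stream = _TokenStream(_tokenize_textgrid(text))
    stream.next_float()  # global xmin
    stream.next_float()  # global xmax
    has_tiers = stream.next()
    if "exists" not in has_tiers:
        return []
    n_tiers = stream.next_int()
    tiers = []
    for _ in range(n_tiers):
        tier_class = stream.next_str()
        name = stream.next_str()
        stream.next_float()  # tier xmin
        stream.next_float()  # tier xmax
        size = stream.next_int()
        entries = []
        if tier_class == "IntervalTier":
            for _ in range(size):
                xmin = stream.next_float()
                xmax = stream.next_float()
                label = stream.next_str()
                entries.append((xmin, xmax, label))
        elif tier_class == "TextTier":
            for _ in range(size):
                t = stream.next_float()
                mark = stream.next_str()
                entries.append((t, mark))
        else:
            raise FormatError(f"unknown tier class {tier_class!r}")
        tiers.append({"class": tier_class, "name": name, "entries": entries})
    return tiers


def read_textgrid(path, tier: str, individual: str,
                  recording: str | None = None) -> AnnotationSet:
    """Element records from one interval tier of a Praat TextGrid.

    Every non-empty interval becomes an :class:`ElementRecord` whose class
    label is the interval label; empty-label intervals are silence and are
    skipped.  Both text dialects and UTF-8/UTF-16 encodings are accepted.
    """
    path = Path(path)
    recording = recording if recording is not None else path.stem
    tiers = {t["name"]: t for t in _parse_textgrid(_decode_textgrid(path))}
    if tier not in tiers:
        raise TierNotFoundError(
            f"tier {tier!r} not in {sorted(tiers)} of {path.name}")
    selected = tiers[tier]
    if selected["class"] != "IntervalTier":
        raise FormatError(
            f"tier {tier!r} of {path.name} is a point tier, "
            f"not an interval tier")
    records = [
        ElementRecord(recording=recording, individual=individual,
                      onset=xmin, offset=xmax, element_class=label)
        for xmin, xmax, label in selected["entries"] if label != ""
    ]
    return AnnotationSet(records, provenance={"source": str(path),
                                              "tier": tier})


def write_textgrid(annotations: AnnotationSet, path, tier: str = "elements",
                   xmin: float = 0.0, xmax: float | None = None,
                   dialect: str = "long") -> None:
    """Write one recording's elements as a Praat TextGrid interval tier.

    Gaps between elements become empty-label intervals so the tier tiles
    ``[xmin, xmax]`` completely, as Praat requires.
    """
    if len(annotations.recordings) > 1:
        raise ValidationError("write_textgrid expects a single recording")
    if dialect not in ("long", "short"):
        raise FormatError(f"unknown TextGrid dialect {dialect!r}")
    records = annotations.records
    if xmax is None:
        xmax = (records[-1].offset if records else xmin) + 1e-3
    intervals: list[tuple[float, float, str]] = []
    cursor = xmin
    for rec in records:
        if rec.onset > cursor:
            intervals.append((cursor, rec.onset, ""))
        intervals.append((rec.onset, rec.offset, rec.element_class))
        cursor = rec.offset
    if xmax > cursor:
        intervals.append((cursor, xmax, ""))
    if not intervals:
        intervals.append((xmin, xmax, ""))

    def q(label: str) -> str:
        return '"' + label.replace('"', '""') + '"'

    lines = ['File type = "ooTextFile"', 'Object class = "TextGrid"', ""]
    if dialect == "long":
        lines += [f"xmin = {xmin!r}", f"xmax = {xmax!r}", "tiers? <exists>",
                  "size = 1", "item []:", "    item [1]:",
                  '        class = "IntervalTier"', f"        name = {q(tier)}",
                  f"        xmin = {xmin!r}", f"        xmax = {xmax!r}",
                  f"        intervals: size = {len(intervals)}"]
        for i, (a, b, label) in enumerate(intervals, start=1):
            lines += [f"        intervals [{i}]:", f"            xmin = {a!r}",
                      f"            xmax = {b!r}",
                      f"            text = {q(label)}"]
    else:
        lines += [f"{xmin!r}", f"{xmax!r}", "<exists>", "1",
                  '"IntervalTier"', q(tier), f"{xmin!r}", f"{xmax!r}",
                  f"{len(intervals)}"]
        for a, b, label in intervals:
            lines += [f"{a!r}", f"{b!r}", q(label)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------- #
# Element tables
# --------------------------------------------------------------------- #
_DEFAULT_COLUMNS = {"onset": "onset", "offset": "offset", "class": "class",
                    "individual": "individual", "recording": "recording"}


def read_element_table(path, columns: dict | None = None) -> AnnotationSet:
    """Element records from a delimited (CSV/TSV) table.

    The header must name at least onset and offset columns (names are
    configurable via ``columns``); missing class labels map to
    ``"unlabeled"``, a missing recording column to the file stem, and a
    missing individual column to ``"unknown"``.  Rows are re-sorted by
    onset; any row with ``offset <= onset`` raises a validation error that
    lists the offending rows.
    """
    path = Path(path)
    cols = dict(_DEFAULT_COLUMNS)
    cols.update(columns or {})
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for required in ("onset", "offset"):
        if cols[required] not in df.columns:
            raise FormatError(
                f"{path.name}: missing required column {cols[required]!r} "
                f"(have {list(df.columns)})")
    onset = df[cols["onset"]].astype(float)
    offset = df[cols["offset"]].astype(float)
    bad = df.index[~(offset > onset)].tolist()
    if bad:
        raise ValidationError(
            f"{path.name}: offset <= onset in rows {bad[:20]}")
    classes = df[cols["class"]].fillna(UNLABELED).astype(str) \
        if cols["class"] in df.columns else pd.Series([UNLABELED] * len(df))
    individuals = df[cols["individual"]].astype(str) \
        if cols["individual"] in df.columns \
        else pd.Series(["unknown"] * len(df))
    recordings = df[cols["recording"]].astype(str) \
        if cols["recording"] in df.columns \
        else pd.Series([path.stem] * len(df))
    records = [
        ElementRecord(recording=recordings.iloc[i],
                      individual=individuals.iloc[i],
                      onset=float(onset.iloc[i]),
                      offset=float(offset.iloc[i]),
                      element_class=classes.iloc[i])
        for i in range(len(df))
    ]
    return AnnotationSet(records, provenance={"source": str(path)})


def write_element_table(annotations: AnnotationSet, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    annotations.to_dataframe().to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------- #
# WAV audio
# --------------------------------------------------------------------- #
def read_wav(path) -> tuple[np.ndarray, int]:
    """Mono float audio in [-1, 1] plus the sample rate.

    Integer PCM (8/16/24/32 bit) is rescaled to float; multi-channel input
    is averaged down to mono.
    """
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = max(abs(info.min), info.max)
        shift = (info.max + info.min + 1) / 2  # centers unsigned formats
        data = (data.astype(float) - shift) / scale
    else:
        data = data.astype(float)
    return data, int(rate)


def write_wav(path, audio: np.ndarray, rate: int) -> None:
    """Write float audio as 16-bit PCM, clipping to [-1, 1]."""
    x = np.clip(np.asarray(audio, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(rate), (x * 32767.0).astype(np.int16))


# --------------------------------------------------------------------- #
# Results documents
# --------------------------------------------------------------------- #
_RESULT_FORMAT = "rhythm-ioi-result"


def write_results(result: RhythmTestResult, path,
                  manifest: dict | None = None) -> None:
    """Serialize a completed analysis to JSON plus companion CSV tables.

    ``<path>`` receives the full document; ``<stem>_grid.csv`` the grid-wise
    arrays and ``<stem>_peaks.csv`` the peak list.  Identical inputs and
    seed produce byte-identical documents.
    """
    path = Path(path)
    profile = result.profile
    doc = {
        "format": _RESULT_FORMAT,
        "version": 1,
        "seed": result.seed,
        "n_ratios": result.n_ratios,
        "observed_max": result.observed_max,
        "test_statistic": result.test_statistic,
        "significant": result.significant,
        "config": result.config_dict(),
        "grid": profile.grid.tolist(),
        "observed_density": profile.observed_density.tolist(),
        "perm_mean": profile.perm_mean.tolist(),
        "perm_sd": profile.perm_sd.tolist(),
        "deviation": profile.deviation.tolist(),
        "ci_low": profile.ci_low.tolist(),
        "ci_high": profile.ci_high.tolist(),
        "sd_floor_mask": [bool(b) for b in profile.sd_floor_mask],
        "perm_maxima": result.perm_maxima.tolist(),
        "peaks": [
            {"ratio_location": p.ratio_location,
             "deviation_value": p.deviation_value, "sign": p.sign}
            for p in result.peaks
        ],
    }
    if manifest is not None:
        doc["manifest"] = manifest
    path.write_text(json.dumps(doc, indent=1), encoding="utf-8")

    grid_table = pd.DataFrame({
        "grid": profile.grid,
        "observed_density": profile.observed_density,
        "perm_mean": profile.perm_mean,
        "perm_sd": profile.perm_sd,
        "deviation": profile.deviation,
        "ci_low": profile.ci_low,
        "ci_high": profile.ci_high,
        "sd_floor_mask": profile.sd_floor_mask.astype(int),
    })
    grid_table.to_csv(path.with_name(path.stem + "_grid.csv"), index=False)
    peak_table = pd.DataFrame(
        doc["peaks"], columns=["ratio_location", "deviation_value", "sign"])
    peak_table.to_csv(path.with_name(path.stem + "_peaks.csv"), index=False)


def read_results(path) -> RhythmTestResult:
    """Reconstruct a :class:`RhythmTestResult` from its JSON document."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != _RESULT_FORMAT:
        raise FormatError(f"{path}: not a rhythm-ioi results document")
    cfg_dict = dict(doc["config"])
    cfg_dict["ci_quantiles"] = tuple(cfg_dict["ci_quantiles"])
    cfg = InferenceConfig(**cfg_dict)
    profile = DeviationProfile(
        grid=np.array(doc["grid"]),
        observed_density=np.array(doc["observed_density"]),
        perm_mean=np.array(doc["perm_mean"]),
        perm_sd=np.array(doc["perm_sd"]),
        deviation=np.array(doc["deviation"]),
        ci_low=np.array(doc["ci_low"]),
        ci_high=np.array(doc["ci_high"]),
        sd_floor_mask=np.array(doc["sd_floor_mask"], dtype=bool),
    )
    peaks = [PeakCall(p["ratio_location"], p["deviation_value"], p["sign"])
             for p in doc["peaks"]]
    return RhythmTestResult(
        observed_max=doc["observed_max"],
        perm_maxima=np.array(doc["perm_maxima"]),
        test_statistic=doc["test_statistic"],
        significant=doc["significant"],
        profile=profile, peaks=peaks, config=cfg, seed=doc["seed"],
        n_ratios=doc["n_ratios"])
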