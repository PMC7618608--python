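"""Element sequences, bouts, inter-onset intervals and revised IOI-ratios.

A vocalization is represented as a sequence of *elements* (onset/offset
intervals with a class label) grouped into *bouts*: maximal runs of elements
whose inter-element silences stay below a species-specific threshold
(250 ms for budgerigars, 500 ms for the human material).  Inter-onset
intervals (IOIs) and their ratios are defined only within bouts.

The rhythm descriptor used throughout the package is the *revised* IOI-ratio

    r_k = IOI_k / (IOI_k + IOI_{k-1}),

which lies in (0, 1): 0.5 marks isochrony (1:1), values above 0.5 local
deceleration (short-long pair, 2/3 = the 1:2 integer ratio) and values below
0.5 local acceleration (1/3 = the 2:1 integer ratio).  The descriptor used in
earlier literature is its mirror image, ``1 - r_k``, available via
:func:`mirror_ratio` or ``convention="legacy"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ElementRecord",
    "AnnotationSet",
    "Bout",
    "IOIRecord",
    "RatioRecord",
    "RhythmDataset",
    "group_bouts",
    "compute_iois",
    "ioi_ratio",
    "mirror_ratio",
    "build_dataset",
]

#: Class label applied when the annotation source carries no labels.
UNLABELED = "unlabeled"

_TIME_TOL = 1e-12


@dataclass(frozen=True)
class ElementRecord:
    """One segmented vocal element."""

    recording: str
    individual: str
    onset: float
    offset: float
    element_class: str = UNLABELED

    @property
    def duration(self) -> float:
        return self.offset - self.onset


class AnnotationSet:
    """Validated, time-ordered collection of :class:`ElementRecord`.

    Records are sorted by ``(recording, onset)``; within one recording the
    element intervals must be non-overlapping, with ``onset >= 0`` and
    ``offset > onset`` (half-open ``[onset, offset)`` convention).
    """

    def __init__(self, records: Iterable[ElementRecord],
                 provenance: dict | None = None):
        self.records: list[ElementRecord] = sorted(
            records, key=lambda r: (r.recording, r.onset, r.offset))
        self.provenance: dict = dict(provenance or {})
        self._validate()

    def _validate(self) -> None:
        bad: list[int] = []
        for i, r in enumerate(self.records):
            if r.onset < 0 or not r.offset > r.onset:
                bad.append(i)
        if bad:
            raise ValidationError(
                f"invalid element intervals (offset <= onset or onset < 0) "
                f"at sorted rows {bad[:20]}")
        for prev, cur in zip(self.records, self.records[1:]):
            if cur.recording == prev.recording and \
                    cur.onset < prev.offset - _TIME_TOL:
                raise ValidationError(
                    f"overlapping elements in recording {cur.recording!r}: "
                    f"[{prev.onset}, {prev.offset}) and "
                    f"[{cur.onset}, {cur.offset})")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ElementRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationSet) and \
            self.records == other.records

    @property
    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.individual)
        return list(seen)

    @property
    def recordings(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.recording)
        return list(seen)

    def for_individual(self, individual: str) -> "AnnotationSet":
        return AnnotationSet(
            [r for r in self.records if r.individual == individual],
            provenance=self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "recording": [r.recording for r in self.records],
                "individual": [r.individual for r in self.records],
                "onset": [r.onset for r in self.records],
                "offset": [r.offset for r in self.records],
                "class": [r.element_class for r in self.records],
            }
        )


@dataclass(frozen=True)
class Bout:
    """Maximal run of elements with inter-element silences below threshold."""

    bout_id: str
    elements: tuple[ElementRecord, ...]

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class IOIRecord:
    """One inter-onset interval (next onset minus current onset).

    ``pair_label`` is the ordered pair (class of the initiating element,
    class of the terminating element); together with ``individual`` it
    defines the default exchangeability stratum for the permutation null.
    """

    value: float
    bout_id: str
    position: int
    individual: str
    pair_label: tuple[str, str]


@dataclass(frozen=True)
class RatioRecord:
    """One revised IOI-ratio, strictly inside (0, 1)."""

    value: float
    bout_id: str
    position: int
    individual: str
    left_pair: tuple[str, str]
    right_pair: tuple[str, str]


def group_bouts(annotations: AnnotationSet, silence_threshold: float,
                gap_mode: str = "offset_to_onset") -> list[Bout]:
    """Split an annotation set into bouts at silences >= ``silence_threshold``.

    The silence between consecutive elements is measured from the offset of
    one element to the onset of the next (``gap_mode="offset_to_onset"``;
    ``"onset_to_onset"`` uses the IOI itself).  A gap exactly equal to the
    threshold splits — strict less-than keeps elements together.  Bouts never
    span recordings or individuals; singleton bouts are allowed.
    """
    if gap_mode not in ("offset_to_onset", "onset_to_onset"):
        raise ValidationError(f"unknown gap_mode {gap_mode!r}")
    bouts: list[Bout] = []
    groups: dict[tuple[str, str], list[ElementRecord]] = {}
    for rec in annotations:
        groups.setdefault((rec.recording, rec.individual), []).append(rec)
    for (recording, individual), elements in groups.items():
        current: list[ElementRecord] = [elements[0]]
        runs: list[list[ElementRecord]] = [current]
        for prev, cur in zip(elements, elements[1:]):
            ref = prev.offset if gap_mode == "offset_to_onset" else prev.onset
            gap = cur.onset - ref
            if gap < silence_threshold:
                current.append(cur)
            else:
                current = [cur]
                runs.append(current)
        for i, run in enumerate(runs):
            bouts.append(Bout(f"{recording}/{individual}/{i}", tuple(run)))
    return bouts


def compute_iois(bout: Bout) -> list[IOIRecord]:
    """Inter-onset intervals of one bout: n elements yield n - 1 records."""
    records: list[IOIRecord] = []
    for k, (a, b) in enumerate(zip(bout.elements, bout.elements[1:])):
        value = b.onset - a.onset
        if value <= 0:
            raise ValidationError(
                f"non-increasing onsets in bout {bout.bout_id!r} "
                f"at position {k}")
        records.append(IOIRecord(
            value=value, bout_id=bout.bout_id, position=k,
            individual=a.individual,
            pair_label=(a.element_class, b.element_class)))
    return records


def ioi_ratio(iois: Sequence[IOIRecord],
              convention: str = "revised") -> list[RatioRecord]:
    """Ratios of consecutive IOIs within one bout.

    ``revised`` (default): r_k = IOI_k / (IOI_k + IOI_{k-1}).
    ``legacy``: the mirrored definition 1 - r_k used in earlier studies.
    A bout of n elements (n - 1 IOIs) yields max(0, n - 2) ratios; ratios
    never span bout boundaries.
    """
    if convention not in ("revised", "legacy"):
        raise ValidationError(f"unknown ratio convention {convention!r}")
    out: list[RatioRecord] = []
    for left, right in zip(iois, iois[1:]):
        if left.value <= 0 or right.value <= 0:
            raise ValidationError("IOI values must be strictly positive")
        if left.bout_id != right.bout_id or \
                right.position != left.position + 1:
            raise ValidationError(
                "ioi_ratio expects consecutive IOIs of a single bout")
        value = right.value / (right.value + left.value)
        if convention == "legacy":
            value = 1.0 - value
        out.append(RatioRecord(
            value=value, bout_id=right.bout_id, position=right.position,
            individual=right.individual, left_pair=left.pair_label,
            right_pair=right.pair_label))
    return out


def mirror_ratio(r: float) -> float:
    """Map between the revised and the legacy ratio definition (1 - r)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0) or np.any(r_arr >= 1):
        raise ValidationError("IOI-ratio must lie strictly in (0, 1)")
    out = 1.0 - r_arr
    return float(out) if out.ndim == 0 else out


class RhythmDataset:
    """Bouts, IOIs and ratios of an annotation set, indexed for permutation.

    Flat arrays over all IOI positions (``ioi_values``, per-position stratum
    metadata) and ratio index pairs (``ratio_left``/``ratio_right`` into the
    IOI arrays) let the permutation machinery re-derive every ratio from a
    shuffled value vector without touching Python-level records.
    """

    def __init__(self, bouts: list[Bout], convention: str = "revised"):
        self.bouts = bouts
        self.convention = convention
        self.ioi_records: list[IOIRecord] = []
        self.ratio_records: list[RatioRecord] = []
        left_idx: list[int] = []
        right_idx: list[int] = []
        offset = 0
        for bout in bouts:
            iois = compute_iois(bout)
            self.ratio_records.extend(ioi_ratio(iois, convention=convention))
            m = len(iois)
            for j in range(m - 1):
                left_idx.append(offset + j)
                right_idx.append(offset + j + 1)
            self.ioi_records.extend(iois)
            offset += m
        self.ioi_values = np.array(
            [r.value for r in self.ioi_records], dtype=float)
        self.ioi_individual = np.array(
            [r.individual for r in self.ioi_records], dtype=object)
        self.ioi_pair = np.array(
            [r.pair_label for r in self.ioi_records], dtype=object)
        self.ratio_left = np.array(left_idx, dtype=np.intp)
        self.ratio_right = np.array(right_idx, dtype=np.intp)

    # ------------------------------------------------------------------ #
    # Counts
    # ------------------------------------------------------------------ #
    @property
    def n_elements(self) -> int:
        return sum(len(b) for b in self.bouts)

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    @property
    def n_iois(self) -> int:
        return len(self.ioi_records)

    @property
    def n_ratios(self) -> int:
        return len(self.ratio_records)

    @property
    def ratio_values(self) -> np.ndarray:
        return self.ratios_from_values(self.ioi_values)

    def ratios_from_values(self, values: np.ndarray) -> np.ndarray:
        """Recompute all ratio values from a (possibly permuted) IOI vector.

        ``values`` may be 1-D (one IOI vector) or 2-D (one vector per row);
        the bout structure and ratio positions are those of the dataset.
        """
        values = np.asarray(values, dtype=float)
        right = values[..., self.ratio_right]
        left = values[..., self.ratio_left]
        r = right / (right + left)
        return 1.0 - r if self.convention == "legacy" else r

    # ------------------------------------------------------------------ #
    # Stratification and pair selection
    # ------------------------------------------------------------------ #
    def stratum_keys(self, mode: str = "pair") -> list[tuple]:
        """Per-IOI exchangeability key.

        ``pair``: (individual, initiating class, terminating class) — the
        default, consistent with permuting within individuals *and* element
        classes; ``initiating_class``: (individual, initiating class);
        ``individual_only``: (individual,), the mode used for unlabeled
        (human) material.
        """
        if mode == "pair":
            return [(r.individual, *r.pair_label) for r in self.ioi_records]
        if mode == "initiating_class":
            return [(r.individual, r.pair_label[0]) for r in self.ioi_records]
        if mode == "individual_only":
            return [(r.individual,) for r in self.ioi_records]
        raise ValidationError(f"unknown stratum_mode {mode!r}")

    def stratum_indices(self, mode: str = "pair") -> dict[tuple, np.ndarray]:
        groups: dict[tuple, list[int]] = {}
        for i, key in enumerate(self.stratum_keys(mode)):
            groups.setdefault(key, []).append(i)
        return {k: np.array(v, dtype=np.intp) for k, v in groups.items()}

    def pair_ratio_mask(self, pair: tuple[str, str]) -> np.ndarray:
        """Ratios whose both constituent IOIs carry the given pair label."""
        pair = tuple(pair)
        return np.array(
            [r.left_pair == pair and r.right_pair == pair
             for r in self.ratio_records], dtype=bool)

    def omit_pairs(self, omit: set[tuple[str, str]]) -> "RhythmDataset":
        """Dataset with all IOIs whose pair label is in ``omit`` removed.

        Surviving IOIs keep their bout membership and original positions;
        ratios are formed only from surviving IOIs that were adjacent in the
        original sequence.
        """
        omit = {tuple(p) for p in omit}
        out = RhythmDataset.__new__(RhythmDataset)
        out.bouts = self.bouts
        out.convention = self.convention
        keep = [i for i, r in enumerate(self.ioi_records)
                if r.pair_label not in omit]
        out.ioi_records = [self.ioi_records[i] for i in keep]
        out.ioi_values = self.ioi_values[keep]
        out.ioi_individual = self.ioi_individual[keep]
        out.ioi_pair = self.ioi_pair[keep]
        pos = {orig: new for new, orig in enumerate(keep)}
        left_idx, right_idx = [], []
        for lo, ro in zip(self.ratio_left, self.ratio_right):
            if int(lo) in pos and int(ro) in pos:
                left_idx.append(pos[int(lo)])
                right_idx.append(pos[int(ro)])
        out.ratio_left = np.array(left_idx, dtype=np.intp)
        out.ratio_right = np.array(right_idx, dtype=np.intp)
        out.ratio_records = [
            r for r in self.ratio_records
            if r.left_pair not in omit and r.right_pair not in omit]
        return out

    # ------------------------------------------------------------------ #
    # Summaries
    # ------------------------------------------------------------------ #
    def summary(self) -> pd.DataFrame:
        """Per-individual element/bout/IOI/ratio bookkeeping."""
        rows: dict[str, dict[str, float]] = {}
        for bout in self.bouts:
            ind = bout.elements[0].individual
            row = rows.setdefault(
                ind, {"elements": 0, "bouts": 0, "iois": 0, "ratios": 0})
            n = len(bout)
            row["elements"] += n
            row["bouts"] += 1
            row["iois"] += max(0, n - 1)
            row["ratios"] += max(0, n - 2)
        df = pd.DataFrame.from_dict(rows, orient="index").rename_axis(
            "individual")
        if len(df):
            df["mean_elements_per_bout"] = df["elements"] / df["bouts"]
        else:
            df["mean_elements_per_bout"] = pd.Series(dtype=float)
        return df


def build_dataset(annotations: AnnotationSet, silence_threshold: float,
                  gap_mode: str = "offset_to_onset",
                  convention: str = "revised") -> RhythmDataset:
    """Group elements into bouts and assemble the full ratio dataset."""
    bouts = group_bouts(annotations, silence_threshold, gap_mode=gap_mode)
    return RhythmDataset(bouts, convention=convention)
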