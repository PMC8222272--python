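"""SMARD fiber statistics: track lengths, fork rates, origins, stalls, telomeres.

A combed DNA fiber is an ordered run-length encoding of labeled segments:
``U`` (unlabeled), ``EDU`` (first 20-min analogue pulse), ``IDU`` (second
20-min pulse) and ``TEL`` (terminal telomere-FISH tract).  Conventions from
the labeling scheme:

* replication track length = length of a maximal IdU segment (second pulse),
  so fork rate = track / pulse duration;
* a stalled fork is a maximal EdU segment with no adjacent IdU (labeled in
  the first pulse, arrested before the second);
* an origin that fired during the first pulse shows as an EdU segment
  flanked by IdU on both sides (two diverging forks);
* a telomere is replicating when its FISH tract is in continuity with an
  EdU or IdU signal, and the FISH tract length approximates telomere length.

Lengths are kb throughout; raw micrometre measurements convert through the
molecular-combing stretch factor (2 kb/um).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Fiber",
    "FiberSet",
    "TelomereClassification",
    "stretch_to_kb",
    "track_lengths",
    "fork_rate",
    "detect_origins",
    "inter_origin_distances",
    "stalled_fraction",
    "classify_telomere_fibers",
    "fiber_summary",
]

LABELS = ("U", "EDU", "IDU", "TEL")
STRETCH_FACTOR_KB_PER_UM = 2.0
PULSE_MINUTES = 20.0


@dataclass
class Fiber:
    """One combed fiber as ordered (label, length_kb) segments."""

    fiber_id: str
    segments: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((str(l), float(k)) for l, k in self.segments)
        self.segments = segs
        for i, (label, kb) in enumerate(segs):
            if label not in LABELS:
                raise ValueError(f"fiber {self.fiber_id}: unknown label {label!r}")
            if kb <= 0:
                raise ValueError(f"fiber {self.fiber_id}: non-positive segment length")
            if i > 0 and segs[i - 1][0] == label:
                raise ValueError(
                    f"fiber {self.fiber_id}: adjacent segments share label {label!r}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.segments)

    @property
    def lengths(self) -> tuple[float, ...]:
        return tuple(k for _, k in self.segments)

    @property
    def length_kb(self) -> float:
        return float(sum(self.lengths))

    def reversed(self) -> "Fiber":
        return Fiber(self.fiber_id, tuple(reversed(self.segments)))

    def telomere_is_terminal(self) -> bool:
        """True when every TEL segment sits at a fiber end."""
        labels = self.labels
        return all(
            label != "TEL" or i in (0, len(labels) - 1) for i, label in enumerate(labels)
        )


@dataclass
class FiberSet:
    fibers: list[Fiber] = field(default_factory=list)
    # generator-side ground truth (e.g. origin positions per fiber); empty
    # for fiber sets read from measured data
    truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self):
        return iter(self.fibers)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fiber_id": f.fiber_id,
                "segment_index": i,
                "label": label,
                "length_kb": kb,
            }
            for f in self.fibers
            for i, (label, kb) in enumerate(f.segments)
        ]
        return pd.DataFrame(rows, columns=["fiber_id", "segment_index", "label", "length_kb"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FiberSet":
        fibers = []
        for fid, group in df.groupby("fiber_id", sort=False):
            group = group.sort_values("segment_index")
            fibers.append(
                Fiber(str(fid), tuple(zip(group["label"], group["length_kb"])))
            )
        return cls(fibers)


def stretch_to_kb(length_um: float, stretch_factor: float = STRETCH_FACTOR_KB_PER_UM):
    """Convert a combed-fiber measurement in um to kb (constant stretch factor)."""
    length_um = np.asarray(length_um, dtype=float)
    if np.any(length_um <= 0) or stretch_factor <= 0:
        raise ValueError("lengths and stretch factor must be > 0")
    out = length_um * stretch_factor
    return float(out) if out.ndim == 0 else out


def track_lengths(fiber: Fiber) -> list[float]:
    """Lengths of maximal IdU segments (second-pulse replication tracks)."""
    return [kb for label, kb in fiber.segments if label == "IDU"]


def fork_rate(track_kb, pulse_minutes: float = PULSE_MINUTES):
    """Fork rate in kb/min from a second-pulse track length."""
    track_kb = np.asarray(track_kb, dtype=float)
    if np.any(track_kb <= 0) or pulse_minutes <= 0:
        raise ValueError("track length and pulse duration must be > 0")
    out = track_kb / pulse_minutes
    return float(out) if out.ndim == 0 else out


def detect_origins(fiber: Fiber) -> list[float]:
    """Centers (kb offset from fiber start) of EdU segments flanked by IdU.

    Under EdU-first labeling, an origin that fired during the first pulse
    leaves a central EdU tract with diverging IdU tracks on both sides; the
    origin position is taken as the EdU segment midpoint.
    """
    labels = fiber.labels
    offsets = np.concatenate([[0.0], np.cumsum(fiber.lengths)])
    centers = []
    for i, label in enumerate(labels):
        if (
            label == "EDU"
            and 0 < i < len(labels) - 1
            and labels[i - 1] == "IDU"
            and labels[i + 1] == "IDU"
        ):
            centers.append(float((offsets[i] + offsets[i + 1]) / 2.0))
    return centers


def inter_origin_distances(fiberset: FiberSet) -> list[float]:
    """Distances between consecutive origin centers within each fiber (kb)."""
    out: list[float] = []
    for fiber in fiberset:
        centers = detect_origins(fiber)
        out.extend(float(d) for d in np.diff(centers))
    return out


def _count_forks(fiberset: FiberSet) -> tuple[int, int]:
    """(stalled, progressing) fork counts over a fiber set.

    Progressing forks are maximal IdU segments; stalled forks are maximal
    EdU segments with no adjacent IdU segment.
    """
    stalled = 0
    progressing = 0
    for fiber in fiberset:
        labels = fiber.labels
        for i, label in enumerate(labels):
            if label == "IDU":
                progressing += 1
            elif label == "EDU":
                left = labels[i - 1] if i > 0 else None
                right = labels[i + 1] if i < len(labels) - 1 else None
                if left != "IDU" and right != "IDU":
                    stalled += 1
    return stalled, progressing


def stalled_fraction(fiberset: FiberSet) -> float:
    """Percent of scored forks that stalled between the two pulses."""
    stalled, progressing = _count_forks(fiberset)
    total = stalled + progressing
    if total == 0:
        raise ValueError("no scorable forks in fiber set")
    return 100.0 * stalled / total


@dataclass
class TelomereClassification:
    replicating: list[Fiber]
    non_replicating: list[Fiber]
    lengths_kb: np.ndarray  # FISH tract lengths of all valid telomere fibers
    invalid: list[Fiber]  # fibers whose TEL tract is not terminal


def classify_telomere_fibers(fiberset: FiberSet) -> TelomereClassification:
    """Split telomere-carrying fibers into replicating / non-replicating.

    A telomere is replicating when its terminal FISH tract is adjacent to an
    EdU or IdU segment; the FISH tract length approximates telomere length.
    Fibers with an internal TEL tract are flagged invalid and excluded.
    """
    replicating: list[Fiber] = []
    non_replicating: list[Fiber] = []
    invalid: list[Fiber] = []
    lengths: list[float] = []
    for fiber in fiberset:
        labels = fiber.labels
        if "TEL" not in labels:
            continue
        if not fiber.telomere_is_terminal():
            invalid.append(fiber)
            continue
        is_replicating = False
        for i, label in enumerate(labels):
            if label != "TEL":
                continue
            lengths.append(fiber.lengths[i])
            neighbours = [
                labels[j] for j in (i - 1, i + 1) if 0 <= j < len(labels)
            ]
            if any(nb in ("EDU", "IDU") for nb in neighbours):
                is_replicating = True
        (replicating if is_replicating else non_replicating).append(fiber)
    return TelomereClassification(
        replicating=replicating,
        non_replicating=non_replicating,
        lengths_kb=np.asarray(lengths, dtype=float),
        invalid=invalid,
    )


def fiber_summary(
    fiberset: FiberSet, pulse_minutes: float = PULSE_MINUTES
) -> pd.DataFrame:
    """Tidy one-row-per-statistic summary of a fiber set."""
    tracks = [kb for f in fiberset for kb in track_lengths(f)]
    iods = inter_origin_distances(fiberset)
    tel = classify_telomere_fibers(fiberset)
    stalled, progressing = _count_forks(fiberset)
    rows = [
        ("n_fibers", len(fiberset)),
        ("n_tracks", len(tracks)),
        ("track_length_mean_kb", float(np.mean(tracks)) if tracks else np.nan),
        (
            "fork_rate_mean_kb_per_min",
            float(np.mean(tracks) / pulse_minutes) if tracks else np.nan,
        ),
        ("n_iod", len(iods)),
        ("iod_mean_kb", float(np.mean(iods)) if iods else np.nan),
        ("n_forks", stalled + progressing),
        (
            "stalled_fork_percent",
            stalled_fraction(fiberset) if (stalled + progressing) else np.nan,
        ),
        ("n_telomere_fibers", len(tel.replicating) + len(tel.non_replicating)),
        ("n_telomere_replicating", len(tel.replicating)),
        (
            "telomere_length_mean_kb",
            float(np.mean(tel.lengths_kb)) if tel.lengths_kb.size else np.nan,
        ),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])
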