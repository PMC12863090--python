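"""Terminal intrinsic disorder, membrane topology and aggregation fractions.

Terminal intrinsically disordered regions (IDRs) of ~30+ residues correlate
with protein degradation; tail-anchored (TA) proteins — a single C-terminal
transmembrane domain (TMD) with a short tail — escape tail-hydrophobicity
triggered degradation via the SGTA/BAG6 routing checkpoint.  This module
consumes per-residue predictor outputs rather than running predictors:

* disorder: IUPred-style three-column text (position, residue, score 0–1);
* topology: one letter per residue over ``i`` (inside), ``o`` (outside),
  ``M`` (membrane), ``S`` (signal peptide);
* aggregation: per-residue beta-pairing free energies and probabilities
  (PASTA-style), summarized as the fraction of residues with energy < −5
  and probability > 0.01.

A deterministic surrogate disorder generator is provided purely as a test
stand-in; it is a window-smoothed per-residue disorder-propensity scale and
NOT a reproduction of any published predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IDR_MIN_LEN = 30
IDR_THRESHOLD = 0.5
TMD_MAX_LEN = 29
TAIL_MAX_LEN = 29
AGG_ENERGY_MAX = -5.0
AGG_PROB_MIN = 0.01

TOPOLOGY_ALPHABET = frozenset("ioMS")


@dataclass(frozen=True)
class DisorderProfile:
    sequence_id: str
    scores: np.ndarray  # per-residue, in [0, 1]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError(f"{self.sequence_id}: scores must be a nonempty 1-D array")
        if (s < 0).any() or (s > 1).any():
            raise ValueError(f"{self.sequence_id}: disorder scores must lie in [0, 1]")
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class TerminalIdrCall:
    n_idr: bool
    c_idr: bool
    n_run_length: int
    c_run_length: int
    min_len: int
    threshold: float


@dataclass(frozen=True)
class TopologyAnnotation:
    sequence_id: str
    has_signal_peptide: bool
    tmd_intervals: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted
    length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.tmd_intervals:
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"{self.sequence_id}: TMD interval ({start},{end}) out of bounds")
            if start <= prev_end:
                raise ValueError(f"{self.sequence_id}: TMD intervals overlap or unsorted")
            prev_end = end


TA_REASONS = ("ok", "signal_peptide", "zero_tmds", "multiple_tmds",
              "tmd_too_long", "tail_too_long")


@dataclass(frozen=True)
class TAClassification:
    is_ta_like: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in TA_REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.is_ta_like != (self.reason == "ok"):
            raise ValueError("is_ta_like must hold exactly when reason == 'ok'")


class DisorderParseError(ValueError):
    pass


def parse_disorder_file(path: str | Path, sequence: Optional[str] = None,
                        sequence_id: Optional[str] = None) -> DisorderProfile:
    """Parse an IUPred-style disorder file (``#`` comments; pos, residue, score).

    Positions must be consecutive from 1.  When ``sequence`` is supplied the
    residue column is cross-checked against it.
    """
    path = Path(path)
    positions, residues, scores = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise DisorderParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                pos = int(parts[0])
                score = float(parts[2])
            except ValueError as exc:
                raise DisorderParseError(f"{path}:{lineno}: {exc}") from None
            positions.append(pos)
            residues.append(parts[1])
            scores.append(score)
    if not positions:
        raise DisorderParseError(f"{path}: no data lines")
    expected = list(range(1, len(positions) + 1))
    if positions != expected:
        raise DisorderParseError(f"{path}: positions are not consecutive 1..{len(positions)}")
    arr = np.array(scores)
    if (arr < 0).any() or (arr > 1).any():
        raise DisorderParseError(f"{path}: disorder score outside [0, 1]")
    if sequence is not None:
        if "".join(residues) != sequence:
            raise DisorderParseError(f"{path}: residue column does not match supplied sequence")
    return DisorderProfile(sequence_id or path.stem, arr)


def read_disorder_multi(path: str | Path) -> dict[str, DisorderProfile]:
    """Read a concatenated disorder file: blocks introduced by ``# <id>`` lines."""
    path = Path(path)
    profiles: dict[str, DisorderProfile] = {}
    cur_id: Optional[str] = None
    scores: list[float] = []

    def flush() -> None:
        nonlocal scores
        if cur_id is not None:
            if not scores:
                raise DisorderParseError(f"{path}: block {cur_id!r} has no scores")
            profiles[cur_id] = DisorderProfile(cur_id, np.array(scores))
        scores = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                flush()
                cur_id = line[1:].strip()
                continue
            parts = line.split()
            if len(parts) < 3:
                raise DisorderParseError(f"{path}: bad data line {line!r}")
            scores.append(float(parts[2]))
    flush()
    return profiles


def call_terminal_idrs(profile: DisorderProfile, min_len: int = IDR_MIN_LEN,
                       threshold: float = IDR_THRESHOLD) -> TerminalIdrCall:
    """Call N- and C-terminal IDRs from the maximal terminal runs of score > threshold.

    The length criterion is inclusive: a run of exactly ``min_len`` residues
    qualifies.
    """
    above = profile.scores > threshold
    n_run = int(np.argmin(above)) if not above.all() else len(above)
    rev = above[::-1]
    c_run = int(np.argmin(rev)) if not rev.all() else len(rev)
    return TerminalIdrCall(n_run >= min_len, c_run >= min_len, n_run, c_run,
                           min_len, threshold)


# Per-residue disorder propensity in [0, 1] (package-defined scale; higher =
# more disorder-promoting).  Pro/Glu/Lys/Ser/Gln promote disorder, the bulky
# hydrophobics and Cys promote order.
DISORDER_PROPENSITY: dict[str, float] = {
    "A": 0.50, "R": 0.57, "N": 0.48, "D": 0.58, "C": 0.46,
    "Q": 0.64, "E": 0.87, "G": 0.56, "H": 0.63, "I": 0.21,
    "L": 0.30, "K": 0.79, "M": 0.26, "F": 0.10, "P": 1.00,
    "S": 0.65, "T": 0.50, "W": 0.00, "Y": 0.20, "V": 0.41,
}

SURROGATE_WINDOW = 21


def surrogate_disorder(seq: str, sequence_id: str = "") -> DisorderProfile:
    """Deterministic disorder stand-in: window-smoothed propensity scale.

    Each residue's score is the mean propensity over a centered window of
    21 residues (truncated at the termini), clipped to [0, 1].  This is a
    synthetic surrogate for testing parsers and pipelines; it does not
    reproduce IUPred or any other predictor.
    """
    vals = np.array([DISORDER_PROPENSITY[c] for c in seq])
    half = SURROGATE_WINDOW // 2
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    idx = np.arange(len(vals))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, len(vals))
    smoothed = (cs[hi] - cs[lo]) / (hi - lo)
    return DisorderProfile(sequence_id, np.clip(smoothed, 0.0, 1.0))


class TopologyParseError(ValueError):
    pass


def topology_from_string(sequence_id: str, topo: str) -> TopologyAnnotation:
    """Decode a one-letter-per-residue topology string into TMD intervals."""
    bad = set(topo) - TOPOLOGY_ALPHABET
    if bad:
        raise TopologyParseError(f"{sequence_id}: unknown topology letters {sorted(bad)}")
    intervals = []
    start = None
    for i, c in enumerate(topo, 1):
        if c == "M" and start is None:
            start = i
        elif c != "M" and start is not None:
            intervals.append((start, i - 1))
            start = None
    if start is not None:
        intervals.append((start, len(topo)))
    return TopologyAnnotation(sequence_id, "S" in topo, tuple(intervals), len(topo))


def parse_topology(path: str | Path) -> dict[str, TopologyAnnotation]:
    """Parse a FASTA-like topology file (``>id`` headers, {i,o,M,S} strings)."""
    path = Path(path)
    annotations: dict[str, TopologyAnnotation] = {}
    cur_id: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if cur_id is not None:
            topo = "".join(chunks)
            if not topo:
                raise TopologyParseError(f"{path}: empty topology for {cur_id!r}")
            annotations[cur_id] = topology_from_string(cur_id, topo)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0]
                chunks = []
            else:
                if cur_id is None:
                    raise TopologyParseError(f"{path}: data before first '>' header")
                chunks.append(line)
    flush()
    return annotations


def classify_ta(topo: TopologyAnnotation, seq_length: Optional[int] = None,
                tmd_max: int = TMD_MAX_LEN, tail_max: int = TAIL_MAX_LEN
                ) -> TAClassification:
    """Tail-anchored architecture call.

    TA-like requires: no signal peptide, exactly one TMD, TMD length
    ≤ ``tmd_max``, and a C-tail after the TMD of ≤ ``tail_max`` residues.
    The first failed criterion (in that order) is reported.
    """
    seq_length = seq_length if seq_length is not None else topo.length
    if topo.has_signal_peptide:
        return TAClassification(False, "signal_peptide")
    if len(topo.tmd_intervals) == 0:
        return TAClassification(False, "zero_tmds")
    if len(topo.tmd_intervals) > 1:
        return TAClassification(False, "multiple_tmds")
    start, end = topo.tmd_intervals[0]
    if end - start + 1 > tmd_max:
        return TAClassification(False, "tmd_too_long")
    if seq_length - end > tail_max:
        return TAClassification(False, "tail_too_long")
    return TAClassification(True, "ok")


def has_cterm_tmd(topo: TopologyAnnotation, seq_length: Optional[int] = None,
                  margin: int = 30) -> bool:
    """True when some TMD ends within ``margin`` residues of the C-terminus."""
    seq_length = seq_length if seq_length is not None else topo.length
    return any(seq_length - end < margin for _, end in topo.tmd_intervals)


def aggregation_fraction(energies: Sequence[float], probabilities: Sequence[float],
                         seq_length: Optional[int] = None,
                         energy_max: float = AGG_ENERGY_MAX,
                         prob_min: float = AGG_PROB_MIN) -> float:
    """Fraction of residues with pairing free energy < energy_max and probability > prob_min."""
    e = np.asarray(energies, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if e.shape != p.shape or e.ndim != 1:
        raise ValueError("energies and probabilities must be 1-D arrays of equal length")
    if seq_length is not None and len(e) != seq_length:
        raise ValueError(f"array length {len(e)} != seq_length {seq_length}")
    qualifying = (e < energy_max) & (p > prob_min)
    return float(qualifying.sum() / len(e))


def parse_aggregation(path: str | Path) -> pd.DataFrame:
    """Parse a per-residue aggregation TSV (position, energy, probability).

    Accepts an optional leading ``id`` column for concatenated multi-sequence
    tables; returns the table unchanged apart from dtype validation.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"position", "energy", "probability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
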