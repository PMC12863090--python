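"""Kyte–Doolittle hydropathy machinery.

The central quantity is the C-terminal tail hydrophobicity (CTTH): the
unweighted arithmetic mean of the Kyte–Doolittle hydropathy values over a
protein's last 30 residues.  Elevated CTTH is associated with proteasomal
degradation, which makes this score a cheap sequence-level proxy for
degradation propensity.  The module also computes the complementary
rest-of-protein GRAVY, a per-position mean hydropathy profile over the tail
region of a dataset, and a quartile-threshold classifier that flags proteins
whose tail hydropathy deviates from the rest of the sequence in either
direction (putatively stabilized vs. destabilized tails).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .sequences import ProteinDataset

#: Kyte–Doolittle hydropathy scale (dimensionless; positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# ASCII lookup table for fast per-sequence vectorization; NaN marks
# non-standard letters so they surface as errors rather than silent zeros.
_KD_LUT = np.full(128, np.nan)
for _aa, _v in KYTE_DOOLITTLE.items():
    _KD_LUT[ord(_aa)] = _v

# Default thresholds for the stability-pattern classifier: lower/upper
# quartile of CTTH in a canonical AUG longest-isoform reference set.
CTTH_LOW_QUARTILE = -0.963
CTTH_HIGH_QUARTILE = -0.110
REST_HYDROPHILIC = -1.0
REST_HYDROPHOBIC = 0.0


def kd_value(residue: str, scale: Optional[dict[str, float]] = None) -> float:
    """Hydropathy value of a single standard residue."""
    scale = scale or KYTE_DOOLITTLE
    try:
        return scale[residue]
    except KeyError:
        raise KeyError(f"residue {residue!r} is not in the hydropathy scale") from None


def kd_values(seq: str, scale: Optional[dict[str, float]] = None) -> np.ndarray:
    """Per-residue hydropathy array for a sequence."""
    if scale is None or scale is KYTE_DOOLITTLE:
        arr = _KD_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if np.isnan(arr).any():
            bad = sorted(set(seq) - set(KYTE_DOOLITTLE))
            raise KeyError(f"sequence contains residues outside the scale: {bad}")
        return arr
    return np.array([kd_value(c, scale) for c in seq])


def ctth(seq: str, window: int = 30, scale: Optional[dict[str, float]] = None) -> float:
    """C-terminal tail hydrophobicity: mean KD over the final ``window`` residues."""
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} < window {window}")
    return float(kd_values(seq[-window:], scale).mean())


def rest_gravy(seq: str, window: int = 30, scale: Optional[dict[str, float]] = None) -> float:
    """Mean KD over the sequence excluding the final ``window`` residues."""
    if len(seq) <= window:
        raise ValueError(f"sequence length {len(seq)} <= window {window}; no rest to score")
    return float(kd_values(seq[:-window], scale).mean())


def tail_profile(ds: ProteinDataset | Iterable[str], last_n: int = 60,
                 scale: Optional[dict[str, float]] = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position mean hydropathy over the last ``last_n`` residues of a dataset.

    Records shorter than ``last_n`` are skipped (their count is returned via
    the per-position ``n`` array, constant here since inclusion is
    all-or-nothing).  Returns ``(offsets, mean_kd, n)`` where ``offsets``
    runs −last_n .. −1.
    """
    seqs = [r.sequence for r in ds] if isinstance(ds, ProteinDataset) else list(ds)
    tails = [s[-last_n:] for s in seqs if len(s) >= last_n]
    if not tails:
        raise ValueError(f"no record is at least {last_n} residues long; empty profile")
    mat = np.stack([kd_values(t, scale) for t in tails])
    offsets = np.arange(-last_n, 0)
    return offsets, mat.mean(axis=0), np.full(last_n, len(tails))


@dataclass(frozen=True)
class StabilityPatternCall:
    """Outcome of the quartile-threshold tail-hydropathy classifier."""

    pattern: str  # stabilized_tail | destabilized_tail | other
    ctth: float
    rest_gravy: float
    excluded_for_cterm_tmd: bool = False


def classify_stability_pattern(ctth_value: float, rest_gravy_value: float,
                               has_cterm_tmd: bool = False,
                               low_q: float = CTTH_LOW_QUARTILE,
                               high_q: float = CTTH_HIGH_QUARTILE,
                               rest_hydrophilic: float = REST_HYDROPHILIC,
                               rest_hydrophobic: float = REST_HYDROPHOBIC
                               ) -> StabilityPatternCall:
    """Classify a protein's tail-vs-rest hydropathy pattern.

    ``stabilized_tail``: a strongly hydrophilic tail (CTTH below the lower
    quartile threshold) on an otherwise hydrophobic protein — a signature of
    selection toward stability.  ``destabilized_tail``: a tail above the
    upper quartile threshold on a strongly hydrophilic protein, after
    excluding proteins with a C-terminal transmembrane domain (membrane
    tail-anchors inflate tail hydrophobicity without implying degradation).
    All inequalities are strict; boundary values fall into ``other``.
    """
    for v in (ctth_value, rest_gravy_value):
        if not np.isfinite(v):
            raise ValueError("ctth and rest_gravy must be finite")
    if ctth_value < low_q and rest_gravy_value > rest_hydrophobic:
        pattern = "stabilized_tail"
    elif (ctth_value > high_q and rest_gravy_value < rest_hydrophilic
          and not has_cterm_tmd):
        pattern = "destabilized_tail"
    else:
        pattern = "other"
    return StabilityPatternCall(pattern, ctth_value, rest_gravy_value,
                                excluded_for_cterm_tmd=has_cterm_tmd)


def ctth_quartiles(ctth_values: Sequence[float]) -> tuple[float, float]:
    """Empirical (lower, upper) quartiles of a reference CTTH distribution.

    Linear-interpolation quantile definition.  Use this to recompute the
    classifier thresholds from your own canonical reference set instead of
    the bundled defaults.
    """
    arr = np.asarray(ctth_values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty reference distribution")
    lo, hi = np.quantile(arr, [0.25, 0.75])
    return float(lo), float(hi)
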