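"""Terminal degron tables and anchored N-/C-end motif scanning.

Degrons are short linear motifs at a protein's N- or C-terminus that recruit
degradation machinery.  Curated tables rank motifs by ΔPSI, the differential
protein stability index (mean stability difference between the motif placed
terminally vs. internally; more negative = stronger degron).  This module
loads such tables, filters by strength (ΔPSI ≤ −0.4 by default), selects the
strongest k motifs, and scans sequences with anchored exact matching:

* N-end motifs match the prefix starting after the initiator methionine
  when the sequence begins with ``M``, else the literal prefix (the ΔPSI
  screens place motifs after the initiator Met; non-Met isoforms have no
  initiator to skip).
* C-end motifs match the literal suffix.

Matching is exact-letter; the analyses downstream use presence/absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .sequences import STANDARD_AA

logger = logging.getLogger(__name__)

DEFAULT_DPSI_MAX = -0.4


@dataclass(frozen=True)
class DegronMotif:
    motif: str
    terminus: str  # "N" or "C"
    dpsi: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.motif or not set(self.motif) <= STANDARD_AA:
            raise ValueError(f"motif {self.motif!r} must be a nonempty standard-residue string")
        if self.terminus not in ("N", "C"):
            raise ValueError(f"terminus must be 'N' or 'C', got {self.terminus!r}")
        if not pd.notna(self.dpsi):
            raise ValueError(f"motif {self.motif!r}: dpsi must be finite")


@dataclass(frozen=True)
class DegronSet:
    terminus: str
    motifs: tuple[DegronMotif, ...]
    filter_threshold: float = DEFAULT_DPSI_MAX

    def __post_init__(self) -> None:
        for m in self.motifs:
            if m.terminus != self.terminus:
                raise ValueError(f"motif {m.motif!r} terminus {m.terminus!r} != set terminus {self.terminus!r}")

    def __len__(self) -> int:
        return len(self.motifs)

    def motif_strings(self) -> list[str]:
        return [m.motif for m in self.motifs]


@dataclass(frozen=True)
class DegronHit:
    sequence_id: str
    motif: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    terminus: str


class DegronTableError(ValueError):
    pass


def load_degron_table(path: str | Path, terminus: str,
                      dpsi_max: float = DEFAULT_DPSI_MAX) -> DegronSet:
    """Load a TSV degron table (columns ``motif``, ``dpsi``, optional ``source_id``).

    Rows with ΔPSI above ``dpsi_max`` are discarded; duplicate motifs are
    collapsed keeping the most negative ΔPSI.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed file
        raise DegronTableError(f"{path}: cannot parse: {exc}") from exc
    for col in ("motif", "dpsi"):
        if col not in df.columns:
            raise DegronTableError(f"{path}: missing required column {col!r}")
    if not pd.api.types.is_numeric_dtype(df["dpsi"]):
        coerced = pd.to_numeric(df["dpsi"], errors="coerce")
        if coerced.isna().any():
            bad = df.loc[coerced.isna(), "dpsi"].iloc[0]
            raise DegronTableError(f"{path}: non-numeric dpsi value {bad!r}")
        df["dpsi"] = coerced
    n_in = len(df)
    df = df[df["dpsi"] <= dpsi_max]
    # duplicate motifs: keep the most negative dpsi
    df = df.sort_values(["motif", "dpsi"]).drop_duplicates("motif", keep="first")
    df = df.sort_values(["dpsi", "motif"]).reset_index(drop=True)
    motifs = tuple(
        DegronMotif(row.motif, terminus, float(row.dpsi),
                    str(getattr(row, "source_id", "") or ""))
        for row in df.itertuples()
    )
    logger.info("load_degron_table(%s, %s): %d rows -> %d motifs at dpsi <= %g",
                path, terminus, n_in, len(motifs), dpsi_max)
    return DegronSet(terminus, motifs, filter_threshold=dpsi_max)


def top_k_by_dpsi(dset: DegronSet, k: int = 20) -> DegronSet:
    """The ``k`` most destabilizing motifs (ties broken lexicographically)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(dset.motifs, key=lambda m: (m.dpsi, m.motif))
    return DegronSet(dset.terminus, tuple(ordered[:k]), filter_threshold=dset.filter_threshold)


def scan_n_degrons(seq: str, dset: DegronSet, sequence_id: str = "") -> list[DegronHit]:
    """Anchored N-end scan: motifs must match the prefix after the initiator Met.

    When the sequence does not begin with ``M`` (non-AUG isoform), matching
    starts at residue 1.  At most one hit per motif.
    """
    if dset.terminus != "N":
        raise ValueError("scan_n_degrons requires an N-terminus DegronSet")
    start = 2 if seq.startswith("M") else 1  # 1-based
    hits = []
    for m in dset.motifs:
        end = start + len(m.motif) - 1
        if end <= len(seq) and seq[start - 1:end] == m.motif:
            hits.append(DegronHit(sequence_id, m.motif, start, end, "N"))
    return hits


def scan_c_degrons(seq: str, dset: DegronSet, sequence_id: str = "") -> list[DegronHit]:
    """Anchored C-end scan: motifs must equal the final residues of the sequence."""
    if dset.terminus != "C":
        raise ValueError("scan_c_degrons requires a C-terminus DegronSet")
    hits = []
    for m in dset.motifs:
        mlen = len(m.motif)
        if mlen <= len(seq) and seq[-mlen:] == m.motif:
            hits.append(DegronHit(sequence_id, m.motif, len(seq) - mlen + 1, len(seq), "C"))
    return hits


def scan_degrons(seq: str, dset: DegronSet, sequence_id: str = "") -> list[DegronHit]:
    """Dispatch to the terminus-appropriate scanner."""
    if dset.terminus == "N":
        return scan_n_degrons(seq, dset, sequence_id)
    return scan_c_degrons(seq, dset, sequence_id)


def bundled_toy_set(terminus: str, dpsi_max: float = DEFAULT_DPSI_MAX) -> DegronSet:
    """Load the bundled toy degron fixture table for one terminus.

    These are small synthetic motif lists for demonstrations and tests, not
    the curated experimental degron catalogs (users supply those as TSV).
    """
    from importlib.resources import files

    name = {"N": "degrons_n_toy.tsv", "C": "degrons_c_toy.tsv"}[terminus]
    return load_degron_table(str(files("degdet") / "data" / name), terminus, dpsi_max)


def degron_set_from_pairs(pairs: Sequence[tuple[str, float]], terminus: str,
                          dpsi_max: float = DEFAULT_DPSI_MAX) -> DegronSet:
    """Build a DegronSet directly from ``(motif, dpsi)`` pairs (applies the cutoff)."""
    best: dict[str, float] = {}
    for motif, dpsi in pairs:
        if dpsi <= dpsi_max and (motif not in best or dpsi < best[motif]):
            best[motif] = dpsi
    motifs = tuple(DegronMotif(m, terminus, d)
                   for m, d in sorted(best.items(), key=lambda kv: (kv[1], kv[0])))
    return DegronSet(terminus, motifs, filter_threshold=dpsi_max)
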