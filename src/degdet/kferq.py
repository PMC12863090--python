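"""KFERQ-like motif detection for chaperone-mediated autophagy / eMI.

KFERQ-like pentapeptides are recognized by the chaperone HSC70 and target
proteins to chaperone-mediated autophagy and endosomal microautophagy.
Three motif classes are scanned:

* **canonical** — a glutamine anchor at either end of the pentapeptide; the
  remaining four residues carry 1–2 basic (K/R), 1–2 hydrophobic (F/I/L/V)
  and exactly 1 acidic (E/D) residue, with basic + hydrophobic = 3.
* **phospho_activated** — as canonical, but the acidic slot is filled by a
  phosphorylatable residue (S/T by default; Y via ``include_tyrosine``) and
  no E/D occupies it.
* **acetyl_activated** — as canonical, but the anchor slot holds a lysine
  (acetyl-K mimics Q); the anchor K does not also count toward the basic
  tally.

Every 5-residue window is classified independently; overlapping hits all
count, and a window satisfying several requested classes yields one hit per
class.  Densities are counts per residue, pooled over a dataset by dividing
the total motif count by the summed sequence length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .sequences import ProteinDataset

logger = logging.getLogger(__name__)

CLASSES = ("canonical", "phospho_activated", "acetyl_activated")

BASIC = frozenset("KR")
HYDROPHOBIC = frozenset("FILV")
ACIDIC = frozenset("ED")
PHOSPHO = frozenset("ST")
PHOSPHO_WITH_Y = frozenset("STY")


@dataclass(frozen=True)
class KferqHit:
    sequence_id: str
    start: int  # 1-based
    pentapeptide: str
    motif_class: str


@dataclass(frozen=True)
class KferqSummary:
    counts: dict[str, int]
    total_count: int
    density: dict[str, float]
    density_total: float
    has_any: bool


def _slots_ok(rest: str, acidic_set: frozenset[str],
              forbid: frozenset[str] = frozenset()) -> bool:
    """Check the four non-anchor residues of a window against the class rules."""
    b = sum(c in BASIC for c in rest)
    h = sum(c in HYDROPHOBIC for c in rest)
    a = sum(c in acidic_set for c in rest)
    if forbid and any(c in forbid for c in rest):
        return False
    return 1 <= b <= 2 and 1 <= h <= 2 and b + h == 3 and a == 1


def _window_matches(window: str, motif_class: str, phospho_set: frozenset[str]) -> bool:
    if motif_class == "canonical":
        anchor, acidic, forbid = "Q", ACIDIC, frozenset()
    elif motif_class == "phospho_activated":
        anchor, acidic, forbid = "Q", phospho_set, ACIDIC
    elif motif_class == "acetyl_activated":
        anchor, acidic, forbid = "K", ACIDIC, frozenset()
    else:
        raise ValueError(f"unknown motif class {motif_class!r}")
    for pos in (0, 4):
        if window[pos] == anchor and _slots_ok(window[:pos] + window[pos + 1:], acidic, forbid):
            return True
    return False


def find_kferq_motifs(seq: str, classes: Optional[Iterable[str]] = None,
                      sequence_id: str = "",
                      include_tyrosine: bool = False) -> list[KferqHit]:
    """All KFERQ-like pentapeptide hits in a sequence.

    Sequences shorter than 5 residues yield an empty list (logged, not an
    error).  Hits are ordered by window start, then class order.
    """
    classes = tuple(classes) if classes is not None else CLASSES
    for c in classes:
        if c not in CLASSES:
            raise ValueError(f"unknown motif class {c!r}")
    if len(seq) < 5:
        logger.debug("sequence %r shorter than 5 residues; no KFERQ windows", sequence_id)
        return []
    phospho_set = PHOSPHO_WITH_Y if include_tyrosine else PHOSPHO
    hits = []
    for i in range(len(seq) - 4):
        window = seq[i:i + 5]
        for cls in classes:
            if _window_matches(window, cls, phospho_set):
                hits.append(KferqHit(sequence_id, i + 1, window, cls))
    return hits


def kferq_summary(hits: Sequence[KferqHit], seq_length: int) -> KferqSummary:
    """Per-sequence class counts and length-normalized densities."""
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    counts = {c: 0 for c in CLASSES}
    for h in hits:
        counts[h.motif_class] += 1
    total = sum(counts.values())
    density = {c: counts[c] / seq_length for c in CLASSES}
    return KferqSummary(counts, total, density, total / seq_length, total > 0)


def dataset_kferq_rates(ds: ProteinDataset, classes: Optional[Iterable[str]] = None,
                        include_tyrosine: bool = False
                        ) -> tuple[dict[str, float], pd.DataFrame]:
    """Pooled per-class motif densities over a dataset, plus a per-sequence table.

    The pooled density divides the total motif count by the total residue
    count of the dataset (motifs per residue), matching the convention of
    normalizing motif counts by the summed dataset length.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    classes = tuple(classes) if classes is not None else CLASSES
    rows = []
    totals = {c: 0 for c in classes}
    total_len = 0
    for rec in ds:
        hits = find_kferq_motifs(rec.sequence, classes, rec.id, include_tyrosine)
        summ = kferq_summary(hits, len(rec))
        total_len += len(rec)
        for c in classes:
            totals[c] += summ.counts[c]
        rows.append({"id": rec.id, "length": len(rec),
                     "canonical_n": summ.counts["canonical"],
                     "phospho_n": summ.counts["phospho_activated"],
                     "acetyl_n": summ.counts["acetyl_activated"],
                     "density_total": summ.density_total,
                     "has_any": summ.has_any})
    pooled = {c: totals[c] / total_len for c in classes}
    pooled["total"] = sum(totals.values()) / total_len
    return pooled, pd.DataFrame(rows)
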