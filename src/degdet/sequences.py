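"""Protein FASTA I/O, dataset filtering and terminal-redundancy collapse.

A :class:`ProteinDataset` is an ordered collection of :class:`ProteinRecord`
objects plus a provenance trail recording every filter applied (name,
parameters, records in/out).  All filters are order-stable: the output is a
subsequence of the input, so repeated application is idempotent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The twenty standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

START_CLASSES = ("AUG", "nonAUG", "unknown")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed or violates record rules."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence.

    ``sequence`` is stored uppercase; a single trailing ``*`` (stop) is the
    only decoration :func:`read_fasta` strips.  Records carrying nonstandard
    letters are *kept* at parse time and rejected later by
    :func:`filter_minimal` — filters reject, they never silently edit.
    """

    id: str
    sequence: str
    dataset_label: str = ""
    start_class: str = "unknown"
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.start_class not in START_CLASSES:
            raise ValueError(f"record {self.id!r}: bad start_class {self.start_class!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterStep:
    """One provenance entry: a named filter with its parameters and counts."""

    name: str
    params: Mapping[str, object]
    records_in: int
    records_out: int

    @property
    def removed(self) -> int:
        return self.records_in - self.records_out


@dataclass
class ProteinDataset:
    name: str
    records: list[ProteinRecord]
    provenance: list[FilterStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in dataset {self.name!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def _derive(self, records: list[ProteinRecord], step: FilterStep) -> "ProteinDataset":
        ds = ProteinDataset(self.name, records, list(self.provenance) + [step])
        return ds

    def provenance_json(self) -> str:
        """Provenance trail serialized as a JSON array."""
        return json.dumps([dataclasses.asdict(s) for s in self.provenance], indent=2)


def read_fasta(path: str | Path, name: Optional[str] = None,
               dataset_label: str = "", start_class: str = "unknown") -> ProteinDataset:
    """Read a protein FASTA file into a :class:`ProteinDataset`.

    Sequences are uppercased and a trailing ``*`` is stripped; the FASTA
    description after the first whitespace is preserved under
    ``meta["description"]``.  Duplicate ids raise :class:`FastaParseError`.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FastaParseError(f"{path}: line 1: expected '>' header, got {first[:30]!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaParseError(f"{path}: empty FASTA header")
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        desc = entry.description[len(entry.id):].strip()
        meta = {"description": desc} if desc else {}
        records.append(ProteinRecord(entry.id, seq, dataset_label=dataset_label,
                                     start_class=start_class, meta=meta))
    return ProteinDataset(name or path.stem, records)


def write_fasta(ds: ProteinDataset | Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA with fixed-width wrapping (byte-stable round trip)."""
    records = ds.records if isinstance(ds, ProteinDataset) else list(ds)
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.meta.get("description", "")
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def filter_minimal(ds: ProteinDataset, min_len: int = 60,
                   forbidden: Optional[frozenset[str] | set[str]] = None) -> ProteinDataset:
    """Remove records shorter than ``min_len`` or carrying forbidden residues.

    With ``forbidden=None`` (default) any letter outside the 20-residue
    standard alphabet is forbidden — selenocysteine ``U`` and the ambiguity
    codes B, Z, X, J, O all disqualify a record, since downstream hydropathy
    and motif scales are undefined for them.  Pass an explicit set (e.g.
    ``{"U"}``) to forbid only those letters.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if forbidden is None:
        def ok(seq: str) -> bool:
            return set(seq) <= STANDARD_AA
    else:
        fset = frozenset(forbidden)

        def ok(seq: str) -> bool:
            return not (set(seq) & fset)

    kept = [r for r in ds.records if len(r) >= min_len and ok(r.sequence)]
    step = FilterStep("filter_minimal",
                      {"min_len": min_len,
                       "forbidden": "nonstandard" if forbidden is None else sorted(forbidden)},
                      len(ds.records), len(kept))
    logger.info("filter_minimal(%s): %d -> %d", ds.name, step.records_in, step.records_out)
    return ds._derive(kept, step)


def collapse_identical(ds: ProteinDataset) -> ProteinDataset:
    """Keep exactly one record per distinct full sequence (first in input order)."""
    seen: set[str] = set()
    kept = []
    for rec in ds.records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            kept.append(rec)
    step = FilterStep("collapse_identical", {}, len(ds.records), len(kept))
    logger.info("collapse_identical(%s): %d -> %d", ds.name, step.records_in, step.records_out)
    return ds._derive(kept, step)


def _terminal_kmer(seq: str, terminus: str, k: int) -> str:
    return seq[:k] if terminus == "N" else seq[-k:]


def collapse_terminal_redundancy(ds: ProteinDataset, terminus: str, k: int) -> ProteinDataset:
    """Among records sharing an identical terminal k-mer keep only the longest.

    ``terminus`` is ``"N"`` or ``"C"``.  Length ties are broken by input
    order (first wins).  Records shorter than ``k`` cannot participate in the
    k-mer uniqueness contract and are dropped with a logged warning.
    """
    if terminus not in ("N", "C"):
        raise ValueError(f"terminus must be 'N' or 'C', got {terminus!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    long_enough = [r for r in ds.records if len(r) >= k]
    n_short = len(ds.records) - len(long_enough)
    if n_short:
        logger.warning("collapse_terminal_redundancy(%s, %s, %d): dropping %d records shorter than k",
                       ds.name, terminus, k, n_short)
    best: dict[str, ProteinRecord] = {}
    for rec in long_enough:
        kmer = _terminal_kmer(rec.sequence, terminus, k)
        cur = best.get(kmer)
        if cur is None or len(rec) > len(cur):
            best[kmer] = rec
    keep_ids = {id(r) for r in best.values()}
    kept = [r for r in long_enough if id(r) in keep_ids]
    step = FilterStep("collapse_terminal_redundancy",
                      {"terminus": terminus, "k": k, "dropped_short": n_short},
                      len(ds.records), len(kept))
    logger.info("collapse_terminal_redundancy(%s, %s, %d): %d -> %d",
                ds.name, terminus, k, step.records_in, step.records_out)
    return ds._derive(kept, step)


def from_sequences(pairs: Iterable[tuple[str, str]], name: str = "dataset",
                   **record_kwargs) -> ProteinDataset:
    """Convenience constructor from ``(id, sequence)`` pairs."""
    return ProteinDataset(name, [ProteinRecord(i, s, **record_kwargs) for i, s in pairs])
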