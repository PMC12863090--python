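"""Synthetic protein datasets with planted degradation determinants.

The generator emulates the statistical structure of canonical-like (CP) and
noncanonical-like (NCP) protein sets: i.i.d. residues drawn from a
human-like amino-acid composition, log-normal lengths floored at 60
residues (the minimum analyzable length for tail-vs-rest hydropathy), an
exponentially tilted tail composition that raises mean C-terminal-tail
hydropathy by a controlled amount, and planted terminal degrons, KFERQ-like
pentapeptides, tail-anchor architectures and terminal disorder runs at
specified prevalences.  Companion disorder/topology/aggregation files are
emitted in the same formats the parsers consume, so the whole pipeline is
testable without any external predictor or download.

Planting semantics: a planting probability is the *realized prevalence* of
that determinant.  When planting is enabled for a terminus, sequences not
selected for planting have accidental anchored matches against the planting
motif set resampled away, so the truth table is exact and two-group effect
sizes are fully controlled.  With planting disabled (probability 0) the
anchored-match rate is whatever the residue composition implies.

The i.i.d. residue model carries no dipeptide structure — deliberately, as
it is the model under which the composition-preserving shuffle null is
exact, which keeps null-calibration tests clean.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .degrons import DegronSet, scan_c_degrons, scan_n_degrons
from .disorder_topology import DisorderProfile
from .hydropathy import KYTE_DOOLITTLE
from .kferq import CLASSES as KFERQ_CLASSES
from .kferq import _window_matches, PHOSPHO
from .null_models import child_seed
from .sequences import ProteinDataset, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Human-like background amino-acid frequencies (normalized at import).
DEFAULT_COMPOSITION: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0664, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
_total = sum(DEFAULT_COMPOSITION.values())
DEFAULT_COMPOSITION = {a: v / _total for a, v in DEFAULT_COMPOSITION.items()}

_TMD_RESIDUES = "ILVFA"
_TMD_WEIGHTS = np.array([0.3, 0.3, 0.2, 0.1, 0.1])

_MAX_PLANT_ATTEMPTS = 100


class SpecError(ValueError):
    """Raised for infeasible or invalid generator specifications."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic protein dataset."""

    n_sequences: int
    length_log_mean: float = math.log(120.0)
    length_log_sigma: float = 0.45
    length_floor: int = 60
    composition: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    tail_kd_shift: float = 0.0
    tail_window: int = 30
    p_n_degron: float = 0.0
    p_c_degron: float = 0.0
    n_degron_motifs: tuple[str, ...] = ()
    c_degron_motifs: tuple[str, ...] = ()
    p_kferq_canonical: float = 0.0
    p_kferq_phospho: float = 0.0
    p_kferq_acetyl: float = 0.0
    p_ta: float = 0.0
    p_n_idr: float = 0.0
    p_c_idr: float = 0.0
    start_with_met: bool = True
    dataset_label: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise SpecError("n_sequences must be >= 1")
        if self.length_floor < 60:
            raise SpecError("length_floor must be >= 60 (analyzable length)")
        comp_keys = set(self.composition)
        if comp_keys != set(AA):
            raise SpecError(f"composition must cover exactly the 20 standard residues; "
                            f"got {len(comp_keys)} keys")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"composition must sum to 1 (got {total!r})")
        for name in ("p_n_degron", "p_c_degron", "p_kferq_canonical", "p_kferq_phospho",
                     "p_kferq_acetyl", "p_ta", "p_n_idr", "p_c_idr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must lie in [0, 1], got {v}")
        if self.p_n_degron > 0 and not self.n_degron_motifs:
            raise SpecError("p_n_degron > 0 requires n_degron_motifs")
        if self.p_c_degron > 0 and not self.c_degron_motifs:
            raise SpecError("p_c_degron > 0 requires c_degron_motifs")
        # feasibility of the tail tilt
        probs = np.array([self.composition[a] for a in AA])
        kd = np.array([KYTE_DOOLITTLE[a] for a in AA])
        base_mean = float(probs @ kd)
        target = base_mean + self.tail_kd_shift
        if not (kd[probs > 0].min() < target < kd[probs > 0].max()):
            raise SpecError(f"tail_kd_shift {self.tail_kd_shift} puts the target tail mean "
                            f"{target:.3f} outside the achievable hydropathy range")


def tilted_composition(composition: dict[str, float], shift: float) -> dict[str, float]:
    """Exponentially tilt a composition on the KD scale to raise its mean by ``shift``.

    Solves for the tilt parameter with mean(θ) = Σ pᵢe^{θkᵢ}kᵢ / Σ pᵢe^{θkᵢ}
    equal to the base mean plus ``shift``; θ = 0 recovers the input.
    """
    if shift == 0.0:
        return dict(composition)
    probs = np.array([composition[a] for a in AA])
    kd = np.array([KYTE_DOOLITTLE[a] for a in AA])
    target = float(probs @ kd) + shift

    def mean_at(theta: float) -> float:
        w = probs * np.exp(theta * kd)
        w /= w.sum()
        return float(w @ kd) - target

    theta = brentq(mean_at, -10.0, 10.0, xtol=1e-12)
    w = probs * np.exp(theta * kd)
    w /= w.sum()
    return {a: float(v) for a, v in zip(AA, w)}


def _random_kferq_window(rng: np.random.Generator, motif_class: str) -> str:
    """Draw a pentapeptide guaranteed to satisfy one KFERQ-like class rule."""
    anchor = "K" if motif_class == "acetyl_activated" else "Q"
    n_basic = int(rng.integers(1, 3))
    n_hydro = 3 - n_basic
    basics = [("KR")[i] for i in rng.integers(0, 2, n_basic)]
    hydros = [("FILV")[i] for i in rng.integers(0, 4, n_hydro)]
    if motif_class == "phospho_activated":
        acidic = [sorted(PHOSPHO)[int(rng.integers(0, len(PHOSPHO)))]]
    else:
        acidic = [("ED")[int(rng.integers(0, 2))]]
    rest = basics + hydros + acidic
    rng.shuffle(rest)
    window = anchor + "".join(rest) if rng.random() < 0.5 else "".join(rest) + anchor
    assert _window_matches(window, motif_class, PHOSPHO)
    return window


def _motif_strings(motifs) -> tuple[str, ...]:
    if isinstance(motifs, DegronSet):
        return tuple(motifs.motif_strings())
    return tuple(motifs)


def generate_dataset(spec: SyntheticSpec, with_companions: bool = True
                     ) -> tuple[ProteinDataset, pd.DataFrame, dict]:
    """Generate one dataset plus its ground truth and companion score inputs.

    Returns ``(dataset, truth, companions)`` where ``truth`` has one row per
    sequence with every planted feature, and ``companions`` holds
    ``disorder`` ({id: DisorderProfile}), ``topology`` ({id: string}) and
    ``aggregation`` (per-residue DataFrame) when ``with_companions`` is
    true.  All randomness derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    probs = np.array([spec.composition[a] for a in AA])
    aa_codes = np.frombuffer(AA.encode("ascii"), dtype=np.uint8)

    lengths = np.maximum(
        spec.length_floor,
        np.round(rng.lognormal(spec.length_log_mean, spec.length_log_sigma, n)).astype(int),
    )
    total = int(lengths.sum())
    flat = aa_codes[rng.choice(20, size=total, p=probs)]
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    seqs = [bytearray(flat[bounds[i]:bounds[i + 1]].tobytes()) for i in range(n)]

    # --- tail composition tilt -------------------------------------------
    tail_comp = tilted_composition(spec.composition, spec.tail_kd_shift)
    tail_probs = np.array([tail_comp[a] for a in AA])
    if spec.tail_kd_shift != 0.0:
        w = spec.tail_window
        tail_flat = aa_codes[rng.choice(20, size=n * w, p=tail_probs)]
        for i, seq in enumerate(seqs):
            seq[-w:] = tail_flat[i * w:(i + 1) * w].tobytes()

    if spec.start_with_met:
        for seq in seqs:
            seq[0] = ord("M")

    n_motifs = _motif_strings(spec.n_degron_motifs)
    c_motifs = _motif_strings(spec.c_degron_motifs)
    max_c = max((len(m) for m in c_motifs), default=0)

    flags = {
        "n_degron": rng.random(n) < spec.p_n_degron,
        "c_degron": rng.random(n) < spec.p_c_degron,
        "kferq_canonical": rng.random(n) < spec.p_kferq_canonical,
        "kferq_phospho": rng.random(n) < spec.p_kferq_phospho,
        "kferq_acetyl": rng.random(n) < spec.p_kferq_acetyl,
        "ta": rng.random(n) < spec.p_ta,
        "n_idr": rng.random(n) < spec.p_n_idr,
        "c_idr": rng.random(n) < spec.p_c_idr,
    }

    truth_rows = []
    topologies: dict[str, str] = {}
    disorder: dict[str, DisorderProfile] = {}

    for i, seq in enumerate(seqs):
        L = lengths[i]
        rec_id = f"{spec.dataset_label}_{i:05d}"
        protected: list[tuple[int, int]] = []  # 1-based inclusive anchored windows

        # --- tail-anchor architecture ------------------------------------
        ta_planted = bool(flags["ta"][i])
        tmd_start = tmd_end = tail_len = 0
        if ta_planted:
            tmd_len = int(rng.integers(18, 26))
            lo_tail = max_c if (flags["c_degron"][i] and c_motifs) else 0
            tail_len = int(rng.integers(lo_tail, 30))
            tmd_end = int(L - tail_len)
            tmd_start = tmd_end - tmd_len + 1
            block = aa_codes[[AA.index(_TMD_RESIDUES[j])
                              for j in rng.choice(len(_TMD_RESIDUES), tmd_len, p=_TMD_WEIGHTS)]]
            seq[tmd_start - 1:tmd_end] = block.tobytes()
            protected.append((tmd_start, tmd_end))
            topologies[rec_id] = "i" * (tmd_start - 1) + "M" * tmd_len + "o" * tail_len
        else:
            topologies[rec_id] = "i" * int(L)

        # --- terminal degrons (anchored; prevalence-exact) ---------------
        n_motif = c_motif = ""
        if n_motifs and spec.p_n_degron > 0:
            start0 = 1 if seq[:1] == b"M" else 0  # 0-based anchor
            if flags["n_degron"][i]:
                n_motif = n_motifs[int(rng.integers(0, len(n_motifs)))]
                seq[start0:start0 + len(n_motif)] = n_motif.encode("ascii")
                protected.append((start0 + 1, start0 + len(n_motif)))
            else:
                for _ in range(_MAX_PLANT_ATTEMPTS):
                    prefix = seq[start0:start0 + max(len(m) for m in n_motifs)].decode("ascii")
                    if not any(prefix.startswith(m) for m in n_motifs):
                        break
                    w = max(len(m) for m in n_motifs)
                    seq[start0:start0 + w] = aa_codes[rng.choice(20, w, p=probs)].tobytes()
                else:
                    raise SpecError("could not scrub accidental N-degron match")
        if c_motifs and spec.p_c_degron > 0:
            if flags["c_degron"][i]:
                c_motif = c_motifs[int(rng.integers(0, len(c_motifs)))]
                seq[-len(c_motif):] = c_motif.encode("ascii")
                protected.append((int(L) - len(c_motif) + 1, int(L)))
            else:
                for _ in range(_MAX_PLANT_ATTEMPTS):
                    suffix = seq[-max_c:].decode("ascii")
                    if not any(suffix.endswith(m) for m in c_motifs):
                        break
                    seq[-max_c:] = aa_codes[rng.choice(20, max_c, p=tail_probs)].tobytes()
                else:
                    raise SpecError("could not scrub accidental C-degron match")

        # --- KFERQ-like pentapeptides (interior, conflict-avoiding) ------
        # keep clear of the anchored terminal windows so planting cannot
        # create or destroy a degron match
        max_n = max((len(m) for m in n_motifs), default=0)
        lo_pos = 2 + (max_n if spec.p_n_degron > 0 else 0)
        hi_pos = int(L) - 4 - (max_c + 1 if spec.p_c_degron > 0 else 1)
        kferq_counts = {"canonical": 0, "phospho_activated": 0, "acetyl_activated": 0}
        for cls, key in (("canonical", "kferq_canonical"),
                         ("phospho_activated", "kferq_phospho"),
                         ("acetyl_activated", "kferq_acetyl")):
            if not flags[key][i]:
                continue
            window = _random_kferq_window(rng, cls)
            for _ in range(_MAX_PLANT_ATTEMPTS):
                pos = int(rng.integers(lo_pos, hi_pos + 1))  # 1-based
                span = (pos, pos + 4)
                if not any(s <= span[1] and span[0] <= e for s, e in protected):
                    seq[pos - 1:pos + 4] = window.encode("ascii")
                    protected.append(span)
                    kferq_counts[cls] = 1
                    break
            else:
                raise SpecError(f"could not place a {cls} KFERQ window without conflicts")

        # --- companion disorder profile with optional terminal runs ------
        if with_companions:
            scores = rng.random(int(L)) * 0.98
            n_idr_planted = bool(flags["n_idr"][i])
            c_idr_planted = bool(flags["c_idr"][i])
            if n_idr_planted:
                run = int(rng.integers(30, 61))
                scores[:run] = 0.501 + 0.499 * rng.random(run)
            if c_idr_planted:
                run = int(rng.integers(30, 61))
                scores[-run:] = 0.501 + 0.499 * rng.random(run)
            disorder[rec_id] = DisorderProfile(rec_id, np.clip(scores, 0.0, 1.0))
        else:
            n_idr_planted = bool(flags["n_idr"][i])
            c_idr_planted = bool(flags["c_idr"][i])

        truth_rows.append({
            "id": rec_id, "length": int(L),
            "ta_planted": ta_planted, "tmd_start": tmd_start, "tmd_end": tmd_end,
            "n_degron_motif": n_motif, "c_degron_motif": c_motif,
            "kferq_canonical_n": kferq_counts["canonical"],
            "kferq_phospho_n": kferq_counts["phospho_activated"],
            "kferq_acetyl_n": kferq_counts["acetyl_activated"],
            "n_idr_planted": n_idr_planted, "c_idr_planted": c_idr_planted,
        })

    records = [ProteinRecord(row["id"], seqs[i].decode("ascii"),
                             dataset_label=spec.dataset_label,
                             start_class="AUG" if spec.start_with_met else "nonAUG")
               for i, row in enumerate(truth_rows)]
    ds = ProteinDataset(spec.dataset_label, records)
    truth = pd.DataFrame(truth_rows)

    companions: dict = {}
    if with_companions:
        companions["topology"] = topologies
        companions["disorder"] = disorder
        agg_rows = []
        for rec in records:
            L = len(rec)
            energies = rng.normal(-2.0, 2.0, L)
            probs_agg = rng.uniform(0.0, 0.02, L)
            agg_rows.append(pd.DataFrame({
                "id": rec.id, "position": np.arange(1, L + 1),
                "energy": energies, "probability": probs_agg,
            }))
        companions["aggregation"] = pd.concat(agg_rows, ignore_index=True)

    _verify_planting(ds, truth, spec)
    return ds, truth, companions


def _verify_planting(ds: ProteinDataset, truth: pd.DataFrame, spec: SyntheticSpec) -> None:
    """Hard assertion: every planted anchored feature is rediscoverable."""
    from .degrons import degron_set_from_pairs

    n_set = (degron_set_from_pairs([(m, -1.0) for m in _motif_strings(spec.n_degron_motifs)], "N")
             if spec.n_degron_motifs else None)
    c_set = (degron_set_from_pairs([(m, -1.0) for m in _motif_strings(spec.c_degron_motifs)], "C")
             if spec.c_degron_motifs else None)
    by_id = {rec.id: rec.sequence for rec in ds}
    for row in truth.itertuples():
        seq = by_id[row.id]
        if row.n_degron_motif and n_set is not None:
            assert any(h.motif == row.n_degron_motif for h in scan_n_degrons(seq, n_set)), row.id
        if row.c_degron_motif and c_set is not None:
            assert any(h.motif == row.c_degron_motif for h in scan_c_degrons(seq, c_set)), row.id


def expected_odds_ratio(p1: float, p2: float) -> float:
    """True odds ratio implied by two planting prevalences (group1 vs group2)."""
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("prevalences must lie strictly inside (0, 1)")
    return (p1 / (1 - p1)) / (p2 / (1 - p2))


# Defaults mirroring the magnitudes reported for canonical-vs-noncanonical
# comparisons: C-end degron prevalence 8.4% vs 16.8% and a +0.15 mean tail
# hydropathy shift in the noncanonical-like group.
DEFAULT_CP_C_DEGRON_PREVALENCE = 0.084
DEFAULT_NCP_C_DEGRON_PREVALENCE = 0.168
DEFAULT_NCP_CTTH_SHIFT = 0.15


def default_two_group_specs(n: int = 5000, seed: int = 0,
                            c_degron_motifs: tuple[str, ...] = ("GG",)
                            ) -> tuple[SyntheticSpec, SyntheticSpec]:
    """CP-like and NCP-like specs for the default two-group study."""
    cp = SyntheticSpec(
        n_sequences=n, dataset_label="CP", seed=child_seed(seed, 0),
        p_c_degron=DEFAULT_CP_C_DEGRON_PREVALENCE, c_degron_motifs=c_degron_motifs,
    )
    ncp = SyntheticSpec(
        n_sequences=n, dataset_label="NCP", seed=child_seed(seed, 1),
        p_c_degron=DEFAULT_NCP_C_DEGRON_PREVALENCE, c_degron_motifs=c_degron_motifs,
        tail_kd_shift=DEFAULT_NCP_CTTH_SHIFT,
    )
    return cp, ncp


def generate_two_group_study(cp_spec: Optional[SyntheticSpec] = None,
                             ncp_spec: Optional[SyntheticSpec] = None,
                             seed: int = 0, n: int = 5000,
                             with_companions: bool = False):
    """Paired CP-like/NCP-like datasets plus truth tables and expected effects.

    Returns ``(cp_ds, ncp_ds, cp_truth, ncp_truth, expected)`` where
    ``expected`` records the true odds ratio and mean-CTTH difference
    implied by the two specs, for parameter-recovery tests.
    """
    if cp_spec is None or ncp_spec is None:
        d_cp, d_ncp = default_two_group_specs(n=n, seed=seed)
        cp_spec = cp_spec or d_cp
        ncp_spec = ncp_spec or d_ncp
    cp_ds, cp_truth, _ = generate_dataset(cp_spec, with_companions=with_companions)
    ncp_ds, ncp_truth, _ = generate_dataset(ncp_spec, with_companions=with_companions)
    expected: dict[str, float] = {
        "true_ctth_diff": ncp_spec.tail_kd_shift - cp_spec.tail_kd_shift,
    }
    if 0 < cp_spec.p_c_degron < 1 and 0 < ncp_spec.p_c_degron < 1:
        expected["true_c_degron_or"] = expected_odds_ratio(
            ncp_spec.p_c_degron, cp_spec.p_c_degron)
    if 0 < cp_spec.p_n_degron < 1 and 0 < ncp_spec.p_n_degron < 1:
        expected["true_n_degron_or"] = expected_odds_ratio(
            ncp_spec.p_n_degron, cp_spec.p_n_degron)
    return cp_ds, ncp_ds, cp_truth, ncp_truth, expected
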