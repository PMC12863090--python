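"""End-to-end orchestration: determinant profiling, group and null comparisons,
lncRNA-localization summaries, and synthetic-bundle simulation.

``profile`` composes the scanner modules into one per-sequence table,
applying the determinant-specific redundancy filters (C-terminal 30-mer
uniqueness before tail-hydropathy scoring, terminal 10-mer uniqueness
before degron scanning, terminal 30-mer uniqueness before disorder calls,
no filter for KFERQ scanning).  Columns for determinants whose input files
were not supplied are left null, never silently defaulted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import shutil
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import disorder_topology as dt
from . import hydropathy as hp
from .degrons import DegronSet, scan_c_degrons, scan_n_degrons
from .kferq import find_kferq_motifs, kferq_summary
from .null_models import child_seed, shuffle_sequence
from .sequences import (ProteinDataset, collapse_terminal_redundancy, write_fasta)
from .stats import (ContingencyTable2x2, DegenerateDataError, bh_adjust,
                    fisher_exact, mcnemar_test, proportion_ci, rank_sum_test,
                    signed_rank_test)
from .synthetic_data import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

#: All configuration defaults (printed analysis parameters).
DEFAULTS: dict[str, float | int] = {
    "tail_window": 30,
    "tail_profile_last_n": 60,
    "degron_dpsi_max": -0.4,
    "degron_terminal_k": 10,
    "ctth_redundancy_k": 30,
    "idr_redundancy_k": 30,
    "idr_min_len": 30,
    "idr_threshold": 0.5,
    "ta_tmd_max": 29,
    "ta_tail_max": 29,
    "ctth_low_quartile": -0.963,
    "ctth_high_quartile": -0.110,
    "rest_hydrophilic": -1.0,
    "rest_hydrophobic": 0.0,
    "agg_energy_max": -5.0,
    "agg_prob_min": 0.01,
    "cyto_ratio_threshold": 0.5,
    "cterm_tmd_margin": 30,
}

ALL_DETERMINANTS = ("ctth", "degrons", "kferq", "idr", "ta", "aggregation", "stability")

CONTINUOUS_COLUMNS = ("ctth", "rest_gravy", "kferq_density", "aggregation_fraction")
BINARY_COLUMNS = ("n_degron_present", "c_degron_present", "n_idr", "c_idr",
                  "both_termini_idr", "ta_like")


def merged_config(config: Optional[Mapping] = None) -> dict:
    cfg = dict(DEFAULTS)
    if config:
        unknown = set(config) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    return cfg


def _check_ids(ds: ProteinDataset, supplied: Iterable[str], what: str) -> None:
    missing = sorted(set(ds.ids()) - set(supplied))
    if missing:
        shown = ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
        raise ValueError(f"{what} inputs missing for {len(missing)} sequence ids: {shown}")


def profile(ds: ProteinDataset,
            config: Optional[Mapping] = None,
            n_degrons: Optional[DegronSet] = None,
            c_degrons: Optional[DegronSet] = None,
            disorder: Optional[Mapping[str, dt.DisorderProfile]] = None,
            topology: Optional[Mapping[str, dt.TopologyAnnotation | str]] = None,
            aggregation: Optional[pd.DataFrame] = None,
            determinants: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Per-sequence determinant profile table.

    Determinants whose required inputs (degron sets, disorder/topology/
    aggregation files) are absent yield null columns.  ``determinants``
    restricts computation to a subset for speed.
    """
    cfg = merged_config(config)
    wanted = tuple(determinants) if determinants is not None else ALL_DETERMINANTS
    for d in wanted:
        if d not in ALL_DETERMINANTS:
            raise ValueError(f"unknown determinant {d!r}")

    df = pd.DataFrame({"id": ds.ids(), "length": [len(r) for r in ds]})
    df = df.set_index("id", drop=False)
    counts: dict[str, int] = {"total": len(ds)}

    if "ctth" in wanted or "stability" in wanted:
        window = int(cfg["tail_window"])
        ctth_ds = collapse_terminal_redundancy(ds, "C", int(cfg["ctth_redundancy_k"]))
        df["ctth"] = np.nan
        df["rest_gravy"] = np.nan
        for rec in ctth_ds:
            if len(rec) > window:
                df.loc[rec.id, "ctth"] = hp.ctth(rec.sequence, window)
                df.loc[rec.id, "rest_gravy"] = hp.rest_gravy(rec.sequence, window)
        counts["ctth"] = int(df["ctth"].notna().sum())

    if "degrons" in wanted:
        k = int(cfg["degron_terminal_k"])
        for terminus, dset, col, scanner in (
                ("N", n_degrons, "n_degron_present", scan_n_degrons),
                ("C", c_degrons, "c_degron_present", scan_c_degrons)):
            df[col] = pd.Series(pd.NA, index=df.index, dtype="boolean")
            if dset is None:
                continue
            sub = collapse_terminal_redundancy(ds, terminus, k)
            for rec in sub:
                df.loc[rec.id, col] = bool(scanner(rec.sequence, dset, rec.id))
            counts[f"{terminus.lower()}_degrons"] = int(df[col].notna().sum())

    if "kferq" in wanted:
        dens, can_n, pho_n, ace_n, has = [], [], [], [], []
        for rec in ds:
            summ = kferq_summary(find_kferq_motifs(rec.sequence, sequence_id=rec.id), len(rec))
            dens.append(summ.density_total)
            can_n.append(summ.counts["canonical"])
            pho_n.append(summ.counts["phospho_activated"])
            ace_n.append(summ.counts["acetyl_activated"])
            has.append(summ.has_any)
        df["kferq_canonical_n"] = can_n
        df["kferq_phospho_n"] = pho_n
        df["kferq_acetyl_n"] = ace_n
        df["kferq_density"] = dens
        df["kferq_has_any"] = has
        counts["kferq"] = len(ds)

    if "idr" in wanted:
        for col in ("n_idr", "c_idr", "both_termini_idr"):
            df[col] = pd.Series(pd.NA, index=df.index, dtype="boolean")
        if disorder is not None:
            _check_ids(ds, disorder.keys(), "disorder")
            k = int(cfg["idr_redundancy_k"])
            for terminus, col in (("N", "n_idr"), ("C", "c_idr")):
                sub = collapse_terminal_redundancy(ds, terminus, k)
                for rec in sub:
                    prof = disorder[rec.id]
                    if len(prof) != len(rec):
                        raise ValueError(f"disorder profile for {rec.id} has length "
                                         f"{len(prof)} != sequence length {len(rec)}")
                    call = dt.call_terminal_idrs(prof, int(cfg["idr_min_len"]),
                                                 float(cfg["idr_threshold"]))
                    df.loc[rec.id, col] = call.n_idr if terminus == "N" else call.c_idr
            both = df["n_idr"] & df["c_idr"]
            df["both_termini_idr"] = both
            counts["idr"] = int((df["n_idr"].notna() & df["c_idr"].notna()).sum())

    topo_by_id: dict[str, dt.TopologyAnnotation] = {}
    if topology is not None:
        for key, val in topology.items():
            topo_by_id[key] = (val if isinstance(val, dt.TopologyAnnotation)
                               else dt.topology_from_string(key, val))

    if "ta" in wanted:
        df["ta_like"] = pd.Series(pd.NA, index=df.index, dtype="boolean")
        if topology is not None:
            _check_ids(ds, topo_by_id.keys(), "topology")
            for rec in ds:
                cls = dt.classify_ta(topo_by_id[rec.id], len(rec),
                                     int(cfg["ta_tmd_max"]), int(cfg["ta_tail_max"]))
                df.loc[rec.id, "ta_like"] = cls.is_ta_like
            counts["ta"] = len(ds)

    if "aggregation" in wanted:
        df["aggregation_fraction"] = np.nan
        if aggregation is not None:
            grouped = dict(tuple(aggregation.groupby("id", sort=False)))
            _check_ids(ds, grouped.keys(), "aggregation")
            for rec in ds:
                sub = grouped[rec.id]
                df.loc[rec.id, "aggregation_fraction"] = dt.aggregation_fraction(
                    sub["energy"].to_numpy(), sub["probability"].to_numpy(),
                    len(rec), float(cfg["agg_energy_max"]), float(cfg["agg_prob_min"]))
            counts["aggregation"] = len(ds)

    if "stability" in wanted:
        df["stability_pattern"] = pd.Series(pd.NA, index=df.index, dtype="string")
        margin = int(cfg["cterm_tmd_margin"])
        for rec in ds:
            cv = df.loc[rec.id, "ctth"]
            rv = df.loc[rec.id, "rest_gravy"]
            if pd.isna(cv) or pd.isna(rv):
                continue
            cterm_tmd = (dt.has_cterm_tmd(topo_by_id[rec.id], len(rec), margin)
                         if rec.id in topo_by_id else False)
            call = hp.classify_stability_pattern(
                float(cv), float(rv), cterm_tmd,
                float(cfg["ctth_low_quartile"]), float(cfg["ctth_high_quartile"]),
                float(cfg["rest_hydrophilic"]), float(cfg["rest_hydrophobic"]))
            df.loc[rec.id, "stability_pattern"] = call.pattern

    df = df.reset_index(drop=True)
    df.attrs["analyzable_counts"] = counts
    logger.info("profile(%s): analyzable counts %s", ds.name, counts)
    return df


def _report_row(determinant: str, comp, note: str = "") -> dict:
    ci = comp.ci if comp is not None and comp.ci else (math.nan, math.nan, math.nan)
    return {
        "determinant": determinant,
        "test": comp.test if comp else "",
        "n1": comp.n1 if comp else 0,
        "n2": comp.n2 if comp else 0,
        "statistic": comp.statistic if comp else math.nan,
        "p_raw": comp.p_raw if comp else math.nan,
        "effect_name": comp.effect_name if comp else "",
        "effect_value": comp.effect_value if comp else math.nan,
        "ci_low": ci[0], "ci_high": ci[1],
        "note": note,
    }


def compare(profile_a: pd.DataFrame, profile_b: pd.DataFrame,
            config: Optional[Mapping] = None) -> pd.DataFrame:
    """Two-group comparison report across all shared determinant columns.

    Continuous determinants: Wilcoxon rank-sum with rank-biserial effect.
    Binary determinants: Fisher's exact test with the odds ratio, plus
    per-group Wilson proportion CIs.  P values are BH-adjusted within the
    report.
    """
    merged_config(config)
    if len(profile_a) == 0 or len(profile_b) == 0:
        raise ValueError("profiles must be non-empty")
    rows = []
    for col in CONTINUOUS_COLUMNS:
        if col not in profile_a.columns or col not in profile_b.columns:
            logger.info("compare: determinant %s missing from a profile; skipped", col)
            continue
        x = profile_a[col].dropna().to_numpy(dtype=float)
        y = profile_b[col].dropna().to_numpy(dtype=float)
        if len(x) == 0 or len(y) == 0:
            continue
        try:
            rows.append(_report_row(col, rank_sum_test(x, y)))
        except DegenerateDataError as exc:
            rows.append(_report_row(col, None, note=str(exc)))
    for col in BINARY_COLUMNS:
        if col not in profile_a.columns or col not in profile_b.columns:
            logger.info("compare: determinant %s missing from a profile; skipped", col)
            continue
        xa = profile_a[col].dropna().astype(bool)
        xb = profile_b[col].dropna().astype(bool)
        if len(xa) == 0 or len(xb) == 0:
            continue
        table = ContingencyTable2x2.from_flags(xa.to_numpy(), xb.to_numpy())
        row = _report_row(col, fisher_exact(table))
        lo1, hi1 = proportion_ci(table.a, table.a + table.b)
        lo2, hi2 = proportion_ci(table.c, table.c + table.d)
        row.update({"prop1": table.a / (table.a + table.b),
                    "prop1_ci_low": lo1, "prop1_ci_high": hi1,
                    "prop2": table.c / (table.c + table.d),
                    "prop2_ci_low": lo2, "prop2_ci_high": hi2})
        rows.append(row)
    report = pd.DataFrame(rows)
    if len(report):
        mask = report["p_raw"].notna()
        report["p_bh"] = np.nan
        report.loc[mask, "p_bh"] = bh_adjust(report.loc[mask, "p_raw"].tolist())
    return report


def null_compare(ds: ProteinDataset, config: Optional[Mapping] = None, seed: int = 0,
                 n_degrons: Optional[DegronSet] = None,
                 c_degrons: Optional[DegronSet] = None,
                 use_surrogate_disorder: bool = False) -> pd.DataFrame:
    """Original-vs-shuffled paired comparison report.

    Each sequence is shuffled once (composition-preserving) with a child
    seed derived from ``seed`` and its ordinal.  Continuous determinants are
    tested with the signed-rank test on paired deltas, binary ones with
    McNemar's test on the discordant counts.  Determinants needing external
    predictor files are computed only when the deterministic surrogate
    disorder generator is enabled.
    """
    from .sequences import ProteinRecord

    cfg = merged_config(config)
    shuffled_records = []
    for ordinal, rec in enumerate(ds.records):
        cseed = child_seed(seed, ordinal, 1)
        res = shuffle_sequence(rec.sequence, cseed, rec.id, 1)
        shuffled_records.append(ProteinRecord(rec.id, res.shuffled_sequence,
                                              dataset_label=rec.dataset_label,
                                              start_class=rec.start_class))
    shuffled = ProteinDataset(f"{ds.name}|shuffled", shuffled_records)

    determinants = ["ctth", "degrons", "kferq"]
    kwargs: dict = {"n_degrons": n_degrons, "c_degrons": c_degrons}
    if use_surrogate_disorder:
        determinants.append("idr")
        kwargs_orig = dict(kwargs, disorder={r.id: dt.surrogate_disorder(r.sequence, r.id)
                                             for r in ds})
        kwargs_shuf = dict(kwargs, disorder={r.id: dt.surrogate_disorder(r.sequence, r.id)
                                             for r in shuffled})
    else:
        kwargs_orig = kwargs_shuf = kwargs

    prof_o = profile(ds, cfg, determinants=determinants, **kwargs_orig)
    prof_s = profile(shuffled, cfg, determinants=determinants, **kwargs_shuf)
    prof_o = prof_o.set_index("id")
    prof_s = prof_s.set_index("id")
    common = prof_o.index.intersection(prof_s.index)

    rows = []
    for col in CONTINUOUS_COLUMNS:
        if col not in prof_o.columns:
            continue
        pair = pd.DataFrame({"o": prof_o.loc[common, col],
                             "s": prof_s.loc[common, col]}).dropna()
        if len(pair) == 0:
            continue
        deltas = (pair["o"] - pair["s"]).to_numpy(dtype=float)
        try:
            rows.append(_report_row(col, signed_rank_test(deltas)))
        except DegenerateDataError as exc:
            rows.append(_report_row(col, None, note=str(exc)))
    for col in BINARY_COLUMNS:
        if col not in prof_o.columns:
            continue
        pair = pd.DataFrame({"o": prof_o.loc[common, col],
                             "s": prof_s.loc[common, col]}).dropna()
        if len(pair) == 0:
            continue
        o = pair["o"].astype(bool).to_numpy()
        s = pair["s"].astype(bool).to_numpy()
        b = int((o & ~s).sum())
        c = int((~o & s).sum())
        try:
            rows.append(_report_row(col, mcnemar_test(b, c)))
        except DegenerateDataError as exc:
            rows.append(_report_row(col, None, note=str(exc)))
    report = pd.DataFrame(rows)
    if len(report):
        mask = report["p_raw"].notna()
        report["p_bh"] = np.nan
        report.loc[mask, "p_bh"] = bh_adjust(report.loc[mask, "p_raw"].tolist())
    return report


def localization_summary(table: pd.DataFrame, threshold: float = 0.5,
                         kind: str = "fpkm") -> tuple[pd.DataFrame, pd.DataFrame]:
    """LncRNA subcellular localization records and translation cross-tabulations.

    ``kind`` declares the expression columns: ``"fpkm"`` expects per-
    compartment ``cyt``/``nuc`` values, ``"cyto_ratio"`` a precomputed
    ``ratio`` in [0, 1], ``"rci"`` a log2 cytoplasm/nucleus concentration
    index.  Duplicate transcript rows are averaged (arithmetic mean) before
    any ratio is derived.  A ``translated`` boolean column drives the
    Fisher cross-tab; an optional ``ctth`` column adds a rank-sum
    comparison of tail hydropathy between cytoplasmic and nuclear
    transcripts.
    """
    if kind not in ("fpkm", "cyto_ratio", "rci"):
        raise ValueError(f"unknown kind {kind!r}")
    if "transcript_id" not in table.columns:
        raise ValueError("table must have a transcript_id column")
    value_cols = {"fpkm": ["cyt", "nuc"], "cyto_ratio": ["ratio"], "rci": ["rci"]}[kind]
    for col in value_cols:
        if col not in table.columns:
            raise ValueError(f"kind={kind!r} requires column {col!r}")
    if kind == "fpkm" and ((table["cyt"] < 0).any() or (table["nuc"] < 0).any()):
        raise ValueError("negative expression values")

    agg_spec = {c: "mean" for c in value_cols}
    for extra in ("translated", "ctth"):
        if extra in table.columns:
            agg_spec[extra] = "first"
    rec = table.groupby("transcript_id", sort=False, as_index=False).agg(agg_spec)

    if kind == "fpkm":
        cyt, nuc = rec["cyt"], rec["nuc"]
        denom = cyt + nuc
        rec["cytoplasmic_ratio"] = np.where(denom > 0, cyt / denom, np.nan)
        rec["rci"] = np.where((cyt > 0) & (nuc > 0), np.log2(cyt.replace(0, np.nan) /
                                                            nuc.replace(0, np.nan)), np.nan)
    elif kind == "cyto_ratio":
        r = rec["ratio"]
        if ((r < 0) | (r > 1)).any():
            raise ValueError("cytoplasmic ratio must lie in [0, 1]")
        rec["cytoplasmic_ratio"] = r
        # RCI is finite only when both compartments have signal
        with np.errstate(divide="ignore", invalid="ignore"):
            rci = np.log2(r / (1 - r))
        rec["rci"] = np.where((r > 0) & (r < 1), rci, np.nan)
    else:
        rec["cytoplasmic_ratio"] = 2.0 ** rec["rci"] / (1 + 2.0 ** rec["rci"])

    rec["cytoplasmic"] = rec["cytoplasmic_ratio"] > threshold

    comp_rows = []
    if "translated" in rec.columns:
        valid = rec.dropna(subset=["cytoplasmic_ratio"])
        t = valid["translated"].astype(bool)
        c = valid["cytoplasmic"].astype(bool)
        table22 = ContingencyTable2x2(int((t & c).sum()), int((t & ~c).sum()),
                                      int((~t & c).sum()), int((~t & ~c).sum()))
        comp_rows.append(_report_row("translated_x_cytoplasmic", fisher_exact(table22)))
    if "ctth" in rec.columns:
        sub = rec.dropna(subset=["ctth", "cytoplasmic_ratio"])
        x = sub.loc[sub["cytoplasmic"], "ctth"].to_numpy(dtype=float)
        y = sub.loc[~sub["cytoplasmic"], "ctth"].to_numpy(dtype=float)
        if len(x) and len(y):
            try:
                comp_rows.append(_report_row("ctth_by_localization", rank_sum_test(x, y)))
            except DegenerateDataError as exc:
                comp_rows.append(_report_row("ctth_by_localization", None, note=str(exc)))
    return rec, pd.DataFrame(comp_rows)


_FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def simulate(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write a synthetic bundle (FASTA + companions + truth + expected effects).

    Outputs are written atomically: everything goes to a temporary
    directory first and is moved into place only on success.  Returns the
    manifest (relative path → sha256).
    """
    out_dir = Path(out_dir)
    ds, truth, companions = generate_dataset(spec, with_companions=True)
    tmp = Path(tempfile.mkdtemp(prefix=".simulate-", dir=out_dir.parent
                                if out_dir.parent.exists() else None))
    try:
        write_fasta(ds, tmp / "sequences.fasta")
        _write_tsv(truth, tmp / "truth.tsv")
        with open(tmp / "disorder.txt", "w") as fh:
            for rec_id, prof in companions["disorder"].items():
                fh.write(f"# {rec_id}\n")
                for pos, score in enumerate(prof.scores, 1):
                    fh.write(f"{pos}\t-\t{score:.6f}\n")
        with open(tmp / "topology.txt", "w") as fh:
            for rec_id, topo in companions["topology"].items():
                fh.write(f">{rec_id}\n{topo}\n")
        _write_tsv(companions["aggregation"], tmp / "aggregation.tsv")
        expected = {
            "n_sequences": spec.n_sequences,
            "p_n_degron": spec.p_n_degron, "p_c_degron": spec.p_c_degron,
            "p_ta": spec.p_ta, "p_n_idr": spec.p_n_idr, "p_c_idr": spec.p_c_idr,
            "tail_kd_shift": spec.tail_kd_shift,
            "seed": spec.seed,
        }
        with open(tmp / "expected_effects.json", "w") as fh:
            json.dump(expected, fh, indent=2, sort_keys=True)

        manifest = {}
        for p in sorted(tmp.iterdir()):
            manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        with open(tmp / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

        out_dir.mkdir(parents=True, exist_ok=True)
        for p in sorted(tmp.iterdir()):
            os.replace(p, out_dir / p.name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    logger.info("simulate: wrote %d files to %s", len(manifest) + 1, out_dir)
    return manifest
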