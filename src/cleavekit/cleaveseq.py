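"""Cleavage-assay read counting and fold-change statistics.

The atomic measurement is a pair of read counts per (sensor, condition):
``a`` reads carrying the cleaved-molecule prefix and ``b`` reads carrying
the uncleaved-molecule prefix.  The cleavage fraction is ``a/(a+b)`` and
the fold change of cleavage between a no-ligand reference condition and a
with-ligand test condition is the odds ratio

    fc = (a_ref * b_test) / (b_ref * a_test)

computed on Haldane-Anscombe ½-pseudocounted counts and divided by a
reference-sequence normalization factor ``k``.  On the log scale the
delta-method standard error is sqrt(1/a' + 1/b' + 1/c' + 1/d'), giving
normal-approximation confidence intervals and a two-sided p-value; the
experiment-wide significance rule is Bonferroni (p < 1/N) plus read-depth
and effect-size floors.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "CountTable",
    "FoldChangeRecord",
    "ReadCounts",
    "count_reads",
    "normalize_by_references",
    "fold_change",
    "fold_change_frame",
    "fold_change_table",
    "call_significant",
]

_Z90 = stats.norm.ppf(0.95)
_Z95 = stats.norm.ppf(0.975)


@dataclass
class CountTable:
    """Cleaved/uncleaved read counts per (sensor, condition)."""

    df: pd.DataFrame

    REQUIRED = ("sensor_id", "condition_id", "cleaved", "uncleaved")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise InputError(f"count table missing columns: {missing}")
        if (self.df[["cleaved", "uncleaved"]] < 0).any().any():
            raise InputError("counts must be non-negative")
        if self.df.duplicated(["sensor_id", "condition_id"]).any():
            raise InputError("(sensor_id, condition_id) pairs must be unique")

    def condition(self, condition_id: str) -> pd.DataFrame:
        """Counts for one condition, indexed by sensor_id."""
        sub = self.df[self.df["condition_id"] == condition_id]
        return sub.set_index("sensor_id")[["cleaved", "uncleaved"]]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def concat(cls, tables: Iterable["CountTable"]) -> "CountTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))


@dataclass(frozen=True)
class FoldChangeRecord:
    """Fold change of cleavage for one sensor across one condition pair."""

    sensor_id: str
    condition_pair: tuple[str, str]  # (reference, test)
    cleavage_fraction_ref: float
    cleavage_fraction_test: float
    fc: float
    log_fc: float
    se_log_fc: float
    ci90: tuple[float, float]
    ci95: tuple[float, float]
    p_value: float
    n_reads_ref: int
    n_reads_test: int
    significant: bool = False

    @property
    def n_total_reads(self) -> int:
        return self.n_reads_ref + self.n_reads_test


@dataclass
class ReadCounts:
    """Result of read counting: the count table plus the unassigned tally."""

    table: CountTable
    n_total: int
    n_unassigned: int
    unassigned_reasons: Counter


def _hamming_leq(a: str, b: str, tol: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > tol:
                return False
    return True


def count_reads(
    reads: str | Path,
    prefix_map: Mapping[str, str],
    suffix: str,
    library: Sequence | None = None,
    barcode_table: Mapping[str, str] | None = None,
    mismatch_tolerance: int = 0,
    condition_id: str = "condition",
    fmt: str | None = None,
) -> ReadCounts:
    """Demultiplex reads into a cleaved/uncleaved count table.

    Each read is assigned a condition (exact barcode match, if a
    ``barcode_table`` barcode -> condition_id mapping is given), a cleavage
    state (cleaved/uncleaved prefix within ``mismatch_tolerance``), and a
    sensor (exact insert identity; mapped to sensor ids via ``library``
    templates when provided, otherwise keyed by the insert sequence itself).
    Unassignable reads are tallied with reasons, never silently dropped.
    """
    from Bio import SeqIO

    path = Path(reads)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".fna") else "fastq"
    pz, pw = prefix_map["cleaved"], prefix_map["uncleaved"]
    if _hamming_leq(pz, pw, 2 * mismatch_tolerance):
        raise InputError("prefixes are not distinguishable at this mismatch tolerance")

    template_to_sensor = (
        {r.template_seq: r.sensor_id for r in library} if library is not None else {}
    )
    barcodes = sorted(barcode_table or {}, key=len, reverse=True)

    counts: Counter = Counter()
    reasons: Counter = Counter()
    n_total = 0
    for rec in SeqIO.parse(str(path), fmt):
        n_total += 1
        seq = str(rec.seq)
        cond = condition_id
        if barcode_table:
            for bc in barcodes:
                if seq.startswith(bc):
                    cond = barcode_table[bc]
                    seq = seq[len(bc):]
                    break
            else:
                reasons["no_barcode"] += 1
                continue
        hit_z = _hamming_leq(seq[: len(pz)], pz, mismatch_tolerance)
        hit_w = _hamming_leq(seq[: len(pw)], pw, mismatch_tolerance)
        if hit_z == hit_w:  # neither, or ambiguous
            reasons["ambiguous_prefix" if hit_z else "no_prefix"] += 1
            continue
        state = "cleaved" if hit_z else "uncleaved"
        body = seq[len(pz) if hit_z else len(pw):]
        if not _hamming_leq(body[-len(suffix):], suffix, mismatch_tolerance):
            reasons["no_suffix"] += 1
            continue
        insert = body[: -len(suffix)]
        sensor = template_to_sensor.get(insert, insert)
        counts[(sensor, cond, state)] += 1

    keys = sorted({(s, c) for (s, c, _) in counts})
    df = pd.DataFrame(
        {
            "sensor_id": [s for s, _ in keys],
            "condition_id": [c for _, c in keys],
            "cleaved": [counts[(s, c, "cleaved")] for s, c in keys],
            "uncleaved": [counts[(s, c, "uncleaved")] for s, c in keys],
        }
    )
    n_unassigned = int(sum(reasons.values()))
    return ReadCounts(CountTable(df), n_total, n_unassigned, reasons)


def fold_change_frame(
    a_ref,
    b_ref,
    a_test,
    b_test,
    k: float = 1.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Vectorized fold-change statistics on raw count arrays.

    Returns a frame with cleavage fractions, fc, log_fc, se_log_fc, CI
    bounds at 90% and 95%, the two-sided normal p-value, and per-condition
    read totals.  Zero-safe through the pseudocount.
    """
    a_ref = np.asarray(a_ref, dtype=float)
    b_ref = np.asarray(b_ref, dtype=float)
    a_test = np.asarray(a_test, dtype=float)
    b_test = np.asarray(b_test, dtype=float)
    if (np.concatenate([np.atleast_1d(x) for x in (a_ref, b_ref, a_test, b_test)]) < 0).any():
        raise InputError("counts must be non-negative")
    ar, br = a_ref + pseudocount, b_ref + pseudocount
    at, bt = a_test + pseudocount, b_test + pseudocount
    log_fc = np.log(ar) + np.log(bt) - np.log(br) - np.log(at) - np.log(k)
    se = np.sqrt(1.0 / ar + 1.0 / br + 1.0 / at + 1.0 / bt)
    z = log_fc / se
    p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    p = np.maximum(p, np.finfo(float).tiny)
    n_ref = a_ref + b_ref
    n_test = a_test + b_test
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_ref = np.where(n_ref > 0, a_ref / np.maximum(n_ref, 1), np.nan)
        frac_test = np.where(n_test > 0, a_test / np.maximum(n_test, 1), np.nan)
    return pd.DataFrame(
        {
            "cleavage_fraction_ref": np.atleast_1d(frac_ref),
            "cleavage_fraction_test": np.atleast_1d(frac_test),
            "fc": np.atleast_1d(np.exp(log_fc)),
            "log_fc": np.atleast_1d(log_fc),
            "se_log_fc": np.atleast_1d(se),
            "ci90_lo": np.atleast_1d(np.exp(log_fc - _Z90 * se)),
            "ci90_hi": np.atleast_1d(np.exp(log_fc + _Z90 * se)),
            "ci95_lo": np.atleast_1d(np.exp(log_fc - _Z95 * se)),
            "ci95_hi": np.atleast_1d(np.exp(log_fc + _Z95 * se)),
            "p_value": np.atleast_1d(p),
            "n_reads_ref": np.atleast_1d(n_ref).astype(int),
            "n_reads_test": np.atleast_1d(n_test).astype(int),
        }
    )


def fold_change(
    a_ref: int,
    b_ref: int,
    a_test: int,
    b_test: int,
    k: float = 1.0,
    pseudocount: float = 0.5,
    sensor_id: str = "",
    condition_pair: tuple[str, str] = ("reference", "test"),
) -> FoldChangeRecord:
    """Fold change of cleavage for one sensor from its four raw counts."""
    row = fold_change_frame(a_ref, b_ref, a_test, b_test, k, pseudocount).iloc[0]
    return FoldChangeRecord(
        sensor_id=sensor_id,
        condition_pair=condition_pair,
        cleavage_fraction_ref=float(row.cleavage_fraction_ref),
        cleavage_fraction_test=float(row.cleavage_fraction_test),
        fc=float(row.fc),
        log_fc=float(row.log_fc),
        se_log_fc=float(row.se_log_fc),
        ci90=(float(row.ci90_lo), float(row.ci90_hi)),
        ci95=(float(row.ci95_lo), float(row.ci95_hi)),
        p_value=float(row.p_value),
        n_reads_ref=int(row.n_reads_ref),
        n_reads_test=int(row.n_reads_test),
    )


def normalize_by_references(
    table_ref_condition: pd.DataFrame,
    table_test_condition: pd.DataFrame,
    reference_ids: Iterable[str],
    min_reads: int = 100,
    min_references: int = 3,
) -> float:
    """Odds-ratio normalization factor ``k`` from unresponsive references.

    ``k`` is the median raw fold change over reference sensors with at
    least ``min_reads`` total reads in both conditions; downstream fold
    changes are divided by ``k``.  With fewer than ``min_references``
    usable references a warning is issued and ``k = 1``.

    Both inputs are sensor-indexed frames with ``cleaved``/``uncleaved``
    columns (see :meth:`CountTable.condition`).
    """
    usable = []
    for rid in reference_ids:
        if rid not in table_ref_condition.index or rid not in table_test_condition.index:
            continue
        ar, br = table_ref_condition.loc[rid, ["cleaved", "uncleaved"]]
        at, bt = table_test_condition.loc[rid, ["cleaved", "uncleaved"]]
        if ar + br >= min_reads and at + bt >= min_reads:
            usable.append(
                float(fold_change_frame(ar, br, at, bt)["fc"].iloc[0])
            )
    if len(usable) < min_references:
        warnings.warn(
            f"only {len(usable)} usable reference sensors (< {min_references}); "
            "using k = 1",
            stacklevel=2,
        )
        return 1.0
    return float(np.median(usable))


def fold_change_table(
    table: CountTable,
    ref_condition: str,
    test_condition: str,
    reference_ids: Iterable[str] | None = None,
    k: float | None = None,
    pseudocount: float = 0.5,
    min_reads_norm: int = 100,
) -> pd.DataFrame:
    """Per-sensor fold-change statistics between two conditions of a table.

    If ``reference_ids`` is given and ``k`` is not, the normalization factor
    is estimated from those references first.  Sensors absent from either
    condition get zero counts there (fully pseudocounted).
    """
    ref = table.condition(ref_condition)
    test = table.condition(test_condition)
    sensors = sorted(set(ref.index) | set(test.index))
    ref = ref.reindex(sensors, fill_value=0)
    test = test.reindex(sensors, fill_value=0)
    if k is None:
        if reference_ids is not None:
            k = normalize_by_references(ref, test, reference_ids, min_reads=min_reads_norm)
        else:
            k = 1.0
    out = fold_change_frame(
        ref["cleaved"].to_numpy(),
        ref["uncleaved"].to_numpy(),
        test["cleaved"].to_numpy(),
        test["uncleaved"].to_numpy(),
        k=k,
        pseudocount=pseudocount,
    )
    out.insert(0, "sensor_id", sensors)
    out.insert(1, "ref_condition", ref_condition)
    out.insert(2, "test_condition", test_condition)
    out.attrs["k"] = k
    return out


def call_significant(
    records: pd.DataFrame,
    n_tested: int,
    min_reads: int = 100,
    fc_threshold: float = 2.0,
    detect_inverse: bool = False,
) -> pd.DataFrame:
    """Flag Bonferroni-significant responders.

    A record is significant iff p < 1/``n_tested`` and both conditions have
    at least ``min_reads`` total reads and fc >= ``fc_threshold`` (or
    fc <= 1/``fc_threshold`` as well, with ``detect_inverse``).
    """
    if n_tested < 1:
        raise InputError("n_tested must be >= 1")
    effect = records["fc"] >= fc_threshold
    if detect_inverse:
        effect = effect | (records["fc"] <= 1.0 / fc_threshold)
    out = records.copy()
    out["significant"] = (
        (records["p_value"] < 1.0 / n_tested)
        & (records["n_reads_ref"] >= min_reads)
        & (records["n_reads_test"] >= min_reads)
        & effect
    )
    return out
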