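"""Pooled LC-MS identity verification of a mixed compound library.

Each compound is expected in a known subset of pools (five, in the standard
design slice) and absent from control pools.  For every compound we look
for a positive-mode adduct peak (M+H, M+Na, M+NH4; singly charged) at a
consistent retention time across the runs: the winning (adduct, RT-cluster)
signature must appear in at least ``presence_min`` expected pools and at
most ``fp_max`` control pools to call the compound identified.  A compound
whose winning m/z collides with another library member's expected adducts
within tolerance is called ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "ADDUCT_SHIFTS",
    "PeakRecord",
    "IdentificationCall",
    "expected_adduct_mz",
    "identify_compound",
    "library_report",
    "simulate_pool_peaks",
    "read_peak_csv",
]

# Singly-charged positive-mode adduct mass shifts (Da).
ADDUCT_SHIFTS = {"M+H": 1.00728, "M+Na": 21.98192, "M+NH4": 18.03383}

PEAK_COLUMNS = ("pool_id", "mz", "rt", "intensity")


@dataclass(frozen=True)
class PeakRecord:
    """One LC-MS peak in one pool run."""

    pool_id: str
    mz: float
    rt: float  # minutes
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.rt < 0:
            raise InputError("peak must have mz > 0 and rt >= 0")


@dataclass(frozen=True)
class IdentificationCall:
    compound_id: str
    status: str  # identified | ambiguous | unassigned
    adduct: str | None
    rt: float | None
    n_expected_present: int
    n_control_present: int


def expected_adduct_mz(mono_mass: float, adduct: str) -> float:
    """Expected m/z of a singly-charged adduct of a neutral mass."""
    if adduct not in ADDUCT_SHIFTS:
        raise ConfigurationError(f"unknown adduct {adduct!r}")
    if mono_mass <= 0:
        raise InputError("mono_mass must be positive")
    return mono_mass + ADDUCT_SHIFTS[adduct]


def read_peak_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"peak CSV missing columns: {missing}")
    return df


def _match_peaks(peaks: pd.DataFrame, target_mz: float, ppm_tol: float) -> pd.DataFrame:
    tol = target_mz * ppm_tol * 1e-6
    return peaks[(peaks["mz"] - target_mz).abs() <= tol]


def _rt_clusters(rts: np.ndarray, rt_tol: float) -> list[np.ndarray]:
    """Greedy single-linkage RT clustering: split at gaps > rt_tol."""
    if len(rts) == 0:
        return []
    order = np.argsort(rts)
    clusters, current = [], [order[0]]
    for i in order[1:]:
        if rts[i] - rts[current[-1]] <= rt_tol:
            current.append(i)
        else:
            clusters.append(np.array(current))
            current = [i]
    clusters.append(np.array(current))
    return clusters


def identify_compound(
    compound,
    expected_pools: Mapping[str, pd.DataFrame],
    control_pools: Mapping[str, pd.DataFrame],
    ppm_tol: float = 10.0,
    rt_tol: float = 0.1,
    presence_min: int = 4,
    fp_max: int = 0,
    library: Sequence | None = None,
    adducts: Sequence[str] = tuple(ADDUCT_SHIFTS),
) -> IdentificationCall:
    """Search for a unique (adduct, retention time) signature of a compound.

    For each adduct, peaks matching the expected m/z (within ``ppm_tol``)
    across all expected and control pool runs are clustered by retention
    time; the signature maximizing expected-pool presence, then minimizing
    control-pool presence, then maximizing mean intensity wins.  ``library``
    (other CompoundRecords) enables the ambiguity check.
    """
    best = None  # (n_expected, -n_control, mean_intensity, adduct, rt)
    for adduct in adducts:
        target = expected_adduct_mz(compound.mono_mass, adduct)
        rows = []
        for pool_id, peaks in expected_pools.items():
            m = _match_peaks(peaks, target, ppm_tol)
            rows.extend((pool_id, True, rt, it) for rt, it in zip(m["rt"], m["intensity"]))
        for pool_id, peaks in control_pools.items():
            m = _match_peaks(peaks, target, ppm_tol)
            rows.extend((pool_id, False, rt, it) for rt, it in zip(m["rt"], m["intensity"]))
        if not rows:
            continue
        pool_ids = np.array([r[0] for r in rows])
        is_exp = np.array([r[1] for r in rows])
        rts = np.array([r[2] for r in rows], dtype=float)
        its = np.array([r[3] for r in rows], dtype=float)
        for idx in _rt_clusters(rts, rt_tol):
            n_exp = len(set(pool_ids[idx][is_exp[idx]]))
            n_ctl = len(set(pool_ids[idx][~is_exp[idx]]))
            key = (n_exp, -n_ctl, float(its[idx].mean()), adduct, float(np.median(rts[idx])))
            if best is None or key[:3] > best[:3]:
                best = key
    if best is None:
        return IdentificationCall(compound.compound_id, "unassigned", None, None, 0, 0)
    n_exp, neg_ctl, _, adduct, rt = best
    n_ctl = -neg_ctl
    if n_exp < presence_min or n_ctl > fp_max:
        return IdentificationCall(compound.compound_id, "unassigned", adduct, rt, n_exp, n_ctl)
    status = "identified"
    if library is not None:
        win_mz = expected_adduct_mz(compound.mono_mass, adduct)
        tol = win_mz * ppm_tol * 1e-6
        for other in library:
            if other.compound_id == compound.compound_id:
                continue
            for a in adducts:
                if abs(expected_adduct_mz(other.mono_mass, a) - win_mz) <= tol:
                    status = "ambiguous"
                    break
            if status == "ambiguous":
                break
    return IdentificationCall(compound.compound_id, status, adduct, rt, n_exp, n_ctl)


def library_report(calls: Sequence[IdentificationCall]) -> tuple[pd.DataFrame, pd.Series]:
    """Per-compound call table plus per-status counts and fractions."""
    df = pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in calls],
            "status": [c.status for c in calls],
            "adduct": [c.adduct for c in calls],
            "rt": [c.rt for c in calls],
            "n_expected_present": [c.n_expected_present for c in calls],
            "n_control_present": [c.n_control_present for c in calls],
        }
    )
    counts = df["status"].value_counts() if len(df) else pd.Series(dtype=int)
    summary = pd.Series(
        {
            "n_total": len(df),
            **{f"n_{s}": int(counts.get(s, 0)) for s in ("identified", "ambiguous", "unassigned")},
            **{
                f"frac_{s}": (counts.get(s, 0) / len(df) if len(df) else 0.0)
                for s in ("identified", "ambiguous", "unassigned")
            },
        }
    )
    return df, summary


def simulate_pool_peaks(
    compounds: Sequence,
    membership: Mapping[str, Sequence[str]],
    pool_ids: Sequence[str],
    dropout: float = 0.0,
    rt_range: tuple[float, float] = (0.5, 29.5),
    mz_jitter_ppm: float = 2.0,
    rt_jitter: float = 0.02,
    noise_peaks_per_pool: int = 0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Generate synthetic LC-MS peak lists for pooled mixtures.

    Each compound gets a latent retention time uniform over ``rt_range``;
    in every pool containing it, each adduct yields a peak with log-normal
    intensity and small m/z/RT jitter, unless the compound-pool observation
    drops out (probability ``dropout``, independent per pool).  Optional
    uniform-random noise peaks emulate background ions.
    """
    rng = np.random.default_rng(seed)
    rts = {c.compound_id: float(rng.uniform(*rt_range)) for c in compounds}
    rows: dict[str, list] = {pid: [] for pid in pool_ids}
    for c in compounds:
        for pid in membership.get(c.compound_id, ()):
            if pid not in rows:
                continue
            if rng.random() < dropout:
                continue
            for adduct, rel in (("M+H", 1.0), ("M+Na", 0.3), ("M+NH4", 0.2)):
                mz = expected_adduct_mz(c.mono_mass, adduct)
                mz *= 1.0 + rng.normal(0.0, mz_jitter_ppm) * 1e-6
                rt = rts[c.compound_id] + rng.normal(0.0, rt_jitter)
                intensity = rel * float(rng.lognormal(10.0, 0.5))
                rows[pid].append((pid, mz, max(rt, 0.0), intensity))
    for pid in pool_ids:
        for _ in range(noise_peaks_per_pool):
            rows[pid].append(
                (
                    pid,
                    float(rng.uniform(100.0, 550.0)),
                    float(rng.uniform(*rt_range)),
                    float(rng.lognormal(8.0, 1.0)),
                )
            )
    return {
        pid: pd.DataFrame(rows[pid], columns=list(PEAK_COLUMNS)).sort_values("mz", ignore_index=True)
        for pid in pool_ids
    }
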