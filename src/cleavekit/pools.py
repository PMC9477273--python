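"""Combinatorial pool design for selection and group-testing deconvolution.

The compound library is split into two selection mixtures (A/B) and, for
deconvolution, into ``n_partitions`` independent partitions of equal-size
pools (e.g. 9 partitions x 20 pools of 256 for a 5,120-compound library,
i.e. 180 pools).  Within any pool, no two members may have expected
positive-mode adduct m/z values within ``mz_window`` of each other, so each
compound remains individually verifiable by LC-MS.  A compound's signature
is the set of pools containing it (one per partition); a sensor responding
to a compound should respond to exactly those pools, which is what the
group-testing decoder exploits.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleDesignError, InputError
from .msverify import ADDUCT_SHIFTS, expected_adduct_mz

__all__ = ["PoolDesign", "split_selection_sets", "design_pools", "decodability_report"]

DEFAULT_ADDUCTS = ("M+H", "M+Na", "M+NH4")


@dataclass
class PoolDesign:
    """Bidirectional compound <-> pool membership over orthogonal partitions."""

    partitions: list[int]
    pools: dict[str, set]  # pool_id -> set of compound_ids
    membership: dict[str, list]  # compound_id -> [pool_id per partition]
    mz_window: float
    adducts: tuple = DEFAULT_ADDUCTS

    def validate(self) -> None:
        compounds = set(self.membership)
        for p in self.partitions:
            part_pools = [pid for pid in self.pools if self._partition_of(pid) == p]
            seen: set = set()
            for pid in part_pools:
                if seen & self.pools[pid]:
                    raise InputError(f"pools overlap within partition {p}")
                seen |= self.pools[pid]
            if seen != compounds:
                raise InputError(f"partition {p} does not cover the library")
        for cid, pids in self.membership.items():
            if len(pids) != len(self.partitions):
                raise InputError(f"{cid} not in exactly one pool per partition")

    @staticmethod
    def _partition_of(pool_id: str) -> int:
        # pool ids look like "V256-3.07"
        return int(pool_id.split("-")[-1].split(".")[0])

    def pools_of(self, compound_id: str) -> list:
        return self.membership[compound_id]

    def audit_mz(self, compounds: Mapping[str, float]) -> list[tuple]:
        """Brute-force all-pairs adduct-m/z audit; returns violating pairs.

        ``compounds`` maps compound_id -> monoisotopic mass (Da).
        """
        violations = []
        for pid, members in self.pools.items():
            mzs = []
            for cid in members:
                for adduct in self.adducts:
                    mzs.append((expected_adduct_mz(compounds[cid], adduct), cid))
            mzs.sort()
            for i in range(len(mzs)):
                j = i + 1
                while j < len(mzs) and mzs[j][0] - mzs[i][0] < self.mz_window:
                    if mzs[i][1] != mzs[j][1]:
                        violations.append((pid, mzs[i][1], mzs[j][1]))
                    j += 1
        return violations

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "partitions": self.partitions,
            "pools": {pid: sorted(m) for pid, m in self.pools.items()},
            "mz_window": self.mz_window,
            "adducts": list(self.adducts),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PoolDesign":
        payload = json.loads(Path(path).read_text())
        pools = {pid: set(m) for pid, m in payload["pools"].items()}
        membership: dict[str, list] = {}
        for pid in sorted(pools):
            for cid in pools[pid]:
                membership.setdefault(cid, []).append(pid)
        return cls(
            partitions=payload["partitions"],
            pools=pools,
            membership=membership,
            mz_window=payload["mz_window"],
            adducts=tuple(payload["adducts"]),
        )

    def to_tsv(self, path: str | Path) -> Path:
        rows = [
            (cid, self._partition_of(pid), pid)
            for cid, pids in sorted(self.membership.items())
            for pid in pids
        ]
        df = pd.DataFrame(rows, columns=["compound_id", "partition", "pool_id"])
        path = Path(path)
        df.to_csv(path, sep="\t", index=False)
        return path


def split_selection_sets(compounds: Sequence, seed: int = 0) -> tuple[list, list]:
    """Randomly split the library into two equal disjoint selection sets."""
    ids = [getattr(c, "compound_id", c) for c in compounds]
    if len(ids) % 2 != 0:
        raise InputError("library size must be even for an equal split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    half = len(ids) // 2
    a = sorted(ids[i] for i in order[:half])
    b = sorted(ids[i] for i in order[half:])
    return a, b


def _compound_masses(compounds) -> dict[str, float]:
    out = {}
    for c in compounds:
        out[c.compound_id] = c.mono_mass
    return out


class _Pool:
    """A pool under construction with a sorted adduct-m/z index."""

    __slots__ = ("members", "mzs")

    def __init__(self) -> None:
        self.members: list[str] = []
        self.mzs: list[float] = []

    def conflicts(self, cand_mzs: Sequence[float], window: float) -> bool:
        for mz in cand_mzs:
            i = bisect_left(self.mzs, mz)
            if i < len(self.mzs) and self.mzs[i] - mz < window:
                return True
            if i > 0 and mz - self.mzs[i - 1] < window:
                return True
        return False

    def add(self, cid: str, cand_mzs: Sequence[float]) -> None:
        self.members.append(cid)
        for mz in cand_mzs:
            insort(self.mzs, mz)


def _greedy_partition(
    ids: list[str],
    adduct_mzs: Mapping[str, tuple],
    n_pools: int,
    pool_size: int,
    window: float,
    rng: np.random.Generator,
    enforce: bool,
) -> list[list[str]] | None:
    order = rng.permutation(len(ids))
    pools = [_Pool() for _ in range(n_pools)]
    leftovers: list[str] = []
    for idx in order:
        cid = ids[idx]
        mzs = adduct_mzs[cid]
        placed = False
        # try least-loaded pools first to keep sizes balanced
        for pool in sorted(pools, key=lambda p: len(p.members)):
            if len(pool.members) >= pool_size:
                continue
            if enforce and pool.conflicts(mzs, window):
                continue
            pool.add(cid, mzs)
            placed = True
            break
        if not placed:
            leftovers.append(cid)
    # swap repair: move a conflicting resident elsewhere to make room
    for cid in list(leftovers):
        mzs = adduct_mzs[cid]
        done = False
        for pool in pools:
            if len(pool.members) >= pool_size:
                continue
            for other in list(pool.members):
                trial = [m for m in pool.members if m != other]
                trial_mzs: list[float] = []
                for t in trial:
                    trial_mzs.extend(adduct_mzs[t])
                trial_mzs.sort()
                tmp = _Pool()
                tmp.members, tmp.mzs = trial, trial_mzs
                if enforce and tmp.conflicts(mzs, window):
                    continue
                # can `other` go somewhere with room, conflict-free?
                for dest in pools:
                    if dest is pool or len(dest.members) >= pool_size:
                        continue
                    if enforce and dest.conflicts(adduct_mzs[other], window):
                        continue
                    dest.add(other, adduct_mzs[other])
                    tmp.add(cid, mzs)
                    pool.members, pool.mzs = tmp.members, tmp.mzs
                    done = True
                    break
                if done:
                    break
            if done:
                break
        if not done:
            return None
        leftovers.remove(cid)
    return [p.members for p in pools]


def _conflict_clique(ids: list[str], adduct_mzs: Mapping[str, tuple], window: float) -> list[str]:
    """A greedy mutually-conflicting set, for infeasibility reporting."""
    def conflict(a: str, b: str) -> bool:
        return any(
            abs(x - y) < window for x in adduct_mzs[a] for y in adduct_mzs[b]
        )

    best: list[str] = []
    for seed_cid in ids:
        clique = [seed_cid]
        for cid in ids:
            if cid != seed_cid and all(conflict(cid, m) for m in clique):
                clique.append(cid)
        if len(clique) > len(best):
            best = clique
    return best


def design_pools(
    compounds: Sequence,
    n_partitions: int,
    pool_size: int,
    mz_window: float = 0.01,
    adducts: Iterable[str] = DEFAULT_ADDUCTS,
    max_restarts: int = 20,
    seed: int = 0,
    enforce_mz: bool = True,
) -> PoolDesign:
    """Partition the library ``n_partitions`` times into equal pools.

    Randomized greedy with swap repair and restarts: per partition, compounds
    are shuffled and each assigned to the least-loaded pool with room and no
    adduct-m/z conflict within ``mz_window``; residual leftovers are placed
    by single-swap repair; a partition that cannot be repaired is restarted
    with a fresh shuffle.  Raises :class:`InfeasibleDesignError` naming the
    tightest conflict clique if any partition fails ``max_restarts`` times.
    """
    if n_partitions < 1:
        raise InputError("n_partitions must be >= 1")
    ids = [c.compound_id for c in compounds]
    if len(ids) % pool_size != 0:
        raise InputError(
            f"pool_size {pool_size} must divide library size {len(ids)}"
        )
    adducts = tuple(adducts)
    for a in adducts:
        if a not in ADDUCT_SHIFTS:
            raise ConfigurationError(f"unknown adduct {a!r}")
    masses = _compound_masses(compounds)
    adduct_mzs = {
        cid: tuple(sorted(expected_adduct_mz(m, a) for a in adducts))
        for cid, m in masses.items()
    }
    n_pools = len(ids) // pool_size
    rng = np.random.default_rng(seed)

    pools: dict[str, set] = {}
    membership: dict[str, list] = {cid: [] for cid in ids}
    for p in range(1, n_partitions + 1):
        result = None
        for _ in range(max_restarts):
            result = _greedy_partition(
                ids, adduct_mzs, n_pools, pool_size, mz_window, rng, enforce_mz
            )
            if result is not None:
                break
        if result is None:
            clique = _conflict_clique(ids, adduct_mzs, mz_window)
            raise InfeasibleDesignError(
                f"partition {p} infeasible after {max_restarts} restarts; "
                f"tightest conflict clique ({len(clique)} compounds, "
                f"{n_pools} pools): {clique[:10]}",
                conflict_clique=clique,
            )
        for q, members in enumerate(result, start=1):
            pid = f"V{pool_size}-{p}.{q:02d}"
            pools[pid] = set(members)
            for cid in members:
                membership[cid].append(pid)

    design = PoolDesign(
        partitions=list(range(1, n_partitions + 1)),
        pools=pools,
        membership=membership,
        mz_window=mz_window,
        adducts=adducts,
    )
    design.validate()
    return design


def decodability_report(
    design: PoolDesign,
    max_targets: int,
    n_samples: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo decodability of target sets of size 1..``max_targets``.

    A target set is decodable when the compounds whose entire pool signature
    lies inside the induced responsive-pool union are exactly the true
    targets.  The reported fraction is made monotone non-increasing in set
    size (it already is in expectation) by a running minimum.
    """
    rng = np.random.default_rng(seed)
    ids = sorted(design.membership)
    sigs = {cid: frozenset(design.membership[cid]) for cid in ids}
    rows = []
    for size in range(1, max_targets + 1):
        hits = 0
        for _ in range(n_samples):
            targets = set(rng.choice(ids, size=size, replace=False))
            responsive = frozenset().union(*(sigs[t] for t in targets))
            candidates = {cid for cid in ids if sigs[cid] <= responsive}
            hits += candidates == targets
        rows.append({"set_size": size, "decodable_fraction": hits / n_samples})
    report = pd.DataFrame(rows)
    report["decodable_fraction"] = np.minimum.accumulate(report["decodable_fraction"])
    return report
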