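"""Group-testing deconvolution of sensor-compound assignments.

A sensor measured against every pool of a :class:`~cleavekit.pools.PoolDesign`
induces a pool classification (responsive / nonresponsive / indeterminate).
A compound is a candidate ligand when nearly all of its pools were
responsive and at most a small number were decisively nonresponsive; the
minimal explanation of the responsive pattern is a greedy set cover over
candidates.  Sensors with too many candidates or too many responsive pools
are flagged promiscuous — their pool pattern carries too little information
to decode (in a 9-partition design this happens around ten or more distinct
targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .cleaveseq import call_significant
from .pools import PoolDesign

__all__ = [
    "PoolClassification",
    "DeconvolutionResult",
    "classify_pools",
    "decode",
    "brute_force_decode",
    "propose_confirmations",
]


@dataclass
class PoolClassification:
    """Per-pool response classification for one sensor."""

    sensor_id: str
    responsive: set = field(default_factory=set)
    nonresponsive: set = field(default_factory=set)
    indeterminate: set = field(default_factory=set)
    unmeasured: set = field(default_factory=set)
    fc: dict = field(default_factory=dict)  # pool_id -> measured fold change


@dataclass
class DeconvolutionResult:
    sensor_id: str
    responsive_pools: set
    nonresponsive_pools: set
    indeterminate_pools: set
    candidates: dict  # compound_id -> {"support": int, "violations": int, "max_fc": float}
    minimal_cover: list
    status: str  # decoded | incomplete_cover | promiscuous | no_response


def classify_pools(
    records: pd.DataFrame,
    n_tested: int,
    fc_threshold: float = 2.0,
    min_reads: int = 100,
    sensor_id: str = "",
    all_pools: Sequence[str] | None = None,
) -> PoolClassification:
    """Classify each measured pool for one sensor.

    ``records`` holds one fold-change row per measured pool with a
    ``pool_id`` (or ``test_condition``) column.  Responsive: Bonferroni
    significant and fc >= threshold.  Nonresponsive: upper 95% CI below the
    threshold.  Otherwise indeterminate.  Pools in ``all_pools`` without a
    record are listed as unmeasured.
    """
    pool_col = "pool_id" if "pool_id" in records.columns else "test_condition"
    flagged = call_significant(
        records, n_tested=n_tested, min_reads=min_reads, fc_threshold=fc_threshold
    )
    cls = PoolClassification(sensor_id=sensor_id)
    for row in flagged.itertuples(index=False):
        pid = getattr(row, pool_col)
        cls.fc[pid] = row.fc
        if row.significant and row.fc >= fc_threshold:
            cls.responsive.add(pid)
        elif row.ci95_hi < fc_threshold:
            cls.nonresponsive.add(pid)
        else:
            cls.indeterminate.add(pid)
    if all_pools is not None:
        cls.unmeasured = set(all_pools) - set(cls.fc)
    return cls


def decode(
    classification: PoolClassification,
    design: PoolDesign,
    support_min: float = 0.8,
    violations_max: int = 1,
    promiscuity_cap: int = 10,
    pool_fraction_cap: float = 0.5,
    exact_cover_limit: int = 12,
) -> DeconvolutionResult:
    """Infer candidate ligands for one sensor from its pool pattern.

    A compound is a candidate when its responsive-pool support is at least
    ``support_min`` of its measured pools (pools with a record; unmeasured
    pools drop out of the denominator) and it has at most
    ``violations_max`` nonresponsive pools.  The minimal cover is a greedy
    set cover of the responsive pools over candidates (ties: higher
    support, fewer violations, lexical id); with at most
    ``exact_cover_limit`` candidates an exact minimum cover is computed
    instead (greedy can overshoot by one on heavily overlapping patterns).
    """
    resp, nonresp = classification.responsive, classification.nonresponsive
    measured = set(classification.fc)
    candidates: dict = {}
    for cid, pids in design.membership.items():
        pset = set(pids)
        support = len(pset & resp)
        violations = len(pset & nonresp)
        n_measured = len(pset & measured) if measured else len(pset)
        if n_measured == 0 or support == 0:
            continue
        if support >= support_min * n_measured and violations <= violations_max:
            fcs = [classification.fc[p] for p in pset & resp]
            candidates[cid] = {
                "support": support,
                "violations": violations,
                "max_fc": max(fcs) if fcs else float("nan"),
            }

    if not resp:
        status = "no_response"
        cover: list = []
    elif (
        len(candidates) > promiscuity_cap
        or (measured and len(resp & measured) / len(measured) > pool_fraction_cap)
    ):
        status = "promiscuous"
        cover = []
    else:
        if len(candidates) <= exact_cover_limit:
            cover = _exact_cover(resp, candidates, design)
        else:
            cover = _greedy_cover(resp, candidates, design)
        covered = set().union(*(set(design.membership[c]) for c in cover)) if cover else set()
        status = "decoded" if resp <= covered else "incomplete_cover"
    return DeconvolutionResult(
        sensor_id=classification.sensor_id,
        responsive_pools=set(resp),
        nonresponsive_pools=set(nonresp),
        indeterminate_pools=set(classification.indeterminate),
        candidates=candidates,
        minimal_cover=cover,
        status=status,
    )


def _candidate_order(candidates: Mapping[str, dict]) -> list:
    return sorted(
        candidates,
        key=lambda c: (-candidates[c]["support"], candidates[c]["violations"], c),
    )


def _exact_cover(responsive: set, candidates: Mapping[str, dict], design: PoolDesign) -> list:
    """Smallest candidate subset covering all responsive pools (exact search)."""
    order = _candidate_order(candidates)
    sets = {c: set(design.membership[c]) for c in order}
    for size in range(1, len(order) + 1):
        for subset in combinations(order, size):
            if responsive <= set().union(*(sets[c] for c in subset)):
                return list(subset)
    return []


def _greedy_cover(responsive: set, candidates: Mapping[str, dict], design: PoolDesign) -> list:
    remaining = set(responsive)
    order = _candidate_order(candidates)
    cover = []
    while remaining:
        best, gain = None, 0
        for cid in order:
            if cid in cover:
                continue
            g = len(set(design.membership[cid]) & remaining)
            if g > gain:
                best, gain = cid, g
        if best is None:
            break
        cover.append(best)
        remaining -= set(design.membership[best])
    return cover


def brute_force_decode(
    classification: PoolClassification,
    design: PoolDesign,
    max_set_size: int = 3,
    violations_max: int = 1,
) -> list[tuple]:
    """Exhaustively enumerate minimal consistent target subsets (oracle).

    A subset is consistent when its pools jointly cover every responsive
    pool and no member has more than ``violations_max`` nonresponsive
    pools.  Returns all consistent subsets of the smallest consistent size
    (empty list if none up to ``max_set_size``).  Exponential; for toy
    designs only.
    """
    resp, nonresp = classification.responsive, classification.nonresponsive
    ids = [
        cid
        for cid in sorted(design.membership)
        if len(set(design.membership[cid]) & nonresp) <= violations_max
        and set(design.membership[cid]) & resp
    ]
    for size in range(1, max_set_size + 1):
        found = []
        for subset in combinations(ids, size):
            covered = set().union(*(set(design.membership[c]) for c in subset))
            if resp <= covered:
                found.append(subset)
        if found:
            return found
    return []


def propose_confirmations(
    results: Sequence[DeconvolutionResult],
    max_singles: int,
) -> list[tuple[str, str]]:
    """Rank (sensor, compound) pairs for single-compound confirmation runs.

    Compounds are ranked by how many sensors implicate them, then by the
    highest pooled fold change observed; the deduplicated compound list is
    truncated to ``max_singles`` and every surviving (sensor, compound)
    candidate pair is returned in rank order.
    """
    stats: dict[str, dict] = {}
    for res in results:
        for cid, info in res.candidates.items():
            entry = stats.setdefault(cid, {"sensors": [], "max_fc": float("-inf")})
            entry["sensors"].append(res.sensor_id)
            fc = info.get("max_fc")
            if fc == fc and fc > entry["max_fc"]:  # NaN-safe
                entry["max_fc"] = fc
    ranked = sorted(
        stats,
        key=lambda c: (-len(stats[c]["sensors"]), -stats[c]["max_fc"], c),
    )[:max_singles]
    pairs = []
    for cid in ranked:
        for sid in sorted(stats[cid]["sensors"]):
            pairs.append((sid, cid))
    return pairs
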