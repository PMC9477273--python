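"""End-to-end synthetic study designs with known ground truth.

Two reference studies are packaged here so tests, examples and scripts can
re-run them identically:

* :func:`pool_screen_benchmark` — the group-testing screen: single-target
  sensors measured against every pool of a full-size design, decoded back
  to their cognate compound.
* :func:`selection_recovery_benchmark` — the whole campaign: a large
  library with a few planted switchers run through the alternating
  selection schedule, sequenced at the final round, and called by the
  fold-change significance test.

Both simulate counts at a fixed per-sensor read coverage: the shared
no-ligand reference condition is sequenced deep (one high-depth run in
practice) while each test condition gets shallow coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cleaveseq import call_significant, fold_change_frame
from .deconv import DeconvolutionResult, classify_pools, decode
from .pools import PoolDesign, design_pools
from .selection import Trajectory, default_schedule, run_selection
from .synthetic import (
    cleavage_fraction,
    generate_compound_library,
    generate_library,
    generate_response_models,
)

__all__ = ["PoolScreenResult", "pool_screen_benchmark", "SelectionRecoveryResult", "selection_recovery_benchmark"]


@dataclass
class PoolScreenResult:
    design: PoolDesign
    truth: dict  # sensor_id -> cognate compound_id
    results: dict  # sensor_id -> DeconvolutionResult
    records: pd.DataFrame  # all fold-change rows (sensor x pool)

    @property
    def exact_recovery(self) -> float:
        """Fraction of sensors decoded to exactly their true single target."""
        ok = sum(
            1
            for sid, cid in self.truth.items()
            if (res := self.results[sid]).status == "decoded"
            and res.minimal_cover == [cid]
            and set(res.candidates) == {cid}
        )
        return ok / len(self.truth)


def pool_screen_benchmark(
    seed: int,
    n_compounds: int = 5120,
    n_partitions: int = 9,
    pool_size: int = 256,
    n_sensors: int = 180,
    pool_depth: int = 200,
    ref_depth: int = 2000,
    fc_max: float = 6.0,
    ec50_um: float = 0.5,
    concentration_um: float = 2.0,
    support_min: float = 0.8,
    violations_max: int = 1,
) -> PoolScreenResult:
    """Simulate and decode a full single-target deconvolution screen.

    Every sensor responds to exactly one random compound; each pool
    condition is measured at ``pool_depth`` reads per sensor (the no-ligand
    reference at ``ref_depth``) and the Bonferroni family is all
    sensor x pool tests.
    """
    rng = np.random.default_rng(seed)
    compounds = generate_compound_library(n_compounds, seed=seed + 1)
    design = design_pools(
        compounds, n_partitions=n_partitions, pool_size=pool_size, seed=seed + 2
    )
    library = generate_library(n_sensors, seed=seed + 3)
    models = generate_response_models(
        library,
        compounds,
        n_switchers=n_sensors,
        seed=seed + 4,
        switcher_fc_max=fc_max,
        ec50_um=ec50_um,
    )
    truth = {r.sensor_id: next(iter(models[r.sensor_id].targets)) for r in library}

    c0 = np.array([models[r.sensor_id].c0 for r in library])
    a_ref = rng.binomial(ref_depth, c0)
    pool_ids = sorted(design.pools)
    frames = []
    for pid in pool_ids:
        conc = {cid: concentration_um for cid in design.pools[pid]}
        frac = np.array(
            [cleavage_fraction(models[r.sensor_id], conc) for r in library]
        )
        a_test = rng.binomial(pool_depth, frac)
        f = fold_change_frame(a_ref, ref_depth - a_ref, a_test, pool_depth - a_test)
        f["pool_id"] = pid
        f["sensor_id"] = [r.sensor_id for r in library]
        frames.append(f)
    records = pd.concat(frames, ignore_index=True)

    n_tested = n_sensors * len(pool_ids)
    results = {}
    for r in library:
        cls = classify_pools(
            records[records["sensor_id"] == r.sensor_id],
            n_tested=n_tested,
            sensor_id=r.sensor_id,
        )
        results[r.sensor_id] = decode(
            cls, design, support_min=support_min, violations_max=violations_max
        )
    return PoolScreenResult(design=design, truth=truth, results=results, records=records)


@dataclass
class SelectionRecoveryResult:
    trajectory: Trajectory
    switcher_ids: list
    flagged: pd.DataFrame  # fold-change rows with `significant`
    sensitivity: float  # recovered switchers / planted switchers
    n_false_positives: int


def selection_recovery_benchmark(
    seed: int,
    n_sensors: int = 10_000,
    n_switchers: int = 20,
    n_rounds: int = 95,
    sample_size: int = 1_000_000,
    sequencing_depth: int = 1_000_000,
    switcher_c0: float = 0.9,
    switcher_fc_max: float = 10.0,
    ec50_um: float = 1.0,
    concentration_um: float = 2.0,
    min_reads: int = 100,
) -> SelectionRecoveryResult:
    """Plant switchers, run the full selection, and call them back.

    The planted switchers share one response parameter set so selection
    fitness is uniform across them; their targets all lie in the selection
    mixture.  After the final round, both the no-ligand and with-mixture
    conditions are sequenced (total ``sequencing_depth`` reads split by
    final abundance) and switchers are recovered with the Bonferroni rule
    at N = library size.
    """
    rng = np.random.default_rng(seed)
    compounds = generate_compound_library(512, seed=seed + 1)
    set_a = [c.compound_id for c in compounds if c.selection_set == "A"]
    set_b = [c.compound_id for c in compounds if c.selection_set == "B"]
    library = generate_library(n_sensors, seed=seed + 2)
    # targets drawn from mixture A only: the selection enriches exactly the
    # sensors whose ligands are present during positive rounds
    comps_a = [c for c in compounds if c.selection_set == "A"]
    models = generate_response_models(
        library,
        comps_a,
        n_switchers=n_switchers,
        seed=seed + 3,
        switcher_c0=switcher_c0,
        switcher_fc_max=switcher_fc_max,
        ec50_um=ec50_um,
    )
    switcher_ids = [
        r.sensor_id for r in library if models[r.sensor_id].targets
    ]

    schedule = default_schedule(
        n_rounds=n_rounds,
        concentration_um=concentration_um,
        sample_size=sample_size,
    )
    trajectory = run_selection(
        library,
        models,
        schedule,
        mixtures={"V2560A": set_a, "V2560B": set_b},
        seed=seed + 4,
    )

    final = trajectory.abundance.iloc[-1].to_numpy()
    conc = {cid: concentration_um for cid in set_a}
    c_ref = np.array([models[r.sensor_id].c0 for r in library])
    c_test = np.array(
        [cleavage_fraction(models[r.sensor_id], conc) for r in library]
    )
    reads_ref = rng.multinomial(sequencing_depth, final)
    reads_test = rng.multinomial(sequencing_depth, final)
    a_ref = rng.binomial(reads_ref, c_ref)
    a_test = rng.binomial(reads_test, c_test)
    records = fold_change_frame(a_ref, reads_ref - a_ref, a_test, reads_test - a_test)
    records.insert(0, "sensor_id", [r.sensor_id for r in library])
    flagged = call_significant(records, n_tested=n_sensors, min_reads=min_reads)

    called = set(flagged.loc[flagged["significant"], "sensor_id"])
    hits = len(called & set(switcher_ids))
    return SelectionRecoveryResult(
        trajectory=trajectory,
        switcher_ids=switcher_ids,
        flagged=flagged,
        sensitivity=hits / len(switcher_ids),
        n_false_positives=len(called - set(switcher_ids)),
    )
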