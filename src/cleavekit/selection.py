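"""Alternating-round selection dynamics for switching ribozymes.

The selection alternates between rounds that keep molecules which cleaved
(no ligand present — removes dead sequences) and rounds that keep molecules
which did not cleave (ligand mixture present — removes ligand-blind
cleavers).  A sensor's per-round survival weight is its cleavage fraction
``c`` under the round's condition (cleaved-selecting rounds) or ``1 - c``
(uncleaved-selecting rounds); over many alternating rounds only switchers
— high ``c`` without ligand, low ``c`` with ligand — keep a weight product
near 1 per round pair.  Amplification is modeled as renormalization, with
an optional multinomial bottleneck per round; parasitic amplicons get a
fixed sense-independent weight, emulating RT-evasion.

The default 95-round schedule: seven initial cleaved-selecting rounds with
no ligand, then alternating rounds with the selection mixture at 2 µM per
compound, and from round 88 on a reduced 1 µM concentration with the
alternate (counter) mixture added to the cleaved-selecting rounds to
penalize cross-reactive sensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ExtinctionError, InputError
from .synthetic import Condition, ResponseModel, SensorRecord, cleavage_fraction

__all__ = [
    "SELECT_CLEAVED",
    "SELECT_UNCLEAVED",
    "RoundSpec",
    "Trajectory",
    "default_schedule",
    "schedule_to_yaml",
    "schedule_from_yaml",
    "run_selection",
    "track_abundance",
]

SELECT_CLEAVED = "select_cleaved"
SELECT_UNCLEAVED = "select_uncleaved"


@dataclass(frozen=True)
class RoundSpec:
    """One selection round: which cleavage state survives, and with what."""

    round_index: int
    sense: str  # SELECT_CLEAVED or SELECT_UNCLEAVED
    mixture: str | None  # mixture name, resolved via `mixtures` at run time
    concentration_um: float  # per-compound concentration in the mixture
    sample_size: int  # molecules carried into the next round

    def __post_init__(self) -> None:
        if self.sense not in (SELECT_CLEAVED, SELECT_UNCLEAVED):
            raise InputError(f"unknown sense {self.sense!r}")
        if self.sense == SELECT_UNCLEAVED and self.mixture is None:
            raise InputError("uncleaved-selecting (positive) rounds need a mixture")


@dataclass
class Trajectory:
    """Per-round relative abundances (rows: round 0 = input, then each round)."""

    abundance: pd.DataFrame  # index: round, columns: sensor_id
    schedule: list

    def __post_init__(self) -> None:
        sums = self.abundance.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise InputError("abundances must sum to 1 each round")


def default_schedule(
    n_rounds: int = 95,
    mixture: str = "V2560A",
    counter_mixture: str = "V2560B",
    concentration_um: float = 2.0,
    final_concentration_um: float = 1.0,
    final_phase_start: int = 88,
    n_initial_cleaved: int = 7,
    sample_size: int = 1_000_000,
    initial_sample_size: int = 10_000_000,
    n_large_volume_rounds: int = 4,
) -> list[RoundSpec]:
    """The standard schedule: 7 ligand-free enrichment rounds, then
    alternating selection, with a reduced-concentration counter-selection
    phase from ``final_phase_start``.

    The first ``n_large_volume_rounds`` rounds carry ``initial_sample_size``
    molecules forward, emulating the large-volume manual rounds that
    protect pre-enrichment diversity; later rounds bottleneck to
    ``sample_size``.
    """
    if n_rounds < n_initial_cleaved:
        raise InputError(f"n_rounds must be >= {n_initial_cleaved}")
    rounds = []
    for i in range(1, n_rounds + 1):
        final = i >= final_phase_start
        conc = final_concentration_um if final else concentration_um
        size = initial_sample_size if i <= n_large_volume_rounds else sample_size
        if i <= n_initial_cleaved:
            spec = RoundSpec(i, SELECT_CLEAVED, None, 0.0, size)
        elif (i - n_initial_cleaved) % 2 == 1:
            spec = RoundSpec(i, SELECT_UNCLEAVED, mixture, conc, size)
        else:
            mix = counter_mixture if final else None
            spec = RoundSpec(i, SELECT_CLEAVED, mix, conc if mix else 0.0, size)
        rounds.append(spec)
    return rounds


def schedule_to_yaml(schedule: Sequence[RoundSpec], path: str | Path) -> Path:
    rows = [
        {
            "round": s.round_index,
            "sense": s.sense,
            "mixture": s.mixture,
            "concentration_um": s.concentration_um,
            "sample_size": s.sample_size,
        }
        for s in schedule
    ]
    path = Path(path)
    path.write_text(yaml.safe_dump(rows, sort_keys=False))
    return path


def schedule_from_yaml(path: str | Path) -> list[RoundSpec]:
    rows = yaml.safe_load(Path(path).read_text())
    return [
        RoundSpec(
            round_index=r["round"],
            sense=r["sense"],
            mixture=r.get("mixture"),
            concentration_um=float(r.get("concentration_um", 0.0)),
            sample_size=int(r.get("sample_size", 0)),
        )
        for r in rows
    ]


def _round_weights(
    library: Sequence[SensorRecord],
    models: Mapping[str, ResponseModel],
    spec: RoundSpec,
    mixtures: Mapping[str, Sequence[str]],
    amplicon_fitness: float,
    cache: dict,
) -> np.ndarray:
    key = (spec.mixture, spec.concentration_um)
    if key not in cache:
        if spec.mixture is None:
            conc: dict[str, float] = {}
        else:
            if spec.mixture not in mixtures:
                raise InputError(f"unknown mixture {spec.mixture!r}")
            conc = {cid: spec.concentration_um for cid in mixtures[spec.mixture]}
        cache[key] = np.array(
            [cleavage_fraction(models[r.sensor_id], conc) for r in library]
        )
    c = cache[key]
    w = c if spec.sense == SELECT_CLEAVED else 1.0 - c
    is_amp = np.array([r.is_amplicon for r in library])
    return np.where(is_amp, amplicon_fitness, w)


def run_selection(
    library: Sequence[SensorRecord],
    models: Mapping[str, ResponseModel] | Sequence[ResponseModel],
    schedule: Sequence[RoundSpec],
    mixtures: Mapping[str, Sequence[str]],
    seed: int = 0,
    amplicon_fitness: float = 0.95,
    resample: bool = True,
) -> Trajectory:
    """Run the round-by-round selection and return the abundance trajectory.

    Each round multiplies abundances by survival weights, renormalizes
    (amplification), and — with ``resample`` — applies a multinomial
    bottleneck of ``sample_size`` molecules.  Deterministic per seed.
    With ``resample=False`` the dynamics are the exact expected-value
    (infinite-population) limit.
    """
    if not isinstance(models, Mapping):
        models = {m.sensor_id: m for m in models}
    indices = [s.round_index for s in schedule]
    if indices != list(range(indices[0], indices[0] + len(indices))):
        raise InputError("schedule round indices must be contiguous")
    rng = np.random.default_rng(seed)
    abund = np.array([r.abundance for r in library], dtype=float)
    abund = abund / abund.sum()
    rows = [abund.copy()]
    cache: dict = {}
    for spec in schedule:
        w = _round_weights(library, models, spec, mixtures, amplicon_fitness, cache)
        abund = abund * w
        total = abund.sum()
        if total <= 0:
            raise ExtinctionError(
                f"all survival weights vanished in round {spec.round_index}",
                round_index=spec.round_index,
            )
        abund = abund / total
        if resample and spec.sample_size > 0:
            counts = rng.multinomial(spec.sample_size, abund)
            abund = counts / counts.sum()
        rows.append(abund.copy())
    df = pd.DataFrame(
        rows,
        index=pd.Index(range(indices[0] - 1, indices[0] + len(schedule)), name="round"),
        columns=[r.sensor_id for r in library],
    )
    return Trajectory(abundance=df, schedule=list(schedule))


def track_abundance(
    trajectory: Trajectory,
    checkpoints: Sequence[int],
    reads_per_checkpoint: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequencing-sampled abundances at checkpoints, with detection floor.

    Each checkpoint round is subsampled with ``reads_per_checkpoint``
    multinomial reads; the detection floor is 1/reads.  Long-format output:
    round, sensor_id, true_abundance, sampled_abundance, detection_floor,
    below_floor (sampled count of zero).
    """
    rng = np.random.default_rng(seed)
    floor = 1.0 / reads_per_checkpoint
    frames = []
    for cp in checkpoints:
        if cp not in trajectory.abundance.index:
            raise InputError(f"checkpoint round {cp} not in trajectory")
        p = trajectory.abundance.loc[cp].to_numpy()
        counts = rng.multinomial(reads_per_checkpoint, p)
        frames.append(
            pd.DataFrame(
                {
                    "round": cp,
                    "sensor_id": trajectory.abundance.columns,
                    "true_abundance": p,
                    "sampled_abundance": counts / reads_per_checkpoint,
                    "detection_floor": floor,
                    "below_floor": counts == 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
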