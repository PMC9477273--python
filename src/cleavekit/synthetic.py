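"""Ground-truth simulation of a ribozyme-biosensor selection library.

This module builds everything the downstream statistics need to be tested
without real sequencing data: a randomized-loop hammerhead ribozyme library,
per-sensor ligand response models on the cleavage-odds scale, a synthetic
small-molecule compound library with template-derived structures, binomial
read-count simulation of a cleavage assay, and FASTQ/FASTA read emission
that round-trips exactly through the read counter.

The forward model: a sensor cleaves a fraction ``c0`` of its transcripts in
the absence of ligand.  A cognate ligand at concentration ``x`` (µM) divides
the cleavage *odds* by a fold change

    FC(x) = 1 + (fc_max - 1) * x / (x + ec50)

so FC(0) = 1 and FC(inf) = fc_max.  Multiple cognate ligands present at once
combine multiplicatively on FC (additively in log-odds).  Read counts are
multinomial across sensors by abundance, and binomial cleaved/uncleaved
within a sensor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "SensorRecord",
    "TargetResponse",
    "ResponseModel",
    "CompoundRecord",
    "Condition",
    "SCAFFOLD_5P",
    "STEM1_UP",
    "STEM1_DOWN",
    "CORE",
    "SCAFFOLD_3P",
    "DEFAULT_PREFIX_MAP",
    "DEFAULT_SUFFIX",
    "generate_library",
    "generate_compound_library",
    "generate_response_models",
    "fold_change_at",
    "cleavage_fraction",
    "simulate_cleaveseq_counts",
    "emit_reads",
    "dump_ground_truth",
]

# Hammerhead scaffold (DNA sense of the sequenced insert).  Stem I is the
# ACTGGA:TCCGGT variant whose GU wobble destabilizes the cDNA helix.
SCAFFOLD_5P = "GCTGTC"
STEM1_UP = "ACTGGA"
STEM1_DOWN = "TCCGGT"
CORE = "CTGATGAGTCC"  # catalytic core + stem II side
SCAFFOLD_3P = "GGACGAAACAGC"

# 5' prefixes distinguishing cleaved (Z) from uncleaved (W, A-rich) molecules,
# and the shared A-rich 3' suffix.
DEFAULT_PREFIX_MAP = {"cleaved": "CGACTGGCATCA", "uncleaved": "AAACAAACAAAC"}
DEFAULT_SUFFIX = "AAAGAAACAAAG"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _assemble_template(small_loop: str, large_loop: str) -> str:
    return (
        SCAFFOLD_5P
        + STEM1_UP
        + small_loop
        + STEM1_DOWN
        + CORE
        + large_loop
        + SCAFFOLD_3P
    )


@dataclass(frozen=True)
class SensorRecord:
    """One library member: randomized loops on the ribozyme scaffold."""

    sensor_id: str
    small_loop: str
    large_loop: str
    template_seq: str
    abundance: float
    is_reference: bool = False
    is_amplicon: bool = False

    def __post_init__(self) -> None:
        if not 4 <= len(self.small_loop) <= 8:
            raise InputError(
                f"small loop must be 4-8 nt, got {len(self.small_loop)}"
            )
        if len(self.large_loop) != 30:
            raise InputError(
                f"large loop must be exactly 30 nt, got {len(self.large_loop)}"
            )
        if self.template_seq.count(self.small_loop) != 1:
            raise InputError("small loop must occur exactly once in template")
        if self.template_seq.count(self.large_loop) != 1:
            raise InputError("large loop must occur exactly once in template")
        if not 0.0 <= self.abundance <= 1.0:
            raise InputError("abundance must lie in [0, 1]")


@dataclass(frozen=True)
class TargetResponse:
    """Saturating response of one sensor to one cognate compound."""

    fc_max: float  # fold change of cleavage at saturation, >= 1
    ec50_um: float  # concentration of half-maximal effect, µM

    def __post_init__(self) -> None:
        if self.fc_max < 1.0:
            raise InputError("fc_max must be >= 1")
        if self.ec50_um <= 0.0:
            raise InputError("ec50 must be positive")

    def fold_change(self, concentration_um: float) -> float:
        x = concentration_um
        return 1.0 + (self.fc_max - 1.0) * x / (x + self.ec50_um)


@dataclass(frozen=True)
class ResponseModel:
    """Ground-truth cleavage behaviour of one sensor.

    ``c0`` is the ligand-free cleavage fraction; ``targets`` maps cognate
    compound ids to their saturating response.  Reference (unresponsive)
    sensors have empty ``targets``.
    """

    sensor_id: str
    c0: float
    targets: Mapping[str, TargetResponse] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.c0 < 1.0:
            raise InputError("c0 must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class CompoundRecord:
    """A small-molecule library member keyed by a plate-well id."""

    compound_id: str
    smiles: str
    mono_mass: float  # monoisotopic mass, Da
    selection_set: str  # "A" or "B"

    def __post_init__(self) -> None:
        if self.mono_mass <= 0:
            raise InputError("mono_mass must be positive")
        if self.selection_set not in ("A", "B"):
            raise InputError("selection_set must be 'A' or 'B'")


@dataclass(frozen=True)
class Condition:
    """An assay condition: compound concentrations (µM) present, by id."""

    condition_id: str
    concentrations: Mapping[str, float] = field(default_factory=dict)


def fold_change_at(model: ResponseModel, concentrations: Mapping[str, float]) -> float:
    """Combined cleavage-odds fold change under the given ligand mix.

    Per-ligand fold changes combine multiplicatively (log-odds additive).
    """
    fc = 1.0
    for cid, x in concentrations.items():
        resp = model.targets.get(cid)
        if resp is not None and x > 0:
            fc *= resp.fold_change(x)
    return fc


def cleavage_fraction(
    model: ResponseModel,
    concentrations: Mapping[str, float] | None = None,
    bias: float = 1.0,
) -> float:
    """Expected cleavage fraction with optional per-condition odds bias."""
    fc = fold_change_at(model, concentrations or {})
    odds = bias * (model.c0 / (1.0 - model.c0)) / fc
    return odds / (1.0 + odds)


def _draw_loops(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    out = []
    for n in lengths:
        out.append(rng.choice(_BASES, size=int(n)).tobytes().decode())
    return out


def _normalize_weights(weights: Mapping[int, float], what: str) -> tuple[list[int], list[float]]:
    lengths = sorted(weights)
    probs = [float(weights[k]) for k in lengths]
    total = sum(probs)
    if any(p < 0 for p in probs) or not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ConfigurationError(
            f"{what} loop-length weights must be non-negative and sum to 1 (got {total})"
        )
    return lengths, probs


def generate_library(
    n_sensors: int,
    n_references: int = 0,
    n_amplicons: int = 0,
    loop_length_weights: Mapping[int, float] | None = None,
    large_loop_length_weights: Mapping[int, float] | None = None,
    seed: int = 0,
    abundance_sigma: float = 1.0,
) -> list[SensorRecord]:
    """Generate a randomized-loop sensor library.

    Loops are drawn uniformly per position over the four bases; the small
    loop length follows ``loop_length_weights`` (default: uniform over 4-8 nt)
    and the large loop is 30 nt.  Relative abundances are log-normal with
    shape ``abundance_sigma``, normalized to sum to one over the whole
    library (sensors + references + amplicons).  Deterministic per seed.
    """
    if n_sensors < 1:
        raise InputError("n_sensors must be >= 1")
    rng = np.random.default_rng(seed)
    small_w = loop_length_weights or {k: 0.2 for k in range(4, 9)}
    large_w = large_loop_length_weights or {30: 1.0}
    small_lengths, small_probs = _normalize_weights(small_w, "small")
    large_lengths, large_probs = _normalize_weights(large_w, "large")

    n_total = n_sensors + n_references + n_amplicons
    abundances = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_total)
    abundances /= abundances.sum()

    records: list[SensorRecord] = []
    seen_templates: set[str] = set()
    for i in range(n_total):
        if i < n_sensors:
            sid, ref, amp = f"S{i:06d}", False, False
        elif i < n_sensors + n_references:
            sid, ref, amp = f"REF{i - n_sensors:04d}", True, False
        else:
            sid, ref, amp = f"AMP{i - n_sensors - n_references:04d}", False, True
        # redraw until loops occur exactly once in the template and the
        # template itself is unique in the library
        for _ in range(1000):
            small_n = rng.choice(small_lengths, p=small_probs)
            large_n = rng.choice(large_lengths, p=large_probs)
            small, large = _draw_loops(rng, np.array([small_n, large_n]))
            template = _assemble_template(small, large)
            if (
                template not in seen_templates
                and template.count(small) == 1
                and template.count(large) == 1
            ):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a unique valid template")
        seen_templates.add(template)
        records.append(
            SensorRecord(
                sensor_id=sid,
                small_loop=small,
                large_loop=large,
                template_seq=template,
                abundance=float(abundances[i]),
                is_reference=ref,
                is_amplicon=amp,
            )
        )
    return records


# Template grammar for synthetic structures: aromatic/aliphatic cores with a
# substitution site, decorated by small substituent fragments.  Compounds
# share substructure across the library so fragment-based classification has
# signal to find.
_CORES = [
    "c1ccc({sub})cc1",            # benzene
    "c1ccc({sub})nc1",            # pyridine
    "c1ccc2ccccc2c1{sub}",        # naphthalene (terminal attach)
    "C1CCN({sub})CC1",            # piperidine
    "c1cc({sub})no1",             # isoxazole
    "c1csc({sub})c1",             # thiophene
    "C1CCC({sub})CC1",            # cyclohexane
    "c1cnc2[nH]ccc2c1{sub}",      # azaindole (terminal attach)
]
_SUBSTITUENTS = [
    "C(=O)O",
    "C(=O)N",
    "CC(=O)O",
    "N",
    "O",
    "OC",
    "Cl",
    "F",
    "C#N",
    "CO",
    "CN(C)C",
    "C(F)(F)F",
    "OC(=O)C",
    "NC(=O)C",
    "S(=O)(=O)N",
    "Cc1ccccc1",
]

_PLATE_ROWS = "ABCDEFGHIJKLMNOP"


def _plate_well_id(index: int) -> str:
    """Map a running index to a 384-well plate-well id like ``125F11``."""
    plate = index // 384 + 1
    well = index % 384
    row = _PLATE_ROWS[well // 24]
    col = well % 24 + 1
    return f"{plate}{row}{col:02d}"


def generate_compound_library(
    n_compounds: int,
    mass_range: tuple[float, float] = (112.0, 500.0),
    seed: int = 0,
) -> list[CompoundRecord]:
    """Generate a synthetic compound library with shared substructures.

    Structures come from a small core x substituent template grammar (not
    real vendor chemistry); monoisotopic masses are drawn uniformly on
    ``mass_range`` and serve as synthetic labels for pool-design and MS
    simulation.  The A/B selection-set split is balanced.
    """
    if n_compounds % 2 != 0:
        raise InputError("n_compounds must be even for a balanced A/B split")
    lo, hi = mass_range
    if lo >= hi or lo <= 0:
        raise ConfigurationError(f"invalid mass_range {mass_range}")
    rng = np.random.default_rng(seed)
    masses = rng.uniform(lo, hi, size=n_compounds)
    sets = np.array(["A", "B"]).repeat(n_compounds // 2)
    rng.shuffle(sets)
    records = []
    for i in range(n_compounds):
        core = _CORES[int(rng.integers(len(_CORES)))]
        sub = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
        smiles = core.format(sub=sub)
        records.append(
            CompoundRecord(
                compound_id=_plate_well_id(i),
                smiles=smiles,
                mono_mass=float(masses[i]),
                selection_set=str(sets[i]),
            )
        )
    return records


def generate_response_models(
    library: Sequence[SensorRecord],
    compounds: Sequence[CompoundRecord],
    n_switchers: int,
    seed: int = 0,
    targets_per_switcher: int = 1,
    fc_max_range: tuple[float, float] = (2.0, 17.0),
    ec50_um: float | tuple[float, float] = 0.5,
    c0_beta: tuple[float, float] = (5.0, 2.0),
    switcher_c0: float | None = None,
    switcher_fc_max: float | None = None,
) -> dict[str, ResponseModel]:
    """Assign ground-truth response models to a library.

    The first ``n_switchers`` non-reference, non-amplicon sensors become
    responsive, each to ``targets_per_switcher`` randomly chosen compounds
    with fc_max ~ logUniform(fc_max_range) (or the fixed ``switcher_fc_max``)
    and the given ec50 (fixed, or logUniform over a (lo, hi) tuple).  All
    other sensors are unresponsive with c0 ~ Beta(*c0_beta).
    """
    rng = np.random.default_rng(seed)
    plain = [r for r in library if not r.is_reference and not r.is_amplicon]
    if n_switchers > len(plain):
        raise InputError("more switchers requested than plain sensors available")
    compound_ids = [c.compound_id for c in compounds]
    models: dict[str, ResponseModel] = {}
    switcher_ids = {r.sensor_id for r in plain[:n_switchers]}
    for rec in library:
        c0 = (
            switcher_c0
            if switcher_c0 is not None and rec.sensor_id in switcher_ids
            else float(rng.beta(*c0_beta))
        )
        c0 = min(max(c0, 1e-4), 1 - 1e-4)
        targets: dict[str, TargetResponse] = {}
        if rec.sensor_id in switcher_ids:
            picks = rng.choice(len(compound_ids), size=targets_per_switcher, replace=False)
            for p in picks:
                if switcher_fc_max is not None:
                    fc_max = switcher_fc_max
                else:
                    fc_max = float(
                        np.exp(rng.uniform(np.log(fc_max_range[0]), np.log(fc_max_range[1])))
                    )
                if isinstance(ec50_um, tuple):
                    ec50 = float(np.exp(rng.uniform(np.log(ec50_um[0]), np.log(ec50_um[1]))))
                else:
                    ec50 = float(ec50_um)
                targets[compound_ids[int(p)]] = TargetResponse(fc_max=fc_max, ec50_um=ec50)
        models[rec.sensor_id] = ResponseModel(rec.sensor_id, c0=c0, targets=targets)
    return models


def simulate_cleaveseq_counts(
    library: Sequence[SensorRecord],
    models: Mapping[str, ResponseModel] | Sequence[ResponseModel],
    condition: Condition,
    depth: int,
    bias: float = 1.0,
    seed: int = 0,
    known_compounds: Iterable[str] | None = None,
):
    """Simulate one cleavage-assay sequencing run as a count table.

    Reads per sensor are multinomial(depth, abundances); cleaved reads are
    binomial with the model cleavage fraction under ``condition`` (the odds
    are further multiplied by ``bias`` to emulate run-to-run ratio bias).
    """
    from .cleaveseq import CountTable

    if depth < 1:
        raise InputError("depth must be >= 1")
    if not isinstance(models, Mapping):
        models = {m.sensor_id: m for m in models}
    missing = [r.sensor_id for r in library if r.sensor_id not in models]
    if missing:
        raise InputError(f"no response model for sensors: {missing[:5]}")
    if known_compounds is not None:
        known = set(known_compounds)
        unknown = set(condition.concentrations) - known
        if unknown:
            raise InputError(f"condition references unknown compounds: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    abund = np.array([r.abundance for r in library], dtype=float)
    abund = abund / abund.sum()
    reads = rng.multinomial(depth, abund)
    fracs = np.array(
        [
            cleavage_fraction(models[r.sensor_id], condition.concentrations, bias=bias)
            for r in library
        ]
    )
    cleaved = rng.binomial(reads, fracs)
    uncleaved = reads - cleaved
    import pandas as pd

    df = pd.DataFrame(
        {
            "sensor_id": [r.sensor_id for r in library],
            "condition_id": condition.condition_id,
            "cleaved": cleaved,
            "uncleaved": uncleaved,
        }
    )
    return CountTable(df)


def emit_reads(
    table,
    library: Sequence[SensorRecord],
    path: str | Path,
    prefix_map: Mapping[str, str] | None = None,
    suffix: str = DEFAULT_SUFFIX,
    fmt: str = "fastq",
    barcode_map: Mapping[str, str] | None = None,
) -> Path:
    """Write one read per counted molecule: [barcode +] prefix + insert + suffix.

    Cleaved molecules carry ``prefix_map['cleaved']``, uncleaved molecules
    ``prefix_map['uncleaved']``.  With more than one condition in the table a
    ``barcode_map`` (condition_id -> barcode) is required; barcodes are
    prepended before the prefix.  Output round-trips exactly through
    :func:`cleavekit.cleaveseq.count_reads`.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    prefix_map = dict(prefix_map or DEFAULT_PREFIX_MAP)
    pz, pw = prefix_map["cleaved"], prefix_map["uncleaved"]
    if pz == pw or pz.startswith(pw) or pw.startswith(pz):
        raise ConfigurationError("prefixes must differ and not be prefixes of each other")
    if fmt not in ("fastq", "fasta"):
        raise InputError(f"unknown read format: {fmt!r}")

    by_id = {r.sensor_id: r for r in library}
    conditions = table.df["condition_id"].unique()
    if len(conditions) > 1 and barcode_map is None:
        raise InputError("multi-condition tables require a barcode_map")

    records = []
    n = 0
    for row in table.df.itertuples(index=False):
        sensor = by_id.get(row.sensor_id)
        insert = sensor.template_seq if sensor is not None else row.sensor_id
        barcode = barcode_map[row.condition_id] if barcode_map else ""
        for state, prefix, count in (
            ("cleaved", pz, row.cleaved),
            ("uncleaved", pw, row.uncleaved),
        ):
            seq = barcode + prefix + insert + suffix
            for i in range(int(count)):
                rec = SeqRecord(
                    Seq(seq),
                    id=f"read{n:08d}|{row.sensor_id}|{state}",
                    description="",
                )
                if fmt == "fastq":
                    rec.letter_annotations["phred_quality"] = [40] * len(seq)
                records.append(rec)
                n += 1
    path = Path(path)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, fmt)
    return path


def dump_ground_truth(
    library: Sequence[SensorRecord],
    models: Mapping[str, ResponseModel],
    path: str | Path,
) -> Path:
    """Dump the generator's ground truth as JSON for recovery tests."""
    payload = {
        "sensors": [
            {
                "sensor_id": r.sensor_id,
                "small_loop": r.small_loop,
                "large_loop": r.large_loop,
                "abundance": r.abundance,
                "is_reference": r.is_reference,
                "is_amplicon": r.is_amplicon,
            }
            for r in library
        ],
        "models": {
            sid: {
                "c0": m.c0,
                "targets": {
                    cid: {"fc_max": t.fc_max, "ec50_um": t.ec50_um}
                    for cid, t in m.targets.items()
                },
            }
            for sid, m in models.items()
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path
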