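"""Synthetic reporter-assay and alignment data with known ground truth.

Real luciferase transactivation measurements for corticosteroid receptor
ligand-binding-domain (LBD) constructs are rarely deposited, so every
downstream stage of this package is exercised against simulated data whose
true parameters are known.

The dose-response generator emulates a GAL4-LBD luciferase assay: raw
luminescence follows a logistic function of steroid dose on top of a vehicle
(ethanol) baseline, replicate noise is multiplicative (reporter noise scales
with signal), and an optional Hill-type decline at high doses mimics the
cytotoxicity-driven drop in activity often seen at the top of a steroid dose
ladder.

The alignment generator plants group-discriminating columns (residues
conserved within each sensitivity group but different between groups) into an
otherwise conserved protein alignment, together with distractor columns that
are non-discriminating by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "DEFAULT_DOSES",
    "VEHICLE_LABEL",
    "MEASUREMENT_COLUMNS",
    "DoseResponseSimConfig",
    "AlignmentSimConfig",
    "simulate_dose_response",
    "simulate_alignment",
    "write_measurements",
    "read_measurements",
    "write_alignment_fasta",
]

#: Ten-fold dose ladder from 10 pM to 1 uM, the standard transactivation range.
DEFAULT_DOSES: tuple[float, ...] = tuple(10.0 ** e for e in range(-11, -5))

#: Ligand label used for vehicle (dose 0) rows in raw measurement tables.
VEHICLE_LABEL = "vehicle"

#: Canonical column order of the raw measurement CSV dialect.
MEASUREMENT_COLUMNS = ["construct", "ligand", "dose_molar", "replicate", "luminescence"]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {message}")


@dataclass(frozen=True)
class DoseResponseSimConfig:
    """True model for one simulated construct x ligand dose-response series.

    Parameters
    ----------
    doses
        Molar treatment concentrations, strictly increasing and positive.
    n_reps
        Replicates per dose (and for the vehicle rows).
    beta0, beta1, beta2, beta3
        True logistic parameters: zero-dose fold-activation (1.0 gives the
        fixed-baseline three-parameter curve), upper bound (fold units),
        EC50 (molar) and shape.
    noise_cv
        Coefficient of variation of the multiplicative Gaussian replicate
        noise (sd = cv * mean, truncated at zero).
    tox_dose, tox_shape
        Half-effect dose (molar) and steepness of the multiplicative
        cytotoxic decline 1 / (1 + (x / tox_dose)**tox_shape); an infinite
        ``tox_dose`` disables the decline.
    vehicle_mean
        Raw luminescence scale of the vehicle treatment.
    """

    doses: Sequence[float] = DEFAULT_DOSES
    n_reps: int = 3
    beta0: float = 1.0
    beta1: float = 8.0
    beta2: float = 1e-9
    beta3: float = 1.0
    noise_cv: float = 0.1
    tox_dose: float = math.inf
    tox_shape: float = 2.0
    vehicle_mean: float = 100.0
    construct: str = "construct"
    ligand: str = "ligand"
    seed: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        _require(d.size > 0, "doses", "must be non-empty")
        _require(bool(np.all(d > 0)), "doses", "must be strictly positive")
        _require(bool(np.all(np.diff(d) > 0)), "doses", "must be strictly increasing")
        _require(self.n_reps >= 1, "n_reps", "must be >= 1")
        _require(self.beta0 > 0, "beta0", "must be > 0")
        _require(self.beta2 > 0, "beta2", "must be > 0 (EC50 is a concentration)")
        _require(self.beta3 > 0, "beta3", "must be > 0")
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")
        _require(self.tox_dose > 0, "tox_dose", "must be > 0 (may be inf)")
        _require(self.tox_shape > 0, "tox_shape", "must be > 0")
        _require(self.vehicle_mean > 0, "vehicle_mean", "must be > 0")

    def clean_fold(self, dose: float) -> float:
        """Noise-free fold-activation at ``dose``: logistic times decline."""
        f = self.beta1 + (self.beta0 - self.beta1) / (1.0 + (dose / self.beta2) ** self.beta3)
        if math.isinf(self.tox_dose):
            return f
        return f / (1.0 + (dose / self.tox_dose) ** self.tox_shape)


def simulate_dose_response(
    config: DoseResponseSimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a raw luminescence table for one construct x ligand series.

    Returns a DataFrame in the measurement dialect
    ``construct, ligand, dose_molar, replicate, luminescence`` with vehicle
    rows at ``dose_molar == 0`` (ligand label :data:`VEHICLE_LABEL`). The
    clean response at dose x is ``vehicle_mean * f(x) * c(x)`` with f the
    logistic and c the cytotoxic decline; vehicle rows are centred on
    ``vehicle_mean`` itself. Reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows: list[tuple[str, str, float, int, float]] = []

    def noisy(mean: float) -> float:
        if config.noise_cv == 0:
            return mean
        return max(mean * (1.0 + config.noise_cv * rng.standard_normal()), 0.0)

    for rep in range(1, config.n_reps + 1):
        rows.append((config.construct, VEHICLE_LABEL, 0.0, rep, noisy(config.vehicle_mean)))
    for dose in config.doses:
        clean = config.vehicle_mean * config.clean_fold(float(dose))
        for rep in range(1, config.n_reps + 1):
            rows.append((config.construct, config.ligand, float(dose), rep, noisy(clean)))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


@dataclass(frozen=True)
class AlignmentSimConfig:
    """Layout of a simulated two-group protein alignment.

    ``planted_sites`` are 1-based ``(column, residue_group_a, residue_group_b)``
    triples: columns fixed to one residue in every group-A sequence and a
    different residue in every group-B sequence. ``n_distractors`` extra
    columns vary but are non-discriminating by construction (they vary within
    a group, share a residue across groups, or carry a gap). All remaining
    columns are identical across sequences.
    """

    group_sizes: tuple[int, int] = (2, 2)
    length: int = 250
    planted_sites: Sequence[tuple[int, str, str]] = ()
    n_distractors: int = 20
    background_residue_pool: str = _AA20
    gap_rate: float = 0.2
    group_labels: tuple[str, str] = ("sensitive", "insensitive")
    seed: int | None = None

    def __post_init__(self) -> None:
        _require(len(self.group_sizes) == 2, "group_sizes", "exactly two groups")
        _require(all(n >= 1 for n in self.group_sizes), "group_sizes", "each group needs >= 1 sequence")
        _require(self.length >= 1, "length", "must be >= 1")
        cols = [c for c, _, _ in self.planted_sites]
        _require(len(set(cols)) == len(cols), "planted_sites", "columns must be distinct")
        _require(all(1 <= c <= self.length for c in cols), "planted_sites", "columns must lie in [1, length]")
        for c, ra, rb in self.planted_sites:
            _require(ra != rb, "planted_sites", f"column {c}: residues must differ between groups")
            _require(ra in _AA20 and rb in _AA20, "planted_sites", f"column {c}: residues must be amino acids")
        _require(self.n_distractors >= 0, "n_distractors", "must be >= 0")
        _require(
            self.n_distractors + len(cols) <= self.length,
            "n_distractors",
            "planted + distractor columns exceed alignment length",
        )
        _require(0.0 <= self.gap_rate <= 1.0, "gap_rate", "must be in [0, 1]")
        _require(len(self.background_residue_pool) > 0, "background_residue_pool", "must be non-empty")
        _require(len(set(self.group_labels)) == 2, "group_labels", "labels must be distinct")


@dataclass(frozen=True)
class SimulatedAlignment:
    """Alignment plus its ground truth."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    groups: dict[str, str]
    planted_sites: tuple[tuple[int, str, str], ...]

    def truth_record(self) -> dict:
        return {
            "planted_sites": [
                {"column": c, "residue_group_a": ra, "residue_group_b": rb}
                for c, ra, rb in self.planted_sites
            ],
            "groups": dict(self.groups),
        }


def simulate_alignment(
    config: AlignmentSimConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedAlignment:
    """Generate a gapped protein alignment whose discriminating columns are
    exactly ``config.planted_sites``.

    Distractor columns cycle through three non-discriminating patterns:
    within-group variation, a residue shared across groups, and gap-bearing
    columns (fraction ``gap_rate``). Sequences are named
    ``<group>_<i>``; the returned group assignment maps id -> group label.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_a, n_b = config.group_sizes
    label_a, label_b = config.group_labels
    ids = tuple(f"{label_a}_{i + 1}" for i in range(n_a)) + tuple(
        f"{label_b}_{i + 1}" for i in range(n_b)
    )
    n_seq = n_a + n_b
    pool = np.array(list(config.background_residue_pool))

    # background: every column identical across sequences
    background = rng.choice(pool, size=config.length)
    cols = np.tile(background, (n_seq, 1))

    planted_cols = {c for c, _, _ in config.planted_sites}
    for c, res_a, res_b in config.planted_sites:
        cols[:n_a, c - 1] = res_a
        cols[n_a:, c - 1] = res_b

    free = [c for c in range(1, config.length + 1) if c not in planted_cols]
    distractor_cols = rng.choice(len(free), size=config.n_distractors, replace=False)
    n_gap = int(round(config.gap_rate * config.n_distractors))
    for k, idx in enumerate(sorted(distractor_cols)):
        c = free[idx] - 1
        r1, r2 = rng.choice(pool, size=2, replace=False)
        if k < n_gap:
            # group-distinct residues but a gap somewhere: only the no-gap
            # rule keeps this column out of the discriminating set
            cols[:n_a, c] = r1
            cols[n_a:, c] = r2
            cols[rng.integers(n_seq), c] = "-"
        elif k % 2 == 0 and max(n_a, n_b) >= 2:
            # varies within the larger group
            gslice = slice(0, n_a) if n_a >= n_b else slice(n_a, n_seq)
            gsize = n_a if n_a >= n_b else n_b
            cols[:, c] = r1
            sub = np.full(gsize, r1)
            sub[rng.integers(gsize)] = r2
            cols[gslice, c] = sub
        else:
            # both groups carry the same residue (conserved, hence shared)
            cols[:, c] = r1
    sequences = tuple("".join(row) for row in cols)
    groups = {sid: (label_a if i < n_a else label_b) for i, sid in enumerate(ids)}
    return SimulatedAlignment(
        ids=ids,
        sequences=sequences,
        groups=groups,
        planted_sites=tuple((int(c), ra, rb) for c, ra, rb in config.planted_sites),
    )


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    """Write a raw measurement table in the canonical CSV dialect."""
    df.loc[:, MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    """Read a raw measurement CSV, validating the dialect."""
    from .errors import ParseError

    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message is adequate
        raise ParseError(f"cannot read measurement CSV {path}: {exc}") from exc
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"measurement CSV {path} missing columns: {', '.join(missing)}")
    if df.empty:
        raise ParseError(f"measurement CSV {path} contains no data rows")
    bad = df.index[~np.isfinite(df["dose_molar"]) | (df["dose_molar"] < 0)]
    if len(bad):
        raise ParseError(f"measurement CSV {path}: non-finite or negative dose at row {bad[0] + 2}")
    return df


def write_alignment_fasta(sim: SimulatedAlignment, path: str | Path) -> None:
    """Write the simulated alignment as aligned FASTA ('-' gaps)."""
    with open(path, "w") as fh:
        for sid, seq in zip(sim.ids, sim.sequences):
            fh.write(f">{sid}\n{seq}\n")


def write_truth_json(sim: SimulatedAlignment, path: str | Path) -> None:
    """Write the planted ground truth as JSON."""
    Path(path).write_text(json.dumps(sim.truth_record(), indent=2) + "\n")
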