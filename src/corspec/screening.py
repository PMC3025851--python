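"""Single-concentration ligand screens and receptor x ligand sensitivity calls.

A screen treats each receptor construct with one dose of each candidate
steroid (10^-7 M by default) and asks, per (receptor, ligand) pair, whether
the vehicle-normalized luciferase activity exceeds the baseline of 1.0 — a
one-sample, one-sided t-test across replicates. The calls are tabulated as a
receptor x ligand matrix of '+' (significant activation), '0' (not
significant) and 'NA' (untested or untestable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError
from .dose_response import normalize_to_vehicle

__all__ = ["ScreenConfig", "ScreenResult", "test_activation", "build_sensitivity_table", "screen_measurements"]


@dataclass(frozen=True)
class ScreenConfig:
    """Screen settings: dose, test level, and an optional Holm correction.

    The test is one-sided (activation means *greater* than baseline); no
    multiple-testing correction is applied by default, matching per-ligand
    testing practice, but ``holm=True`` adjusts p-values across the ligands
    of each receptor.
    """

    screen_dose: float = 1e-7
    alpha: float = 0.05
    holm: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha: must be in (0, 1)")
        if self.screen_dose <= 0:
            raise ConfigError("screen_dose: must be > 0")


@dataclass(frozen=True)
class ScreenResult:
    """One receptor x ligand activation test."""

    receptor: str
    ligand: str
    mean_fold: float | None
    t_stat: float | None
    p_value: float | None
    call: str  # '+', '0' or 'NA'
    reason: str = ""


def test_activation(folds: Sequence[float], config: ScreenConfig | None = None,
                    receptor: str = "", ligand: str = "") -> ScreenResult:
    """One-sample, one-sided t-test of fold-activation against baseline 1.0.

    Call is '+' iff the mean exceeds 1 and the one-sided p-value is below
    alpha. Fewer than two replicates or zero variance yield an 'NA' call
    with a reason rather than a test.
    """
    cfg = config or ScreenConfig()
    y = np.asarray(folds, dtype=float)
    if y.size < 2:
        return ScreenResult(receptor, ligand, float(y.mean()) if y.size else None,
                            None, None, "NA", reason="fewer than 2 replicates")
    if np.ptp(y) == 0:
        return ScreenResult(receptor, ligand, float(y.mean()),
                            None, None, "NA", reason="zero variance across replicates")
    t, p = stats.ttest_1samp(y, popmean=1.0, alternative="greater")
    mean = float(y.mean())
    call = "+" if (p < cfg.alpha and mean > 1.0) else "0"
    return ScreenResult(receptor, ligand, mean, float(t), float(p), call)


def _holm_adjust(results: list[ScreenResult], alpha: float) -> list[ScreenResult]:
    from dataclasses import replace

    tested = [r for r in results if r.p_value is not None]
    m = len(tested)
    order = sorted(range(m), key=lambda i: tested[i].p_value)
    adj = {}
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * tested[i].p_value))
        adj[id(tested[i])] = running
    out = []
    for r in results:
        if r.p_value is None:
            out.append(r)
        else:
            p = adj[id(r)]
            call = "+" if (p < alpha and r.mean_fold > 1.0) else "0"
            out.append(replace(r, p_value=p, call=call))
    return out


def build_sensitivity_table(results: Iterable[ScreenResult]) -> pd.DataFrame:
    """Tabulate screen calls as a receptor x ligand matrix of +/0/NA.

    (receptor, ligand) keys must be unique; untested pairs are 'NA'.
    """
    results = list(results)
    keys = [(r.receptor, r.ligand) for r in results]
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise InputError(f"duplicate (receptor, ligand) keys: {sorted(dupes)}")
    receptors = sorted({r.receptor for r in results})
    ligands = sorted({r.ligand for r in results})
    table = pd.DataFrame("NA", index=pd.Index(receptors, name="receptor"),
                         columns=pd.Index(ligands, name="ligand"))
    for r in results:
        table.loc[r.receptor, r.ligand] = r.call
    return table


def screen_measurements(raw: pd.DataFrame, config: ScreenConfig | None = None,
                        rel_dose_tol: float = 1e-6) -> tuple[pd.DataFrame, list[ScreenResult]]:
    """Run the screen over a raw measurement table.

    Normalizes each construct to its vehicle mean, restricts to rows at the
    screen dose (matched to relative tolerance ``rel_dose_tol``), tests each
    (construct, ligand) pair and returns the sensitivity matrix plus the
    underlying per-pair results.
    """
    cfg = config or ScreenConfig()
    results: list[ScreenResult] = []
    for construct, sub in raw.groupby("construct", sort=True):
        per_receptor: list[ScreenResult] = []
        for series in normalize_to_vehicle(sub):
            for dose, reps in series.points:
                if abs(dose - cfg.screen_dose) <= rel_dose_tol * cfg.screen_dose:
                    per_receptor.append(
                        test_activation(reps, cfg, receptor=str(construct), ligand=series.ligand)
                    )
        if cfg.holm:
            per_receptor = _holm_adjust(per_receptor, cfg.alpha)
        results.extend(per_receptor)
    return build_sensitivity_table(results), results
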