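"""Batch experiments and statistics.

A *condition* is one :class:`~sproutsim.config.SimulationConfig`; a
*batch* is ``num_sim`` independent replicates of a condition with
consecutive seeds; a *preset* is a named list of conditions mirroring
the model's canonical experiments (verification sweeps, the
ratio-calibrated control, added sVEGFR-1, added adenosine, the combined
sVEGFR-1/Ado = 2 panel, the cycle-count sweep and the four-condition
comparison panel).

Batch summaries are mean vessel area, mean reach and a t-based 95%
confidence interval of the area mean. Conditions are contrasted with
Welch two-sample t-tests; area-reach association is quantified with
Spearman rank correlation on pooled per-replicate pairs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTROL, SimulationConfig
from .engine import run_simulation
from .metrics import SimulationResult

__all__ = [
    "BatchSpec",
    "BatchResult",
    "ComparisonReport",
    "Condition",
    "PresetResult",
    "run_batch",
    "sweep",
    "preset_conditions",
    "preset_experiment",
    "compare_to_control",
    "compare_samples",
    "area_reach_correlation",
    "min_max_change_percent",
    "PRESET_NAMES",
]


@dataclasses.dataclass(frozen=True)
class BatchSpec:
    """Replicate plan for one condition: replicate ``i`` of ``num_sim``
    runs with seed ``base_seed + i``."""

    base_config: SimulationConfig
    num_sim: int
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.num_sim < 1:
            raise ValueError(f"num_sim must be >= 1, got {self.num_sim}")


@dataclasses.dataclass
class BatchResult:
    """Per-replicate results of one condition plus their summary."""

    spec: BatchSpec
    results: list[SimulationResult]
    mean_area: float
    mean_reach: float
    ci95_area: tuple[float, float]

    @property
    def areas(self) -> np.ndarray:
        return np.array([r.area for r in self.results])

    @property
    def reaches(self) -> np.ndarray:
        return np.array([r.reach for r in self.results])

    def to_frame(self, condition_id: str = "") -> pd.DataFrame:
        """One row per replicate: condition, parameters, seed, metrics."""
        cfg = self.spec.base_config
        return pd.DataFrame(
            {
                "condition_id": condition_id,
                "n_vegf": cfg.n_vegf,
                "n_svegfr1": cfg.n_svegfr1,
                "n_ado": cfg.n_ado,
                "ruleset": cfg.ruleset,
                "num_cycles": cfg.num_cycles,
                "p_execute": cfg.p_execute,
                "seed": [r.seed for r in self.results],
                "final_ec_count": [r.final_ec_count for r in self.results],
                "area": [r.area for r in self.results],
                "reach": [r.reach for r in self.results],
            }
        )


@dataclasses.dataclass
class ComparisonReport:
    """Welch t-test contrast of two batches (experiment minus control)."""

    t_statistic: float
    p_value: float
    mean_difference: float
    ci95_difference: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "mean_difference": self.mean_difference,
            "ci95_low": self.ci95_difference[0],
            "ci95_high": self.ci95_difference[1],
        }


def _mean_ci95(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    """t-based 95% CI around the mean; width 0 for degenerate samples."""
    m = float(np.mean(x))
    n = len(x)
    s = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if n < 2 or s == 0.0:
        return m, (m, m)
    half = stats.t.ppf(0.975, n - 1) * s / math.sqrt(n)
    return m, (m - half, m + half)


def run_batch(spec: BatchSpec, engine: str = "fast") -> BatchResult:
    """Run ``num_sim`` independent replicates and aggregate them."""
    results = [
        run_simulation(
            spec.base_config.replace(seed=spec.base_seed + i), engine=engine
        )
        for i in range(spec.num_sim)
    ]
    areas = np.array([r.area for r in results])
    mean_area, ci = _mean_ci95(areas)
    mean_reach = float(np.mean([r.reach for r in results]))
    return BatchResult(
        spec=spec,
        results=results,
        mean_area=mean_area,
        mean_reach=mean_reach,
        ci95_area=ci,
    )


def sweep(
    base: BatchSpec,
    parameter: str,
    values: Sequence,
    engine: str = "fast",
) -> list[tuple[object, BatchResult]]:
    """One batch per value of a :class:`SimulationConfig` field.

    All other fields are held fixed; the value order is preserved.
    Condition ``j`` uses seeds ``base_seed + j*num_sim ..``, so every
    replicate in the sweep has a distinct seed.
    """
    if parameter not in {f.name for f in dataclasses.fields(SimulationConfig)}:
        raise ValueError(f"unknown SimulationConfig field {parameter!r}")
    out = []
    for j, value in enumerate(values):
        cfg = base.base_config.replace(**{parameter: value})
        spec = BatchSpec(cfg, base.num_sim, base.base_seed + j * base.num_sim)
        out.append((value, run_batch(spec, engine=engine)))
    return out


# ---------------------------------------------------------------------------
# Presets


@dataclasses.dataclass(frozen=True)
class Condition:
    label: str
    config: SimulationConfig
    is_control: bool = False


def _ctrl(**kw) -> SimulationConfig:
    return CONTROL.replace(**kw)


def _verification_vegf() -> list[Condition]:
    # sVEGFR-1 fixed at 10000, VEGF variable, 100 cycles.
    return [
        Condition(f"vegf_{v}", _ctrl(n_vegf=v, n_svegfr1=10000, num_cycles=100))
        for v in (5000, 10000, 20000, 40000, 80000)
    ]


def _verification_svegfr1() -> list[Condition]:
    # VEGF fixed at 10000, sVEGFR-1 variable, 100 cycles.
    return [
        Condition(f"svegfr1_{v}", _ctrl(n_vegf=10000, n_svegfr1=v, num_cycles=100))
        for v in (1000, 5000, 10000, 20000, 50000)
    ]


def _ratio_calibration() -> list[Condition]:
    # sVEGFR-1/VEGF held at 1/5; the 40000/8000 member is the control model.
    return [
        Condition(
            f"vegf_{v}_svegfr1_{v // 5}",
            _ctrl(n_vegf=v, n_svegfr1=v // 5),
            is_control=(v == 40000),
        )
        for v in (10000, 20000, 40000, 80000)
    ]


#: Added-sVEGFR-1 amounts on top of the control 8000 (brackets the
#: landmarks: departures from control beyond +1000 added, reduction
#: saturation from 40000 total).
ADDED_SVEGFR1_GRID = (0, 1000, 2000, 5000, 12000, 32000, 72000)

#: Added-adenosine amounts (brackets the landmarks 4000, 8000 and the
#: post-saturation region beyond 8000).
ADO_GRID = (0, 1000, 2000, 4000, 8000, 12000, 16000)


def _added_svegfr1() -> list[Condition]:
    return [
        Condition(
            f"added_svegfr1_{a}",
            _ctrl(n_svegfr1=8000 + a, ruleset="R1"),
            is_control=(a == 0),
        )
        for a in ADDED_SVEGFR1_GRID
    ]


def _added_ado() -> list[Condition]:
    return [
        Condition(
            f"ado_{a}",
            _ctrl(n_ado=a, ruleset="R2"),
            is_control=(a == 0),
        )
        for a in ADO_GRID
    ]


def _combined_ratio2() -> list[Condition]:
    # Added sVEGFR-1 = 2 x added Ado, on top of the control condition.
    conds = [Condition("control", _ctrl(ruleset="R2"), is_control=True)]
    conds += [
        Condition(
            f"ado_{a}_svegfr1_{8000 + 2 * a}",
            _ctrl(n_ado=a, n_svegfr1=8000 + 2 * a, ruleset="R2"),
        )
        for a in (2500, 5000, 10000, 20000)
    ]
    return conds


def _cycle_sweep() -> list[Condition]:
    # Adenosine-treatment setting at increasing cycle counts.
    return [
        Condition(
            f"cycles_{n}",
            _ctrl(n_ado=4000, ruleset="R2", num_cycles=n),
            is_control=(n == 300),
        )
        for n in (300, 600, 900, 1200, 1500)
    ]


def _comparison_panel() -> list[Condition]:
    # The four in-silico conditions matched against the Matrigel assay.
    return [
        Condition("control", _ctrl(ruleset="R2"), is_control=True),
        Condition("added_svegfr1", _ctrl(n_svegfr1=20000, ruleset="R2")),
        Condition("added_ado", _ctrl(n_ado=4000, ruleset="R2")),
        Condition(
            "added_combination", _ctrl(n_svegfr1=20000, n_ado=10000, ruleset="R2")
        ),
    ]


_PRESETS = {
    "verification_vegf": _verification_vegf,
    "verification_svegfr1": _verification_svegfr1,
    "ratio_calibration": _ratio_calibration,
    "added_svegfr1": _added_svegfr1,
    "added_ado": _added_ado,
    "combined_ratio2": _combined_ratio2,
    "reach_vs_ado": _added_ado,  # same conditions, reach-focused analysis
    "cycle_sweep": _cycle_sweep,
    "comparison_panel": _comparison_panel,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset_conditions(name: str) -> list[Condition]:
    """The fully instantiated condition list of a named preset."""
    try:
        build = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; known presets: {', '.join(PRESET_NAMES)}"
        ) from None
    return build()


@dataclasses.dataclass
class PresetResult:
    """All batches of one preset, ready for statistics."""

    name: str
    conditions: list[Condition]
    batches: list[BatchResult]

    @property
    def control(self) -> BatchResult | None:
        for cond, batch in zip(self.conditions, self.batches):
            if cond.is_control:
                return batch
        return None

    def replicate_frame(self) -> pd.DataFrame:
        """One row per replicate across all conditions."""
        return pd.concat(
            [b.to_frame(c.label) for c, b in zip(self.conditions, self.batches)],
            ignore_index=True,
        )

    def summary_frame(self) -> pd.DataFrame:
        """One row per condition: mean_area, 95% CI, mean_reach, n."""
        rows = []
        for cond, batch in zip(self.conditions, self.batches):
            rows.append(
                {
                    "condition_id": cond.label,
                    "mean_area": batch.mean_area,
                    "ci95_low": batch.ci95_area[0],
                    "ci95_high": batch.ci95_area[1],
                    "mean_reach": batch.mean_reach,
                    "n": batch.spec.num_sim,
                }
            )
        return pd.DataFrame(rows)


def preset_experiment(
    name: str,
    num_sim: int = 50,
    base_seed: int = 0,
    engine: str = "fast",
) -> PresetResult:
    """Run every condition of a named preset.

    Condition ``j`` uses the seed block ``base_seed + j*num_sim``
    onward, so a preset re-run with the same ``base_seed`` reproduces
    its output exactly.
    """
    conditions = preset_conditions(name)
    batches = [
        run_batch(
            BatchSpec(cond.config, num_sim, base_seed + j * num_sim),
            engine=engine,
        )
        for j, cond in enumerate(conditions)
    ]
    return PresetResult(name=name, conditions=conditions, batches=batches)


# ---------------------------------------------------------------------------
# Statistics


def compare_to_control(
    experiment: BatchResult,
    control: BatchResult,
    metric: str = "area",
) -> ComparisonReport:
    """Welch two-sample t-test of experiment vs control per-replicate
    values (default: vessel areas), with the 95% CI of the difference.

    Zero-variance batches with equal means (for example two ``p_execute
    = 0`` batches) are reported as no difference with p = 1.
    """
    attr = {"area": "areas", "reach": "reaches"}.get(metric)
    if attr is None:
        raise ValueError(f"metric must be 'area' or 'reach', got {metric!r}")
    return compare_samples(getattr(experiment, attr), getattr(control, attr))


def compare_samples(x: np.ndarray, y: np.ndarray) -> ComparisonReport:
    """Welch t-test of two per-replicate samples (x minus y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 values")
    diff = float(np.mean(x) - np.mean(y))
    if np.std(x) == 0.0 and np.std(y) == 0.0:
        if diff == 0.0:
            return ComparisonReport(0.0, 1.0, 0.0, (0.0, 0.0))
        return ComparisonReport(
            math.inf if diff > 0 else -math.inf, 0.0, diff, (diff, diff)
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    lo, hi = res.confidence_interval(0.95)
    p = float(res.pvalue)
    if math.isnan(p):  # degenerate fallback
        p = 1.0
    return ComparisonReport(float(res.statistic), p, diff, (float(lo), float(hi)))


def area_reach_correlation(
    batches: Iterable[BatchResult],
) -> tuple[float, float]:
    """Spearman rank correlation of pooled per-replicate (area, reach)
    pairs across the given batches, with its p-value."""
    areas: list[float] = []
    reaches: list[float] = []
    for b in batches:
        areas.extend(b.areas)
        reaches.extend(b.reaches)
    if len(areas) < 3:
        raise ValueError("need at least 3 pooled (area, reach) pairs")
    rho, p = stats.spearmanr(areas, reaches)
    return float(rho), float(p)


def min_max_change_percent(
    sweep_results: Sequence[tuple[object, BatchResult]],
    reference: BatchResult,
    denominator: str = "control",
) -> float:
    """Min-to-max change in mean vessel area over a sweep, as a percent.

    ``denominator`` names the normalization — the reading of "percent"
    is a genuine modelling choice, so it is exposed:

    * ``"control"`` (default): percent of the reference (control)
      condition's mean area;
    * ``"min"``: percent of the sweep's own minimum mean area;
    * ``"grid"``: absolute change in area units times 100, i.e.
      percentage points of total grid area.
    """
    if not sweep_results:
        raise ValueError("sweep_results is empty")
    means = np.array([b.mean_area for _, b in sweep_results])
    span = float(means.max() - means.min())
    if denominator == "control":
        if reference.mean_area <= 0:
            raise ValueError("reference mean area must be positive")
        return 100.0 * span / reference.mean_area
    if denominator == "min":
        if means.min() <= 0:
            raise ValueError("sweep minimum mean area must be positive")
        return 100.0 * span / float(means.min())
    if denominator == "grid":
        return 100.0 * span
    raise ValueError(f"unknown denominator {denominator!r}")
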