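"""Prior-scale robustness: BF10 as a function of the Cauchy prior width.

A default Bayes factor depends on the scale of the effect-size prior, so a
standard sanity check sweeps the scale over a grid and asks whether the
qualitative conclusion — which hypothesis the data favour — survives.  The
three conventional markers are the analysis prior (0.707), the wide prior
(1) and the ultrawide prior (sqrt 2); a result is called *stable* when all
three marker BF10 values fall on the same side of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .jzs_core import (
    DEFAULT_SCALE,
    ULTRAWIDE_SCALE,
    WIDE_SCALE,
    PriorSpec,
    QuadratureError,
    jzs_bf10,
)
from .summary_io import NORMAL, REPLICATE, SubgroupSummary, TTestSummary, t_from_summary

MARKER_SCALES = (DEFAULT_SCALE, WIDE_SCALE, ULTRAWIDE_SCALE)

DEFAULT_GRID_MAX = 1.5
DEFAULT_GRID_POINTS = 200


def default_scale_grid(
    r_max: float = DEFAULT_GRID_MAX, n_points: int = DEFAULT_GRID_POINTS
) -> np.ndarray:
    """Evenly spaced scales on (0, r_max]; excludes 0 where the BF is undefined."""
    return np.linspace(r_max / n_points, r_max, n_points)


@dataclass(frozen=True)
class RobustnessCurve:
    """BF10 over a grid of prior scales plus the three named markers."""

    scales: np.ndarray
    bf10_values: np.ndarray
    markers: dict[str, float]  # keys: user, wide, ultrawide
    stable: bool

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.bf10_values):
            raise ValueError("scales and bf10_values must have equal length")
        if len(self.scales) == 0:
            raise ValueError("scale grid must be nonempty")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")


def _same_side_of_one(values: Sequence[float]) -> bool:
    return all(v > 1.0 for v in values) or all(v < 1.0 for v in values)


def robustness_curve(
    tsum: TTestSummary, scale_grid: Sequence[float] | None = None
) -> RobustnessCurve:
    """Evaluate BF10 at every scale on the grid and at the three markers."""
    grid = np.asarray(default_scale_grid() if scale_grid is None else scale_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("scale grid must be nonempty")
    if np.any(grid <= 0):
        raise ValueError("all prior scales must be > 0")
    values = np.empty_like(grid)
    for i, scale in enumerate(grid):
        try:
            values[i] = jzs_bf10(tsum, PriorSpec(scale)).bf10
        except QuadratureError as exc:
            raise QuadratureError(f"at prior scale {scale}: {exc}") from exc
    markers = {
        name: jzs_bf10(tsum, PriorSpec(scale)).bf10
        for name, scale in zip(("user", "wide", "ultrawide"), MARKER_SCALES)
    }
    return RobustnessCurve(
        scales=grid,
        bf10_values=values,
        markers=markers,
        stable=_same_side_of_one(list(markers.values())),
    )


def stability_report(
    rows: Sequence[SubgroupSummary],
    priors: Sequence[float] = MARKER_SCALES,
    quantile_rule: str = NORMAL,
    arm_rule: str = REPLICATE,
) -> pd.DataFrame:
    """Per-subgroup BF10 at each named prior scale with a stability flag.

    Returns one row per subgroup with columns ``bf10_user``, ``bf10_wide``,
    ``bf10_ultrawide`` (for the default marker trio) and ``stable``.
    """
    names = ("user", "wide", "ultrawide")
    records = []
    for row in rows:
        tsum = t_from_summary(row, quantile_rule=quantile_rule, arm_rule=arm_rule)
        bfs = [jzs_bf10(tsum, PriorSpec(s)).bf10 for s in priors]
        record: dict[str, object] = {"category": row.category, "subgroup": row.subgroup}
        for name, scale, bf in zip(names, priors, bfs):
            record[f"bf10_{name}"] = bf
        record["stable"] = _same_side_of_one(bfs)
        records.append(record)
    columns = ["category", "subgroup"] + [f"bf10_{n}" for n in names[: len(priors)]] + ["stable"]
    return pd.DataFrame.from_records(records, columns=columns)


def plot_curve(curve: RobustnessCurve, path: str, title: str = "") -> None:
    """Render the robustness curve (log BF10 axis, reference line at 1)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.scales, curve.bf10_values, color="C0")
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
    for name, scale in zip(("user", "wide", "ultrawide"), MARKER_SCALES):
        ax.plot([scale], [curve.markers[name]], "o", label=f"{name} ({scale:.3g})")
    ax.set_yscale("log")
    ax.set_xlabel("Cauchy prior scale")
    ax.set_ylabel("BF10")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
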