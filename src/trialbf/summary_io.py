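"""Read, validate and convert published subgroup summary rows.

A row of a published forest table gives an adjusted mean difference with a
confidence interval and a total sample size.  To feed the Bayes-factor
machinery we need the two-sample t statistic, its degrees of freedom and
the effective sample size N0 = n1*n2/(n1+n2).  This module performs that
back-conversion: CI -> standard error -> t, and total n -> per-arm sizes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Quantile rules for converting a CI half-width to a standard error.
NORMAL = "normal"
STUDENT = "student"

#: Arm-size rules for deriving (n1, n2) from a printed total.
SPLIT = "split"          # divide n_total by the allocation ratio
REPLICATE = "replicate"  # use n_total as the size of each arm

_REQUIRED_COLUMNS = (
    "category",
    "subgroup",
    "n_total",
    "mean_diff",
    "ci_lower",
    "ci_upper",
    "ci_level",
    "allocation",
)


@dataclass(frozen=True)
class SubgroupSummary:
    """One published subgroup row: effect estimate, CI and sample size.

    Parameters
    ----------
    category, subgroup
        Row labels, e.g. ``"MAO-B inhibitor"`` / ``"Yes"``.
    n_total
        Total number of participants in the comparison.
    mean_diff
        Adjusted mean difference (active minus placebo) in outcome units,
        e.g. MDS-UPDRS Part III points.
    ci_lower, ci_upper
        Confidence-interval bounds in the same units.
    ci_level
        Coverage of the interval, strictly in (0, 1).  Default 0.80.
    allocation
        Active:placebo weights used when the total is split into arms.
        Default (2, 1): two pooled active doses against one placebo arm.
    """

    category: str
    subgroup: str
    n_total: int
    mean_diff: float
    ci_lower: float
    ci_upper: float
    ci_level: float = 0.80
    allocation: tuple[float, float] = (2.0, 1.0)

    def __post_init__(self) -> None:
        label = f"{self.category}/{self.subgroup}"
        for name in ("mean_diff", "ci_lower", "ci_upper", "ci_level"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"row {label!r}: non-finite {name}")
        if self.ci_upper <= self.ci_lower:
            raise ValueError(
                f"row {label!r}: degenerate interval "
                f"[{self.ci_lower}, {self.ci_upper}]"
            )
        if not (self.ci_lower < self.mean_diff < self.ci_upper):
            raise ValueError(
                f"row {label!r}: mean_diff {self.mean_diff} outside its CI"
            )
        if self.n_total < 4:
            raise ValueError(f"row {label!r}: n_total must be >= 4")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"row {label!r}: ci_level must be in (0, 1)")
        w1, w2 = self.allocation
        if w1 <= 0 or w2 <= 0:
            raise ValueError(f"row {label!r}: allocation weights must be > 0")


@dataclass(frozen=True)
class TTestSummary:
    """Derived (t, nu, N0) triple consumed by the Bayes-factor integral."""

    t: float
    nu: int
    n_eff: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.nu != self.n1 + self.n2 - 2:
            raise ValueError("nu must equal n1 + n2 - 2")
        expected = self.n1 * self.n2 / (self.n1 + self.n2)
        if not np.isclose(self.n_eff, expected, rtol=1e-6):
            raise ValueError("n_eff must equal n1*n2/(n1+n2)")


def _ci_quantile(ci_level: float, quantile_rule: str, df: int | None) -> float:
    p = (1.0 + ci_level) / 2.0
    if quantile_rule == NORMAL:
        return float(stats.norm.ppf(p))
    if quantile_rule == STUDENT:
        if df is None or df < 1:
            raise ValueError("student quantile rule requires df >= 1")
        return float(stats.t.ppf(p, df))
    raise ValueError(f"unknown quantile rule {quantile_rule!r}")


def se_from_ci(
    mean_diff: float,
    ci_lower: float,
    ci_upper: float,
    ci_level: float = 0.80,
    quantile_rule: str = NORMAL,
    df: int | None = None,
) -> float:
    """Back-convert a confidence interval to the standard error.

    Returns ``(ci_upper - ci_lower) / (2 q)`` where ``q`` is the
    ``(1 + ci_level)/2`` quantile of the reference distribution (standard
    normal by default, Student t with ``df`` degrees of freedom otherwise).
    ``mean_diff`` is only used for validation: it must lie inside the
    interval.
    """
    if not all(np.isfinite(x) for x in (mean_diff, ci_lower, ci_upper)):
        raise ValueError("non-finite estimate or CI bound")
    if ci_upper <= ci_lower:
        raise ValueError(f"degenerate interval [{ci_lower}, {ci_upper}]")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be strictly between 0 and 1")
    q = _ci_quantile(ci_level, quantile_rule, df)
    return (ci_upper - ci_lower) / (2.0 * q)


def split_n(n_total: int, allocation: tuple[float, float] = (2.0, 1.0)) -> tuple[int, int]:
    """Split a printed total into per-arm sizes by the allocation weights.

    n1 is the total times w1/(w1+w2), rounded half up; n2 is the remainder,
    so the split always conserves ``n_total``.  A split leaving either arm
    with fewer than 2 participants is rejected.
    """
    w1, w2 = allocation
    if n_total < 4:
        raise ValueError("n_total must be >= 4")
    if w1 <= 0 or w2 <= 0:
        raise ValueError("allocation weights must be > 0")
    # round-half-up, deterministic regardless of banker's rounding
    n1 = int(np.floor(n_total * w1 / (w1 + w2) + 0.5))
    n2 = n_total - n1
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"allocation {w1}:{w2} leaves an arm with < 2 of {n_total} participants"
        )
    return n1, n2


def arm_sizes(
    n_total: int,
    allocation: tuple[float, float] = (2.0, 1.0),
    arm_rule: str = REPLICATE,
) -> tuple[int, int]:
    """Per-arm sizes under the chosen rule.

    ``"split"`` divides the total by the allocation ratio.  ``"replicate"``
    uses the printed total as the size of each arm (n1 = n2 = n_total),
    which is how the published subgroup table was evidently analysed and is
    therefore the pipeline default.
    """
    if arm_rule == SPLIT:
        return split_n(n_total, allocation)
    if arm_rule == REPLICATE:
        if n_total < 2:
            raise ValueError("n_total must be >= 2 under the replicate rule")
        return n_total, n_total
    raise ValueError(f"unknown arm rule {arm_rule!r}")


def t_from_summary(
    row: SubgroupSummary,
    quantile_rule: str = NORMAL,
    arm_rule: str = REPLICATE,
) -> TTestSummary:
    """Convert a published (estimate, CI, n) row into a (t, nu, N0) triple.

    The t statistic is ``mean_diff / SE`` with the SE recovered from the CI,
    so its sign follows the direction of the estimated effect.
    """
    df = row.n_total - 2 if quantile_rule == STUDENT else None
    try:
        se = se_from_ci(
            row.mean_diff, row.ci_lower, row.ci_upper, row.ci_level,
            quantile_rule, df,
        )
        n1, n2 = arm_sizes(row.n_total, row.allocation, arm_rule)
    except ValueError as exc:
        raise ValueError(f"row {row.category!r}/{row.subgroup!r}: {exc}") from exc
    t = row.mean_diff / se
    return TTestSummary(
        t=t,
        nu=n1 + n2 - 2,
        n_eff=n1 * n2 / (n1 + n2),
        n1=n1,
        n2=n2,
    )


def _parse_allocation(text: str) -> tuple[float, float]:
    parts = text.split(":")
    if len(parts) != 2:
        raise ValueError(f"allocation must look like '2:1', got {text!r}")
    w1, w2 = (float(p) for p in parts)
    return w1, w2


def read_subgroup_table(path: str | Path) -> list[SubgroupSummary]:
    """Read a comma-separated subgroup summary table.

    Required header: category, subgroup, n_total, mean_diff, ci_lower,
    ci_upper, ci_level, allocation (as "2:1").  Each invalid cell or row is
    reported with the file, line number and field name.  An empty file
    yields an empty list with a logged warning.
    """
    path = Path(path)
    rows: list[SubgroupSummary] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("%s: empty file, no subgroup rows read", path)
            return rows
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
        for record in reader:
            line = reader.line_num
            parsed: dict[str, object] = {
                "category": record["category"],
                "subgroup": record["subgroup"],
            }
            for name, caster in (
                ("n_total", int),
                ("mean_diff", float),
                ("ci_lower", float),
                ("ci_upper", float),
                ("ci_level", float),
            ):
                try:
                    parsed[name] = caster(record[name])
                except (TypeError, ValueError) as exc:
                    raise ValueError(
                        f"{path}, line {line}, field {name!r}: "
                        f"non-numeric cell {record.get(name)!r}"
                    ) from exc
            try:
                parsed["allocation"] = _parse_allocation(record["allocation"])
                rows.append(SubgroupSummary(**parsed))  # type: ignore[arg-type]
            except ValueError as exc:
                raise ValueError(f"{path}, line {line}: {exc}") from exc
    if not rows:
        logger.warning("%s: no subgroup rows read", path)
    return rows


def write_results_table(
    results: "Sequence[dict] | Iterable[dict]",
    path: str | Path,
    format: str = "csv",
    header_comments: Sequence[str] = (),
) -> None:
    """Write analysis results mirroring the published results-table layout.

    Each result dict carries category, subgroup, bf10, p10 plus the derived
    columns (t, nu, n_eff, prior_scale, evidence_category).  BF10 is
    reported to 2 decimals; P10 (in percent) is computed from the unrounded
    BF10 and then reported to 2 decimals — rounding the BF first would not
    reproduce a self-consistent published pair such as 0.125 -> 11.11%.
    """
    path = Path(path)
    columns = (
        "category", "subgroup", "bf10", "p10_pct",
        "t", "nu", "n_eff", "prior_scale", "evidence_category",
    )
    rendered = []
    for res in results:
        bf10 = float(res["bf10"])
        p10_pct = 100.0 * bf10 / (bf10 + 1.0)
        rendered.append({
            "category": res["category"],
            "subgroup": res["subgroup"],
            "bf10": f"{bf10:.2f}",
            "p10_pct": f"{p10_pct:.2f}",
            "t": f"{res['t']:.4f}",
            "nu": str(res["nu"]),
            "n_eff": f"{res['n_eff']:.4f}",
            "prior_scale": f"{res['prior_scale']:.4g}",
            "evidence_category": str(res["evidence_category"]),
        })
    with path.open("w", newline="", encoding="utf-8") as fh:
        if format == "csv":
            for comment in header_comments:
                fh.write(f"# {comment}\n")
            writer = csv.DictWriter(fh, fieldnames=columns)
            writer.writeheader()
            writer.writerows(rendered)
        elif format == "markdown":
            fh.write("| " + " | ".join(columns) + " |\n")
            fh.write("|" + "|".join(["---"] * len(columns)) + "|\n")
            for row in rendered:
                fh.write("| " + " | ".join(row[c] for c in columns) + " |\n")
        else:
            raise ValueError(f"unknown output format {format!r}")


def write_subgroup_table(rows: Sequence[SubgroupSummary], path: str | Path) -> None:
    """Write subgroup rows back to the input CSV format (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REQUIRED_COLUMNS)
        for row in rows:
            w1, w2 = row.allocation
            alloc = f"{w1:g}:{w2:g}"
            writer.writerow([
                row.category, row.subgroup, row.n_total,
                repr(row.mean_diff), repr(row.ci_lower), repr(row.ci_upper),
                repr(row.ci_level), alloc,
            ])
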