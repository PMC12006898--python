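"""Synthetic two-arm trials with known ground truth.

Generates subgroup summary rows of exactly the shape a published forest
table prints — adjusted mean difference, CI at a stated level, total n —
from a simple generative model: normally distributed outcome changes with
a true between-arm difference delta and common SD sigma.  Because the CI
is built from the pooled-variance two-sample standard error with the same
quantile rule the back-conversion uses, the pipeline-recovered t equals
the directly computed t to floating-point accuracy, which makes every
downstream stage testable without any external data.

The calibration experiment runs many replicate trials through the full
pipeline (summary -> t -> Bayes factor) and reports how often each
evidence category is reached — e.g. how quickly a true null accumulates
evidence of absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .jzs_core import EvidenceCategory, PriorSpec, classify_evidence, jzs_bf10
from .summary_io import NORMAL, SPLIT, STUDENT, SubgroupSummary, t_from_summary

#: Within-arm SD of 52-week MDS-UPDRS-III change used in example scenarios.
DEFAULT_SIGMA = 8.0


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Generative parameters for replicated two-arm trials.

    delta is the true active-minus-placebo mean difference in outcome
    units; sigma the common within-arm SD; n1/n2 the arm sizes.  Each
    replicate uses an independent substream derived from (seed, rep_index)
    so any single replicate is reproducible in isolation.
    """

    delta: float
    sigma: float = DEFAULT_SIGMA
    n1: int = 39
    n2: int = 20
    ci_level: float = 0.80
    quantile_rule: str = NORMAL
    n_reps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each arm needs at least 2 participants")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass(frozen=True)
class CalibrationResult:
    """Aggregate of many replicate trials pushed through the BF pipeline."""

    prop_substantial_H1: float
    prop_substantial_H0: float
    prop_anecdotal: float
    median_bf10: float
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        total = self.prop_substantial_H1 + self.prop_substantial_H0 + self.prop_anecdotal
        if abs(total - 1.0) > 1e-12:
            raise ValueError("category proportions must partition the replicates")


def _rep_rng(seed: int, rep_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, rep_index)))


def simulate_subgroup(config: SyntheticTrialConfig, rep_index: int) -> SubgroupSummary:
    """Simulate one two-arm trial and summarise it as a published-style row.

    The CI is mean difference +/- q * SE_pooled where SE_pooled is the
    pooled-variance two-sample standard error and q the normal (default)
    or Student-t quantile at (1 + ci_level)/2.  With the same quantile rule
    on both sides, the back-conversion in ``t_from_summary`` is the exact
    inverse of this construction.
    """
    rng = _rep_rng(config.seed, rep_index)
    active = rng.normal(config.delta, config.sigma, config.n1)
    placebo = rng.normal(0.0, config.sigma, config.n2)
    n1, n2 = config.n1, config.n2
    mean_diff = float(active.mean() - placebo.mean())
    pooled_var = ((n1 - 1) * active.var(ddof=1) + (n2 - 1) * placebo.var(ddof=1)) / (n1 + n2 - 2)
    se = float(np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2)))
    p = (1.0 + config.ci_level) / 2.0
    if config.quantile_rule == NORMAL:
        q = float(stats.norm.ppf(p))
    elif config.quantile_rule == STUDENT:
        q = float(stats.t.ppf(p, n1 + n2 - 2))
    else:
        raise ValueError(f"unknown quantile rule {config.quantile_rule!r}")
    return SubgroupSummary(
        category="synthetic",
        subgroup=f"rep{rep_index}",
        n_total=n1 + n2,
        mean_diff=mean_diff,
        ci_lower=mean_diff - q * se,
        ci_upper=mean_diff + q * se,
        ci_level=config.ci_level,
        allocation=(float(n1), float(n2)),
    )


def direct_t(config: SyntheticTrialConfig, rep_index: int) -> float:
    """Pooled-variance two-sample t computed straight from the raw draws.

    Regenerates the replicate's outcome vectors from its substream, so it
    is an independent check on the CI round-trip rather than a re-use of
    the summary path.
    """
    rng = _rep_rng(config.seed, rep_index)
    active = rng.normal(config.delta, config.sigma, config.n1)
    placebo = rng.normal(0.0, config.sigma, config.n2)
    t, _ = stats.ttest_ind(active, placebo, equal_var=True)
    return float(t)


def calibration_experiment(
    config: SyntheticTrialConfig, prior: PriorSpec | float = PriorSpec()
) -> CalibrationResult:
    """Push ``n_reps`` simulated trials through the full pipeline.

    Each replicate row is converted with the split arm rule (the simulated
    allocation is known exactly, so the split reproduces n1 and n2) and the
    same quantile rule used to build its CI.
    """
    if isinstance(prior, (int, float)):
        prior = PriorSpec(float(prior))
    if config.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    records = []
    for rep in range(config.n_reps):
        try:
            row = simulate_subgroup(config, rep)
            tsum = t_from_summary(row, quantile_rule=config.quantile_rule, arm_rule=SPLIT)
            result = jzs_bf10(tsum, prior)
        except Exception as exc:
            raise RuntimeError(f"replicate {rep} failed: {exc}") from exc
        records.append(
            {
                "rep": rep,
                "true_delta": config.delta,
                "t": tsum.t,
                "bf10": result.bf10,
                "category": str(result.category),
            }
        )
    frame = pd.DataFrame.from_records(records)
    counts = frame["category"].value_counts()
    n = len(frame)
    return CalibrationResult(
        prop_substantial_H1=counts.get(str(EvidenceCategory.substantial_H1), 0) / n,
        prop_substantial_H0=counts.get(str(EvidenceCategory.substantial_H0), 0) / n,
        prop_anecdotal=counts.get(str(EvidenceCategory.anecdotal), 0) / n,
        median_bf10=float(frame["bf10"].median()),
        records=frame,
    )
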