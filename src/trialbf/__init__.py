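"""trialbf: JZS Bayes factors for two-arm trial subgroups from summary statistics.

Converts published subgroup rows (adjusted mean difference, confidence
interval, total n) into two-sample t statistics, computes default
Jeffreys–Zellner–Siow Bayes factors by numerical integration, sweeps the
Cauchy prior scale for robustness, and validates the whole chain on
synthetic two-arm trials with known ground truth.
"""

from importlib import resources

__version__ = "0.1.0"

from .jzs_core import (
    BayesFactorResult,
    EvidenceCategory,
    PriorSpec,
    QuadratureError,
    classify_evidence,
    jzs_bf01,
    jzs_bf10,
    mc_oracle_bf,
    posterior_prob,
)
from .robustness import RobustnessCurve, robustness_curve, stability_report
from .summary_io import (
    SubgroupSummary,
    TTestSummary,
    arm_sizes,
    read_subgroup_table,
    se_from_ci,
    split_n,
    t_from_summary,
    write_results_table,
    write_subgroup_table,
)
from .synthetic_trials import (
    CalibrationResult,
    SyntheticTrialConfig,
    calibration_experiment,
    simulate_subgroup,
)

__all__ = [
    "BayesFactorResult",
    "CalibrationResult",
    "EvidenceCategory",
    "PriorSpec",
    "QuadratureError",
    "RobustnessCurve",
    "SubgroupSummary",
    "SyntheticTrialConfig",
    "TTestSummary",
    "arm_sizes",
    "calibration_experiment",
    "classify_evidence",
    "jzs_bf01",
    "jzs_bf10",
    "mc_oracle_bf",
    "packaged_subgroup_table",
    "posterior_prob",
    "read_subgroup_table",
    "robustness_curve",
    "se_from_ci",
    "simulate_subgroup",
    "split_n",
    "stability_report",
    "t_from_summary",
    "write_results_table",
    "write_subgroup_table",
]


def packaged_subgroup_table():
    """Path to the packaged PASADENA subgroup summary table (8 rows)."""
    return resources.files("trialbf").joinpath("data/pasadena_subgroups.csv")
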