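"""Monte-Carlo operating-characteristic studies of the full pipeline.

Two canned studies back the package's calibration claims:

* :func:`null_rejection_rate` - type-I error of the Step-1 omnibus test on
  null data (planted effect delta = 0) at reduced dimensions (default
  p = 30 parcels, N = 100 subjects), running the complete pipeline
  (normalize -> residualize -> Step 1) on every replicate.
* :func:`planted_recovery_study` - detection rates with a planted
  sex-by-diagnosis interaction on the connectivity-density panel at the
  study dimensions (N = 193, p = 165): Step-1 power for CD, false flags on
  the other metrics, Step-2/3 selectivity for the interaction predictor and
  Step-4 recovery of the planted parcel set.

Both are deterministic given their seed and scale linearly in ``n_reps``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import default_target_parcels
from .pipeline import PipelineConfig, run_pipeline
from .simulate import default_paper_spec, scaled_down_spec

__all__ = ["null_rejection_rate", "planted_recovery_study", "RecoveryStudy"]


def null_rejection_rate(
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_parcels: int = 30,
) -> tuple[float, int]:
    """Per-metric Step-1 rejection rate (raw p <= alpha) on null data.

    Returns ``(rate, n_trials)`` with ``n_trials = 5 * n_reps`` (five metric
    panels per replicate). Under correct calibration the rate is ~alpha.
    """
    rejections = 0
    trials = 0
    for r in range(n_reps):
        spec = scaled_down_spec(n_parcels=n_parcels, delta=0.0)
        rep = run_pipeline(PipelineConfig(spec=spec, seed=seed * 1_000_003 % 2**31 + r))
        rejections += int((rep.step1["p"] <= alpha).sum())
        trials += len(rep.step1)
    return rejections / trials, trials


@dataclass
class RecoveryStudy:
    """Detection rates from :func:`planted_recovery_study` (fractions of replicates)."""

    n_reps: int
    delta: float
    step1_cd_power: float  # CD omnibus rejected (FDR across metrics)
    step1_other_flagged: float  # any null metric rejected
    step1_cd_only: float  # CD rejected and no other metric
    step23_interaction_power: float  # interaction rejected in both frames
    step23_null_predictor_flagged: float  # sex or diagnosis rejected
    step23_interaction_only: float
    strict_selectivity: float  # CD-only AND interaction-only, steps 1-3
    step4_mean_recovery: float  # mean fraction of targets in the top-|targets|


def planted_recovery_study(
    n_reps: int = 200,
    delta: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> RecoveryStudy:
    """Run the full pipeline on ``n_reps`` planted replicates at study size."""
    targets = set(default_target_parcels())
    k = len(targets)
    cd_pow = other = cd_only = i_pow = null_fp = i_only = strict = 0
    recovery = []
    base = seed * 1_000_003 % 2**31
    for r in range(n_reps):
        spec = default_paper_spec(delta=delta)
        rep = run_pipeline(
            PipelineConfig(spec=spec, seed=base + r, force_all_steps=True)
        )
        s1 = rep.step1
        cd_rej = bool(s1.loc["CD", "reject"])
        oth = bool(s1.drop("CD")["reject"].any())
        cd_pow += cd_rej
        other += oth
        cd_only += cd_rej and not oth
        s2, s3 = rep.step2["CD"], rep.step3["CD"]
        inter = bool(s2.loc["interaction", "reject"]) and bool(s3.loc["interaction", "reject"])
        fp = bool(
            s2.loc[["sex", "diagnosis"], "reject"].any()
            or s3.loc[["sex", "diagnosis"], "reject"].any()
        )
        i_pow += inter
        null_fp += fp
        i_only += inter and not fp
        strict += cd_rej and not oth and inter and not fp
        top = rep.step4["CD"].nlargest(k, "partial_f")
        recovery.append(sum(p in targets for p in top["parcel"]) / k)
    n = n_reps
    return RecoveryStudy(
        n_reps=n,
        delta=delta,
        step1_cd_power=cd_pow / n,
        step1_other_flagged=other / n,
        step1_cd_only=cd_only / n,
        step23_interaction_power=i_pow / n,
        step23_null_predictor_flagged=null_fp / n,
        step23_interaction_only=i_only / n,
        strict_selectivity=strict / n,
        step4_mean_recovery=float(np.mean(recovery)),
    )
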