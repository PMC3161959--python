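"""Site-frequency-spectrum diversity estimators and class ratios.

Implements the three classical estimators of the population mutation rate
4Nu from an unfolded sample spectrum of n chromosomes:

    theta_W  = S / a_n,             a_n = sum_{i=1}^{n-1} 1/i
    theta_pi = sum_i S_i 2 i (n-i) / (n (n-1))
    theta_H  = sum_i S_i 2 i^2     / (n (n-1))

where S_i is the number of sites at derived count i (i = 1..n-1) and
S = sum_i S_i.  theta_W weights low-frequency, theta_pi intermediate- and
theta_H high-frequency derived variants; all are unbiased for 4Nu under
neutrality.  The deleterious/neutral ratio of each estimator, averaged over
replicates as a ratio of replicate means, is the summary used to quantify
how hitchhiking reshapes linked deleterious polymorphism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import wf_sim
from .wf_sim import SampleResult

ESTIMATORS = ("theta_w", "theta_pi", "theta_h")


@dataclass
class ThetaEstimates:
    theta_w: float
    theta_pi: float
    theta_h: float
    S: int
    n: int
    a_n: float

    def get(self, which: str) -> float:
        if which not in ESTIMATORS:
            raise KeyError(f"unknown estimator {which!r}; one of {ESTIMATORS}")
        return getattr(self, which)


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def estimate_thetas(sfs: np.ndarray, n: int) -> ThetaEstimates:
    """Diversity estimators from an unfolded spectrum over counts 1..n-1."""
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    sfs = np.asarray(sfs, dtype=float)
    if sfs.shape != (n - 1,):
        raise ValueError(f"spectrum must have length n-1 = {n - 1}")
    if (sfs < 0).any():
        raise ValueError("spectrum entries must be non-negative")
    i = np.arange(1, n)
    S = float(sfs.sum())
    a_n = harmonic(n)
    denom = n * (n - 1)
    return ThetaEstimates(
        theta_w=S / a_n,
        theta_pi=float(np.dot(sfs, 2.0 * i * (n - i)) / denom),
        theta_h=float(np.dot(sfs, 2.0 * i * i) / denom),
        S=int(round(S)),
        n=n,
        a_n=a_n,
    )


def class_ratio(num: ThetaEstimates, den: ThetaEstimates, which: str) -> float:
    """theta_x(deleterious) / theta_x(neutral) for one replicate.

    Returns NaN (a flagged missing value) when the denominator is zero; such
    replicates are excluded (and counted) by the aggregators below.
    """
    d = den.get(which)
    if d == 0:
        return float("nan")
    return num.get(which) / d


def thetas_from_sample(result: SampleResult, mclass: int) -> ThetaEstimates:
    return estimate_thetas(result.sfs_by_class[mclass], result.n)


def results_to_frame(results: list[SampleResult], rho: float = float("nan")) -> pd.DataFrame:
    """Tidy per-replicate estimator table (one row per rep/epoch/class)."""
    rows = []
    for res in results:
        for mclass, name in wf_sim.CLASS_NAMES.items():
            est = thetas_from_sample(res, mclass)
            rows.append({
                "rep": res.rep_id, "epoch": res.epoch, "rho": rho, "class": name,
                "theta_w": est.theta_w, "theta_pi": est.theta_pi,
                "theta_h": est.theta_h, "S": est.S,
            })
    return pd.DataFrame(rows)


def aggregate_ratio_of_means(frame: pd.DataFrame, which: str,
                             num_class: str = "deleterious",
                             den_class: str = "neutral") -> float:
    """Deleterious/neutral ratio as a ratio of replicate means.

    Mean of the per-replicate theta within each class first, then the ratio:
    per-replicate ratios are unstable whenever a replicate's neutral theta is
    zero, while the ratio of means is well-defined as long as the mean is.
    """
    means = frame.groupby("class")[which].mean()
    if den_class not in means or means[den_class] == 0:
        return float("nan")
    return float(means[num_class] / means[den_class])


def aggregate_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Per (rho, class, estimator) mean, standard error and replicate count."""
    rows = []
    for (rho, name), grp in frame.groupby(["rho", "class"], dropna=False):
        for which in ESTIMATORS:
            vals = grp[which].to_numpy()
            rows.append({
                "rho": rho, "class": name, "estimator": which,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                "n_reps": len(vals),
            })
    return pd.DataFrame(rows)
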