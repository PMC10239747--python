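"""Differential expression, signature intersection and survival stratification.

Differential calls use a Welch unequal-variance t-test on log2 values with
Benjamini–Hochberg FDR control; a feature is called "down" ("up") only when
both the effect-size and FDR thresholds are met.  Two cohort signatures are
intersected direction-aware to obtain the conserved signature.  Patients are
stratified by the median of a z-score signature over the conserved miRNAs
and compared with a two-group log-rank test computed from first principles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    CASE,
    CONTROL,
    DIRECTION_DOWN,
    DIRECTION_UNCHANGED,
    DIRECTION_UP,
    ClinicalTable,
    DESignature,
    ExpressionMatrix,
)
from .exceptions import (
    ConfigurationError,
    DegenerateSplitError,
    EmptySignatureError,
    InsufficientReplicationError,
)

logger = logging.getLogger(__name__)


def compute_de(mat: ExpressionMatrix, fc_threshold: float = 1.0,
               q_threshold: float = 0.05) -> DESignature:
    """Welch-t differential expression of case vs control, with BH FDR.

    ``log2fc`` is case mean minus control mean.  Features where both groups
    have zero variance get p = 1 when the means agree and p = 0 when they
    differ (the noise-free limit of the test).  Direction is ``down`` iff
    ``log2fc <= -fc_threshold`` and ``q <= q_threshold``; ``up`` is
    symmetric; otherwise ``unchanged``.
    """
    if mat.group is None:
        raise ConfigurationError("group: differential expression requires group labels")
    case_cols = mat.samples_in_group(CASE)
    ctrl_cols = mat.samples_in_group(CONTROL)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise InsufficientReplicationError(
            f"need >=2 samples per group, got case={len(case_cols)}, control={len(ctrl_cols)}")

    case = mat.values[case_cols].to_numpy(dtype=float)
    ctrl = mat.values[ctrl_cols].to_numpy(dtype=float)
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    zerovar = (case.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    p[zerovar & (lfc == 0)] = 1.0
    p[zerovar & (lfc != 0)] = 0.0
    p[np.isnan(p)] = 1.0

    q = multipletests(p, method="fdr_bh")[1]
    direction = np.full(len(lfc), DIRECTION_UNCHANGED, dtype=object)
    direction[(lfc <= -fc_threshold) & (q <= q_threshold)] = DIRECTION_DOWN
    direction[(lfc >= fc_threshold) & (q <= q_threshold)] = DIRECTION_UP
    table = pd.DataFrame(
        {"log2fc": lfc, "p": p, "q": q, "direction": direction},
        index=mat.values.index.copy(),
    )
    table.index.name = "feature_id"
    return DESignature(table)


def intersect_signatures(
    sig_a: DESignature, sig_b: DESignature
) -> tuple[set[str], set[str], set[str]]:
    """Direction-aware intersection of two DE signatures.

    Returns ``(down, up, discordant)``: features called down in both, up in
    both, and called in both but in opposite directions.  The three sets are
    disjoint and the operation is symmetric in its arguments.
    """
    down = sig_a.down & sig_b.down
    up = sig_a.up & sig_b.up
    discordant = (sig_a.down & sig_b.up) | (sig_a.up & sig_b.down)
    return down, up, discordant


def signature_score(mat: ExpressionMatrix, features) -> pd.Series:
    """Per-sample signature score: mean of feature-wise z-scores.

    Each listed feature is standardized across samples (population SD); a
    zero-variance feature contributes 0.  Features missing from the matrix
    are skipped with a warning; if none are present an
    :class:`EmptySignatureError` is raised.
    """
    features = sorted(set(features))
    present = [f for f in features if f in mat.values.index]
    missing = sorted(set(features) - set(present))
    if missing:
        logger.warning("signature_score: %d features absent from matrix: %s",
                       len(missing), missing[:5])
    if not present:
        raise EmptySignatureError("none of the signature features are present in the matrix")
    sub = mat.values.loc[present].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (sub - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.mean(axis=0), index=mat.values.columns, name="score")


def logrank_statistic(time, event, in_group_a) -> tuple[float, float]:
    """Two-group log-rank test (chi-square with 1 df), from first principles.

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the risk sets; the squared
    standardized sum is chi-square(1) under the null.  Ties are handled with
    the hypergeometric variance.  A zero total variance (no information)
    yields ``(0.0, 1.0)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    in_a = np.asarray(in_group_a, dtype=bool)
    observed_minus_expected = 0.0
    variance = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        deaths = int(((time == t) & (event == 1)).sum())
        deaths_a = int(((time == t) & (event == 1) & in_a).sum())
        observed_minus_expected += deaths_a - deaths * n_a / n
        if n > 1:
            variance += deaths * (n_a / n) * (1 - n_a / n) * (n - deaths) / (n - 1)
    if variance <= 0:
        return 0.0, 1.0
    chi_square = observed_minus_expected ** 2 / variance
    return float(chi_square), float(stats.chi2.sf(chi_square, df=1))


def logrank_by_median_score(
    scores: pd.Series, clin: ClinicalTable
) -> tuple[float, float, dict[str, int]]:
    """Split samples at the median signature score and log-rank the halves.

    Ties at the median go to the low group.  Returns ``(chi_square, p,
    group_sizes)`` where group sizes are keyed ``"low"`` / ``"high"``.
    """
    shared = [s for s in scores.index if s in clin.table.index]
    if len(shared) != len(scores) or len(shared) != len(clin.table):
        raise ConfigurationError(
            "scores and clinical table must cover the same samples")
    scores = scores.loc[shared]
    table = clin.table.loc[shared]
    if int(table["event"].sum()) < 1:
        raise ConfigurationError("log-rank requires at least one observed event")
    median = float(scores.median())
    low = scores <= median
    sizes = {"low": int(low.sum()), "high": int((~low).sum())}
    if sizes["low"] == 0 or sizes["high"] == 0:
        raise DegenerateSplitError(
            f"median split put all {len(scores)} samples in one group")
    chi_square, p = logrank_statistic(
        table["time_months"].to_numpy(), table["event"].to_numpy(), (~low).to_numpy())
    return chi_square, p, sizes


def plot_kaplan_meier(scores: pd.Series, clin: ClinicalTable, path) -> None:
    """Optional Kaplan–Meier figure for the median-score split (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    median = float(scores.median())
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, mask in (("low score", scores <= median), ("high score", scores > median)):
        sub = clin.table.loc[scores.index[mask]]
        t = np.sort(sub["time_months"].to_numpy())
        surv, times, s = 1.0, [0.0], [1.0]
        for ti in t:
            row = sub[sub["time_months"] == ti]
            at_risk = (sub["time_months"] >= ti).sum()
            d = int(row["event"].sum())
            if at_risk > 0 and d > 0:
                surv *= 1 - d / at_risk
            times.append(float(ti))
            s.append(surv)
        ax.step(times, s, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
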