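"""Within-patient inference on paired T/N uptake data.

The trial's estimand is the difference (or ratio) between the T/N uptake
ratio of the intra-arterially treated lobe and that of the contralateral
control lobe, within each patient.  The battery comprises:

* a paired t-test on the raw T/N pairs (primary endpoint, cycle 1);
* a paired t-test on log T/N with back-transformed (geometric) estimates;
* a two-level random-intercept linear mixed model over all cycles
  (random intercepts per patient and per cycle within patient);
* covariate effect-modification tests on that model;
* Fisher's exact test on r x c response tables by complete enumeration;
* the proportion of patients whose treated lobe increased.

All p-values are two-sided and no multiplicity adjustment is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "PairedTestResult",
    "RatioTestResult",
    "LMMResult",
    "paired_t_test",
    "log_ratio_test",
    "fit_two_level_lmm",
    "covariate_test",
    "fisher_exact_rxc",
    "proportion_increased",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "tn_ia", "tn_control")


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    t_statistic: float
    df: int
    p_value: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class RatioTestResult:
    geometric_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    df: int
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class LMMResult:
    fixed_effect_arm: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    var_patient: float
    var_cycle_within_patient: float
    var_residual: float
    n_obs: int
    converged: bool


def _complete_pairs(samples: pd.DataFrame, cycle: int | None) -> pd.DataFrame:
    df = samples.copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if cycle is not None:
        df = df[df["cycle"] == cycle]
    n_before = len(df)
    df = df.dropna(subset=["tn_ia", "tn_control"])
    if len(df) < n_before:
        logger.info("dropped %d incomplete pairs", n_before - len(df))
    return df


def _one_sample_t(diffs: np.ndarray, conf: float = 0.95):
    """One-sample t on differences: (mean, lo, hi, t, df, p, degenerate)."""
    n = diffs.size
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    df = n - 1
    if sd <= 1e-12 * max(abs(mean), np.max(np.abs(diffs)), 1e-300):
        # No within-pair variability: the point estimate is exact, the test
        # statistic is undefined unless the estimate is itself zero.
        if mean == 0.0:
            return 0.0, 0.0, 0.0, 0.0, df, 1.0, False
        return mean, mean, mean, math.inf, df, math.nan, True
    se = sd / math.sqrt(n)
    t = mean / se
    half = sps.t.ppf(0.5 + conf / 2, df) * se
    p = 2 * sps.t.sf(abs(t), df)
    return mean, mean - half, mean + half, t, df, float(p), False


def paired_t_test(samples: pd.DataFrame, cycle: int | None = 1) -> PairedTestResult:
    """Paired t-test of tn_ia against tn_control at one cycle.

    Equivalent to a one-sample t-test on the within-patient differences;
    rows with a missing side are dropped (available-case analysis).
    """
    df = _complete_pairs(samples, cycle)
    diffs = (df["tn_ia"] - df["tn_control"]).to_numpy(dtype=float)
    mean, lo, hi, t, dof, p, degen = _one_sample_t(diffs)
    return PairedTestResult(mean, lo, hi, t, dof, p, n=diffs.size, degenerate=degen)


def log_ratio_test(samples: pd.DataFrame, cycle: int | None = 1) -> RatioTestResult:
    """Paired t-test on natural-log T/N; estimates back-transformed by exp.

    The point estimate is the geometric mean of the within-patient ratios
    tn_ia / tn_control.  With zero variance on the log scale the estimate
    and the (zero-width) CI are still reported, with an undefined p-value
    flagged as degenerate.
    """
    df = _complete_pairs(samples, cycle)
    bad = df[(df["tn_ia"] <= 0) | (df["tn_control"] <= 0)]
    if len(bad):
        raise ValueError(
            f"non-positive T/N for patient(s) {sorted(bad['patient_id'].unique())}: "
            "log transform undefined"
        )
    diffs = np.log(df["tn_ia"].to_numpy(float)) - np.log(df["tn_control"].to_numpy(float))
    mean, lo, hi, _t, dof, p, degen = _one_sample_t(diffs)
    return RatioTestResult(
        geometric_ratio=math.exp(mean), ci_low=math.exp(lo), ci_high=math.exp(hi),
        p_value=p, df=dof, n=diffs.size, degenerate=degen,
    )


def _long_format(samples: pd.DataFrame, log_scale: bool) -> pd.DataFrame:
    rows = []
    for _, r in samples.iterrows():
        for arm, col in (("control", "tn_control"), ("ia", "tn_ia")):
            rows.append({
                "patient_id": r["patient_id"], "cycle": r.get("cycle", 1),
                "arm": 1 if arm == "ia" else 0,
                "tn": math.log(r[col]) if log_scale else r[col],
                **{c: r[c] for c in samples.columns if c not in
                   ("patient_id", "cycle", "tn_ia", "tn_control", "basis")},
            })
    return pd.DataFrame(rows).dropna(subset=["tn"])


def _fit_mixed(df: pd.DataFrame, formula: str):
    """REML fit with patient random intercept and, when more than one cycle
    is present, an additional random intercept per cycle within patient."""
    multi_cycle = df["cycle"].nunique() > 1
    kwargs = dict(groups=df["patient_id"], re_formula="1")
    if multi_cycle:
        kwargs["vc_formula"] = {"cycle": "0 + C(cycle)"}
    model = smf.mixedlm(formula, df, **kwargs)
    result = model.fit(reml=True, method=["lbfgs", "powell"])
    if not result.converged:
        raise RuntimeError(
            "mixed model did not converge; "
            f"{len(df)} rows, {df['patient_id'].nunique()} patients"
        )
    return result, multi_cycle


def fit_two_level_lmm(samples: pd.DataFrame, log_scale: bool = False) -> LMMResult:
    """Two-level random-intercept LMM for the arm effect over all cycles.

    Model: tn = intercept + beta * arm + u_patient + v_patient:cycle + eps,
    fitted by REML.  With a single cycle the per-cycle component coincides
    with the patient intercept and is dropped (reported as 0), which makes
    the balanced-design beta identical to the paired-t mean difference.
    """
    df = _long_format(_complete_pairs(samples, None), log_scale)
    result, multi_cycle = _fit_mixed(df, "tn ~ arm")
    beta = float(result.params["arm"])
    se = float(result.bse["arm"])
    ci = result.conf_int().loc["arm"]
    var_patient = float(np.asarray(result.cov_re)[0, 0])
    var_cycle = float(result.vcomp[0]) if multi_cycle else 0.0
    if min(var_patient, var_cycle) < 1e-10:
        logger.info("variance component at boundary: patient=%.3g cycle=%.3g",
                    var_patient, var_cycle)
    return LMMResult(
        fixed_effect_arm=beta, se=se, ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_value=float(result.pvalues["arm"]), var_patient=var_patient,
        var_cycle_within_patient=var_cycle, var_residual=float(result.scale),
        n_obs=len(df), converged=bool(result.converged),
    )


def covariate_test(samples: pd.DataFrame, covariate: str, log_scale: bool = True) -> float:
    """p-value of covariate-by-arm effect modification in the mixed model.

    Tests whether a per-patient factor (e.g. hypervascularity, treated lobe,
    tumour burden) changes the within-patient arm effect.
    """
    if covariate not in samples.columns:
        raise ValueError(f"covariate {covariate!r} not present")
    if samples[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    df = _long_format(_complete_pairs(samples, None), log_scale)
    numeric = pd.api.types.is_numeric_dtype(df[covariate])
    term = covariate if numeric else f"C({covariate})"
    result, _ = _fit_mixed(df, f"tn ~ arm * {term}")
    inter = [name for name in result.params.index
             if "arm" in name.split(":") and name != "arm"]
    if not inter:
        raise RuntimeError("interaction term not found in fitted model")
    pvals = result.pvalues[inter]
    return float(pvals.min()) if len(pvals) > 1 else float(pvals.iloc[0])


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - float(np.sum(gammaln(table + 1)))


def fisher_exact_rxc(table) -> float:
    """Fisher's exact test for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    conditional (multivariate hypergeometric) probabilities of tables no
    more probable than the observed one.  Suitable for the small tables of
    a response analysis; complexity grows rapidly with the margins.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("table has an empty row or column")
    total = int(obs.sum())
    log_margin_const = (
        float(np.sum(gammaln(row_sums + 1)) + np.sum(gammaln(col_sums + 1)))
        - float(gammaln(total + 1))
    )
    log_p_obs = _log_table_prob(obs, log_margin_const)

    r, c = obs.shape
    cells = [(i, j) for i in range(r) for j in range(c)]
    p_sum = 0.0
    p_total = 0.0
    work = np.zeros((r, c), dtype=int)

    def recurse(pos: int, row_rem: np.ndarray, col_rem: np.ndarray) -> None:
        nonlocal p_sum, p_total
        if pos == len(cells):
            lp = _log_table_prob(work, log_margin_const)
            p_total += math.exp(lp)
            if lp <= log_p_obs + 1e-9:
                p_sum += math.exp(lp)
            return
        i, j = cells[pos]
        # Last column of a row / last row of a column are forced.
        if j == c - 1:
            v = row_rem[i]
            if v > col_rem[j]:
                return
            work[i, j] = v
            row_rem[i] -= v
            col_rem[j] -= v
            recurse(pos + 1, row_rem, col_rem)
            row_rem[i] += v
            col_rem[j] += v
            return
        if i == r - 1:
            v = col_rem[j]
            if v > row_rem[i]:
                return
            work[i, j] = v
            row_rem[i] -= v
            col_rem[j] -= v
            recurse(pos + 1, row_rem, col_rem)
            row_rem[i] += v
            col_rem[j] += v
            return
        hi = min(row_rem[i], col_rem[j])
        for v in range(hi + 1):
            work[i, j] = v
            row_rem[i] -= v
            col_rem[j] -= v
            recurse(pos + 1, row_rem, col_rem)
            row_rem[i] += v
            col_rem[j] += v

    recurse(0, row_sums.copy(), col_sums.copy())
    # Normalizing by the enumerated total removes floating-point drift and
    # makes "all tables included" return exactly 1.0.
    return float(min(p_sum / p_total, 1.0))


def proportion_increased(samples: pd.DataFrame, cycle: int | None = 1):
    """Fraction of patients with tn_ia strictly greater than tn_control.

    Ties count as no increase (conservative).  Returns (fraction,
    n_increased, n_total).
    """
    df = _complete_pairs(samples, cycle)
    n_total = len(df)
    n_up = int((df["tn_ia"] > df["tn_control"]).sum())
    frac = n_up / n_total if n_total else 0.0
    return frac, n_up, n_total
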