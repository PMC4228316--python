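"""Process-evaluation statistics: Likert summaries, responder comparisons,
proportional-odds regressions and report assembly.

The proportional-odds (cumulative-logit) model treats an ordinal rating
``Y`` on levels ``1..K`` as ``P(Y <= k | x) = logit^{-1}(theta_k - x'beta)``
with one common ``beta`` across thresholds, so ``exp(beta_j)`` is the odds
ratio of rating *higher* per unit of predictor ``j``.  On a binary outcome
the model reduces exactly to binary logistic regression, and with a single
binary predictor the ML odds-ratio estimate is the 2x2 cross-product ratio —
both serve as independent checks of the fitter.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError

LIKERT_MIN, LIKERT_MAX = 1, 5


@dataclass(frozen=True)
class LikertSummary:
    """Completer summary of one 1–5 rating item."""

    item: str
    n: int
    mean: float
    sd: float
    p_ge3: float

    def as_dict(self) -> dict:
        return {"item": self.item, "n": self.n, "mean": self.mean,
                "sd": self.sd, "p_ge3": self.p_ge3}


def summarize_likert(values: Sequence[float], item: str = "item") -> LikertSummary:
    """Mean, sample SD and share responding >= 3 ("somewhat" to "very
    much"), computed on completers; missing values are excluded."""
    arr = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError(f"{item}: no observed ratings")
    if ((arr < LIKERT_MIN) | (arr > LIKERT_MAX)).any():
        raise ValueError(f"{item}: ratings outside the 1-5 scale")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return LikertSummary(
        item=item,
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        p_ge3=float(np.mean(arr >= 3)),
    )


# ---------------------------------------------------------------------------
# Proportional-odds regression
# ---------------------------------------------------------------------------

@dataclass
class OrdinalFit:
    """Estimates from a cumulative-logit fit.

    ``table`` has one row per predictor with columns ``or_`` (odds ratio of
    rating higher), ``ci_low``, ``ci_high`` (Wald 95% bounds on the OR
    scale), and ``p`` (unadjusted Wald p-value).
    """

    outcome: str
    table: pd.DataFrame
    cutpoints: np.ndarray
    converged: bool
    n_used: int
    mode: str = "multivariable"
    notes: tuple[str, ...] = field(default_factory=tuple)

    def odds_ratio(self, predictor: Optional[str] = None) -> float:
        if predictor is None:
            predictor = self.table.index[0]
        return float(self.table.loc[predictor, "or_"])


_SEPARATION_BETA = 15.0


def _fit_one(outcome: np.ndarray, X: pd.DataFrame, ci_level: float):
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()])) \
            < X.shape[1] + 1:
        raise FitError("singular design matrix")
    endog = pd.Series(pd.Categorical(outcome, ordered=True))
    model = OrderedModel(endog, X.to_numpy(), distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(method="bfgs", maxiter=500, disp=False)
    k = X.shape[1]
    beta = np.asarray(result.params[:k], dtype=float)
    se = np.asarray(result.bse[:k], dtype=float)
    cutpoints = np.asarray(model.transform_threshold_params(
        result.params)[1:-1], dtype=float)
    converged = bool(result.mle_retvals.get("converged", True))
    if np.any(np.abs(beta) > _SEPARATION_BETA) or np.any(~np.isfinite(se)):
        raise FitError(
            "complete or quasi-complete separation: unbounded estimate for "
            f"predictor(s) {list(X.columns[np.abs(beta) > _SEPARATION_BETA])}"
        )
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    table = pd.DataFrame({
        "or_": np.exp(beta),
        "ci_low": np.exp(beta - z * se),
        "ci_high": np.exp(beta + z * se),
        "p": 2.0 * stats.norm.sf(np.abs(beta / se)),
    }, index=list(X.columns))
    return table, cutpoints, converged


def fit_proportional_odds(
    outcome: Sequence[float],
    predictors: Union[pd.DataFrame, pd.Series, np.ndarray, Sequence[float]],
    outcome_name: str = "outcome",
    mode: str = "multivariable",
    ci_level: float = 0.95,
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit with Wald intervals.

    ``mode='multivariable'`` enters all predictors jointly;
    ``mode='univariable'`` fits each predictor in its own model (a
    per-predictor screen) and stacks the rows.  Rows with any missing value
    are dropped.  Constant outcomes, singular designs and separation raise
    :class:`FitError`; plain non-convergence is flagged on the result, not
    silently ignored.
    """
    if isinstance(predictors, pd.Series):
        predictors = predictors.to_frame()
    elif not isinstance(predictors, pd.DataFrame):
        arr = np.asarray(predictors, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        predictors = pd.DataFrame(
            arr, columns=[f"x{i + 1}" for i in range(arr.shape[1])])
    y = np.asarray(pd.to_numeric(pd.Series(outcome), errors="coerce"), dtype=float)
    frame = predictors.copy()
    frame.insert(0, "__y__", y)
    frame = frame.dropna()
    if frame.empty:
        raise FitError("no complete cases")
    y = frame.pop("__y__").to_numpy()
    if len(np.unique(y)) < 2:
        raise FitError("outcome is constant")
    n_used = len(frame)

    notes: list[str] = []
    if mode == "multivariable":
        table, cutpoints, converged = _fit_one(y, frame, ci_level)
    elif mode == "univariable":
        tables = []
        cutpoints = np.empty(0)
        converged = True
        for col in frame.columns:
            t, cutpoints, ok = _fit_one(y, frame[[col]], ci_level)
            tables.append(t)
            converged = converged and ok
        table = pd.concat(tables)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not converged:
        notes.append("optimizer did not report convergence")
        warnings.warn(f"{outcome_name}: proportional-odds fit did not converge",
                      stacklevel=2)
    return OrdinalFit(
        outcome=outcome_name,
        table=table,
        cutpoints=cutpoints,
        converged=converged,
        n_used=n_used,
        mode=mode,
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Responder / non-responder comparison
# ---------------------------------------------------------------------------

def compare_responders(
    data: pd.DataFrame,
    responder: Sequence[bool],
    variables: Sequence[str],
) -> pd.DataFrame:
    """Standardised differences between responders and non-responders.

    Continuous variables get the standardised mean difference (pooled SD)
    with a Welch t-test; binary variables get the proportion difference
    with a chi-squared test.  No multiplicity adjustment is applied and
    none is claimed.
    """
    responder = np.asarray(responder, dtype=bool)
    if responder.all() or not responder.any():
        raise ValueError("need at least one responder and one non-responder")
    rows = []
    for name in variables:
        values = pd.to_numeric(data[name], errors="coerce").to_numpy(dtype=float)
        keep = ~np.isnan(values)
        grp1 = values[keep & responder]
        grp0 = values[keep & ~responder]
        if grp1.size == 0 or grp0.size == 0:
            raise ValueError(f"{name}: a comparison group is empty")
        observed = np.unique(values[keep])
        binary = observed.size <= 2
        if binary:
            hi = observed.max()
            p1, p0 = float(np.mean(grp1 == hi)), float(np.mean(grp0 == hi))
            contingency = np.array([
                [np.sum(grp1 == hi), np.sum(grp1 != hi)],
                [np.sum(grp0 == hi), np.sum(grp0 != hi)],
            ])
            if contingency.sum(axis=0).min() == 0:
                statistic, p_value = np.nan, 1.0
            else:
                chi2 = stats.chi2_contingency(contingency, correction=False)
                statistic, p_value = float(chi2.statistic), float(chi2.pvalue)
            pooled = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
            smd = 0.0 if pooled == 0 else (p1 - p0) / pooled
            rows.append({"variable": name, "kind": "binary",
                         "difference": p1 - p0, "smd": float(smd),
                         "statistic": statistic, "p": p_value})
        else:
            v1 = np.var(grp1, ddof=1) if grp1.size > 1 else 0.0
            v0 = np.var(grp0, ddof=1) if grp0.size > 1 else 0.0
            pooled = np.sqrt((v1 + v0) / 2.0)
            diff = float(np.mean(grp1) - np.mean(grp0))
            smd = 0.0 if pooled == 0 else diff / pooled
            if pooled == 0:
                statistic, p_value = 0.0, 1.0
            else:
                t = stats.ttest_ind(grp1, grp0, equal_var=False)
                statistic, p_value = float(t.statistic), float(t.pvalue)
            rows.append({"variable": name, "kind": "continuous",
                         "difference": diff, "smd": float(smd),
                         "statistic": statistic, "p": p_value})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _hash_config(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def build_report(
    summaries: Sequence[LikertSummary],
    fits: Sequence[OrdinalFit] = (),
    heterogeneity: Optional[pd.DataFrame] = None,
    meta: Optional[Mapping[str, object]] = None,
) -> dict:
    """Assemble a deterministic evaluation report echoing all inputs.

    The report is a plain JSON-serialisable dict; ``meta`` (seed, config
    hashes, …) is embedded verbatim plus a content hash of itself.
    """
    meta = dict(meta or {})
    meta.setdefault("config_hash", _hash_config(meta))
    report: dict = {
        "meta": meta,
        "likert_summaries": [s.as_dict() for s in summaries],
        "ordinal_fits": [
            {
                "outcome": f.outcome,
                "mode": f.mode,
                "n_used": f.n_used,
                "converged": f.converged,
                "notes": list(f.notes),
                "p_values_adjusted": False,
                "cutpoints": [float(c) for c in f.cutpoints],
                "predictors": {
                    str(name): {
                        "or": float(row["or_"]),
                        "ci_low": float(row["ci_low"]),
                        "ci_high": float(row["ci_high"]),
                        "p": float(row["p"]),
                    }
                    for name, row in f.table.iterrows()
                },
            }
            for f in fits
        ],
    }
    if heterogeneity is not None:
        report["heterogeneity"] = heterogeneity.to_dict(orient="records")
    return report


def report_to_json(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def read_report(path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def report_to_html(report: Mapping) -> str:
    """Plain HTML rendering of a report for human review."""
    parts = ["<html><body>", "<h1>Process evaluation report</h1>"]
    parts.append("<h2>Rating summaries</h2><table border='1'>")
    parts.append("<tr><th>item</th><th>n</th><th>mean</th><th>SD</th>"
                 "<th>P(&ge;3)</th></tr>")
    for s in report.get("likert_summaries", []):
        parts.append(
            f"<tr><td>{s['item']}</td><td>{s['n']}</td>"
            f"<td>{s['mean']:.2f}</td><td>{s['sd']:.2f}</td>"
            f"<td>{s['p_ge3']:.3f}</td></tr>")
    parts.append("</table>")
    for fit in report.get("ordinal_fits", []):
        parts.append(f"<h2>Ordinal model: {fit['outcome']} "
                     f"(n={fit['n_used']}, {fit['mode']})</h2>")
        parts.append("<table border='1'><tr><th>predictor</th><th>OR</th>"
                     "<th>95% CI</th><th>p (unadjusted)</th></tr>")
        for name, row in fit["predictors"].items():
            parts.append(
                f"<tr><td>{name}</td><td>{row['or']:.2f}</td>"
                f"<td>{row['ci_low']:.2f}&ndash;{row['ci_high']:.2f}</td>"
                f"<td>{row['p']:.3g}</td></tr>")
        parts.append("</table>")
    parts.append("</body></html>")
    return "\n".join(parts)
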