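"""Marginal likelihoods, Bayes factors, HPD intervals and model screening.

The regime comparison rests on three ingredients:

* the 95% highest-posterior-density interval of the sampled log-likelihood
  (shortest interval containing the requested mass);
* the log marginal likelihood, estimated from the post-burn-in likelihood
  trace by the harmonic-mean estimator computed stably in log space
  (log-sum-exp), with a moving-block bootstrap standard error — the
  estimator is known to be upwardly biased and noisy, which is why the SE
  is always carried along; the naive variant is exposed for comparison;
* log Bayes factors lnBF = lnML_A - lnML_B read against the conventional
  thresholds: > 2 positive, > 5 strong evidence.

Also here: the likelihood-saturation scan over mixture components K (the
"how many rate matrices are enough" question) and small-sample-corrected
AIC screening of substitution models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .mcmc import McmcTrace


class ComparisonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# posterior summaries


def hpd_interval(values, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` of the sorted values.

    Ties between equally short candidate intervals break to the left-most,
    making the result deterministic on multimodal samples.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 20:
        raise ComparisonError(f"need >= 20 values for an HPD interval, got {n}")
    if not (0 < mass <= 1):
        raise ComparisonError("mass must be in (0, 1]")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: left-most tie-break
    return float(x[i]), float(x[i + k - 1])


def log_marginal_likelihood(
    trace_or_lnls, n_bootstrap: int = 200, block: int | None = None, seed: int = 0,
    stabilized: bool = True,
) -> tuple[float, float]:
    """Harmonic-mean estimate of ln marginal likelihood with a bootstrap SE.

    lnML = -( logsumexp(-lnL_i) - ln n ) over post-burn-in samples; the
    log-sum-exp keeps the computation finite however large the likelihoods
    are.  The SE comes from a moving-block bootstrap (block length ~ sqrt(n)
    by default) to respect chain autocorrelation.  ``stabilized=False``
    accumulates the harmonic mean directly in probability space (shifted by
    the minimum); identical in exact arithmetic, exposed so the naive
    accumulation can be compared.

    Returns (lnML, bootstrap SE).
    """
    if isinstance(trace_or_lnls, McmcTrace):
        lnls = trace_or_lnls.lnl_values(post_burn_in=True)
        if len(lnls) < 100:
            import warnings

            warnings.warn(
                f"only {len(lnls)} post-burn-in samples: harmonic-mean estimate "
                "will be unstable",
                RuntimeWarning,
            )
    else:
        lnls = np.asarray(trace_or_lnls, dtype=float)
    n = lnls.size
    if n < 2:
        raise ComparisonError("need at least 2 likelihood samples")

    def hm(v: np.ndarray) -> float:
        if stabilized:
            return float(-(logsumexp(-v) - np.log(v.size)))
        return float(-np.log(np.mean(np.exp(-(v - v.min()))))) + float(v.min())

    est = hm(lnls)
    b = block or max(1, int(np.sqrt(n)))
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / b))
    starts_max = n - b + 1
    reps = np.empty(n_bootstrap)
    for r in range(n_bootstrap):
        starts = rng.integers(0, starts_max, n_blocks)
        sample = np.concatenate([lnls[s : s + b] for s in starts])[:n]
        reps[r] = hm(sample)
    return est, float(reps.std(ddof=1))


def log_bayes_factor(lnml_a: float, lnml_b: float) -> tuple[float, str]:
    """logBF = lnML_A - lnML_B with the >2 positive / >5 strong convention."""
    if not (np.isfinite(lnml_a) and np.isfinite(lnml_b)):
        raise ComparisonError("marginal likelihoods must be finite")
    bf = float(lnml_a - lnml_b)
    mag = abs(bf)
    verdict = "strong" if mag > 5 else "positive" if mag > 2 else "indistinguishable"
    return bf, verdict


# ---------------------------------------------------------------------------
# the comparison table


@dataclass(frozen=True)
class ComparisonRow:
    regime: str
    mean_neg_lnl: float
    hpd_low: float
    hpd_high: float
    hpd_half_width: float
    mean_tl: float
    ln_marginal_likelihood: float
    ln_ml_se: float


@dataclass(frozen=True)
class BayesFactorMatrix:
    regimes: tuple[str, ...]
    logbf: np.ndarray  # antisymmetric, [i, j] = lnML_i - lnML_j

    def verdict(self, a: str, b: str) -> tuple[float, str]:
        i, j = self.regimes.index(a), self.regimes.index(b)
        bf = float(self.logbf[i, j])
        return log_bayes_factor(bf, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.logbf, index=self.regimes, columns=self.regimes)


def comparison_table(
    traces: list[McmcTrace], labels: list[str] | None = None
) -> tuple[list[ComparisonRow], BayesFactorMatrix]:
    """Regime comparison: mean -lnL, 95% HPD, mean TL, lnML and pairwise logBF.

    Rows are sorted by mean -lnL descending (worst fit first), matching the
    conventional presentation.  Mean -lnL and the Bayes factors are distinct
    functionals of the trace and are reported separately.
    """
    if len(traces) < 2:
        raise ComparisonError("need at least two traces to compare")
    labels = labels or [t.label for t in traces]
    burnins = {t.config.burn_in_generations / t.config.n_generations for t in traces}
    if len(burnins) > 1:
        raise ComparisonError("traces have mismatched burn-in fractions")
    rows = []
    for lbl, tr in zip(labels, traces):
        lnls = tr.lnl_values()
        lo, hi = hpd_interval(lnls) if len(lnls) >= 20 else (lnls.min(), lnls.max())
        lnml, se = log_marginal_likelihood(tr.lnl_values())
        rows.append(
            ComparisonRow(
                regime=lbl,
                mean_neg_lnl=float(-lnls.mean()),
                hpd_low=float(lo),
                hpd_high=float(hi),
                hpd_half_width=float((hi - lo) / 2),
                mean_tl=float(tr.tl_values().mean()),
                ln_marginal_likelihood=lnml,
                ln_ml_se=se,
            )
        )
    rows.sort(key=lambda r: -r.mean_neg_lnl)
    names = tuple(r.regime for r in rows)
    lnml = np.array([r.ln_marginal_likelihood for r in rows])
    mat = lnml[:, None] - lnml[None, :]
    return rows, BayesFactorMatrix(names, mat)


def comparison_to_csv(rows: list[ComparisonRow], matrix: BayesFactorMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "regime": [r.regime for r in rows],
            "mean_neg_lnL": [r.mean_neg_lnl for r in rows],
            "hpd95_low": [r.hpd_low for r in rows],
            "hpd95_high": [r.hpd_high for r in rows],
            "mean_TL": [r.mean_tl for r in rows],
            "ln_marginal_likelihood": [r.ln_marginal_likelihood for r in rows],
            "ln_ml_se": [r.ln_ml_se for r in rows],
        }
    )
    bf = matrix.to_dataframe().add_prefix("logBF_vs_")
    pd.concat([df.set_index("regime"), bf], axis=1).to_csv(path)


# ---------------------------------------------------------------------------
# saturation over mixture components


def saturation_analysis(
    results: list[tuple[int, float]], plateau_fraction: float = 0.10
) -> dict:
    """Successive lnL improvements over increasing mixture size K.

    ``results`` is a (K, lnL-summary) sequence with K strictly increasing
    from 1.  The plateau K is the first K whose improvement over the
    previous model falls below ``plateau_fraction`` of the first step's
    improvement — the point where adding rate matrices stops paying.
    """
    ks = [k for k, _ in results]
    if len(results) < 2:
        raise ComparisonError("need at least two (K, lnL) entries")
    if ks[0] != 1 or any(b <= a for a, b in zip(ks, ks[1:])):
        raise ComparisonError("K values must strictly increase starting at 1")
    lnls = np.array([v for _, v in results], dtype=float)
    deltas = np.diff(lnls)
    first = deltas[0]
    plateau_k = None
    for i, d in enumerate(deltas):
        if d <= plateau_fraction * max(first, 0) or d <= 0:
            plateau_k = ks[i + 1]
            break
    if plateau_k is None:
        plateau_k = ks[-1]
    return {
        "K": ks,
        "lnL": lnls.tolist(),
        "delta_lnL": deltas.tolist(),
        "plateau_K": int(plateau_k),
    }


def saturation_to_csv(result: dict, path) -> None:
    pd.DataFrame(
        {
            "K": result["K"],
            "lnL": result["lnL"],
            "delta_lnL": [np.nan] + list(result["delta_lnL"]),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# AICc screening


def aicc_select(candidates: list[tuple[str, float, int]], n_sites: int) -> pd.DataFrame:
    """Rank substitution models by small-sample-corrected AIC.

    AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1), with lnL the maximized
    log-likelihood, k the free-parameter count and n the site count.
    Returns an ascending table with a delta column.
    """
    for name, _lnl, k in candidates:
        if n_sites <= k + 1:
            raise ComparisonError(
                f"model {name!r}: n={n_sites} too small for k={k} parameters"
            )
    rows = [
        (name, lnl, k, -2 * lnl + 2 * k + 2 * k * (k + 1) / (n_sites - k - 1))
        for name, lnl, k in candidates
    ]
    df = pd.DataFrame(rows, columns=["model", "lnL", "k", "AICc"]).sort_values(
        "AICc", kind="stable", ignore_index=True
    )
    df["delta_AICc"] = df["AICc"] - df["AICc"].iloc[0]
    return df
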