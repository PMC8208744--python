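"""Per-pair hypothesis testing: filters, model routing and FDR control.

For each region pair the long-isoform ratio R_j = n_long / (n_short +
n_long) is modelled against the condition of interest plus known
covariates.  Pairs whose ratios stay inside (0,1) use the beta
regression; a ratio exactly at 0 or 1 in any sample routes the pair to
the quasi-binomial GLM, whose likelihood is defined at the boundary.
P-values on the condition coefficient are two-sided Wald (beta path,
normal reference; optionally likelihood-ratio) or t-based (quasi-binomial
path), adjusted across tested pairs by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regression import BetaRegression, QuasiBinomialRegression


def compute_ratio(n_short, n_long):
    """Long-region read proportion R = n_long / (n_short + n_long).

    Vectorized; a zero total yields NaN (masked: no information about the
    isoform proportion).
    """
    n_short = np.asarray(n_short, dtype=float)
    n_long = np.asarray(n_long, dtype=float)
    total = n_short + n_long
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, n_long / np.where(total > 0, total, 1), np.nan)
    if r.ndim == 0:
        return float(r)
    return r


def build_design(samples: pd.DataFrame, condition: str = "group",
                 covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Build the per-sample design matrix (without intercept).

    The condition column must have exactly two levels and becomes a 0/1
    indicator named 'condition' (second level in sorted order = 1).
    Categorical covariates are expanded to treatment-coded indicators;
    numeric covariates are kept as-is.  A rank-deficient design (e.g. a
    covariate confounded with the condition) is a hard error naming the
    collinear columns, since silently dropping columns would misattribute
    effects.
    """
    if condition not in samples.columns:
        raise ValueError(f"sample sheet lacks condition column {condition!r}")
    levels = sorted(samples[condition].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"condition column {condition!r} must have exactly 2 levels, "
            f"got {levels}"
        )
    cols = {"condition": (samples[condition].astype(str) == levels[1]).astype(float)}
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"sample sheet lacks covariate column {cov!r}")
        col = samples[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].astype(float)
    X = pd.DataFrame(cols, index=samples.index)
    if (X["condition"] == X["condition"].iloc[0]).all():
        raise ValueError("condition column is constant across samples")
    full = np.column_stack([np.ones(len(X)), X.to_numpy()])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(
            "design matrix is rank-deficient; collinear columns: "
            + ", ".join(bad)
        )
    return X


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    names = list(X.columns)
    base = np.ones((len(X), 1))
    bad = []
    for name in names:
        cand = np.column_stack([base, X[name].to_numpy()])
        if np.linalg.matrix_rank(cand) == base.shape[1]:
            bad.append(name)
        else:
            base = cand
    return bad or names


def filter_pairs(counts: pd.DataFrame, tin: pd.DataFrame | None = None,
                 min_short: float = 10, min_tin: float = 40) -> pd.DataFrame:
    """Per-pair filter flags.

    low_short_reads: mean n_short across samples below ``min_short`` (too
    few reads in the short region to inform the proportion).
    low_tin: median TIN across samples below ``min_tin`` (degraded
    transcript, coverage not trustworthy).  TIN filtering is skipped when
    no TIN table is given.
    all_zero_long: no long-region read in any sample.
    """
    if min_short < 0 or min_tin < 0:
        raise ValueError("filter thresholds must be >= 0")
    g = counts.groupby("pair_id", sort=False)
    flags = pd.DataFrame({
        "low_short_reads": g["n_short"].mean() < min_short,
        "all_zero_long": g["n_long"].sum() == 0,
    })
    flags["low_tin"] = False
    if tin is not None:
        med = tin.groupby("transcript_id")["tin"].median()
        tx_of = g["transcript_id"].first()
        flags["low_tin"] = tx_of.map(med).fillna(0.0) < min_tin
    return flags[["low_short_reads", "low_tin", "all_zero_long"]]


@dataclass
class APATestResult:
    """Outcome of testing one region pair."""

    pair_id: str
    transcript_id: str
    method: str  # 'beta' | 'quasibinomial' | 'filtered'
    estimate: float = np.nan
    std_error: float = np.nan
    statistic: float = np.nan
    p_value: float = np.nan
    p_adjusted: float = np.nan
    flags: tuple[str, ...] = ()

    def to_row(self) -> dict:
        d = self.__dict__.copy()
        d["flags"] = ";".join(self.flags) if self.flags else ""
        return d


def test_pair(n_short, n_long, X, *, routing: str = "any_boundary",
              test: str = "wald") -> dict:
    """Fit one pair and test the condition coefficient (two-sided).

    ``X`` is the design without intercept, condition in column 0.
    ``routing`` decides when to fall back to the quasi-binomial model:
    'any_boundary' (default; any sample ratio exactly 0 or 1) or
    'all_zero_long' (only when no sample has long reads).  ``test``
    selects 'wald' (default) or 'lrt' p-values on the beta path.
    """
    if routing not in ("any_boundary", "all_zero_long"):
        raise ValueError(f"unknown routing rule {routing!r}")
    if test not in ("wald", "lrt"):
        raise ValueError(f"unknown test {test!r}")
    n_short = np.asarray(n_short, dtype=float)
    n_long = np.asarray(n_long, dtype=float)
    X = np.asarray(X, dtype=float)
    total = n_short + n_long
    keep = total > 0
    r = compute_ratio(n_short[keep], n_long[keep])
    Xk = X[keep]
    boundary = np.any((r == 0) | (r == 1))
    use_qb = boundary if routing == "any_boundary" else np.all(n_long == 0)
    if use_qb:
        fit = QuasiBinomialRegression().fit(Xk, r, totals=total[keep])
        if not fit.testable_:
            return {"method": "quasibinomial", "estimate": np.nan,
                    "std_error": np.nan, "statistic": np.nan,
                    "p_value": np.nan, "converged": False}
        return {"method": "quasibinomial", "estimate": fit.params_[1],
                "std_error": fit.bse_[1], "statistic": fit.tvalues_[1],
                "p_value": fit.pvalues_[1], "converged": True}
    if boundary:  # routing says beta but the likelihood is undefined there
        fit = QuasiBinomialRegression().fit(Xk, r, totals=total[keep])
        if not fit.testable_:
            return {"method": "quasibinomial", "estimate": np.nan,
                    "std_error": np.nan, "statistic": np.nan,
                    "p_value": np.nan, "converged": False}
        return {"method": "quasibinomial", "estimate": fit.params_[1],
                "std_error": fit.bse_[1], "statistic": fit.tvalues_[1],
                "p_value": fit.pvalues_[1], "converged": True}
    try:
        fit = BetaRegression().fit(Xk, r)
    except (ValueError, np.linalg.LinAlgError):
        return {"method": "beta", "estimate": np.nan, "std_error": np.nan,
                "statistic": np.nan, "p_value": np.nan, "converged": False}
    if not fit.converged_:
        return {"method": "beta", "estimate": np.nan, "std_error": np.nan,
                "statistic": np.nan, "p_value": np.nan, "converged": False}
    est, se = fit.params_[1], fit.bse_[1]
    z = fit.zvalues_[1]
    if test == "wald":
        p = fit.pvalues_[1]
    else:
        null = fit.loglik_null(Xk, r, drop=1)
        lr = 2 * (fit.loglik_ - null.loglik_)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return {"method": "beta", "estimate": est, "std_error": se,
            "statistic": z, "p_value": p, "converged": True}


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def run_apa(counts: pd.DataFrame, samples: pd.DataFrame, *,
            tin: pd.DataFrame | None = None, condition: str = "group",
            covariates: tuple[str, ...] = (), min_short: float = 10,
            min_tin: float = 40, alpha: float = 0.05,
            routing: str = "any_boundary", test: str = "wald") -> pd.DataFrame:
    """Run the full per-pair testing pipeline on a counts table.

    ``counts`` has columns pair_id, transcript_id, sample_id, n_short,
    n_long; ``samples`` has sample_id, the condition column and any
    covariates.  Returns one row per input pair (tested or filtered),
    ordered by adjusted p-value; deterministic given inputs and options.
    """
    required = {"pair_id", "transcript_id", "sample_id", "n_short", "n_long"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks columns: {sorted(missing)}")
    if "sample_id" not in samples.columns:
        raise ValueError("sample sheet lacks a sample_id column")
    count_samples = set(counts["sample_id"].unique())
    sheet_samples = set(samples["sample_id"].astype(str))
    unknown = count_samples - sheet_samples
    if unknown:
        raise ValueError(
            f"samples present in counts but missing from the sample sheet: "
            f"{sorted(unknown)}"
        )
    samples = samples.set_index("sample_id", drop=False)
    X = build_design(samples, condition=condition, covariates=covariates)

    flags_df = filter_pairs(counts, tin=tin, min_short=min_short, min_tin=min_tin)
    results: list[APATestResult] = []
    for pair_id, sub in counts.groupby("pair_id", sort=False):
        tx = sub["transcript_id"].iloc[0]
        sub = sub.set_index("sample_id")
        order = [s for s in samples.index if s in sub.index]
        sub = sub.loc[order]
        Xp = X.loc[order].to_numpy()
        fl = flags_df.loc[pair_id]
        flag_names = tuple(n for n in ("low_short_reads", "low_tin") if fl[n])
        if flag_names:
            results.append(APATestResult(pair_id, tx, "filtered",
                                         flags=flag_names))
            continue
        extra = ("all_zero_long",) if fl["all_zero_long"] else ()
        out = test_pair(sub["n_short"].to_numpy(), sub["n_long"].to_numpy(),
                        Xp, routing=routing, test=test)
        results.append(APATestResult(
            pair_id, tx, out["method"], out["estimate"], out["std_error"],
            out["statistic"], out["p_value"], flags=extra))

    df = pd.DataFrame([r.to_row() for r in results])
    df["p_adjusted"] = adjust_pvalues(df["p_value"].to_numpy())
    df = df.sort_values(
        ["p_adjusted", "p_value", "pair_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["alpha"] = alpha
    df.attrs["n_significant"] = int((df["p_adjusted"] < alpha).sum())
    return df
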