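"""Kaplan-Meier estimation and log-rank screening of candidate genes.

Samples are split into high/low expression groups at the median (strictly
above = high, ties go to low; the quantile is configurable), survival in the
two groups is estimated with the product-limit (Kaplan-Meier) estimator, and
the difference is scored with the standard two-group log-rank chi-square test
(1 df).  Screening a gene list inside one subtype's patients reports each
gene's statistic, p-value and a significance flag at p < alpha (strict,
default 0.05, uncorrected by default; Benjamini-Hochberg optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from gainet.io_formats import OmicsMatrix


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalRecords:
    """Per-sample follow-up: time on study and event indicator (1 = death)."""

    table: pd.DataFrame  # columns: sample_id, time, event

    REQUIRED = ("sample_id", "time", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SurvivalError(f"survival table missing column(s) {missing}")
        t = self.table["time"].to_numpy(dtype=float)
        e = self.table["event"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise SurvivalError("times must be finite and nonnegative")
        if not np.all(np.isin(e, (0, 1))):
            raise SurvivalError("event must be 0 (censored) or 1 (death)")

    def subset(self, sample_ids) -> "SurvivalRecords":
        t = self.table[self.table["sample_id"].isin(list(sample_ids))]
        return SurvivalRecords(t.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class KMResult:
    """Two-group survival comparison: step functions plus the log-rank test."""

    groups: dict[str, pd.DataFrame]  # per group: time, at_risk, events, survival
    group_sizes: dict[str, int]
    statistic: float  # NaN when undefined (no events anywhere)
    p_value: float


def read_survival(path, sep: str = "\t") -> SurvivalRecords:
    df = pd.read_csv(path, sep=sep)
    return SurvivalRecords(df.astype({"sample_id": str}))


def dichotomize_by_expression(values, quantile: float = 0.5) -> np.ndarray:
    """Label samples 'high' (strictly above the quantile) or 'low' (at or below).

    Raises if either group would be empty (e.g. constant expression).
    """
    v = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(v)):
        raise SurvivalError("expression values must be finite")
    cut = np.quantile(v, quantile)
    labels = np.where(v > cut, "high", "low")
    if len(np.unique(labels)) < 2:
        raise SurvivalError(
            "dichotomization produced an empty group (constant expression?)"
        )
    return labels


def km_estimate(records: SurvivalRecords) -> pd.DataFrame:
    """Product-limit survival curve: S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Returns one row per distinct event/censoring time with the number at
    risk, observed events and the survival estimate.  Subjects censored at
    an event time are counted at risk at that time.
    """
    if len(records) == 0:
        raise SurvivalError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(records.table["time"], records.table["event"])
    et = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": et.index.to_numpy(dtype=float),
            "at_risk": et["at_risk"].to_numpy(dtype=float),
            "events": et["observed"].to_numpy(dtype=float),
            "survival": surv.reindex(et.index).to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


def logrank_test(group_a: SurvivalRecords, group_b: SurvivalRecords) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df): U^2/V with hypergeometric variance.

    Returns (statistic, p).  With no events in either group the statistic is
    undefined and (NaN, NaN) is returned rather than 0.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise SurvivalError("both groups must be non-empty")
    if group_a.table["event"].sum() == 0 and group_b.table["event"].sum() == 0:
        return float("nan"), float("nan")
    res = _ll_logrank(
        group_a.table["time"],
        group_b.table["time"],
        event_observed_A=group_a.table["event"],
        event_observed_B=group_b.table["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def compare_groups(records: SurvivalRecords, labels: np.ndarray) -> KMResult:
    """KM curves plus log-rank for a two-level grouping of the records."""
    labels = np.asarray(labels)
    if len(labels) != len(records):
        raise SurvivalError("one label per record required")
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise SurvivalError(f"exactly two groups required, got {names}")
    parts = {}
    for name in names:
        t = records.table[labels == name].reset_index(drop=True)
        parts[name] = SurvivalRecords(t)
    stat, p = logrank_test(parts[names[0]], parts[names[1]])
    return KMResult(
        groups={n: km_estimate(parts[n]) for n in names},
        group_sizes={n: len(parts[n]) for n in names},
        statistic=stat,
        p_value=p,
    )


def screen_genes(
    expr: OmicsMatrix,
    records: SurvivalRecords,
    gene_list: list[str],
    alpha_level: float = 0.05,
    quantile: float = 0.5,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Median-split + log-rank for each gene over the given samples.

    Only samples present in both the expression matrix and the survival
    records are used.  Significance is p < alpha_level strictly, uncorrected
    unless ``bh_correct``; genes whose expression cannot be dichotomised or
    whose test is undefined get NaN statistics and a False flag.
    """
    rec = records.subset(expr.sample_ids)
    ids = [s for s in expr.sample_ids if s in set(rec.table["sample_id"])]
    if not ids:
        raise SurvivalError("no overlap between expression samples and survival records")
    rec = SurvivalRecords(
        rec.table.set_index("sample_id").loc[ids].reset_index()
    )
    expr = expr.subset(sample_ids=ids)

    rows = []
    for gene in gene_list:
        if gene not in expr.feature_ids:
            rows.append({"gene": gene, "statistic": np.nan, "p": np.nan})
            continue
        values = expr.values[expr.feature_ids.index(gene)]
        try:
            labels = dichotomize_by_expression(values, quantile)
            stat, p = logrank_test(
                SurvivalRecords(rec.table[labels == "low"].reset_index(drop=True)),
                SurvivalRecords(rec.table[labels == "high"].reset_index(drop=True)),
            )
        except SurvivalError:
            stat, p = np.nan, np.nan
        rows.append({"gene": gene, "statistic": stat, "p": p})
    out = pd.DataFrame(rows, columns=["gene", "statistic", "p"])
    if bh_correct and len(out):
        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        pcol = "p_adjusted"
    else:
        pcol = "p"
    out["significant"] = out[pcol].notna() & (out[pcol] < alpha_level)
    return out
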