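"""Per-subject taxon-metabolite association with FDR control.

Dense longitudinal series allow association to be assessed within each subject
separately: for every subject, Spearman's rank correlation is computed between
each retained taxon's relative abundance and each metabolite concentration
across that subject's time points, p-values come from the t approximation with
n-2 degrees of freedom, and Benjamini-Hochberg correction is applied within
the subject (optionally across the whole grid).  Cross-subject summaries
report the mean +/- SD of r per pair and the number of subjects significant at
a q threshold.

No autocorrelation adjustment is made — consecutive stool samples are treated
as exchangeable, which inflates nominal significance on strongly autocorrelated
series; see the methods note.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortDataset, SCFA_COLUMNS

logger = logging.getLogger(__name__)


def spearman(x, y, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Returns (r, p); p is two-sided from the t approximation with n-2 df
    (``method='exact'`` uses the permutation-exact distribution, sensible for
    n <= 10).  When either ranked vector is constant the correlation is
    undefined and (nan, nan) is returned rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 paired samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("constant series: Spearman correlation undefined")
        return float("nan"), float("nan")
    if method == "exact":
        res = stats.permutation_test(
            (x,), lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings", n_resamples=np.inf,
        )
        r = float(stats.spearmanr(x, y).statistic)
        return r, float(res.pvalue)
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def per_subject_correlations(
    cohort: CohortDataset,
    metabolites=SCFA_COLUMNS,
    min_abundance: float = 0.02,
    max_taxa: int = 6,
    min_samples: int = 10,
    fdr_scope: str = "subject",
) -> pd.DataFrame:
    """Spearman r/p/q for each subject x taxon x metabolite.

    Taxa are order-level abundances filtered to mean abundance >
    ``min_abundance`` across all samples, keeping at most ``max_taxa`` (the
    most abundant).  Subjects with fewer than ``min_samples`` samples are
    skipped with a log entry.  ``fdr_scope`` is 'subject' (BH within each
    subject across all pairs tested, the default) or 'global'.
    """
    if fdr_scope not in ("subject", "global"):
        raise ValueError("fdr_scope must be 'subject' or 'global'")
    orders = cohort.order_table()
    mean_ab = orders.mean(axis=0).sort_values(ascending=False)
    taxa = list(mean_ab[mean_ab > min_abundance].index[:max_taxa])
    if not taxa:
        logger.warning("no taxa pass the %.3g abundance threshold", min_abundance)
        return pd.DataFrame(
            columns=["subject_id", "taxon", "metabolite", "r", "p", "q", "n"]
        )
    rows = []
    for sid, comp in orders.groupby(cohort.composition["subject_id"]):
        if len(comp) < min_samples:
            logger.info("subject %s skipped (%d < %d samples)", sid, len(comp), min_samples)
            continue
        scfa = cohort.scfa.loc[comp.index]
        for taxon in taxa:
            for met in metabolites:
                r, p = spearman(comp[taxon].to_numpy(), scfa[met].to_numpy())
                rows.append({"subject_id": sid, "taxon": taxon, "metabolite": met,
                             "r": r, "p": p, "n": len(comp)})
    results = pd.DataFrame(rows)
    if results.empty:
        results["q"] = []
        return results
    results["q"] = np.nan
    if fdr_scope == "global":
        ok = results["p"].notna()
        results.loc[ok, "q"] = bh_adjust(results.loc[ok, "p"].to_numpy())
    else:
        for _, grp in results.groupby("subject_id"):
            sel = grp.index[grp["p"].notna()]
            if len(sel):
                results.loc[sel, "q"] = bh_adjust(results.loc[sel, "p"].to_numpy())
    return results


def cross_subject_summary(results: pd.DataFrame, q_threshold: float = 0.01) -> pd.DataFrame:
    """Mean/SD of r per taxon x metabolite pair over subjects, and how many
    subjects are significant at ``q < q_threshold``.

    Undefined correlations (constant series) are excluded from the mean; the
    SD uses the n-1 denominator and is absent (NaN) for a single subject.
    """
    if results.empty:
        return pd.DataFrame(
            columns=["taxon", "metabolite", "mean_r", "sd_r", "n_subjects", "n_significant"]
        )
    rows = []
    for (taxon, met), grp in results.groupby(["taxon", "metabolite"], sort=True):
        r = grp["r"].dropna()
        rows.append({
            "taxon": taxon,
            "metabolite": met,
            "mean_r": float(r.mean()) if len(r) else np.nan,
            "sd_r": float(r.std(ddof=1)) if len(r) > 1 else np.nan,
            "n_subjects": int(len(r)),
            "n_significant": int((grp["q"].dropna() < q_threshold).sum()),
        })
    return pd.DataFrame(rows)
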