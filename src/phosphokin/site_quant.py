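"""Site-group quantification: grouping, normalization, summarization, testing.

The quantification path mirrors the standard label-free phosphoproteomics
workflow: peptide ions are grouped by the set of phosphosites they carry
("phosphorylation site groups"), log2 intensities are normalized by median
equalization, fragments are combined into one value per site group and
sample by Tukey median polish, and condition contrasts are tested with
two-sample pooled-variance Student's t-tests followed by Benjamini-Hochberg
adjustment. Missing values stay missing at every stage; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ParseError
from .sites import make_group_key

__all__ = [
    "flag_sample_outliers",
    "to_site_groups",
    "normalize_median_equalization",
    "median_polish",
    "summarize_median_polish",
    "summarize_site_groups",
    "differential_sites",
    "adjust_bh",
    "MedianPolishResult",
]


# ---------------------------------------------------------------------------
# sample-level QC


def flag_sample_outliers(
    evidence: pd.DataFrame, threshold: float = 3.0, min_effect: float = 0.1
) -> list[str]:
    """Flag samples whose log total intensity or detection count is aberrant.

    For each sample, computes the log10 summed intensity and the log10 number
    of observed peptide ions, then a robust z-score against the across-sample
    median using the MAD (scaled by 1.4826). A sample is flagged when it
    exceeds ``threshold`` robust z-units on either metric *and* deviates from
    the median by at least ``min_effect`` log10 units (~25% by default) — the
    floor keeps the screen from firing on sampling jitter when the MAD across
    a handful of well-behaved samples is near zero. Flagging only — the
    caller decides whether to drop. With fewer than three samples there is no
    reference population and nothing is flagged.
    """
    if evidence is None or len(evidence) == 0:
        raise ParameterError("flag_sample_outliers: evidence table is empty")
    obs = evidence.dropna(subset=["intensity"])
    totals = np.log10(obs.groupby("sample")["intensity"].sum())
    counts = obs.groupby("sample")["intensity"].size().astype(float)
    if len(totals) < 3:
        return []
    flagged: set[str] = set()
    for metric in (totals, np.log10(counts)):
        z = _robust_z(metric.values)
        dev = np.abs(metric.values - np.median(metric.values))
        flagged.update(metric.index[(np.abs(z) > threshold) & (dev >= min_effect)])
    return sorted(flagged)


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    dev = x - med
    if mad == 0:
        # degenerate reference: identical samples score 0, any deviant is infinitely far
        return np.where(dev == 0, 0.0, np.inf)
    return dev / mad


# ---------------------------------------------------------------------------
# site grouping


def to_site_groups(evidence: pd.DataFrame) -> pd.DataFrame:
    """Attach a canonical site-group key to every evidence row.

    Peptides and fragments carrying the same (protein, phosphosite set) share
    one key; row count is unchanged and the operation is idempotent.
    """
    out = evidence.copy()
    keys = {}
    groups = []
    for idx, sites in out["phosphosites"].items():
        if not isinstance(sites, str) or not sites:
            raise ParseError(f"row {idx}: empty phosphosite set; non-phospho evidence must be filtered upstream")
        if sites not in keys:
            keys[sites] = make_group_key(sites.split(";"))
        groups.append(keys[sites])
    out["site_group"] = groups
    return out


# ---------------------------------------------------------------------------
# normalization


def normalize_median_equalization(
    data: pd.DataFrame,
    sample_col: str = "sample",
    value_col: str = "log2_intensity",
) -> pd.DataFrame:
    """Shift each sample's log2 values so all per-sample medians are equal.

    The common reference is the median of the per-sample medians; each sample
    is shifted by a constant, so within-sample differences are preserved
    exactly. A sample with no observed values is an error (there is no median
    to equalize).
    """
    medians = data.groupby(sample_col)[value_col].median()
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ParameterError(f"normalize_median_equalization: sample(s) with no observed values: {bad}")
    reference = medians.median()
    shifts = reference - medians
    out = data.copy()
    out[value_col] = data[value_col] + data[sample_col].map(shifts).astype(float)
    return out


# ---------------------------------------------------------------------------
# median polish summarization


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray  # NaN for columns with no observed entry
    residuals: np.ndarray
    converged: bool
    n_iter: int

    @property
    def col_summaries(self) -> np.ndarray:
        """Per-column summary: overall + column effect."""
        return self.overall + self.col_effects


def median_polish(matrix, tol: float = 1e-6, max_iter: int = 50) -> MedianPolishResult:
    """Tukey median polish of a two-way table with missing entries.

    Alternately sweeps row and column medians (row sweep first) out of the
    residuals, accumulating row effects, column effects and an overall term,
    until the largest absolute change in any effect is at most ``tol`` or
    ``max_iter`` iterations are reached. Medians ignore missing entries;
    even-length medians are the mean of the two central values. A row or
    column with no observed entry takes no part in the sweeps; such a
    column's effect (and hence summary) is reported missing.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ParameterError("median_polish: matrix must be 2-D and non-empty")
    nrow, ncol = X.shape
    row_ok = ~np.all(np.isnan(X), axis=1)
    col_ok = ~np.all(np.isnan(X), axis=0)
    if not row_ok.any() or not col_ok.any():
        raise ParameterError("median_polish: matrix has no observed entries")

    Z = X[np.ix_(row_ok, col_ok)]
    resid = Z.copy()
    r = np.zeros(row_ok.sum())
    c = np.zeros(col_ok.sum())
    overall = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        prev = np.concatenate(([overall], r, c))

        rmed = np.nanmedian(resid, axis=1)
        resid -= rmed[:, None]
        r += rmed
        delta = np.median(c)
        c -= delta
        overall += delta

        cmed = np.nanmedian(resid, axis=0)
        resid -= cmed[None, :]
        c += cmed
        delta = np.median(r)
        r -= delta
        overall += delta

        change = np.max(np.abs(np.concatenate(([overall], r, c)) - prev))
        if change <= tol:
            converged = True
            break

    row_effects = np.full(nrow, np.nan)
    row_effects[row_ok] = r
    col_effects = np.full(ncol, np.nan)
    col_effects[col_ok] = c
    residuals = np.full_like(X, np.nan)
    residuals[np.ix_(row_ok, col_ok)] = resid
    return MedianPolishResult(overall, row_effects, col_effects, residuals, converged, n_iter)


def summarize_median_polish(matrix, tol: float = 1e-6, max_iter: int = 50):
    """Combine a fragment x sample log2 matrix into one value per sample.

    Returns overall + column effect for each sample (a pandas Series when
    the input is a DataFrame, else an ndarray). A single-fragment matrix is
    returned unchanged; a sample column with no observation stays missing.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    values = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ParameterError("summarize_median_polish: matrix must be 2-D and non-empty")
    if values.shape[0] == 1:
        summaries = values[0].copy()
    else:
        summaries = median_polish(values, tol=tol, max_iter=max_iter).col_summaries
    if is_frame:
        return pd.Series(summaries, index=matrix.columns)
    return summaries


def summarize_site_groups(
    evidence: pd.DataFrame,
    samples=None,
    value_col: str = "log2_intensity",
    tol: float = 1e-6,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Build the site-group x sample matrix by median-polishing each group.

    ``evidence`` must carry ``site_group`` (see :func:`to_site_groups`) and a
    log2 value column. Rows with missing values are dropped before pivoting;
    a (group, sample) cell never observed stays missing in the output.
    """
    if "site_group" not in evidence.columns:
        raise ParameterError("summarize_site_groups: evidence lacks 'site_group'; run to_site_groups first")
    if samples is None:
        samples = sorted(evidence["sample"].unique())
    obs = evidence.dropna(subset=[value_col])
    # one pivot for the whole table, then slice contiguous per-group blocks
    wide = obs.pivot_table(
        index=["site_group", "peptide", "fragment"], columns="sample", values=value_col, aggfunc="first"
    ).reindex(columns=samples).sort_index()
    values = wide.to_numpy(dtype=float)
    group_labels = wide.index.get_level_values("site_group")
    codes, groups = pd.factorize(group_labels)
    boundaries = np.searchsorted(codes, np.arange(len(groups) + 1))
    summaries = np.empty((len(groups), len(samples)))
    for g in range(len(groups)):
        block = values[boundaries[g] : boundaries[g + 1]]
        summaries[g] = summarize_median_polish(block, tol=tol, max_iter=max_iter)
    matrix = pd.DataFrame(summaries, index=groups, columns=samples)
    matrix.index.name = "site_group"
    return matrix


# ---------------------------------------------------------------------------
# differential testing


def differential_sites(
    matrix: pd.DataFrame,
    design: pd.Series,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Per-site-group differential statistics for contrast (A, B).

    log2FC = mean(A) - mean(B) over observed per-sample summaries; a
    two-sample pooled-variance Student's t-test gives the two-sided raw P;
    BH adjustment is applied across all testable rows. Rows with fewer than
    two observations in either condition, or zero pooled variance with
    unequal means, are emitted with missing statistics and a reason code.
    """
    cond_a, cond_b = contrast
    for cond in contrast:
        if cond not in set(design.values):
            raise ParameterError(f"differential_sites: unknown condition label {cond!r}")
    samples_a = [s for s in matrix.columns if design.get(s) == cond_a]
    samples_b = [s for s in matrix.columns if design.get(s) == cond_b]

    records = []
    for group, row in matrix.iterrows():
        a = row[samples_a].dropna().to_numpy(dtype=float)
        b = row[samples_b].dropna().to_numpy(dtype=float)
        rec = {
            "site_group": group,
            "log2FC": np.nan, "t": np.nan, "df": np.nan,
            "pvalue": np.nan, "adj_pvalue": np.nan,
            "nA": len(a), "nB": len(b), "reason": "",
        }
        if len(a) >= 1 and len(b) >= 1:
            rec["log2FC"] = a.mean() - b.mean()
        if len(a) < 2 or len(b) < 2:
            rec["reason"] = "insufficient_replicates"
        else:
            sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
            if sp2 == 0 and a.mean() != b.mean():
                rec["reason"] = "zero_variance"
            elif sp2 == 0:  # identical constant groups: no evidence of change
                rec.update(t=0.0, df=float(len(a) + len(b) - 2), pvalue=1.0)
            else:
                t, p = stats.ttest_ind(a, b, equal_var=True)
                rec.update(t=float(t), df=float(len(a) + len(b) - 2), pvalue=float(p))
        records.append(rec)
    result = pd.DataFrame.from_records(records)
    tested = result["pvalue"].notna()
    if tested.any():
        result.loc[tested, "adj_pvalue"] = adjust_bh(result.loc[tested, "pvalue"].to_numpy())
    return result


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ParameterError("adjust_bh: expected a 1-D array of P values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ParameterError("adjust_bh: P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
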