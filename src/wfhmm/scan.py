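"""End-to-end locus scan: count tables in, per-locus LRT, q-value FDR out.

Input format: a tab-separated table with one row per locus and paired
per-date columns ``n_<t>`` / ``y_<t>`` (haploid sample size and
alternative-allele count at generation ``t``), plus a ``locus`` identifier
and optional ``line`` (population label), ``chrom`` and ``pos`` columns.

The scan excludes one-step-fixation trajectories (whose MLE degenerates to a
domain edge) and monomorphic loci (uninformative), computes the likelihood
profile of every retained locus under the chosen transition kernel, converts
the LRT statistics to chi2(1) p-values, and controls FDR with Storey
q-values (pooled across lines by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import (
    TimeSeries,
    default_nes_grid,
    is_one_step_fixation,
    profile_batch,
)
from .kernels import FrequencyGrid

SCAN_COLUMNS = ["locus_id", "line", "s_hat", "loglik0", "loglik_mle",
                "lambda", "pvalue", "qvalue", "significant", "excluded"]


def _date_columns(columns):
    """Extract the paired n_<t>/y_<t> columns, sorted by date."""
    ns, ys = {}, {}
    for c in columns:
        if c.startswith("n_"):
            ns[int(c[2:])] = c
        elif c.startswith("y_"):
            ys[int(c[2:])] = c
    dates = sorted(ns)
    if dates != sorted(ys):
        raise ValueError("n_<t> and y_<t> columns do not pair up")
    if len(dates) < 1:
        raise ValueError("no n_<t>/y_<t> column pairs found")
    return dates, [ns[t] for t in dates], [ys[t] for t in dates]


def read_counts(path) -> dict[str, list[TimeSeries]]:
    """Read a counts TSV into per-line lists of time series.

    Malformed rows (counts exceeding sample sizes, non-integer entries) are
    reported together with their row numbers.
    """
    df = pd.read_csv(path, sep="\t")
    if "locus" not in df.columns:
        raise ValueError("counts table must have a 'locus' column")
    dates, ncols, ycols = _date_columns(df.columns)
    n = df[ncols].to_numpy()
    y = df[ycols].to_numpy()
    if not (np.issubdtype(n.dtype, np.integer) and np.issubdtype(y.dtype, np.integer)):
        raise ValueError("sample sizes and counts must be integers")
    bad = np.flatnonzero(((y < 0) | (y > n)).any(axis=1))
    if bad.size:
        raise ValueError(
            "counts exceed sample sizes (or are negative) at rows: "
            + ", ".join(str(i + 2) for i in bad[:20])  # +2: header + 1-based
        )
    lines = df["line"] if "line" in df.columns else pd.Series(["pop"] * len(df))
    out: dict[str, list[TimeSeries]] = {}
    for i in range(len(df)):
        ts = TimeSeries(locus_id=str(df["locus"].iloc[i]), dates=dates,
                        sizes=n[i], counts=y[i])
        out.setdefault(str(lines.iloc[i]), []).append(ts)
    return out


def write_counts(path, per_line: dict[str, list[TimeSeries]]) -> None:
    """Write per-line time series back to the counts TSV format."""
    rows = []
    dates = None
    for line, series in per_line.items():
        for ts in series:
            if dates is None:
                dates = ts.dates.tolist()
            elif ts.dates.tolist() != dates:
                raise ValueError("all loci in one file must share sampling dates")
            row = {"locus": ts.locus_id, "line": line}
            for t, n, y in zip(dates, ts.sizes, ts.counts):
                row[f"n_{t}"] = int(n)
                row[f"y_{t}"] = int(y)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    ``pi0`` (the null proportion) is estimated by the smoother method --
    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` fitted over
    ``lambda = 0.05, ..., 0.95`` with a cubic polynomial evaluated at the
    largest lambda -- unless supplied explicitly.  With ``pi0=1`` the result
    equals Benjamini-Hochberg adjusted p-values.  For fewer than 100 tests
    the estimate is unstable and pi0 defaults to 1 (conservative).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            lams = np.arange(0.05, 0.951, 0.05)
            pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lams])
            coef = np.polynomial.polynomial.polyfit(lams, pi0_lam, deg=3)
            pi0 = float(np.polynomial.polynomial.polyval(lams[-1], coef))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _is_monomorphic(ts: TimeSeries) -> bool:
    return bool(np.all(ts.counts == 0) or np.all(ts.counts == ts.sizes))


def scan(per_line: dict[str, list[TimeSeries]], ne_per_line: dict[str, int],
         h: float = 0.5, model: str = "BwS", fdr: float = 0.05,
         nes_grid: np.ndarray | None = None,
         grid: FrequencyGrid | None = None,
         pool_lines: bool = True) -> pd.DataFrame:
    """Per-line, per-locus selection scan with FDR control.

    One-step-fixation and monomorphic loci are excluded before testing.
    q-values are computed over the pooled p-values of all lines by default
    (``pool_lines=False`` adjusts within each line separately).  The output
    is deterministic for identical inputs.
    """
    missing = [ln for ln in per_line if ln not in ne_per_line]
    if missing:
        raise ValueError(f"no Ne supplied for line(s): {missing}")
    if nes_grid is None:
        nes_grid = default_nes_grid()
    records = []
    for line, series in per_line.items():
        flags = []
        for ts in series:
            if _is_monomorphic(ts):
                flags.append("monomorphic")
            elif is_one_step_fixation(ts):
                flags.append("one_step_fixation")
            else:
                flags.append("")
        kept = [ts for ts, f in zip(series, flags) if f == ""]
        profiles = iter(profile_batch(kept, model, ne_per_line[line], h=h,
                                      nes_grid=nes_grid, grid=grid))
        for ts, f in zip(series, flags):
            rec = {"locus_id": ts.locus_id, "line": line, "excluded": f,
                   "s_hat": np.nan, "loglik0": np.nan, "loglik_mle": np.nan,
                   "lambda": np.nan, "pvalue": np.nan}
            if f == "":
                pr = next(profiles)
                rec.update(s_hat=pr.s_hat, loglik0=pr.loglik0,
                           loglik_mle=pr.loglik_mle, pvalue=pr.pvalue)
                rec["lambda"] = pr.lam
            records.append(rec)
    df = pd.DataFrame(records)
    df["qvalue"] = np.nan
    tested = df["excluded"] == ""
    if pool_lines:
        df.loc[tested, "qvalue"] = qvalues(df.loc[tested, "pvalue"].to_numpy())
    else:
        for line in df["line"].unique():
            sel = tested & (df["line"] == line)
            df.loc[sel, "qvalue"] = qvalues(df.loc[sel, "pvalue"].to_numpy())
    df["significant"] = (df["qvalue"] <= fdr).fillna(False)
    return df
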