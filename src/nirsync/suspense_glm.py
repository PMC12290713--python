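"""GLM linking subjective suspense ratings to group-averaged hemodynamics.

Group-averaged HbO/HbR series from an Intact condition are reduced to the
rating sampling grid (interval averaging, which carries its own
anti-aliasing) and regressed, channel by channel and chromophore by
chromophore, on z-scored suspense ratings with the same channel's Scrambled
group average as a nuisance regressor.  The nuisance term removes slow
envelope-driven components that correlate with suspense only by chance.
The suspense beta's t-statistics are corrected across all channel x
chromophore tests with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError
from .preprocess import HemoglobinSeries
from .synthetic_data import SuspenseRatings

__all__ = ["GLMResult", "resample_to_ratings", "suspense_glm", "group_average"]


@dataclass
class GLMResult:
    table: pd.DataFrame  # channel, chromophore, beta, t, p, q, significant, dof
    dof: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def group_average(cohort_hb: list[HemoglobinSeries]) -> HemoglobinSeries:
    """Average hemoglobin series across participants (truncated to common length)."""
    n_t = min(h.n_samples for h in cohort_hb)
    hbo = np.mean([h.hbo[:, :n_t] for h in cohort_hb], axis=0)
    hbr = np.mean([h.hbr[:, :n_t] for h in cohort_hb], axis=0)
    return HemoglobinSeries(
        hbo=hbo, hbr=hbr, fs=cohort_hb[0].fs,
        channel_ids=list(cohort_hb[0].channel_ids),
        provenance=["group_average"],
    )


def resample_to_ratings(
    hb: HemoglobinSeries, ratings: SuspenseRatings, method: str = "interval_mean"
) -> HemoglobinSeries:
    """Reduce a hemoglobin series to one value per rating time.

    ``interval_mean`` (default) averages the samples falling in each rating
    interval, which low-passes the series as a side effect; ``decimate``
    takes the nearest sample instead.
    """
    times = ratings.times
    if times[-1] > hb.n_samples / hb.fs + 1.0 / hb.fs:
        raise ValidationError("ratings extend beyond the recording")
    n_r = times.size
    edges = np.concatenate([times, [times[-1] + (times[-1] - times[-2])]])

    def _reduce(a: np.ndarray) -> np.ndarray:
        out = np.empty((a.shape[0], n_r))
        t_samp = np.arange(a.shape[1]) / hb.fs
        if method == "decimate":
            idx = np.clip(np.searchsorted(t_samp, times), 0, a.shape[1] - 1)
            return a[:, idx]
        for k in range(n_r):
            sel = (t_samp >= edges[k]) & (t_samp < edges[k + 1])
            if not sel.any():  # rating grid finer than sampling - nearest sample
                j = int(np.argmin(np.abs(t_samp - times[k])))
                out[:, k] = a[:, j]
            else:
                out[:, k] = a[:, sel].mean(axis=1)
        return out

    return HemoglobinSeries(
        hbo=_reduce(hb.hbo),
        hbr=_reduce(hb.hbr),
        fs=1.0 / float(np.median(np.diff(times))),
        channel_ids=list(hb.channel_ids),
        provenance=hb.provenance + [f"resample_to_ratings({method})"],
    )


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def suspense_glm(
    hb_intact_group: HemoglobinSeries,
    hb_scrambled_group: HemoglobinSeries,
    ratings: SuspenseRatings,
    alpha: float = 0.05,
) -> GLMResult:
    """Per-channel OLS of the Intact group series on suspense ratings.

    Design per channel and chromophore: [intercept, z-scored ratings,
    z-scored same-channel Scrambled group series].  Scrambled series are
    aligned from time zero and truncated to the Intact resampled length.
    Returns the suspense beta, its t and p, and BH-FDR q across all tests.
    """
    if hb_intact_group.channel_ids != hb_scrambled_group.channel_ids:
        raise ValidationError("Intact and Scrambled series must share channels")
    n = min(hb_intact_group.n_samples, hb_scrambled_group.n_samples, ratings.values.size)
    if n < 8:
        raise ValidationError("too few resampled time points for a GLM")
    susp = _z(ratings.values[:n])

    rows = []
    dof = None
    for chrom, y_all, nuis_all in (
        ("HbO", hb_intact_group.hbo, hb_scrambled_group.hbo),
        ("HbR", hb_intact_group.hbr, hb_scrambled_group.hbr),
    ):
        for i, ch in enumerate(hb_intact_group.channel_ids):
            X = np.column_stack([np.ones(n), susp, _z(nuis_all[i, :n])])
            if np.linalg.cond(X) > 1e6:
                rows.append(
                    {"channel": ch, "chromophore": chrom, "beta": np.nan,
                     "t": np.nan, "p": np.nan, "error": "collinear regressors"}
                )
                continue
            fit = sm.OLS(y_all[i, :n], X).fit()
            dof = int(fit.df_resid)
            rows.append(
                {"channel": ch, "chromophore": chrom, "beta": fit.params[1],
                 "t": fit.tvalues[1], "p": fit.pvalues[1], "error": ""}
            )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    df["significant"] = False
    valid = df["p"].notna()
    if valid.any():
        rej, qv, *_ = multipletests(df.loc[valid, "p"], alpha=alpha, method="fdr_bh")
        df.loc[valid, "q"] = qv
        df.loc[valid, "significant"] = rej
    df["dof"] = dof
    return GLMResult(table=df, dof=dof if dof is not None else 0)
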