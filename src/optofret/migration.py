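"""Migration persistence statistics and phenotype-fraction testing.

Tracks of randomly migrating cells (positions at fixed 30 s intervals
over ~7 min) are summarized by two persistence measures: the mean
squared displacement from the track start as a function of time lag,
and the mean cosine of the angle between the first 30 s step and each
subsequent frame-to-frame step (1 for straight-line migration, ~0 for
an uncorrelated random walk).  Manually counted phenotype fractions per
experiment are compared with a two-tailed Welch (unequal-variance)
t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("experiment", "cell", "frame", "x_um", "y_um")


def _iter_tracks(tracks: pd.DataFrame):
    for (exp, cell), grp in tracks.groupby(["experiment", "cell"], sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if frames.size >= 2 and np.any(np.diff(frames) != 1):
            raise ValueError(
                f"track ({exp}, {cell}) has missing interior frames")
        yield exp, cell, grp[["x_um", "y_um"]].to_numpy(dtype=float)


def mean_squared_displacement(tracks: pd.DataFrame, *,
                              min_net_um: float = 5.0) -> pd.DataFrame:
    """MSD versus lag, mean +/- SEM across experiments.

    ``tracks`` is tidy with columns experiment, cell, frame, x_um, y_um
    at a uniform frame interval.  MSD(lag) averages
    ``|r(t0 + lag) - r(t0)|^2`` over included cells with t0 fixed at the
    track start (displacement-from-start, non-overlapping origin).
    Cells are included only if their net displacement over the whole
    track is at least ``min_net_um``.  Returns columns lag (frames),
    msd_um2, sem, n_cells.
    """
    per_exp: dict[str, list[np.ndarray]] = {}
    n_lags = 0
    for exp, _cell, xy in _iter_tracks(tracks):
        net = np.linalg.norm(xy[-1] - xy[0])
        if net < min_net_um:
            continue
        sq = np.sum((xy - xy[0]) ** 2, axis=1)
        per_exp.setdefault(exp, []).append(sq)
        n_lags = max(n_lags, sq.size)
    if not per_exp:
        raise ValueError(f"no cells moved at least {min_net_um} um")
    exp_means = []
    counts = np.zeros(n_lags, dtype=int)
    for exp, rows in per_exp.items():
        mat = np.full((len(rows), n_lags), np.nan)
        for i, sq in enumerate(rows):
            mat[i, :sq.size] = sq
            counts[:sq.size] += 1
        exp_means.append(np.nanmean(mat, axis=0))
    exp_means = np.asarray(exp_means)
    mean = np.nanmean(exp_means, axis=0)
    if exp_means.shape[0] >= 2:
        sem = (np.nanstd(exp_means, axis=0, ddof=1)
               / np.sqrt(np.sum(np.isfinite(exp_means), axis=0)))
    else:
        sem = np.full(n_lags, np.nan)
    return pd.DataFrame({"lag": np.arange(n_lags), "msd_um2": mean,
                         "sem": sem, "n_cells": counts})


def persistence_cosine(tracks: pd.DataFrame, *,
                       min_first_step_um: float = 5.0) -> pd.DataFrame:
    """Mean cos(angle to the first-step direction) versus lag.

    Per cell, the reference direction is the first frame-to-frame step;
    each subsequent step contributes the cosine of its angle to that
    reference.  Only cells whose first step is at least
    ``min_first_step_um`` are included (so the initial direction is
    well determined); zero-length later steps are skipped.  The mean is
    taken per lag over cells within each experiment, then mean +/- SEM
    across experiments.  Returns columns lag, cos_mean, sem, n_cells.
    """
    per_exp: dict[str, list[np.ndarray]] = {}
    n_lags = 0
    for exp, _cell, xy in _iter_tracks(tracks):
        steps = np.diff(xy, axis=0)
        if steps.shape[0] < 1:
            continue
        first = steps[0]
        norm0 = np.linalg.norm(first)
        if norm0 < min_first_step_um:
            continue
        lens = np.linalg.norm(steps, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosines = (steps @ first) / (lens * norm0)
        cosines[lens == 0] = np.nan  # zero-length steps contribute nothing
        per_exp.setdefault(exp, []).append(cosines)
        n_lags = max(n_lags, cosines.size)
    if not per_exp:
        raise ValueError(
            f"no cells moved at least {min_first_step_um} um in the first step")
    exp_means = []
    counts = np.zeros(n_lags, dtype=int)
    for exp, rows in per_exp.items():
        mat = np.full((len(rows), n_lags), np.nan)
        for i, c in enumerate(rows):
            mat[i, :c.size] = c
            counts[:c.size] += 1
        with np.errstate(invalid="ignore"):
            exp_means.append(np.nanmean(mat, axis=0))
    exp_means = np.asarray(exp_means)
    mean = np.nanmean(exp_means, axis=0)
    if exp_means.shape[0] >= 2:
        sem = (np.nanstd(exp_means, axis=0, ddof=1)
               / np.sqrt(np.sum(np.isfinite(exp_means), axis=0)))
    else:
        sem = np.full(n_lags, np.nan)
    return pd.DataFrame({"lag": 1 + np.arange(n_lags), "cos_mean": mean,
                         "sem": sem, "n_cells": counts})


def phenotype_fraction_test(counts_a: list[tuple[int, int]],
                            counts_b: list[tuple[int, int]]) -> dict:
    """Welch two-sample t-test on per-experiment phenotype fractions.

    Each group is a list of (positives, total) per independent
    experiment.  Returns per-group means and SEMs, the Welch t
    statistic with Welch-Satterthwaite degrees of freedom, the
    two-sided p value, and a 95% confidence interval on the difference
    of means.  With zero variance in both groups and equal means,
    t = 0 and p = 1.
    """
    def fractions(counts):
        out = []
        for pos, tot in counts:
            if tot <= 0 or pos < 0 or pos > tot:
                raise ValueError("counts must satisfy 0 <= positives <= total")
            out.append(pos / tot)
        return np.asarray(out, dtype=float)

    fa, fb = fractions(counts_a), fractions(counts_b)
    if fa.size < 2 or fb.size < 2:
        raise ValueError("need at least 2 experiments per group")
    na, nb = fa.size, fb.size
    va, vb = fa.var(ddof=1), fb.var(ddof=1)
    diff = fa.mean() - fb.mean()
    se2 = va / na + vb / nb
    if se2 == 0:
        t_stat, df, p = (0.0, float(na + nb - 2), 1.0) if diff == 0 else \
            (np.inf * np.sign(diff), float(na + nb - 2), 0.0)
    else:
        t_stat = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(abs(t_stat), df)
    half = (stats.t.ppf(0.975, df) * np.sqrt(se2)) if se2 > 0 else 0.0
    return {
        "mean_a": float(fa.mean()), "sem_a": float(fa.std(ddof=1) / np.sqrt(na)),
        "mean_b": float(fb.mean()), "sem_b": float(fb.std(ddof=1) / np.sqrt(nb)),
        "t": float(t_stat), "df": float(df), "p": float(p),
        "diff": float(diff),
        "ci95": (float(diff - half), float(diff + half)),
    }
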