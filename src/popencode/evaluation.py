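"""Noise-corrected model evaluation and the accompanying statistics.

Prediction accuracy on the validation data is the Pearson correlation
between prediction and response, corrected for trial-to-trial variability:

* TTRC (trial-to-trial response correlation) — the mean correlation over all
  unique repeat pairs of the validation raster; the noise ceiling.
* R_norm — the mean single-trial prediction correlation divided by the
  square root of the TTRC; 1 means the model predicts everything
  predictable given the noise, 0 is chance.  Sampling noise can push it
  slightly above 1; it is reported unclamped.

Also provided: a variance-decomposition SNR (per-neuron signal-variance
fraction across repeats), model equivalence (correlation between two models'
predicted PSTHs), a jackknifed t-test for above-chance prediction, and the
rank-based population comparisons (Wilcoxon signed-rank / Mann-Whitney U).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["ttrc", "noise_corrected_correlation", "equivalence", "snr",
           "jackknife_above_chance", "responsive_subset",
           "compare_populations", "score_population", "TTRC_FLOOR"]

TTRC_FLOOR = 0.05   # below this the R_norm correction is unstable; flagged


def _corr(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def ttrc(raster_row: np.ndarray) -> float:
    """Trial-to-trial response correlation of one neuron.

    ``raster_row`` is (T, M).  Returns the mean Pearson correlation over all
    M(M-1)/2 unordered repeat pairs; pairs involving a zero-variance trial
    are excluded.  NaN if fewer than two repeats or no valid pair.
    """
    r = np.asarray(raster_row, dtype=float)
    T, M = r.shape
    if M < 2:
        return np.nan
    vals = []
    for i in range(M):
        for j in range(i + 1, M):
            c = _corr(r[:, i], r[:, j])
            if not np.isnan(c):
                vals.append(c)
    return float(np.mean(vals)) if vals else np.nan


def noise_corrected_correlation(raster_row: np.ndarray,
                                prediction: np.ndarray,
                                ttrc_value: float | None = None) -> float:
    """R_norm: mean single-trial prediction correlation divided by sqrt(TTRC).

    For repeats r_i = signal + independent noise with signal-variance
    fraction q, corr(r_i, p) for a perfect prediction p equals sqrt(q)
    while TTRC estimates q, so dividing the mean single-trial correlation
    by sqrt(TTRC) makes 1 the noise-limited ceiling.  On noise-free data
    (identical repeats, TTRC = 1) R_norm equals the raw Pearson
    correlation exactly.

    NaN when the prediction is constant or TTRC is undefined or at/below
    ``TTRC_FLOOR`` (the correction is unstable there).  Values above 1 from
    sampling noise are not clamped.
    """
    r = np.asarray(raster_row, dtype=float)
    p = np.asarray(prediction, dtype=float)
    if ttrc_value is None:
        ttrc_value = ttrc(r)
    if np.isnan(ttrc_value) or ttrc_value <= TTRC_FLOOR:
        return np.nan
    cs = [_corr(r[:, i], p) for i in range(r.shape[1])]
    cs = [c for c in cs if not np.isnan(c)]
    if not cs:
        return np.nan
    return float(np.mean(cs) / np.sqrt(ttrc_value))


def equivalence(pred_a: np.ndarray, pred_b: np.ndarray) -> float:
    """Model equivalence: Pearson correlation between two predicted PSTHs."""
    return _corr(pred_a, pred_b)


def snr(raster_row: np.ndarray) -> float:
    """Per-neuron signal-variance fraction across repeats.

    Estimated by variance decomposition: ``var(PSTH)`` contains the signal
    variance plus ``var_noise / M`` from residual trial noise, so the signal
    fraction is ``max(0, (var(PSTH) - var_noise/M) / var_total)`` where
    ``var_noise`` is the mean within-bin variance across repeats and
    ``var_total = var_signal + var_noise``.  Monotone in the true signal
    fraction; 1 for identical repeats, ~0 for pure noise.
    """
    r = np.asarray(raster_row, dtype=float)
    T, M = r.shape
    if M < 2:
        return np.nan
    psth = r.mean(axis=1)
    var_noise = float(np.mean(r.var(axis=1, ddof=1)))
    var_signal = max(0.0, float(psth.var()) - var_noise / M)
    var_total = var_signal + var_noise
    if var_total == 0:
        return 0.0
    return var_signal / var_total


def jackknife_above_chance(raster_row: np.ndarray, prediction: np.ndarray,
                           n_folds: int = 20,
                           prediction_b: np.ndarray | None = None,
                           psth: np.ndarray | None = None):
    """Jackknifed t-test on prediction correlation.

    The validation PSTH is cut into ``n_folds`` contiguous time segments;
    the prediction correlation is recomputed leaving each segment out and
    the jackknife t-statistic tests the correlation against zero (two
    sided).  With ``prediction_b``, the test is paired: the statistic is the
    jackknifed difference in correlation between the two predictions.

    Returns ``(p_value, mean_correlation_or_difference)``.
    """
    r = np.asarray(raster_row, dtype=float)
    psth = r.mean(axis=1) if r.ndim == 2 else r
    p = np.asarray(prediction, dtype=float)
    T = psth.size
    if T < n_folds:
        warnings.warn("fewer time bins than folds; reducing fold count")
        n_folds = T
    edges = np.linspace(0, T, n_folds + 1).astype(int)
    masks = [np.ones(T, dtype=bool) for _ in range(n_folds)]
    for i in range(n_folds):
        masks[i][edges[i]: edges[i + 1]] = False

    def stat(mask):
        c = _corr(psth[mask], p[mask])
        if prediction_b is not None:
            cb = _corr(psth[mask], np.asarray(prediction_b)[mask])
            return c - cb
        return c

    theta = np.array([stat(m) for m in masks])
    if np.isnan(theta).any():
        ok = ~np.isnan(theta)
        if ok.sum() < 3:
            return np.nan, np.nan
        warnings.warn("degenerate jackknife folds dropped")
        theta = theta[ok]
        n_folds = theta.size
    mean = theta.mean()
    se = np.sqrt((n_folds - 1) / n_folds * np.sum((theta - mean) ** 2))
    if se == 0:
        return (1.0, float(mean)) if mean == 0 else (0.0, float(mean))
    t = mean / se
    pval = 2 * scipy.stats.t.sf(abs(t), df=n_folds - 1)
    return float(pval), float(mean)


def responsive_subset(score_tables: dict, alpha: float = 0.05) -> np.ndarray:
    """Neurons predicted above chance by every model in ``score_tables``.

    ``score_tables`` maps model_id -> ScoreTable DataFrame (as produced by
    :func:`score_population`); in the full protocol the three exemplar
    models (1Dx2-CNN, pop-LN, single-CNN) define auditory responsiveness.
    Returns the sorted neuron_ids in the intersection.
    """
    if not score_tables:
        raise ValueError("no score tables given")
    sets = []
    for model_id, tab in score_tables.items():
        if tab is None:
            raise ValueError(f"missing scores for model {model_id!r}")
        ok = tab.loc[tab["p_above_chance"] < alpha, "neuron_id"]
        sets.append(set(ok.tolist()))
    common = set.intersection(*sets)
    return np.array(sorted(common))


def compare_populations(scores_a, scores_b, paired: bool = False):
    """Rank-based comparison of two score distributions.

    Paired -> two-sided Wilcoxon signed-rank; unpaired -> two-sided
    Mann-Whitney U.  Returns a dict with the p-value, statistic and medians.
    NaN scores are dropped (pairwise for the paired test).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs matched score vectors")
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        if a.size < 5:
            warnings.warn("fewer than 5 pairs; exact small-sample test")
        d = a - b
        if np.all(d == 0):
            res_p, stat = 1.0, 0.0
        else:
            method = "exact" if a.size < 25 else "auto"
            stat, res_p = scipy.stats.wilcoxon(a, b, method=method)
        test = "wilcoxon-signed-rank"
    else:
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if min(a.size, b.size) < 5:
            warnings.warn("fewer than 5 samples; exact small-sample test")
            stat, res_p = scipy.stats.mannwhitneyu(a, b, method="exact")
        else:
            stat, res_p = scipy.stats.mannwhitneyu(a, b)
        test = "mann-whitney-u"
    return {"test": test, "p": float(res_p), "statistic": float(stat),
            "median_a": float(np.median(a)) if a.size else np.nan,
            "median_b": float(np.median(b)) if b.size else np.nan,
            "n": int(a.size)}


def score_population(val_raster, predictions, model_id: str = "model",
                     n_folds: int = 20, alpha: float = 0.05) -> pd.DataFrame:
    """ScoreTable for one model: per-neuron evaluation records.

    Parameters
    ----------
    val_raster : TrialRaster
        Validation responses (N, T, M), M >= 2 for the corrected score.
    predictions : ndarray (N, T)
        Model predictions aligned with the validation stimulus.

    Returns a DataFrame with columns neuron_id, site_id, model_id, raw_r,
    ttrc, r_norm, snr, p_above_chance, responsive.
    """
    preds = np.asarray(predictions, dtype=float)
    rows = []
    psth = val_raster.psth()
    for n in range(val_raster.n_neurons):
        rr = val_raster.rates[n]
        tt = ttrc(rr)
        raw = _corr(psth[n], preds[n])
        rn = noise_corrected_correlation(rr, preds[n], tt)
        pval, _ = jackknife_above_chance(rr, preds[n], n_folds=n_folds)
        rows.append({
            "neuron_id": val_raster.neuron_ids[n],
            "site_id": val_raster.site_ids[n],
            "model_id": model_id,
            "raw_r": raw, "ttrc": tt, "r_norm": rn, "snr": snr(rr),
            "p_above_chance": pval,
            "responsive": bool(pval < alpha) if not np.isnan(pval) else False,
        })
    return pd.DataFrame(rows)
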