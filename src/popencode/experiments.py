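"""Generalization protocols: held-out vs matched sites, cross-population
transfer, SNR-matched subsetting, and estimation-data subsampling.

All protocols share one mechanic: fit the shared model core (stage 1) on a
population that *excludes* some neurons, then fit only the per-neuron
readouts (stage 2) for the excluded target neurons with the core frozen.
If target performance matches that of a control model whose core saw an
equally sized but score-matched exclusion, the core's representation
generalizes to unseen neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import compare_populations, score_population
from .fitting import FitConfig, fit_stage1, fit_stage2, stage2_predictions
from .models import ModelSpec
from .synthetic import SyntheticDataset

__all__ = ["ProtocolPlan", "plan_heldout", "plan_matched",
           "run_generalization", "run_cross_population",
           "snr_matched_subsets", "run_subsample", "ln_baseline_scores",
           "run_plan"]


@dataclass
class ProtocolPlan:
    """Which neurons are excluded from stage 1, and who gets stage-2 fits."""

    protocol: str                       # heldout | matched | cross_population
    target_site: object = None          # site S whose neurons are scored
    excluded_neurons: np.ndarray = field(default_factory=lambda: np.array([]))
    subsample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.excluded_neurons = np.asarray(self.excluded_neurons)
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")


def _site_rows(dataset, site):
    rows = np.flatnonzero(np.asarray(dataset.site_ids) == site)
    if rows.size == 0:
        raise ValueError(f"unknown or empty site {site!r}")
    return rows


def plan_heldout(dataset: SyntheticDataset, site) -> ProtocolPlan:
    """Exclude every neuron of one recording site from stage 1."""
    rows = _site_rows(dataset, site)
    if rows.size == dataset.n_neurons:
        raise ValueError("held-out site covers the whole population; "
                         "stage 1 would be empty")
    return ProtocolPlan("heldout", target_site=site,
                        excluded_neurons=np.asarray(dataset.neuron_ids)[rows])


def plan_matched(dataset: SyntheticDataset, site,
                 baseline_scores: np.ndarray) -> ProtocolPlan:
    """Exclude K off-site neurons whose baseline (single-neuron LN) scores
    best match the K neurons of the target site.

    Greedy nearest-score matching without replacement, target neurons
    visited in descending score order — deterministic and auditable.
    """
    scores = np.asarray(baseline_scores, dtype=float)
    if scores.size != dataset.n_neurons:
        raise ValueError("need one baseline score per neuron")
    rows_s = _site_rows(dataset, site)
    off = np.setdiff1d(np.arange(dataset.n_neurons), rows_s)
    if off.size < rows_s.size:
        raise ValueError("fewer off-site neurons than the target site holds")
    order = rows_s[np.argsort(-scores[rows_s])]
    avail = set(off.tolist())
    chosen = []
    for r in order:
        best = min(avail, key=lambda j: (abs(scores[j] - scores[r]), j))
        avail.remove(best)
        chosen.append(best)
    return ProtocolPlan("matched", target_site=site,
                        excluded_neurons=np.asarray(dataset.neuron_ids)[
                            np.array(chosen)])


# ---------------------------------------------------------------------------
# protocol execution
# ---------------------------------------------------------------------------

def _subsample_segments(stim, resp, fraction, seed):
    """Uniformly drawn snippet subset, identical for a given seed."""
    n = stim.seg_lens.size
    keep = max(5, int(round(fraction * n)))
    if keep > n:
        raise ValueError("subsample fraction leaves too few snippets")
    idx = np.sort(np.random.default_rng(seed).permutation(n)[:keep])
    from .fitting import _take
    return _take(stim, resp, idx)


def run_plan(dataset: SyntheticDataset, spec_template: ModelSpec,
             plan: ProtocolPlan, config: FitConfig,
             pretrained_stage1=None):
    """Execute one protocol arm.

    Stage 1 is fit on the population minus ``plan.excluded_neurons`` (or
    reused from ``pretrained_stage1``); stage 2 refits the readout of every
    target-site neuron on its own estimation data (subsampled if the plan
    says so), with the core frozen.  Neurons excluded from stage 1 get
    freshly initialized readouts; included neurons start from their stage-1
    weights.  Returns ``(ScoreTable for the target site, stage-1 result)``.
    """
    ids = np.asarray(dataset.neuron_ids)
    excl_mask = np.isin(ids, plan.excluded_neurons)
    target_rows = _site_rows(dataset, plan.target_site)

    if pretrained_stage1 is None:
        ds1 = dataset.subset_neurons(np.flatnonzero(~excl_mask))
        spec1 = replace(spec_template, n_neurons=ds1.n_neurons)
        stage1 = fit_stage1(spec1, ds1.est_stim, ds1.est_resp, config)
        kept_ids = np.asarray(ds1.neuron_ids)
    else:
        stage1, kept_ids = pretrained_stage1

    est_stim, est_resp = dataset.est_stim, dataset.est_resp
    if plan.subsample_fraction < 1.0:
        (est_stim, est_resp) = _subsample_segments(
            est_stim, est_resp, plan.subsample_fraction, plan.seed)

    # stage 2, one target neuron at a time
    stage2 = _fit_targets(stage1, est_stim, est_resp, target_rows, ids,
                          kept_ids, config)
    preds = stage2_predictions(stage1, stage2, dataset.val_stim)
    table = score_population(dataset.val_resp.subset_neurons(target_rows),
                             preds, model_id=f"{plan.protocol}")
    return table, stage1


def _fit_targets(stage1, est_stim, est_resp, target_rows, ids, kept_ids,
                 config):
    """Stage-2 readout fits for the protocol's target neurons.

    Every arm uses the identical procedure — fresh multi-initialization
    readout fits against the frozen core — regardless of whether the
    neuron happened to be part of stage 1.  Warm-starting included neurons
    from their stage-1 weights would hand the control arms a systematic
    head start that is not available to held-out neurons, biasing the
    generalization comparison.
    """
    target_rows = np.asarray(target_rows)
    sub = est_resp.subset_neurons(target_rows)
    return fit_stage2(stage1, est_stim, sub, config, readout_init="fresh",
                      warm_rows={})


def run_generalization(dataset: SyntheticDataset, spec_template: ModelSpec,
                       config: FitConfig, baseline_scores=None, sites=None):
    """Held-out vs matched comparison over recording sites.

    For every site S: the held-out arm excludes S from stage 1; the matched
    arm excludes an equal number of score-matched off-site neurons; both
    arms then refit only the readouts of S's neurons.  Returns per-neuron
    paired scores and the signed-rank comparison.  Fit failures at a site
    are logged and skipped; the protocol continues.
    """
    if baseline_scores is None:
        baseline_scores = ln_baseline_scores(dataset, config)
    if sites is None:
        sites = np.unique(np.asarray(dataset.site_ids))
    rows = []
    for site in sites:
        try:
            t_h, _ = run_plan(dataset, spec_template,
                              plan_heldout(dataset, site), config)
            t_m, _ = run_plan(dataset, spec_template,
                              plan_matched(dataset, site, baseline_scores),
                              config)
        except RuntimeError as e:       # pragma: no cover - rare
            warnings.warn(f"site {site!r} failed: {e}; skipped")
            continue
        merged = t_h.merge(t_m, on="neuron_id", suffixes=("_heldout",
                                                          "_matched"))
        merged["site"] = site
        rows.append(merged)
    if not rows:
        raise RuntimeError("every site failed")
    table = pd.concat(rows, ignore_index=True)
    comparison = compare_populations(table["r_norm_heldout"],
                                     table["r_norm_matched"], paired=True)
    return {"table": table, "comparison": comparison}


def run_cross_population(source: SyntheticDataset, target: SyntheticDataset,
                         spec_template: ModelSpec, config: FitConfig):
    """Pre-fit the core on one population, refit readouts on another.

    Both datasets must share the stimulus.  Every target neuron gets a
    fresh stage-2 readout fit on its own estimation responses; scores are
    computed on the target validation raster.
    """
    if (source.est_stim.values.shape != target.est_stim.values.shape or
            not np.array_equal(source.est_stim.values,
                               target.est_stim.values)):
        raise ValueError("source and target must share the same stimulus")
    spec1 = replace(spec_template, n_neurons=source.n_neurons)
    stage1 = fit_stage1(spec1, source.est_stim, source.est_resp, config)
    stage2 = fit_stage2(stage1, target.est_stim, target.est_resp, config,
                        readout_init="fresh")
    preds = stage2_predictions(stage1, stage2, target.val_stim)
    return score_population(target.val_resp, preds,
                            model_id="cross_population")


def snr_matched_subsets(snr_a, snr_b, n_bins: int = 20):
    """Largest subsets of two populations with identical binned SNR
    distributions.

    SNR values are histogrammed into ``n_bins`` equal-width bins over the
    pooled range; each bin keeps ``min(count_a, count_b)`` neurons from each
    side, highest-SNR-first within the bin.  Returns index arrays into the
    two inputs.
    """
    a = np.asarray(snr_a, dtype=float)
    b = np.asarray(snr_b, dtype=float)
    pooled = np.concatenate([a, b])
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        warnings.warn("no SNR values; empty subsets")
        return np.array([], int), np.array([], int)
    edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    edges[-1] += 1e-12
    keep_a, keep_b = [], []
    for i in range(n_bins):
        in_a = np.flatnonzero((a >= edges[i]) & (a < edges[i + 1]))
        in_b = np.flatnonzero((b >= edges[i]) & (b < edges[i + 1]))
        k = min(in_a.size, in_b.size)
        if k:
            keep_a.extend(in_a[np.argsort(-a[in_a])][:k])
            keep_b.extend(in_b[np.argsort(-b[in_b])][:k])
    if not keep_a:
        warnings.warn("SNR distributions do not overlap; empty subsets")
    return np.sort(np.array(keep_a, int)), np.sort(np.array(keep_b, int))


def run_subsample(dataset: SyntheticDataset, spec_template: ModelSpec,
                  fractions, config: FitConfig, site,
                  baseline_stage1=None):
    """Pre-trained vs standard fits on subsampled estimation data.

    The pre-trained arm fits stage 1 once on the full estimation data minus
    the held-out site, then refits the site's readouts on each subsample.
    The standard arm runs both stages on the subsample alone (full
    population).  Subsamples are drawn uniformly over snippets and are
    identical across arms for a given seed.  Per-fraction medians are also
    reported normalized to the standard arm's full-data median when
    fraction 1.0 is included.
    """
    fractions = sorted(set(float(f) for f in fractions))
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    hold = plan_heldout(dataset, site)
    ids = np.asarray(dataset.neuron_ids)
    if baseline_stage1 is None:
        ds1 = dataset.subset_neurons(
            np.flatnonzero(~np.isin(ids, hold.excluded_neurons)))
        spec1 = replace(spec_template, n_neurons=ds1.n_neurons)
        pre_stage1 = fit_stage1(spec1, ds1.est_stim, ds1.est_resp, config)
        pre_kept = np.asarray(ds1.neuron_ids)
    else:
        pre_stage1, pre_kept = baseline_stage1

    results = []
    n_snip = dataset.est_stim.seg_lens.size
    for f in fractions:
        if int(round(f * n_snip)) < 5:
            warnings.warn(f"fraction {f} leaves too few snippets; skipped")
            continue
        sub_seed = (config.seed * 1000 + int(round(f * 1000))) % (2**31 - 1)
        plan_pre = ProtocolPlan("heldout", target_site=site,
                                excluded_neurons=hold.excluded_neurons,
                                subsample_fraction=f, seed=sub_seed)
        t_pre, _ = run_plan(dataset, spec_template, plan_pre, config,
                            pretrained_stage1=(pre_stage1, pre_kept))
        plan_std = ProtocolPlan("standard", target_site=site,
                                excluded_neurons=np.array([]),
                                subsample_fraction=f, seed=sub_seed)
        sub_stim, sub_resp = _subsample_segments(
            dataset.est_stim, dataset.est_resp, f, sub_seed)
        spec_full = replace(spec_template, n_neurons=dataset.n_neurons)
        std_stage1 = fit_stage1(spec_full, sub_stim, sub_resp, config)
        t_std, _ = run_plan(dataset, spec_template, plan_std, config,
                            pretrained_stage1=(std_stage1, ids))
        results.append({"fraction": f,
                        "pretrained": t_pre, "standard": t_std,
                        "median_pretrained":
                            float(np.nanmedian(t_pre["r_norm"])),
                        "median_standard":
                            float(np.nanmedian(t_std["r_norm"]))})
    if not results:
        raise ValueError("no usable fractions")
    full = [r for r in results if r["fraction"] == 1.0]
    if full:
        ref = full[0]["median_standard"]
        for r in results:
            r["norm_pretrained"] = r["median_pretrained"] / ref
            r["norm_standard"] = r["median_standard"] / ref
    return results


def ln_baseline_scores(dataset: SyntheticDataset, config: FitConfig,
                       rank: int = 1) -> np.ndarray:
    """Per-neuron single-neuron LN prediction scores (for matched exclusion).

    Fits a rank-``rank`` LN model to every neuron independently and returns
    its validation R_norm (raw correlation where the noise ceiling is
    undefined)."""
    scores = np.empty(dataset.n_neurons)
    spec = ModelSpec("LN", rank=rank, n_freq=dataset.est_stim.F)
    for n in range(dataset.n_neurons):
        sub = dataset.subset_neurons([n])
        s1 = fit_stage1(spec, sub.est_stim, sub.est_resp, config)
        from .fitting import predict
        pred = predict(spec, s1.params, sub.val_stim)[0]
        tab = score_population(sub.val_resp, pred[None], model_id="LN")
        r = tab["r_norm"].iloc[0]
        scores[n] = r if np.isfinite(r) else tab["raw_r"].iloc[0]
    return scores
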