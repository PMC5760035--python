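"""Preprocessing: outlier arrays, detection filtering, quantile normalization.

The contract mirrors standard array QC practice: each brain region is
handled independently; sample outliers are removed first (scored on all
probes), then probes are kept only when flagged mature + mouse and
detected (detection p < 0.06) on at least 80% of the region's remaining
arrays.  A quantile-normalization stand-in is provided for pipelines
that start from expression matrices rather than probe-level data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset

DETECTION_P_THRESHOLD = 0.06
DETECTION_FRACTION = 0.80
MAD_SCALE = 1.4826  # consistency constant: scaled MAD estimates sigma under normality


@dataclass
class PreprocessReport:
    """Audit record of what preprocessing removed and why."""

    probes_in: int = 0
    probes_kept: int = 0
    outliers_removed: list[tuple[str, float]] = field(default_factory=list)
    filter_threshold: float = DETECTION_P_THRESHOLD
    filter_fraction: float = DETECTION_FRACTION

    def to_dict(self) -> dict:
        return {
            "probes_in": self.probes_in,
            "probes_kept": self.probes_kept,
            "outliers_removed": [[s, float(v)] for s, v in self.outliers_removed],
            "filter_threshold": self.filter_threshold,
            "filter_fraction": self.filter_fraction,
        }


def outlier_scores(values: pd.DataFrame) -> pd.Series:
    """Median inter-array Spearman correlation of each sample.

    Computed on all probes; a low score means the array disagrees with
    the bulk of its region-mates.
    """
    corr = values.corr(method="spearman")
    np.fill_diagonal(corr.to_numpy(), np.nan)
    return corr.median(axis=0, skipna=True)


def detect_outliers(
    ds: ExpressionDataset, n_mad: float = 3.0, min_drop: float = 0.1
) -> tuple[ExpressionDataset, PreprocessReport]:
    """Flag and remove outlier samples per region.

    A sample is an outlier when its median inter-array Spearman
    correlation falls strictly below ``median - max(n_mad * MAD,
    min_drop)`` of the region's score distribution (MAD scaled by
    1.4826).  The absolute ``min_drop`` guard keeps the rule from
    flagging ordinary treatment-group structure when arrays are so
    reproducible that the MAD is tiny: a genuinely corrupted array loses
    most of its inter-array correlation, a treatment effect shifts it by
    a few thousandths.  Regions with fewer than 4 samples are skipped
    with a warning.
    """
    report = PreprocessReport(probes_in=ds.n_probes, probes_kept=ds.n_probes)
    flagged: list[str] = []
    for region in ds.regions:
        sub = ds.region(region)
        if sub.n_samples < 4:
            warnings.warn(f"region {region}: fewer than 4 samples, outlier check skipped")
            continue
        scores = outlier_scores(sub.values)
        med = scores.median()
        mad = MAD_SCALE * (scores - med).abs().median()
        cut = med - max(n_mad * mad, min_drop)
        for sid, sc in scores.items():
            if sc < cut:
                flagged.append(sid)
                report.outliers_removed.append((sid, float(sc)))
    keep = [s for s in ds.values.columns if s not in set(flagged)]
    return ds.subset_samples(keep), report


def detection_filter(
    ds: ExpressionDataset,
    p_thresh: float = DETECTION_P_THRESHOLD,
    frac: float = DETECTION_FRACTION,
    species: str | None = "mouse",
    maturity: str | None = "mature",
) -> ExpressionDataset:
    """Keep probes detected above background on enough arrays.

    A probe survives when (a) it carries the requested species and
    maturity flags, and (b) its detection p is strictly below
    ``p_thresh`` on at least ``frac`` (inclusive) of the dataset's
    arrays.  Call per region (`ds.region(...)`) to match the
    region-independent analysis contract.  Probe order is preserved.
    """
    mask = pd.Series(True, index=ds.probes.index)
    if species is not None:
        mask &= ds.probes["species"] == species
    if maturity is not None:
        mask &= ds.probes["maturity"] == maturity
    if ds.n_samples > 0:
        det_frac = (ds.detection_p < p_thresh).sum(axis=1) / ds.n_samples
        mask &= det_frac >= frac
    kept = list(ds.probes.index[mask])
    if not kept:
        warnings.warn("detection filter removed every probe")
    return ds.subset_probes(kept)


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force identical empirical distributions across samples.

    Every sample's sorted vector becomes the across-sample mean of
    sorted vectors; ranks within a sample are preserved and ties receive
    the mean of their tied target quantiles.
    """
    x = ds.values.to_numpy(dtype=float)
    n_probes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n_probes, dtype=int)
        ranks[order] = np.arange(n_probes)
        out[:, j] = ref[ranks]
        # ties: average the target quantiles of each tied run
        sorted_col = col[order]
        i = 0
        while i < n_probes:
            k = i
            while k + 1 < n_probes and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                out[order[i : k + 1], j] = ref[i : k + 1].mean()
            i = k + 1
    values = pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(
        values=values, detection_p=ds.detection_p, samples=ds.samples, probes=ds.probes
    )


def preprocess_region(
    ds: ExpressionDataset,
    region: str,
    p_thresh: float = DETECTION_P_THRESHOLD,
    frac: float = DETECTION_FRACTION,
    species: str | None = "mouse",
    maturity: str | None = "mature",
    normalize: bool = True,
) -> tuple[ExpressionDataset, PreprocessReport]:
    """Outlier removal -> detection filter -> quantile normalization for one region."""
    sub = ds.region(region)
    clean, report = detect_outliers(sub)
    filtered = detection_filter(clean, p_thresh=p_thresh, frac=frac, species=species, maturity=maturity)
    report.probes_in = ds.n_probes
    report.probes_kept = filtered.n_probes
    if normalize and filtered.n_samples >= 2 and filtered.n_probes > 0:
        filtered = quantile_normalize(filtered)
    return filtered, report
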