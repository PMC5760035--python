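"""Empirical-Bayes moderated two-sample t-statistics.

For each probe g a treated-vs-control contrast at one (region, time)
yields an effect beta_g (log2 mean difference), a pooled residual
variance s_g^2 on d_g degrees of freedom, and an unscaled variance
v = 1/n1 + 1/n2.  The per-probe variances are modeled as scaled
chi-square draws around a prior variance s0^2 with d0 prior degrees of
freedom; the posterior variance

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d)

replaces s2 in the t-statistic, which then has d0 + d degrees of
freedom.  The hyperparameters (d0, s0^2) are estimated by the
method of moments on log variances: with

    e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2),

the excess variance of e_g over mean(trigamma(d_g/2)) equals
trigamma(d0/2), solved for d0 by Newton iteration on the trigamma
inverse; then s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2)).  When
the moment estimate of the excess variance is non-positive the prior is
degenerate (d0 = +inf) and every probe shrinks fully to s0^2, with
normal rather than Student-t tails.

The model is exposed statsmodels-style: :class:`ModeratedTTest` is
constructed from an :class:`~tempomir.datasets.ExpressionDataset` (or
raw arrays) and ``fit()`` returns a :class:`ModeratedTTestResults`
carrying estimates, hyperparameters, p-values, FDR and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import CONTROL, TREATED, ExpressionDataset

MIRNA = "mirna"
MRNA = "mrna"
NOMINAL_ALPHA = 0.05
FDR_ALPHA = 0.05


@dataclass(frozen=True)
class EBayesHyper:
    """Variance-prior hyperparameters: d0 (may be +inf) and s0^2.

    The estimator always returns d0 > 0; d0 = 0 is accepted here as the
    classical-t limit (no shrinkage), useful for cross-validation
    against the ordinary pooled two-sample t.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the monotone transform Newton step on 1/trigamma, which is
    nearly linear in y, so convergence is fast from y0 = 0.5 + 1/x.
    """
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            return float(y)
    warnings.warn("trigamma inverse did not reach tolerance")
    return float(y)


def estimate_hyperparameters(s2: np.ndarray, d) -> EBayesHyper:
    """Method-of-moments fit of (d0, s0^2) from per-probe variances.

    Zero (or non-finite) variances are excluded with a warning; at least
    10 usable probes with d >= 1 are required.
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (d >= 1)
    if ok.sum() < s2.size:
        warnings.warn(f"excluding {int(s2.size - ok.sum())} zero/invalid variances from the prior fit")
    if ok.sum() < 10:
        raise ValueError("need >= 10 probes with positive variance and d >= 1")
    s2, d = s2[ok], d[ok]
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - np.mean(special.polygamma(1, d / 2.0))
    if excess <= 0:
        # degenerate prior: all true variances equal; the scale is the
        # arithmetic mean of the observed variances
        return EBayesHyper(d0=np.inf, s0_sq=float(s2.mean()))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesHyper(d0=float(d0), s0_sq=s0_sq)


def fit_group_means(
    ds: ExpressionDataset, region: str, time_h: int
) -> pd.DataFrame:
    """Per-probe treated-vs-control effect and pooled variance at one contrast.

    Returns a DataFrame with columns beta (treated - control log2 mean
    difference), s2 (pooled within-group variance), d (= n1 + n2 - 2)
    and v (= 1/n1 + 1/n2).
    """
    treated = ds.group_samples(region, time_h, TREATED)
    control = ds.group_samples(region, time_h, CONTROL)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError(
            f"contrast {region}/{time_h}h needs >= 2 samples per group "
            f"(treated={len(treated)}, control={len(control)})"
        )
    xt = ds.values[treated].to_numpy()
    xc = ds.values[control].to_numpy()
    n1, n2 = xt.shape[1], xc.shape[1]
    beta = xt.mean(axis=1) - xc.mean(axis=1)
    ss = xt.var(axis=1, ddof=1) * (n1 - 1) + xc.var(axis=1, ddof=1) * (n2 - 1)
    d = n1 + n2 - 2
    s2 = ss / d
    return pd.DataFrame(
        {"beta": beta, "s2": s2, "d": float(d), "v": 1.0 / n1 + 1.0 / n2},
        index=ds.values.index,
    )


def moderated_t(
    beta: np.ndarray,
    s2: np.ndarray,
    d,
    v,
    hyper: EBayesHyper,
) -> pd.DataFrame:
    """Moderated t-statistics, total df and two-sided p-values.

    ``hyper.d0 = 0`` reduces exactly to the classical pooled two-sample
    t; ``hyper.d0 = inf`` fully shrinks every variance to s0^2 and uses
    normal tails.  A zero posterior variance leaves the probe's p
    undefined (NaN) and flags it.
    """
    beta = np.asarray(beta, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), beta.shape)
    v = np.broadcast_to(np.asarray(v, dtype=float), beta.shape)
    if np.isinf(hyper.d0):
        s2_post = np.full_like(beta, hyper.s0_sq)
        df_total = np.full_like(beta, np.inf)
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + d * s2) / (hyper.d0 + d)
        df_total = hyper.d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_post * v)
    undefined = s2_post <= 0
    p = np.full_like(beta, np.nan)
    finite_df = np.isfinite(df_total)
    ok = ~undefined
    p[ok & finite_df] = 2.0 * stats.t.sf(np.abs(t[ok & finite_df]), df_total[ok & finite_df])
    p[ok & ~finite_df] = 2.0 * stats.norm.sf(np.abs(t[ok & ~finite_df]))
    # beta == 0 must give t = 0, p = 1 even if the variance is also 0
    zero_beta = beta == 0
    t[zero_beta & undefined] = 0.0
    p[zero_beta] = 1.0
    out = pd.DataFrame({"t_mod": t, "df_total": df_total, "p": p, "s2_post": s2_post})
    out["undefined"] = undefined & ~zero_beta
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def signed_fold_change(beta) -> np.ndarray:
    """Signed linear fold change: 2^beta when >= 1, else -2^-beta.

    beta = 0 maps to +1; a treated/control ratio of 1/1.35 reports as
    -1.35 (control higher), the usual array reporting convention.
    """
    beta = np.asarray(beta, dtype=float)
    r = np.power(2.0, beta)
    return np.where(r >= 1.0, r, -1.0 / r)


# ----------------------------------------------------------------------
# Model / Results objects
# ----------------------------------------------------------------------

class ModeratedTTest:
    """Two-group moderated-t model for one (region, time) contrast.

    Parameters
    ----------
    beta, s2, d, v : array-like
        Per-probe effect, pooled variance, residual df, and unscaled
        variance; usually from :func:`fit_group_means`.
    probe_ids : sequence, optional
    """

    def __init__(self, beta, s2, d, v, probe_ids=None):
        self.beta = np.asarray(beta, dtype=float)
        self.s2 = np.asarray(s2, dtype=float)
        self.d = np.broadcast_to(np.asarray(d, dtype=float), self.beta.shape).copy()
        self.v = np.broadcast_to(np.asarray(v, dtype=float), self.beta.shape).copy()
        self.probe_ids = (
            pd.Index(probe_ids) if probe_ids is not None else pd.RangeIndex(len(self.beta))
        )
        self.region: str | None = None
        self.time_h: int | None = None

    @classmethod
    def from_dataset(cls, ds: ExpressionDataset, region: str, time_h: int) -> "ModeratedTTest":
        fitted = fit_group_means(ds, region, time_h)
        model = cls(
            fitted["beta"], fitted["s2"], fitted["d"], fitted["v"], probe_ids=fitted.index
        )
        model.region, model.time_h = region, time_h
        return model

    def fit(self, hyper: EBayesHyper | None = None) -> "ModeratedTTestResults":
        if hyper is None:
            hyper = estimate_hyperparameters(self.s2, self.d)
        mod = moderated_t(self.beta, self.s2, self.d, self.v, hyper)
        table = pd.DataFrame(
            {
                "beta": self.beta,
                "s2": self.s2,
                "d": self.d,
                "v": self.v,
                "s2_post": mod["s2_post"].to_numpy(),
                "t_mod": mod["t_mod"].to_numpy(),
                "df_total": mod["df_total"].to_numpy(),
                "p": mod["p"].to_numpy(),
            },
            index=self.probe_ids,
        )
        table["fdr"] = bh_fdr(table["p"].to_numpy())
        table["fc_signed"] = signed_fold_change(table["beta"].to_numpy())
        return ModeratedTTestResults(model=self, hyper=hyper, table=table)


class ModeratedTTestResults:
    """Fitted moderated-t contrast: per-probe table plus hyperparameters."""

    def __init__(self, model: ModeratedTTest, hyper: EBayesHyper, table: pd.DataFrame):
        self.model = model
        self.hyper = hyper
        self.table = table

    @property
    def d0(self) -> float:
        return self.hyper.d0

    @property
    def s0_sq(self) -> float:
        return self.hyper.s0_sq

    def summary(self, alpha: float = NOMINAL_ALPHA) -> str:
        t = self.table
        lines = [
            "Moderated two-sample t-test",
            "===========================",
            f"contrast:       {self.model.region or '-'} / {self.model.time_h if self.model.time_h is not None else '-'}h (treated - control)",
            f"probes:         {len(t)}",
            f"prior df d0:    {self.hyper.d0:.4g}",
            f"prior var s0^2: {self.hyper.s0_sq:.4g}",
            f"p <= {alpha:g}:      {int((t['p'] <= alpha).sum())}",
            f"FDR <= {alpha:g}:    {int((t['fdr'] <= alpha).sum())}",
        ]
        top = t.nsmallest(min(10, len(t)), "p")[["beta", "fc_signed", "t_mod", "p", "fdr"]]
        lines.append("")
        lines.append(top.to_string(float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)


# ----------------------------------------------------------------------
# DE calling with the role/time threshold scheme
# ----------------------------------------------------------------------

def call_de(results: pd.DataFrame, role: str, time_h: int, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the role- and time-specific DE thresholds and resolve duplicates.

    miRNAs are called DE at nominal p <= alpha at every time point.
    mRNA targets are called at FDR <= alpha for the 0 and 8 h contrasts
    and at nominal p <= alpha for the 120 h contrast.  Duplicate probes
    mapping to one annotation are resolved by minimum p: the output is
    one row per annotation carrying its best probe's statistics.

    ``results`` must have columns annotation, p, fdr (plus anything else
    to carry through, e.g. beta/fc_signed).
    """
    if role not in (MIRNA, MRNA):
        raise ValueError(f"unknown role {role!r}; expected '{MIRNA}' or '{MRNA}'")
    res = results.copy()
    if role == MIRNA:
        res["is_de"] = res["p"] <= alpha
    else:
        if time_h in (0, 8):
            res["is_de"] = res["fdr"] <= alpha
        else:
            res["is_de"] = res["p"] <= alpha
    res = res.sort_values(["p", "annotation"], kind="stable")
    res = res[~res["annotation"].duplicated(keep="first")]
    return res.sort_index()


def run_contrasts(
    ds: ExpressionDataset,
    region: str,
    role: str,
    times_h=(0, 8, 120),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every time contrast of one region and stack the annotated calls.

    Returns a long DataFrame: one row per (annotation, time) with the
    probe-level statistics of the minimum-p probe and the is_de call.
    """
    frames = []
    for t in times_h:
        res = ModeratedTTest.from_dataset(ds, region, t).fit()
        table = res.table.copy()
        table["annotation"] = ds.probes.loc[table.index, "annotation"]
        table["probe_id"] = table.index
        called = call_de(table, role=role, time_h=t, alpha=alpha)
        called["region"] = region
        called["time_h"] = t
        frames.append(called.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def de_sets_by_time(calls: pd.DataFrame) -> dict[int, set[str]]:
    """Map time -> set of DE annotations from a `run_contrasts` table."""
    out: dict[int, set[str]] = {}
    for t, grp in calls.groupby("time_h"):
        out[int(t)] = set(grp.loc[grp["is_de"], "annotation"])
    return out
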