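"""Preprocessing and moderated-t differential expression.

Pipeline order is fixed: clamp -> 75th-percentile normalization -> presence
filter -> log2 -> (optional noise filter) -> per-gene contrast fit ->
empirical-Bayes hyperparameter estimation -> moderated t -> Benjamini-
Hochberg -> up/down classification.  The variance prior is the scaled
inverse-chi-square of the standard moderated-t model; hyperparameters are
estimated by moment matching on log sample variances with digamma/trigamma
corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import SCALE_LINEAR, SCALE_LOG2, ExpressionMatrix, ScaleError

QUANTILE_CONVENTION = "linear interpolation at position 1+(n-1)q"


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison: treatment vs control."""

    treatment_group: str
    control_group: str

    def validate(self, m: ExpressionMatrix, min_per_group: int = 2) -> None:
        for g in (self.treatment_group, self.control_group):
            n = len(m.samples_in_group(g))
            if n < min_per_group:
                raise ValueError(
                    f"group {g!r} has {n} samples; need >= {min_per_group}"
                )


@dataclass(frozen=True)
class EBayesHyper:
    """Variance-prior hyperparameters: degrees of freedom and scale."""

    d0: float  # may be +inf (infinitely strong prior)
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (0 disables shrinkage)")
        if not (self.s0_sq > 0) and self.d0 != 0:
            raise ValueError("s0_sq must be positive")


# ---------------------------------------------------------------------------
# preprocessing


def clamp_negatives(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Replace all values <= 0 by ``floor`` (default 1.0).

    Zeros are clamped along with negatives so the later log2 transform is
    safe.  Linear scale only.
    """
    if m.scale != SCALE_LINEAR:
        raise ScaleError("clamp_negatives requires linear-scale intensities")
    values = m.values.where(m.values > 0, other=floor)
    return m.with_values(values)


def normalize_p75(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its 75th percentile.

    The percentile uses linear interpolation between order statistics
    (position 1+(n-1)q).  After the call every column's 75th percentile
    is exactly 1.
    """
    if m.scale != SCALE_LINEAR:
        raise ScaleError("normalize_p75 requires linear-scale intensities")
    p75 = m.values.quantile(0.75, interpolation="linear")
    if (p75 <= 0).any():
        bad = list(p75.index[p75 <= 0])
        raise ValueError(f"non-positive 75th percentile in samples {bad}; clamp first")
    values = m.values.div(p75, axis=1)
    return m.with_values(values, normalized=True)


def filter_expressed(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep probes flagged Present or Marginal in at least one sample."""
    if m.flags is None:
        raise ValueError("filter_expressed requires detection flags")
    keep = m.flags.isin(["P", "M"]).any(axis=1)
    if not keep.any():
        warnings.warn("no probes flagged Present/Marginal in any sample", stacklevel=2)
    return m.with_values(m.values.loc[keep], flags=m.flags.loc[keep])


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform a linear matrix; sets the scale marker."""
    if m.scale != SCALE_LINEAR:
        raise ScaleError("matrix is already on the log2 scale")
    if (m.values.values <= 0).any():
        raise ValueError("non-positive values; run clamp_negatives first")
    return m.with_values(np.log2(m.values), scale=SCALE_LOG2)


def preprocess(m: ExpressionMatrix) -> ExpressionMatrix:
    """clamp -> p75 normalization -> presence filter -> log2."""
    m = clamp_negatives(m)
    m = normalize_p75(m)
    if m.flags is not None:
        m = filter_expressed(m)
    return log2_transform(m)


# ---------------------------------------------------------------------------
# differential expression


def fit_contrast(m: ExpressionMatrix, c: ContrastSpec) -> pd.DataFrame:
    """Per-gene group means, log2 fold change and pooled within-group variance.

    Returns a DataFrame indexed by probe with columns ``mean_control``,
    ``mean_treatment``, ``log2fc``, ``s2`` (pooled residual variance) and
    ``df_residual`` (= n1 + n2 - 2).
    """
    if m.scale != SCALE_LOG2:
        raise ScaleError("fit_contrast requires log2-scale data")
    if not m.normalized:
        raise ValueError("running DEA on unnormalized data is an error")
    c.validate(m)
    ctrl = m.values[m.samples_in_group(c.control_group)]
    trt = m.values[m.samples_in_group(c.treatment_group)]
    n1, n2 = ctrl.shape[1], trt.shape[1]
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    ss_within = ((ctrl.sub(mean_c, axis=0)) ** 2).sum(axis=1) + (
        (trt.sub(mean_t, axis=0)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    out = pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_treatment": mean_t,
            "log2fc": mean_t - mean_c,
            "s2": ss_within / df,
            "df_residual": df,
        }
    )
    out.attrs["n_control"] = n1
    out.attrs["n_treatment"] = n2
    return out


def _trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # trigamma(x) ~ 1/x for large x, ~ 1/x**2 for small x: robust start
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = special.polygamma(1, x) - y
        fprime = special.polygamma(2, x)
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * (1 + abs(x)):
            return x_new
        x = x_new
    return x


def estimate_hyper(s2, df: int) -> EBayesHyper:
    """Moment-match the scaled inverse-chi-square variance prior.

    Works on e_g = log(s2_g): under the model var(e) = trigamma(d0/2) +
    trigamma(df/2), so d0 solves trigamma(d0/2) = var(e) - trigamma(df/2).
    When the observed spread is no larger than the sampling noise the prior
    is returned as d0 = +inf with the corresponding point scale.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.all(s2 == 0):
        raise ValueError("all residual variances are zero")
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need >= 2 finite positive variances")
    e = np.log(s2)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    bias = special.digamma(df / 2.0) - np.log(df / 2.0)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return EBayesHyper(d0=np.inf, s0_sq=float(np.exp(e_mean - bias)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(
        e_mean - bias + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    )
    return EBayesHyper(d0=float(d0), s0_sq=float(s0_sq))


def moderated_t(stats_df: pd.DataFrame, h: EBayesHyper, c: ContrastSpec | None = None) -> pd.DataFrame:
    """Fill ``t_mod``, ``p`` and ``s2_post`` columns.

    Posterior variance is (d0*s0^2 + df*s2)/(d0 + df); with d0 = 0 this is
    the classical pooled-t, with d0 = +inf the prior scale.  Two-sided
    p-values use Student t with d0 + df degrees of freedom (normal when
    d0 is infinite).  Zero posterior variance yields p = 0 with the
    ``degenerate_variance`` flag set, never a division error.
    """
    out = stats_df.copy()
    n1 = out.attrs.get("n_control")
    n2 = out.attrs.get("n_treatment")
    if n1 is None or n2 is None:
        raise ValueError("fit_contrast output required (sample sizes missing)")
    df = out["df_residual"].to_numpy(dtype=float)
    s2 = out["s2"].to_numpy(dtype=float)
    if np.isinf(h.d0):
        s2_post = np.full_like(s2, h.s0_sq)
        df_total = np.full_like(s2, np.inf)
    elif h.d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (h.d0 * h.s0_sq + df * s2) / (h.d0 + df)
        df_total = h.d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    lfc = out["log2fc"].to_numpy(dtype=float)
    degenerate = s2_post == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.sign(lfc) * np.inf, lfc / se)
    p = np.empty_like(t)
    finite_df = np.isfinite(df_total)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
    p[degenerate & (lfc == 0)] = 1.0  # 0/0: no evidence either way
    p[degenerate & (lfc != 0)] = 0.0
    out["s2_post"] = s2_post
    out["t_mod"] = t
    out["p"] = p
    out["degenerate_variance"] = degenerate
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def classify_degs(
    stats_df: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 0.1
) -> pd.DataFrame:
    """Assign status up/down/ns by strict thresholds on adj_p and log2fc."""
    out = stats_df.copy()
    if "adj_p" not in out:
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    sig = out["adj_p"] < alpha
    out["status"] = "ns"
    out.loc[sig & (out["log2fc"] > lfc_threshold), "status"] = "up"
    out.loc[sig & (out["log2fc"] < -lfc_threshold), "status"] = "down"
    return out


def run_dea(
    m: ExpressionMatrix,
    c: ContrastSpec,
    alpha: float = 0.05,
    lfc_threshold: float = 0.1,
    shrinkage: bool = True,
) -> pd.DataFrame:
    """fit -> hyperparameters -> moderated t -> BH -> classification."""
    fit = fit_contrast(m, c)
    if shrinkage:
        hyper = estimate_hyper(fit["s2"].to_numpy(), int(fit["df_residual"].iloc[0]))
    else:
        hyper = EBayesHyper(d0=0.0, s0_sq=1.0)
    res = moderated_t(fit, hyper, c)
    res["adj_p"] = bh_adjust(res["p"].to_numpy())
    res = classify_degs(res, alpha=alpha, lfc_threshold=lfc_threshold)
    res.attrs["hyper"] = hyper
    return res


# ---------------------------------------------------------------------------
# noise filtering and contrast intersection


def noise_filter(
    m: ExpressionMatrix,
    c: ContrastSpec,
    sd_max: float = 0.3,
    dist_min: float = 0.5,
) -> list[str]:
    """Probes with both intra-group SDs < sd_max and |mean difference| > dist_min.

    Both inequalities are strict.  Meant to be applied before DEA in the
    secondary (treatment vs inhibitor) contrast.
    """
    if m.scale != SCALE_LOG2:
        raise ScaleError("noise_filter requires log2-scale data")
    ctrl = m.values[m.samples_in_group(c.control_group)]
    trt = m.values[m.samples_in_group(c.treatment_group)]
    sd_ok = (ctrl.std(axis=1, ddof=1) < sd_max) & (trt.std(axis=1, ddof=1) < sd_max)
    dist_ok = (trt.mean(axis=1) - ctrl.mean(axis=1)).abs() > dist_min
    keep = sd_ok & dist_ok
    return list(m.values.index[keep])


def select_tf_degs(stats_df: pd.DataFrame, catalog) -> pd.DataFrame:
    """Rows of DEGs (status != ns) whose gene is in the TF catalog."""
    catalog = set(catalog)
    if not catalog:
        warnings.warn("empty transcription-factor catalog", stacklevel=2)
    degs = stats_df[stats_df["status"] != "ns"]
    return degs[degs.index.isin(catalog)]


def intersect_contrasts(
    degs_a: pd.DataFrame, degs_b: pd.DataFrame, catalog=()
) -> dict:
    """Genes concordantly up / down in both classified contrasts."""
    catalog = set(catalog)
    out: dict[str, object] = {}
    for direction in ("up", "down"):
        a = set(degs_a.index[degs_a["status"] == direction])
        b = set(degs_b.index[degs_b["status"] == direction])
        out[f"common_{direction}"] = sorted(a & b)
    out["tf_flags"] = {
        g: (g in catalog) for g in out["common_up"] + out["common_down"]
    }
    return out


def volcano_table(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: log2fc vs log1p(-log10 adj_p)."""
    with np.errstate(divide="ignore"):
        score = np.log1p(-np.log10(stats_df["adj_p"].to_numpy()))
    return pd.DataFrame(
        {"log2fc": stats_df["log2fc"], "neglog_adj_p": score, "status": stats_df["status"]},
        index=stats_df.index,
    )
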