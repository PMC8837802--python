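"""Log response ratio (lnRR) random-effects meta-analysis.

Each study contributes one effect record per variable: the natural log of the
ratio of rhizosphere to bulk group means, lnRR = ln(X_t / X_c), with
within-study variance

    v = S_t^2 / (n_t X_t^2) + S_c^2 / (n_c X_c^2).

Studies are pooled under a random-effects model: between-study variance tau^2
is estimated by DerSimonian-Laird (floored at zero) and studies are weighted
by w = 1 / (v + tau^2). Confidence intervals come from a nonparametric
bootstrap over studies (999 resamples, percentile method, tau^2 re-estimated
per resample). Pooled effects are reported as percent change,
(exp(mean) - 1) * 100.

Also here: the Q_T = Q_W + Q_B heterogeneity partition for categorical
subgroups (subgroups with fewer than 10 studies are excluded), Egger's
regression test and Duval-Tweedie trim-and-fill for publication bias, and
all-subsets AICc Akaike-weight predictor importance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("rhizometa")


# ---------------------------------------------------------------------------
# effect records
# ---------------------------------------------------------------------------

@dataclass
class EffectRecord:
    """One study-level rhizosphere-vs-bulk comparison for one variable."""

    study_id: str
    variable: str
    x_t: float          # rhizosphere group mean
    x_c: float          # bulk group mean
    s_t: float          # group standard deviations (n-1 denominator)
    s_c: float
    n_t: int
    n_c: int
    lnrr: float
    v: float            # within-study variance of lnRR
    degenerate: bool = False   # a group had n = 1 (SD taken as 0)


def effect_from_groups(rhizo, bulk, study_id: str, variable: str
                       ) -> EffectRecord | None:
    """Build an EffectRecord from per-sample values of the two groups.

    Returns None (with a logged reason) when either group mean is
    non-positive, since the log ratio is undefined there. Groups of size 1
    contribute SD = 0 and are flagged ``degenerate``.
    """
    rhizo = np.asarray(rhizo, dtype=float)
    bulk = np.asarray(bulk, dtype=float)
    rhizo = rhizo[~np.isnan(rhizo)]
    bulk = bulk[~np.isnan(bulk)]
    if rhizo.size == 0 or bulk.size == 0:
        logger.info("effect_from_groups: %s/%s skipped (empty group)", study_id, variable)
        return None
    x_t, x_c = float(rhizo.mean()), float(bulk.mean())
    if x_t <= 0 or x_c <= 0:
        logger.info("effect_from_groups: %s/%s skipped (non-positive mean)",
                    study_id, variable)
        return None
    n_t, n_c = rhizo.size, bulk.size
    s_t = float(rhizo.std(ddof=1)) if n_t > 1 else 0.0
    s_c = float(bulk.std(ddof=1)) if n_c > 1 else 0.0
    lnrr = math.log(x_t / x_c)
    v = s_t ** 2 / (n_t * x_t ** 2) + s_c ** 2 / (n_c * x_c ** 2)
    return EffectRecord(study_id=study_id, variable=variable, x_t=x_t, x_c=x_c,
                        s_t=s_t, s_c=s_c, n_t=n_t, n_c=n_c, lnrr=lnrr, v=v,
                        degenerate=(n_t == 1 or n_c == 1))


def records_to_frame(records: list[EffectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# ---------------------------------------------------------------------------
# random-effects pooling
# ---------------------------------------------------------------------------

def dersimonian_laird(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird tau^2 estimate, floored at zero."""
    w = 1.0 / np.maximum(v, 1e-12)
    mu_fe = (w * y).sum() / w.sum()
    q = (w * (y - mu_fe) ** 2).sum()
    k = len(y)
    c = w.sum() - (w ** 2).sum() / w.sum()
    if c <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / c)


def _dl_pooled_mean(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    tau2 = dersimonian_laird(y, v)
    denom = v + tau2
    if np.all(denom == 0):
        return float(y.mean()), tau2
    w = 1.0 / np.maximum(denom, 1e-12)
    return float((w * y).sum() / w.sum()), tau2


def _dl_pooled_mean_rows(y: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorised DL pooled mean over bootstrap rows (n_boot, k)."""
    w = 1.0 / np.maximum(v, 1e-12)
    sw = w.sum(axis=1)
    mu_fe = (w * y).sum(axis=1) / sw
    q = (w * (y - mu_fe[:, None]) ** 2).sum(axis=1)
    k = y.shape[1]
    c = sw - (w ** 2).sum(axis=1) / sw
    tau2 = np.maximum(0.0, (q - (k - 1)) / np.maximum(c, 1e-12))
    w_re = 1.0 / np.maximum(v + tau2[:, None], 1e-12)
    return (w_re * y).sum(axis=1) / w_re.sum(axis=1)


def percent_change(lnrr: float) -> float:
    """(exp(lnRR) - 1) * 100: back-conversion of a pooled log response ratio."""
    return (math.exp(lnrr) - 1.0) * 100.0


@dataclass
class MetaSummary:
    """Pooled random-effects summary of one variable (or subgroup)."""

    variable: str
    group: str
    k: int
    mean_lnrr: float
    tau2: float
    ci_low: float
    ci_high: float
    pct_change: float
    pct_ci_low: float
    pct_ci_high: float
    significant: bool
    degenerate_ci: bool = False


def random_effects_pool(records: list[EffectRecord], n_boot: int = 999,
                        seed: int | np.random.Generator = 0,
                        group: str = "overall") -> MetaSummary:
    """Random-effects pooled mean with a study-level bootstrap percentile CI.

    tau^2 is re-estimated (DerSimonian-Laird) inside every bootstrap
    resample; 999 resamples by default. With identical effects and all-zero
    variances the CI collapses to the point estimate and is flagged.
    """
    if len(records) < 2:
        raise ValueError(f"need at least 2 studies to pool, got {len(records)}")
    y = np.array([r.lnrr for r in records])
    v = np.array([r.v for r in records])
    variable = records[0].variable
    mean, tau2 = _dl_pooled_mean(y, v)
    rng = (np.random.default_rng(seed)
           if not isinstance(seed, np.random.Generator) else seed)
    k = len(y)
    idx = rng.integers(0, k, size=(n_boot, k))
    boot_means = _dl_pooled_mean_rows(y[idx], v[idx])
    ci_low, ci_high = np.percentile(boot_means, [2.5, 97.5])
    degenerate = bool(np.allclose(y, y[0]) and np.allclose(v, 0.0))
    if degenerate:
        ci_low = ci_high = mean
    # the point estimate always lies inside the reported interval
    ci_low, ci_high = min(ci_low, mean), max(ci_high, mean)
    significant = not (ci_low <= 0.0 <= ci_high)
    return MetaSummary(
        variable=variable, group=group, k=k, mean_lnrr=mean, tau2=tau2,
        ci_low=float(ci_low), ci_high=float(ci_high),
        pct_change=percent_change(mean),
        pct_ci_low=percent_change(float(ci_low)),
        pct_ci_high=percent_change(float(ci_high)),
        significant=bool(significant), degenerate_ci=degenerate,
    )


# ---------------------------------------------------------------------------
# subgroup heterogeneity partition
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityPartition:
    q_total: float
    q_within: float
    q_between: float
    df_between: int
    p_between: float


def subgroup_analysis(records: list[EffectRecord], labels: dict | pd.Series,
                      min_k: int = 10, n_boot: int = 999,
                      seed: int | np.random.Generator = 0
                      ) -> tuple[list[MetaSummary], HeterogeneityPartition | None]:
    """Per-subgroup pooling plus the Q_T = Q_W + Q_B heterogeneity partition.

    ``labels`` maps study_id -> categorical level. Subgroups with fewer than
    ``min_k`` studies are excluded (and logged). The partition uses
    mixed-model weights w = 1/(v + tau^2) with tau^2 pooled across groups
    (within-group DerSimonian-Laird), under which Q_T = Q_W + Q_B is an
    algebraic identity and Q_B stays chi-square calibrated when true
    between-study heterogeneity is present; Q_B is referred to chi-square
    with (groups - 1) df.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    rng = (np.random.default_rng(seed)
           if not isinstance(seed, np.random.Generator) else seed)
    by_group: dict[str, list[EffectRecord]] = {}
    for r in records:
        lab = labels.get(r.study_id)
        if lab is None:
            logger.info("subgroup_analysis: study %s has no label; skipped", r.study_id)
            continue
        by_group.setdefault(str(lab), []).append(r)
    kept = {g: rs for g, rs in by_group.items() if len(rs) >= min_k}
    for g, rs in by_group.items():
        if g not in kept:
            logger.info("subgroup_analysis: subgroup %r excluded (k=%d < %d)",
                        g, len(rs), min_k)
    summaries = [random_effects_pool(rs, n_boot=n_boot, seed=rng, group=g)
                 for g, rs in sorted(kept.items())]
    if len(kept) < 2:
        logger.warning("subgroup_analysis: fewer than 2 surviving subgroups; "
                       "heterogeneity partition skipped")
        return summaries, None
    # pooled within-group tau^2 (DL on the within-group Q), then mixed weights
    all_records = [r for rs in kept.values() for r in rs]
    y = np.array([r.lnrr for r in all_records])
    v = np.maximum(np.array([r.v for r in all_records]), 1e-12)
    q_within_fe, c_within, k_total = 0.0, 0.0, 0
    for rs in kept.values():
        yg = np.array([r.lnrr for r in rs])
        vg = np.maximum(np.array([r.v for r in rs]), 1e-12)
        wg = 1.0 / vg
        mu_g = (wg * yg).sum() / wg.sum()
        q_within_fe += float((wg * (yg - mu_g) ** 2).sum())
        c_within += float(wg.sum() - (wg ** 2).sum() / wg.sum())
        k_total += len(rs)
    tau2_pooled = max(0.0, (q_within_fe - (k_total - len(kept))) / max(c_within, 1e-12))
    w = 1.0 / (v + tau2_pooled)
    grand = (w * y).sum() / w.sum()
    q_total = float((w * (y - grand) ** 2).sum())
    q_within = 0.0
    pos = 0
    for rs in kept.values():
        yg = np.array([r.lnrr for r in rs])
        wg = w[pos:pos + len(rs)]
        pos += len(rs)
        mu_g = (wg * yg).sum() / wg.sum()
        q_within += float((wg * (yg - mu_g) ** 2).sum())
    q_between = q_total - q_within
    df = len(kept) - 1
    p = float(stats.chi2.sf(max(q_between, 0.0), df))
    return summaries, HeterogeneityPartition(
        q_total=q_total, q_within=q_within, q_between=q_between,
        df_between=df, p_between=p)


# ---------------------------------------------------------------------------
# publication bias
# ---------------------------------------------------------------------------

def egger_test(records: list[EffectRecord]) -> dict:
    """Egger's regression: standardized effect (lnRR/se) on precision (1/se).

    A non-zero intercept indicates small-study asymmetry. Records with v = 0
    are excluded with a warning.
    """
    usable = [r for r in records if r.v > 0]
    if len(usable) < len(records):
        logger.warning("egger_test: excluded %d records with zero variance",
                       len(records) - len(usable))
    if len(usable) < 3:
        raise ValueError(f"Egger's test needs at least 3 usable studies, got {len(usable)}")
    y = np.array([r.lnrr for r in usable])
    se = np.sqrt(np.array([r.v for r in usable]))
    z = y / se
    precision = 1.0 / se
    fit = stats.linregress(precision, z)
    t = fit.intercept / fit.intercept_stderr
    df = len(usable) - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"intercept": float(fit.intercept), "se": float(fit.intercept_stderr),
            "p_value": float(p), "slope": float(fit.slope), "k": len(usable)}


@dataclass
class BiasDiagnostics:
    k0: int
    side: str                    # which side studies are presumed missing from
    adjusted_mean: float
    unadjusted_mean: float
    converged: bool
    funnel: pd.DataFrame = field(repr=False, default=None)


def trim_and_fill(records: list[EffectRecord], side: str = "auto",
                  estimator: str = "L0", max_iter: int = 50) -> BiasDiagnostics:
    """Duval-Tweedie trim-and-fill estimate of missing studies.

    ``side`` is the side of the funnel presumed deficient ("left", "right",
    or "auto" = opposite the sign of Egger's intercept). The k0 most extreme
    studies on the overrepresented side are iteratively trimmed, the centre
    re-estimated from the trimmed set, and finally k0 mirror-image studies
    are imputed before re-pooling (random effects).

    ``estimator``: "L0" (rank-sum mass estimator, default) or "R0" (rightmost
    run length; more sensitive when the *most extreme* studies on one side
    were suppressed).
    """
    if estimator not in ("L0", "R0"):
        raise ValueError(f"estimator must be L0 or R0, got {estimator!r}")
    if len(records) < 3:
        raise ValueError("trim-and-fill needs at least 3 studies")
    if side == "auto":
        try:
            side = "left" if egger_test(records)["intercept"] > 0 else "right"
        except ValueError:
            side = "left"
    if side not in ("left", "right"):
        raise ValueError(f"side must be left, right or auto, got {side!r}")
    y = np.array([r.lnrr for r in records])
    v = np.array([r.v for r in records])
    flip = -1.0 if side == "right" else 1.0   # work in "missing on left" frame
    yy = flip * y
    n = len(yy)
    w = 1.0 / np.maximum(v, 1e-12)

    def fe_mean(mask: np.ndarray) -> float:
        return float((w[mask] * yy[mask]).sum() / w[mask].sum())

    k0 = 0
    converged = False
    order = np.argsort(yy)                     # ascending; trim from the top
    for _ in range(max_iter):
        mask = np.ones(n, dtype=bool)
        if k0 > 0:
            mask[order[n - k0:]] = False
        mu = fe_mean(mask)
        centered = yy - mu
        ranks = stats.rankdata(np.abs(centered))
        if estimator == "L0":
            s_rank = ranks[centered > 0].sum()
            est = (4.0 * s_rank - n * (n + 1)) / (2.0 * n - 1.0)
        else:
            # R0: length of the run of top-ranked |deviations| that are all
            # positive, minus one
            by_rank = np.argsort(ranks)[::-1]
            run = 0
            for idx in by_rank:
                if centered[idx] > 0:
                    run += 1
                else:
                    break
            est = run - 1.0
        k0_new = max(0, min(n - 3, int(round(est))))
        if k0_new == k0:
            converged = True
            break
        k0 = k0_new
    if not converged:
        logger.warning("trim_and_fill: k0 did not converge in %d iterations; "
                       "using last iterate %d", max_iter, k0)
    mask = np.ones(n, dtype=bool)
    if k0 > 0:
        mask[order[n - k0:]] = False
    mu = fe_mean(mask)
    unadjusted, _ = _dl_pooled_mean(yy, v)
    if k0 > 0:
        top = order[n - k0:]
        y_fill = np.concatenate([yy, 2.0 * mu - yy[top]])
        v_fill = np.concatenate([v, v[top]])
    else:
        y_fill, v_fill = yy, v
    adjusted, _ = _dl_pooled_mean(y_fill, v_fill)
    funnel = pd.DataFrame({
        "lnrr": np.concatenate([y, flip * (2.0 * mu - yy[order[n - k0:]])
                                if k0 > 0 else np.empty(0)]),
        "precision": np.concatenate([1.0 / np.sqrt(np.maximum(v, 1e-12)),
                                     1.0 / np.sqrt(np.maximum(v[order[n - k0:]], 1e-12))
                                     if k0 > 0 else np.empty(0)]),
        "imputed": [False] * n + [True] * k0,
    })
    return BiasDiagnostics(k0=int(k0), side=side,
                           adjusted_mean=float(flip * adjusted),
                           unadjusted_mean=float(flip * unadjusted),
                           converged=converged, funnel=funnel)


# ---------------------------------------------------------------------------
# predictor importance (all-subsets Akaike weights)
# ---------------------------------------------------------------------------

def predictor_importance(y, v, predictors: pd.DataFrame,
                         importance_cutoff: float = 0.8) -> pd.DataFrame:
    """Akaike-weight importance of each study covariate for the lnRR response.

    Fits every subset of up to 6 predictors by variance-weighted least
    squares (weights 1/(v + tau^2) with tau^2 from the full-null DL fit),
    converts AICc differences to Akaike weights, and scores each predictor by
    the summed weight of the models containing it. Predictors at or above
    ``importance_cutoff`` are flagged important.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    x = predictors.copy()
    complete = ~(np.isnan(y) | np.isnan(v) | x.isna().any(axis=1).to_numpy())
    y, v, x = y[complete], v[complete], x.loc[complete]
    n, m = x.shape
    if m > 6:
        raise ValueError(f"at most 6 predictors supported (2^6 model space), got {m}")
    if m == 0:
        raise ValueError("no predictors supplied")
    # collinearity guard: name the offending pair
    xs = (x - x.mean()) / x.std(ddof=0).replace(0.0, np.nan)
    if xs.isna().any().any():
        const = x.columns[x.std(ddof=0) == 0].tolist()
        raise ValueError(f"constant predictors: {const}")
    corr = xs.corr().to_numpy()
    for i in range(m):
        for j in range(i + 1, m):
            if abs(corr[i, j]) > 1.0 - 1e-8:
                raise ValueError(
                    f"collinear predictors: {x.columns[i]!r} and {x.columns[j]!r}")
    tau2 = dersimonian_laird(y, v)
    w = 1.0 / np.maximum(v + tau2, 1e-12)
    sw = np.sqrt(w)
    names = list(x.columns)
    results = []
    for r in range(m + 1):
        for subset in itertools.combinations(range(m), r):
            design = np.column_stack([np.ones(n)] + [x.iloc[:, j].to_numpy()
                                                     for j in subset])
            p = design.shape[1] + 1            # coefficients + error scale
            if n - p - 1 <= 0:
                continue
            wy = sw * y
            wx = design * sw[:, None]
            beta, *_ = np.linalg.lstsq(wx, wy, rcond=None)
            resid = wy - wx @ beta
            rss = float(resid @ resid)
            # Gaussian log-likelihood of the weighted model
            sigma2 = rss / n
            llf = -0.5 * n * (math.log(2 * math.pi * max(sigma2, 1e-300)) + 1) \
                + 0.5 * np.log(w).sum()
            aicc = -2 * llf + 2 * p + 2 * p * (p + 1) / (n - p - 1)
            results.append((subset, aicc))
    aiccs = np.array([a for _, a in results])
    delta = aiccs - aiccs.min()
    weights = np.exp(-0.5 * delta)
    weights /= weights.sum()
    importance = np.zeros(m)
    for (subset, _), wgt in zip(results, weights):
        for j in subset:
            importance[j] += wgt
    out = pd.DataFrame({
        "importance": importance,
        "important": importance >= importance_cutoff,
    }, index=pd.Index(names, name="predictor"))
    return out.sort_values("importance", ascending=False)
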