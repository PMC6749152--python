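"""Empirical-Bayes moderated differential expression and meta-combination.

Per dataset, each feature's pooled two-group variance s_g^2 is shrunk toward
an empirically estimated prior (d0, s0^2): the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t-statistic ``effect / sqrt(s~^2 (1/n1 + 1/n2))`` is
referred to a Student t distribution with d0 + d_g degrees of freedom.
Hyperparameters are fit by method of moments on the log sample variances
(Smyth-style closed forms with a trigamma inversion).

Evidence from several datasets is combined per feature by a signed-z
Stouffer rule with sqrt(total-sample-size) weights, followed by
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

_MIN_FEATURES_FOR_PRIOR = 10


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (features x samples) with two-group labels.

    ``conditions`` maps each sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    conditions: pd.Series
    tag: str = "dataset"

    def __post_init__(self) -> None:
        self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            missing = list(self.values.columns[self.conditions.isna()])
            raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.conditions.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"condition labels must be case/control, got {bad}")
        if self.values.index.duplicated().any():
            dups = list(self.values.index[self.values.index.duplicated()])
            raise ValueError(f"duplicated feature ids: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        for grp in ("case", "control"):
            if (self.conditions == grp).sum() < 2:
                raise ValueError(f"need >=2 {grp} samples in dataset {self.tag!r}")

    @property
    def n_case(self) -> int:
        return int((self.conditions == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.conditions == "control").sum())

    def group_values(self, group: str) -> np.ndarray:
        cols = self.conditions.index[self.conditions == group]
        return self.values.loc[:, cols].to_numpy(dtype=float)


@dataclass
class ModeratedStats:
    """Per-feature moderated t results for one dataset.

    ``table`` columns: effect, s_sq, s_tilde_sq, t_mod, p_two (index =
    feature ids). ``d_g`` is the residual degrees of freedom, shared by all
    features in a two-group design.
    """

    table: pd.DataFrame
    d_g: float
    d0: float
    s0_sq: float
    n_case: int
    n_control: int
    tag: str = "dataset"

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


@dataclass
class MetaDEResult:
    """Combined evidence per feature across datasets.

    ``table`` columns: z_meta, p_two, fdr, direction, n_datasets_observed.
    """

    table: pd.DataFrame
    weights: dict = field(default_factory=dict)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError(f"trigamma inverse requires y > 0, got {y}")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def estimate_prior(s_sq, d_g) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0_sq).

    Works on ``e_g = log(s_g^2) - psi(d_g/2) + log(d_g/2)``, an unbiased
    estimator of log(sigma_g^2) under the scaled-inverse-chi-square model:
    solves ``psi'(d0/2) = var(e) - mean(psi'(d_g/2))`` for d0 and recovers
    s0_sq from the mean.  Returns ``(inf, exp(mean(e)))`` when the observed
    spread of log variances does not exceed the chi-square sampling noise.

    Non-positive sample variances carry no information about log-variance
    spread and are excluded from the fit.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d_arr = np.broadcast_to(np.asarray(d_g, dtype=float), s_sq.shape)
    ok = np.isfinite(s_sq) & (s_sq > 0) & (d_arr >= 1)
    n_ok = int(ok.sum())
    if n_ok < _MIN_FEATURES_FOR_PRIOR:
        raise ValueError(
            f"prior estimation needs >= {_MIN_FEATURES_FOR_PRIOR} features with "
            f"positive variance and d_g >= 1; got {n_ok}"
        )
    s_sq, d_arr = s_sq[ok], d_arr[ok]
    e = np.log(s_sq) - special.digamma(d_arr / 2.0) + np.log(d_arr / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    spread = e_var - float(np.mean(special.polygamma(1, d_arr / 2.0)))
    if spread <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(spread)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    dataset: ExpressionDataset,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModeratedStats:
    """Moderated two-group t-statistics for every feature of one dataset.

    By default the prior ``(d0, s0_sq)`` is estimated from the data;
    passing them explicitly overrides the fit (``d0=0`` recovers the
    ordinary pooled t-test, ``d0=inf`` the s0-based z statistic).
    """
    case = dataset.group_values("case")
    ctrl = dataset.group_values("control")
    n1, n2 = dataset.n_case, dataset.n_control
    d_g = float(n1 + n2 - 2)

    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = (case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1))
    s_sq = ss / d_g

    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_prior(s_sq, d_g)
        d0 = est_d0 if d0 is None else float(d0)
        s0_sq = est_s0 if s0_sq is None else float(s0_sq)
    d0, s0_sq = float(d0), float(s0_sq)
    if d0 < 0 or (d0 > 0 and not s0_sq > 0):
        raise ValueError(f"invalid prior d0={d0}, s0_sq={s0_sq}")

    if np.isinf(d0):
        s_tilde = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s_tilde = s_sq.copy()
        df_total = d_g
    else:
        s_tilde = (d0 * s0_sq + d_g * s_sq) / (d0 + d_g)
        df_total = d0 + d_g

    se = np.sqrt(s_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, effect / np.where(se > 0, se, 1.0), np.where(effect == 0, 0.0, np.inf * np.sign(effect)))
    if np.isinf(df_total):
        p_two = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_two = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    table = pd.DataFrame(
        {
            "effect": effect,
            "s_sq": s_sq,
            "s_tilde_sq": s_tilde,
            "t_mod": t_mod,
            "p_two": p_two,
        },
        index=dataset.values.index,
    )
    return ModeratedStats(
        table=table,
        d_g=d_g,
        d0=d0,
        s0_sq=s0_sq,
        n_case=n1,
        n_control=n2,
        tag=dataset.tag,
    )


def combine_datasets(
    stats_list: list[ModeratedStats],
    weights: list[float] | None = None,
) -> MetaDEResult:
    """Stouffer signed-z combination of per-dataset moderated-t evidence.

    Each dataset contributes ``z_i = sign(effect) * Phi^-1(1 - p/2)``;
    the meta z is the weight-normalized sum over the datasets in which a
    feature is observed (weights default to sqrt of each dataset's total
    sample size). Features observed nowhere are excluded with a logged
    count.
    """
    if not stats_list:
        raise ValueError("need at least one dataset to combine")
    if weights is None:
        weights = [float(np.sqrt(s.n_total)) for s in stats_list]
    if len(weights) != len(stats_list):
        raise ValueError("one weight per dataset required")

    all_features = pd.Index([])
    for s in stats_list:
        all_features = all_features.union(s.table.index)

    z_per = pd.DataFrame(np.nan, index=all_features, columns=range(len(stats_list)))
    for i, s in enumerate(stats_list):
        p = np.clip(s.table["p_two"].to_numpy(dtype=float), 1e-300, 1.0)
        z = np.sign(s.table["effect"].to_numpy(dtype=float)) * stats.norm.isf(p / 2.0)
        z_per.loc[s.table.index, i] = z

    observed = z_per.notna()
    n_obs = observed.sum(axis=1)
    dropped = int((n_obs == 0).sum())
    if dropped:
        logger.warning("excluding %d features observed in no dataset", dropped)
    keep = n_obs > 0
    z_per, observed, n_obs = z_per[keep], observed[keep], n_obs[keep]

    w = np.asarray(weights, dtype=float)
    w_mat = observed.to_numpy() * w[None, :]
    num = np.nansum(z_per.to_numpy() * w_mat, axis=1)
    denom = np.sqrt((w_mat**2).sum(axis=1))
    z_meta = num / denom
    p_two = 2.0 * stats.norm.sf(np.abs(z_meta))
    table = pd.DataFrame(
        {
            "z_meta": z_meta,
            "p_two": p_two,
            "fdr": bh_adjust(p_two),
            "direction": np.sign(z_meta).astype(int),
            "n_datasets_observed": n_obs.astype(int),
        },
        index=z_per.index,
    )
    return MetaDEResult(
        table=table,
        weights={s.tag: float(wi) for s, wi in zip(stats_list, weights)},
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Shared by the differential-expression and enrichment stages so both
    produce bit-identical adjustments on identical inputs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.isnan(p).any():
        bad = np.flatnonzero(np.isnan(p))
        raise ValueError(f"NaN p-values at positions {bad.tolist()[:10]}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def select_de(result: MetaDEResult, fdr_threshold: float) -> set[str]:
    """Feature ids significant at ``fdr < fdr_threshold`` (strict).

    Conventional thresholds: 0.01 for the gene meta-analysis, 0.05 for the
    single miRNA dataset.
    """
    if not (0.0 < fdr_threshold <= 1.0):
        raise ValueError(f"fdr threshold must be in (0, 1], got {fdr_threshold}")
    mask = result.table["fdr"] < fdr_threshold
    return set(result.table.index[mask])


def single_dataset_de(dataset: ExpressionDataset) -> MetaDEResult:
    """Moderated t plus BH for a lone dataset (no meta step needed)."""
    return combine_datasets([moderated_t(dataset)])
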