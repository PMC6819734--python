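"""Likelihood machinery for testing mutualistic and parasitic interactions.

Each taxon pair w contributes, per sample, a bivariate observation
(y_w^+, y_w^-): the sum and the (consistently oriented) difference of the
two log abundances. Pairs are grouped by their clade-pair annotation at a
chosen rank (e.g. all strain pairs belonging to one species pair), and the
likelihood is a product of bivariate normal densities with group-specific
mean vectors (mu_s^+, mu_s^-) and a covariance matrix
(sigma_+^2, sigma_-^2, rho) shared across groups. Only the means carry an s
index; the shared-covariance structure holds under both the null and the
alternative of every test here.

Three likelihood-ratio tests are provided:

* pair-group effect: H0 ties both components' group means to a common
  vector (df = 2(S-1)); rejecting H0 says clade pairs shape the
  interactions among their member taxa.
* component effect, "plus": H0 ties only the mutualism means (df = S-1),
  probing whether mutualism/parasitism structure exists at that rank.
* component effect, "minus": H0 ties only the difference means (df = S-1),
  probing group-specific reciprocal exploitation (reciprocal altruism).

The free and fully tied fits are closed form; the single-component-tied
null has no closed form and is fitted by alternating exact GLS mean updates
with ML covariance updates (monotone ascent, iterated to convergence).

Aggregate-network element tests (one-sample t against zero for signed
parasitism, against the grand element mean for mutualism) and Welch
two-sample tests between group aggregates (the winter/summer +/0/- codes)
live here too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interaction_scores import PairTable
from .network_builder import MUTUALISM, PARASITISM, InteractionNetwork
from .taxa_io import ValidationError

logger = logging.getLogger("microgame")

_LOG2PI = math.log(2.0 * math.pi)


class SingularCovarianceError(ValueError):
    """The fitted covariance matrix is singular (e.g. constant data)."""


@dataclass
class BivariateFit:
    """MLE of the grouped bivariate-normal interaction model."""

    group_means: pd.DataFrame  # index pair-group label; columns mu_plus, mu_minus
    sigma_plus_sq: float
    sigma_minus_sq: float
    rho: float
    loglik: float
    n_groups: int
    n_obs: int
    constraint: str = "free"  # free | tied | tie_plus | tie_minus

    @property
    def cov(self) -> np.ndarray:
        c = self.rho * math.sqrt(self.sigma_plus_sq * self.sigma_minus_sq)
        return np.array([[self.sigma_plus_sq, c], [c, self.sigma_minus_sq]])


@dataclass
class LRTResult:
    """Likelihood-ratio test result.

    ``statistic`` is 2(loglik_alt - loglik_null) with ``df`` constrained mean
    parameters. ``p_value`` uses the exact finite-sample null distribution:
    both nulls are general linear hypotheses on the mean matrix of a Gaussian
    linear model with unknown shared covariance, so Wilks'
    Lambda = exp(-statistic/n) follows an exact F transformation (Rao's, exact
    at 2 response dimensions; plain univariate F for the single-component
    tests). ``p_value_chisq`` is the asymptotic chi-square tail, which is
    visibly anticonservative at small n.
    """

    statistic: float
    df: int
    p_value: float
    null_fit: BivariateFit
    alt_fit: BivariateFit
    hypothesis: str
    p_value_chisq: float = float("nan")


def _check_cov(cov: np.ndarray) -> None:
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if not np.isfinite(det) or det <= 0 or cov[0, 0] <= 0 or cov[1, 1] <= 0:
        raise SingularCovarianceError(
            "singular pooled covariance (constant or collinear observations); "
            "consider a pseudocount or jitter on the abundances"
        )


def _loglik(y: np.ndarray, means: np.ndarray, cov: np.ndarray) -> float:
    """Exact Gaussian log likelihood; `means` is per-observation (n x 2)."""
    _check_cov(cov)
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det
    r = y - means
    quad = (
        inv[0, 0] * r[:, 0] ** 2
        + 2.0 * inv[0, 1] * r[:, 0] * r[:, 1]
        + inv[1, 1] * r[:, 1] ** 2
    )
    n = y.shape[0]
    return float(-n * _LOG2PI - 0.5 * n * math.log(det) - 0.5 * quad.sum())


def _ml_cov(resid: np.ndarray) -> np.ndarray:
    # maximum-likelihood denominator n, not n-1
    n = resid.shape[0]
    return resid.T @ resid / n


def _group_stats(y: np.ndarray, codes: np.ndarray, n_groups: int):
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if (counts == 0).any():
        raise ValidationError("empty pair-group encountered")
    sums = np.zeros((n_groups, 2))
    np.add.at(sums, codes, y)
    return counts, sums / counts[:, None]


def fit_bivariate_values(
    y: np.ndarray, codes: np.ndarray, n_groups: int, constraint: str = "free",
    group_labels=None, tol: float = 1e-10, max_iter: int = 500,
) -> BivariateFit:
    """Array-level MLE. `y` is n x 2 (plus, minus); `codes` in [0, n_groups)."""
    y = np.asarray(y, dtype=float)
    codes = np.asarray(codes)
    n = y.shape[0]
    if n < n_groups + 3:
        raise ValidationError(
            f"need at least n_groups + 3 observations ({n_groups + 3}), have {n}"
        )
    counts, means = _group_stats(y, codes, n_groups)
    grand = y.mean(axis=0)
    if constraint == "tied":
        mu = np.tile(grand, (n_groups, 1))
        cov = _ml_cov(y - grand)
    elif constraint == "free":
        mu = means
        cov = _ml_cov(y - means[codes])
    elif constraint in ("tie_plus", "tie_minus"):
        # tied component t, free component f; exact GLS mean update given the
        # covariance: tied mean = grand mean of component t; free means are
        # the group means of f shifted by -(cov_tf/cov_tt)*(group - grand)
        # deviation of t. Alternate with the ML covariance until converged.
        t = 0 if constraint == "tie_plus" else 1
        f = 1 - t
        cov = _ml_cov(y - means[codes])
        _check_cov(cov)
        mu = means.copy()
        prev = -np.inf
        for _ in range(max_iter):
            b = grand[t]
            adj = (cov[t, f] / cov[t, t]) * (means[:, t] - b)
            mu = means.copy()
            mu[:, t] = b
            mu[:, f] = means[:, f] - adj
            cov = _ml_cov(y - mu[codes])
            ll = _loglik(y, mu[codes], cov)
            if abs(ll - prev) < tol * (1.0 + abs(ll)):
                break
            prev = ll
    else:
        raise ValidationError(f"unknown constraint {constraint!r}")
    ll = _loglik(y, mu[codes], cov)
    if group_labels is None:
        group_labels = list(range(n_groups))
    gm = pd.DataFrame(mu, index=pd.Index(group_labels, name="pair_group"),
                      columns=["mu_plus", "mu_minus"])
    rho = float(cov[0, 1] / math.sqrt(cov[0, 0] * cov[1, 1]))
    return BivariateFit(
        group_means=gm,
        sigma_plus_sq=float(cov[0, 0]),
        sigma_minus_sq=float(cov[1, 1]),
        rho=rho,
        loglik=ll,
        n_groups=n_groups,
        n_obs=n,
        constraint=constraint,
    )


def _observations(pair_table: PairTable, grouping_rank: str):
    """Flatten a pair table into (y, codes, labels) across pairs x samples.

    Signed differences are oriented to the sorted clade pair so that all
    members of a pair-group share one orientation; within-clade groups keep
    the stored lexicographic taxon order.
    """
    labels = pair_table.group_labels(grouping_rank)
    plus = pair_table.y_plus.to_numpy().ravel()
    minus = pair_table.oriented_minus(grouping_rank).to_numpy().ravel()
    n_samples = len(pair_table.samples)
    codes_pair, uniques = pd.factorize(labels, sort=True)
    codes = np.repeat(codes_pair, n_samples)
    y = np.column_stack([plus, minus])
    return y, codes, list(uniques)


def fit_bivariate_mle(
    pair_table: PairTable, grouping_rank: str, tie_means: bool = False
) -> BivariateFit:
    """Fit the grouped bivariate model on a pair table.

    With ``tie_means=False``: per-group mean vectors with the pooled
    (maximum-likelihood) within-group covariance. With ``tie_means=True``:
    one global mean vector and the total ML covariance.
    """
    y, codes, labels = _observations(pair_table, grouping_rank)
    return fit_bivariate_values(
        y, codes, len(labels), "tied" if tie_means else "free", group_labels=labels
    )


def _exact_p(stat: float, n: int, n_groups: int, bivariate: bool) -> float:
    """Exact null p via Wilks' Lambda = exp(-stat/n).

    q = S-1 hypothesis df, v = n - S error df. For the 2-dimensional
    (pair-group) hypothesis Rao's F = ((1-sqrt(L))/sqrt(L)) * (v-1)/q on
    (2q, 2(v-1)) df is exact; the single-component hypothesis reduces to a
    univariate ANOVA with F = ((1-L)/L) * v/q on (q, v) df.
    """
    lam = math.exp(-stat / n)
    q = n_groups - 1
    v = n - n_groups
    if bivariate:
        if v <= 1:
            return float("nan")
        root = math.sqrt(lam)
        f = (1.0 - root) / root * (v - 1) / q
        return float(stats.f.sf(f, 2 * q, 2 * (v - 1)))
    if v < 1:
        return float("nan")
    f = (1.0 - lam) / lam * v / q
    return float(stats.f.sf(f, q, v))


def _lrt(null: BivariateFit, alt: BivariateFit, df: int, hypothesis: str) -> LRTResult:
    stat = 2.0 * (alt.loglik - null.loglik)
    if stat < -1e-8:
        raise AssertionError(f"negative LRT statistic {stat}: fits not nested?")
    stat = max(stat, 0.0)
    return LRTResult(
        statistic=stat,
        df=df,
        p_value=_exact_p(stat, alt.n_obs, alt.n_groups, hypothesis == "pair_group_effect"),
        null_fit=null,
        alt_fit=alt,
        hypothesis=hypothesis,
        p_value_chisq=float(stats.chi2.sf(stat, df)),
    )


def lrt_from_values(y, codes, n_groups, hypothesis: str, group_labels=None) -> LRTResult:
    """Array-level LRT; hypothesis in {pair_group_effect, mutualism_exists,
    parasitism_exists} mapping to the tied / tie_plus / tie_minus nulls."""
    if n_groups < 2:
        raise ValidationError("need >= 2 pair-groups for a likelihood-ratio test")
    alt = fit_bivariate_values(y, codes, n_groups, "free", group_labels)
    if hypothesis == "pair_group_effect":
        null = fit_bivariate_values(y, codes, n_groups, "tied", group_labels)
        df = 2 * (n_groups - 1)
    elif hypothesis == "mutualism_exists":
        null = fit_bivariate_values(y, codes, n_groups, "tie_plus", group_labels)
        df = n_groups - 1
    elif hypothesis == "parasitism_exists":
        null = fit_bivariate_values(y, codes, n_groups, "tie_minus", group_labels)
        df = n_groups - 1
    else:
        raise ValidationError(f"unknown hypothesis {hypothesis!r}")
    return _lrt(null, alt, df, hypothesis)


def lrt_pair_group_effect(pair_table: PairTable, grouping_rank: str) -> LRTResult:
    """Do clade pairs at `grouping_rank` determine the interactions?

    H0 ties every pair-group's mean vector to a common (mu+, mu-);
    df = 2(S-1) for S pair-groups.
    """
    y, codes, labels = _observations(pair_table, grouping_rank)
    return lrt_from_values(y, codes, len(labels), "pair_group_effect", labels)


def lrt_component_effect(
    pair_table: PairTable, grouping_rank: str, component: str
) -> LRTResult:
    """Tie only one component's group means (df = S-1).

    ``component="plus"`` ties the mutualism means (existence of
    mutualism/parasitism structure at this rank); ``component="minus"`` ties
    the difference means (existence of reciprocal altruism/exploitation).
    The other component's means stay free.
    """
    if component not in ("plus", "minus"):
        raise ValidationError(f"component must be plus|minus, got {component!r}")
    y, codes, labels = _observations(pair_table, grouping_rank)
    hypothesis = "mutualism_exists" if component == "plus" else "parasitism_exists"
    return lrt_from_values(y, codes, len(labels), hypothesis, labels)


# ---------------------------------------------------------------------------
# aggregate-network element tests


def _element_rows(network: InteractionNetwork):
    for k in sorted(network.nodes, key=str):
        yield "node", k, str(k), "", network.nodes[k], network.node_var.get(k), network.node_n.get(k)
    for k in sorted(network.edges, key=str):
        yield "edge", k, str(k[0]), str(k[1]), network.edges[k], network.edge_var.get(k), network.edge_n.get(k)


def element_significance(aggregate: InteractionNetwork, fdr: bool = True) -> pd.DataFrame:
    """Per-element one-sample t tests of an aggregate network.

    Signed parasitism weights are tested against 0 (their natural null).
    Mutualism log-products have no natural zero (they shift with overall
    abundance scale), so each element is tested against the grand mean of
    all element weights in the network: "significant" reads as stronger or
    weaker than typical for this network. Elements observed in < 2 hosts are
    flagged untestable; zero-variance elements are flagged degenerate with
    the p-value reported below the machine floor.
    """
    rows = list(_element_rows(aggregate))
    if not rows:
        raise ValidationError("aggregate network has no weighted elements")
    if aggregate.interaction == PARASITISM:
        reference = 0.0
    else:
        reference = float(np.mean([r[4] for r in rows]))
    out = []
    for etype, _key, c1, c2, mean, var, n in rows:
        rec = {
            "element_type": etype, "clade_1": c1, "clade_2": c2,
            "mean": mean, "variance": var, "n": n, "reference": reference,
            "t": float("nan"), "df": float("nan"), "p": float("nan"),
            "degenerate": False, "testable": True,
        }
        if n is None or n < 2 or var is None or math.isnan(var):
            rec["testable"] = False
        elif var == 0.0:
            rec["degenerate"] = True
            if mean == reference:
                rec["t"], rec["p"] = 0.0, 1.0
            else:
                rec["t"] = math.inf if mean > reference else -math.inf
                rec["p"] = 0.0  # below machine floor
            rec["df"] = n - 1
        else:
            t = (mean - reference) / math.sqrt(var / n)
            rec["t"] = t
            rec["df"] = n - 1
            rec["p"] = float(2.0 * stats.t.sf(abs(t), n - 1))
        out.append(rec)
    df = pd.DataFrame(out)
    df["q"] = float("nan")
    if fdr:
        mask = df["p"].notna()
        if mask.any():
            df.loc[mask, "q"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def group_difference_test(
    aggregate_1: InteractionNetwork,
    aggregate_2: InteractionNetwork,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t test per shared element between two aggregates.

    The sign column codes the change from group 1 to group 2: "increase" /
    "decrease" when p <= alpha with the corresponding mean ordering, else
    "none" (the 0 code). Elements missing from one side are skipped and
    logged.
    """
    if (
        aggregate_1.rank != aggregate_2.rank
        or aggregate_1.interaction != aggregate_2.interaction
    ):
        raise ValidationError("aggregates must share rank and interaction type")
    e1 = {(t, k): (m, v, n) for t, k, _, _, m, v, n in _element_rows(aggregate_1)}
    e2 = {(t, k): (m, v, n) for t, k, _, _, m, v, n in _element_rows(aggregate_2)}
    skipped = set(e1) ^ set(e2)
    for key in sorted(skipped, key=str):
        logger.info("element %r missing from one group; skipped", key)
    rows = []
    for etype, key in sorted(set(e1) & set(e2), key=str):
        m1, v1, n1 = e1[(etype, key)]
        m2, v2, n2 = e2[(etype, key)]
        rec = {
            "element_type": etype,
            "clade_1": str(key[0]) if etype == "edge" else str(key),
            "clade_2": str(key[1]) if etype == "edge" else "",
            "mean_1": m1, "mean_2": m2,
            "se_1": float("nan"), "se_2": float("nan"),
            "statistic": float("nan"), "df": float("nan"), "p": float("nan"),
            "sign": "none",
        }
        usable = all(
            v is not None and not math.isnan(v) and n is not None and n >= 2
            for v, n in ((v1, n1), (v2, n2))
        )
        if usable and (v1 > 0 or v2 > 0):
            se1, se2 = math.sqrt(v1 / n1), math.sqrt(v2 / n2)
            denom = math.sqrt(v1 / n1 + v2 / n2)
            t = (m2 - m1) / denom
            df_w = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
            p = float(2.0 * stats.t.sf(abs(t), df_w))
            rec.update(se_1=se1, se_2=se2, statistic=t, df=df_w, p=p)
            if p <= alpha:
                rec["sign"] = "increase" if m2 > m1 else "decrease"
        elif usable:
            # both variances zero: any difference is a degenerate sure change
            if m1 != m2:
                rec["sign"] = "increase" if m2 > m1 else "decrease"
                rec["p"] = 0.0
            else:
                rec["p"] = 1.0
        rows.append(rec)
    return pd.DataFrame(rows)
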