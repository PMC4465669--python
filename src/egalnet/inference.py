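"""Statistical analyses of giving behavior.

Hurdle (two-part) regression of giving decisions with cluster-robust
standard errors, Beta maximum likelihood on recipient poverty
positions, the exact Wilcoxon signed-rank comparison of initial versus
end-round Gini coefficients, reverse-redistribution statistics, and the
giving time-course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.discrete.truncated_model import TruncatedLFPoisson

from .metrics import gini
from .simulate import TrialLog

DEFAULT_COVARIATES = ("X", "R", "L", "K")


# -- hurdle regression ----------------------------------------------------


@dataclass
class HurdlePart:
    """One part of a two-part fit: point estimates, cluster-robust SEs
    and p-values indexed by term name, plus the observation count."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    nobs: int


@dataclass
class HurdleFit:
    """Two-part giving model.

    ``prob`` is a binary logistic model of the give indicator; ``amount``
    a zero-truncated Poisson (log link) of the positive token amounts,
    fitted only on giver-rounds. Both use a cluster-robust sandwich
    covariance grouped by subject. Zero-variance covariates (e.g. degree
    in a regular lattice) are dropped and listed in ``dropped``.
    """

    prob: HurdlePart
    amount: HurdlePart
    n_records: int
    n_clusters: int
    dropped: tuple[str, ...] = ()


def _cluster_groups(records: pd.DataFrame, cluster_on: str) -> np.ndarray:
    if cluster_on == "subject" and "session" in records.columns:
        keys = records["session"].astype(str) + ":" + records["subject"].astype(str)
    else:
        keys = records[cluster_on].astype(str)
    return pd.factorize(keys)[0]


def _part(model, groups) -> HurdlePart:
    kw = dict(disp=0, maxiter=200, cov_type="cluster", cov_kwds={"groups": groups})
    if isinstance(model, TruncatedLFPoisson):
        # warm start from an untruncated Poisson; retry with BFGS if Newton stalls
        kw["start_params"] = sm.GLM(
            model.endog, model.exog, family=sm.families.Poisson()
        ).fit().params
    res = model.fit(**kw)
    if not res.mle_retvals.get("converged", True):
        res = model.fit(**{**kw, "method": "bfgs", "maxiter": 1000})
    return HurdlePart(
        params=pd.Series(res.params, index=model.exog_names),
        bse=pd.Series(res.bse, index=model.exog_names),
        pvalues=pd.Series(res.pvalues, index=model.exog_names),
        nobs=int(res.nobs),
    )


def fit_hurdle(
    records: pd.DataFrame,
    cluster_on: str = "subject",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> HurdleFit:
    """Fit the two-part giving model with subject-clustered errors.

    Part 1 regresses the binary give indicator on the covariates by
    logistic regression; part 2 regresses the positive amounts on the
    same covariates by zero-truncated Poisson. Requires both outcome
    classes, at least one positive amount, and at least two clusters.
    """
    groups = _cluster_groups(records, cluster_on)
    n_clusters = int(groups.max()) + 1
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters for clustered errors")
    y = records["gave"].to_numpy()
    if y.min() == y.max():
        raise ValueError("give indicator must contain both classes")
    keep = [c for c in covariates if records[c].nunique() > 1]
    dropped = tuple(c for c in covariates if c not in keep)
    exog = sm.add_constant(records[list(keep)].astype(float), has_constant="add")
    prob = _part(sm.Logit(y, exog), groups)
    pos = records["amount"].to_numpy() > 0
    if not pos.any():
        raise ValueError("no positive amounts: part 2 unfittable")
    amount = _part(
        TruncatedLFPoisson(
            records.loc[pos, "amount"].to_numpy(), exog.loc[pos], truncation=0
        ),
        groups[pos],
    )
    return HurdleFit(
        prob=prob,
        amount=amount,
        n_records=len(records),
        n_clusters=n_clusters,
        dropped=dropped,
    )


# -- Beta allocation fit --------------------------------------------------


@dataclass
class BetaFit:
    """Maximum-likelihood Beta shape estimates on (0, 1) positions."""

    beta1: float
    beta2: float
    loglik: float
    n: int


def fit_beta(positions) -> BetaFit:
    """MLE of Beta(beta1, beta2) on values strictly inside (0, 1)."""
    x = np.asarray(positions, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 positions")
    if (x <= 0).any() or (x >= 1).any():
        raise ValueError("positions must lie strictly inside (0, 1)")
    a, b, _, _ = scipy.stats.beta.fit(x, floc=0, fscale=1)
    ll = float(scipy.stats.beta.logpdf(x, a, b).sum())
    return BetaFit(beta1=float(a), beta2=float(b), loglik=ll, n=int(x.size))


def recipient_positions(logs: list[TrialLog]) -> np.ndarray:
    """Recipient poverty positions in (0, 1), one per giving event.

    For each event the recipient's income rank among the giver's
    neighbors at round start (poorest to richest, average ranks under
    ties, m neighbors) is mapped to the bin midpoint (rank - 1/2)/m, so
    positions stay strictly inside the open unit interval.
    """
    out: list[float] = []
    for log in logs:
        adj = log.topology.adjacency()
        for e in log.events:
            x = log.incomes_by_round[e.t - 1]
            nbrs = adj[e.giver]
            ranks = rankdata(x[nbrs])
            rank = float(ranks[np.flatnonzero(nbrs == e.recipient)[0]])
            out.append((rank - 0.5) / nbrs.size)
    return np.asarray(out)


# -- Wilcoxon signed-rank -------------------------------------------------


@dataclass
class WilcoxonResult:
    """W = sum of ranks of positive differences (after - before)."""

    W: float
    p: float
    n: int
    sidedness: str


def _exact_tail_probs(two_ranks: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) under the exact sign-flip null.

    Subset-sum dynamic program over doubled midranks (integers even
    under ties), equivalent to enumerating all 2^n sign assignments.
    """
    total = int(two_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in two_ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(two_ranks)
    return float(dist[: w2 + 1].sum()), float(dist[w2:].sum())


def wilcoxon_signed_rank(before, after, sidedness: str = "less") -> WilcoxonResult:
    """Paired signed-rank test of ``after`` against ``before``.

    Zero differences are dropped before ranking. For n <= 25 the p-value
    is exact (full sign-flip null, valid under tied ranks); larger n
    uses the normal approximation with tie correction and continuity
    correction. ``sidedness``: 'less' (after < before), 'greater', or
    'two-sided'.
    """
    if sidedness not in ("less", "greater", "two-sided"):
        raise ValueError("sidedness must be less, greater or two-sided")
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be equal-length vectors")
    d = after - before
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    if n <= 25:
        two_ranks = np.rint(2 * ranks).astype(int)
        p_less, p_greater = _exact_tail_probs(two_ranks, int(round(2 * W)))
    else:
        mu = n * (n + 1) / 4.0
        tie_sizes = np.unique(np.abs(d), return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_sizes**3 - tie_sizes).sum()) / 48.0
        sd = np.sqrt(var)
        p_less = float(scipy.stats.norm.cdf((W - mu + 0.5) / sd))
        p_greater = float(scipy.stats.norm.sf((W - mu - 0.5) / sd))
    if sidedness == "less":
        p = p_less
    elif sidedness == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return WilcoxonResult(W=W, p=float(p), n=n, sidedness=sidedness)


# -- session-level inequality ---------------------------------------------


def end_round_gini_table(logs: list[TrialLog]) -> pd.DataFrame:
    """One row per (session, treatment): initial and end-round Gini."""
    if not logs:
        raise ValueError("no trial logs")
    rows = [
        {
            "session": log.session,
            "treatment": log.label,
            "gini_initial": log.initial_gini(),
            "gini_end": log.end_gini(),
            "rounds": log.rounds,
            "stop_reason": log.stop_reason,
        }
        for log in logs
    ]
    return pd.DataFrame(rows).sort_values(["treatment", "session"]).reset_index(drop=True)


def wilcoxon_by_treatment(
    logs: list[TrialLog], sidedness: str = "less"
) -> pd.DataFrame:
    """Session-level signed-rank test (end vs initial Gini) per treatment."""
    table = end_round_gini_table(logs)
    rows = []
    for label, sub in table.groupby("treatment", sort=True):
        try:
            res = wilcoxon_signed_rank(sub["gini_initial"], sub["gini_end"], sidedness)
            rows.append(
                {"treatment": label, "W": res.W, "p": res.p, "n_sessions": res.n}
            )
        except ValueError:
            rows.append(
                {"treatment": label, "W": np.nan, "p": np.nan, "n_sessions": len(sub)}
            )
    return pd.DataFrame(rows)


# -- reverse redistribution ----------------------------------------------


def reverse_redistribution_stats(
    logs: list[TrialLog], records: pd.DataFrame
) -> tuple[float, HurdleFit | None]:
    """Share of reverse giving events and the reciprocity hurdle fit.

    An event is *reverse* when the recipient's round-start income is at
    least the giver's. The reciprocity model regresses the per-record
    reverse-donation indicator / amount on the tokens received in the
    previous round (subject-clustered); None when unfittable (e.g. no
    reverse events).
    """
    if not logs:
        raise ValueError("no trial logs")
    n_events = 0
    n_reverse = 0
    rev_amount: dict[tuple, int] = {}
    for log in logs:
        for e in log.events:
            x = log.incomes_by_round[e.t - 1]
            n_events += 1
            if x[e.recipient] >= x[e.giver]:
                n_reverse += 1
                key = (log.session, log.label, e.t, e.giver)
                rev_amount[key] = rev_amount.get(key, 0) + e.amount
    share = n_reverse / n_events if n_events else 0.0
    rec = records.copy()
    keys = list(
        zip(
            rec["session"] if "session" in rec else [None] * len(rec),
            rec["treatment"],
            rec["round"],
            rec["subject"],
        )
    )
    rec["amount"] = [rev_amount.get(k, 0) for k in keys]
    rec["gave"] = (rec["amount"] > 0).astype(int)
    fit: HurdleFit | None = None
    if rec["gave"].nunique() == 2:
        try:
            fit = fit_hurdle(rec, cluster_on="subject", covariates=("received_prev",))
        except Exception:
            fit = None
    return share, fit


# -- time-course ----------------------------------------------------------


def giving_timecourse(records: pd.DataFrame) -> pd.DataFrame:
    """Per-round donor proportion and mean fraction of income given."""
    if records.empty:
        raise ValueError("no records")
    rec = records.copy()
    rec["frac"] = np.where(rec["X"] > 0, rec["amount"] / rec["X"].clip(lower=1), 0.0)
    out = (
        rec.groupby("round")
        .agg(prop_donating=("gave", "mean"), mean_fraction_given=("frac", "mean"))
        .reset_index()
    )
    return out
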