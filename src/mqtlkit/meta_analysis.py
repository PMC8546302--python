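"""Meta-QTL consolidation: Gaussian mixture with known per-QTL variances.

Projected QTL peaks on one chromosome are modelled as draws from a mixture
of K consensus loci,

    y_i ~ sum_k pi_k N(mu_k, s_i^2),

where each observation's variance s_i^2 is fixed, derived from its
projected 95% confidence interval (s = CI width / 3.92).  Free parameters
are the K means and K-1 weights (p = 2K - 1).  The number of loci is chosen
by majority vote among AIC, AICc, AIC3, BIC and AWE, and each hard cluster
is summarised by its inverse-variance-weighted consensus position with a
pooled 95% CI of width 3.92 / sqrt(sum 1/s_i^2).

This follows the classical meta-QTL statistical model of the
Goffinet-Gerber / Veyrieras lineage.

The module is organised around :class:`QtlMixtureModel` (built from the
observations) whose :meth:`~QtlMixtureModel.fit` returns a
:class:`QtlMixtureResults` carrying estimates, information criteria and a
``summary()`` table.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import InvalidInputError
from .map_projection import GeneticMap, ProjectedQtl, ProjectionStatus

__all__ = [
    "CI_TO_SD_FACTOR",
    "SD_FLOOR_CM",
    "ci_to_sd",
    "QtlObservation",
    "observations_from_projected",
    "QtlMixtureModel",
    "QtlMixtureResults",
    "ModelSelectionResult",
    "select_model",
    "MetaQtl",
    "summarize_mqtl",
    "run_meta_analysis",
    "mqtl_table",
]

#: 95% two-sided normal quantile span (2 x 1.96)
CI_TO_SD_FACTOR = 3.92
#: lower bound on the positional SD (cM) to keep zero-width published CIs
#: from producing singular likelihoods
SD_FLOOR_CM = 0.05

CRITERIA = ("AIC", "AICc", "AIC3", "BIC", "AWE")

_EM_TOL = 1e-11
_EM_MAX_ITER = 1000
_N_RESTARTS = 5
#: below this sample size, EM additionally starts from every contiguous
#: partition of the ordered observations, which in one dimension makes the
#: search effectively exhaustive
_SMALL_N_EXHAUSTIVE = 12
#: at or below this sample size the multistart is fully exhaustive: every
#: set partition into K blocks seeds one EM run, so the best fit is the
#: global optimum of the mixture likelihood
_TINY_N_ALL_PARTITIONS = 8


def _k_block_partitions(n: int, k: int):
    """Restricted-growth enumeration of set partitions of ``range(n)``
    into exactly ``k`` non-empty blocks, as label lists."""
    labels = [0] * n

    def rec(i: int, used: int):
        if n - i < k - used:
            return
        if i == n:
            if used == k:
                yield list(labels)
            return
        for lab in range(min(used + 1, k)):
            labels[i] = lab
            yield from rec(i + 1, max(used, lab + 1))

    yield from rec(0, 0)


def ci_to_sd(ci_lo: float, ci_hi: float) -> float:
    """Positional SD from a 95% CI: ``max((hi - lo) / 3.92, 0.05)`` cM."""
    if ci_hi < ci_lo:
        raise InvalidInputError(f"inverted interval [{ci_lo}, {ci_hi}]")
    return max((ci_hi - ci_lo) / CI_TO_SD_FACTOR, SD_FLOOR_CM)


@dataclass(frozen=True)
class QtlObservation:
    """One projected QTL as a (position, SD) pair for the mixture."""

    y: float
    s: float
    qtl_id: str = ""
    trait: str = ""
    source: ProjectedQtl | None = None

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise InvalidInputError(f"observation {self.qtl_id!r}: s must be > 0")

    @property
    def weight_inverse_variance(self) -> float:
        return 1.0 / (self.s * self.s)


def observations_from_projected(
    projected: Iterable[ProjectedQtl],
) -> dict[str, list[QtlObservation]]:
    """Group successfully projected QTLs by chromosome as observations."""
    by_chrom: dict[str, list[QtlObservation]] = {}
    for p in projected:
        if p.status != ProjectionStatus.PROJECTED:
            continue
        obs = QtlObservation(
            y=float(p.consensus_peak),
            s=ci_to_sd(float(p.consensus_ci_lo), float(p.consensus_ci_hi)),
            qtl_id=p.source.qtl_id,
            trait=p.source.trait,
            source=p,
        )
        by_chrom.setdefault(p.source.chromosome, []).append(obs)
    return by_chrom


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------


class QtlMixtureModel:
    """One-dimensional Gaussian mixture with fixed per-observation variances.

    Parameters
    ----------
    y : array-like
        Projected peak positions (cM).
    s : array-like
        Known positional SDs (cM), same length as ``y``; all > 0.
    """

    def __init__(self, y, s) -> None:
        self.y = np.asarray(y, dtype=float)
        self.s = np.asarray(s, dtype=float)
        if self.y.ndim != 1 or self.y.shape != self.s.shape:
            raise InvalidInputError("y and s must be one-dimensional and aligned")
        if self.y.size == 0:
            raise InvalidInputError("empty observation set")
        if np.any(self.s <= 0):
            raise InvalidInputError("all SDs must be > 0")
        self.nobs = int(self.y.size)
        self._order = np.argsort(self.y, kind="stable")

    @classmethod
    def from_observations(cls, obs: Sequence[QtlObservation]) -> "QtlMixtureModel":
        return cls([o.y for o in obs], [o.s for o in obs])

    # ---- likelihood machinery -------------------------------------------

    def _log_component_density(self, means: np.ndarray) -> np.ndarray:
        """(n, K) matrix of log N(y_i; mu_k, s_i^2)."""
        z = (self.y[:, None] - means[None, :]) / self.s[:, None]
        return -0.5 * z * z - np.log(self.s[:, None]) - 0.5 * np.log(2.0 * np.pi)

    def loglike(self, means: np.ndarray, weights: np.ndarray) -> float:
        logdens = self._log_component_density(np.asarray(means, float))
        return float(np.sum(logsumexp(logdens + np.log(weights)[None, :], axis=1)))

    def _em(self, means0: np.ndarray, weights0: np.ndarray):
        """Run EM to convergence from one start; returns (ll, means, weights,
        responsibilities, converged)."""
        means = means0.copy()
        weights = weights0.copy()
        inv_var = 1.0 / (self.s * self.s)
        ll_prev = -np.inf
        converged = False
        resp = np.full((self.nobs, means.size), 1.0 / means.size)
        for _ in range(_EM_MAX_ITER):
            logdens = self._log_component_density(means)
            logw = np.log(np.clip(weights, 1e-300, None))
            joint = logdens + logw[None, :]
            norm = logsumexp(joint, axis=1)
            ll = float(np.sum(norm))
            resp = np.exp(joint - norm[:, None])
            if abs(ll - ll_prev) <= _EM_TOL * max(1.0, abs(ll)):
                ll_prev = ll
                converged = True
                break
            ll_prev = ll
            # M-step: inverse-variance-weighted means, mean responsibilities
            wr = resp * inv_var[:, None]
            denom = wr.sum(axis=0)
            numer = (wr * self.y[:, None]).sum(axis=0)
            keep = denom > 0
            means[keep] = numer[keep] / denom[keep]
            weights = resp.mean(axis=0)
        return ll_prev, means, weights, resp, converged

    def _starts(self, k: int, seed: int | None) -> list[tuple[np.ndarray, np.ndarray]]:
        """Deterministic (means, weights) starts: position quantiles, seeded
        jitter restarts, and (for small n) every contiguous partition of the
        ordered observations with block-proportional weights."""
        ys = self.y[self._order]
        uniform = np.full(k, 1.0 / k)
        base = np.quantile(self.y, [(j + 1) / (k + 1) for j in range(k)])
        starts = [(base, uniform)]
        rng = np.random.default_rng(0 if seed is None else seed)
        scale = max(np.std(self.y), 1.0)
        for _ in range(_N_RESTARTS - 1):
            starts.append((base + rng.normal(0.0, 0.1 * scale, size=k), uniform))
        if self.nobs <= _TINY_N_ALL_PARTITIONS:
            inv_var = 1.0 / (self.s * self.s)
            for labels in _k_block_partitions(self.nobs, k):
                lab_arr = np.asarray(labels)
                means = np.empty(k)
                sizes = np.empty(k)
                for j in range(k):
                    idx = lab_arr == j
                    means[j] = np.average(self.y[idx], weights=inv_var[idx])
                    sizes[j] = idx.sum() / self.nobs
                starts.append((means, sizes))
        elif self.nobs <= _SMALL_N_EXHAUSTIVE:
            inv_var = 1.0 / (self.s[self._order] ** 2)
            for cuts in itertools.combinations(range(1, self.nobs), k - 1):
                bounds = (0, *cuts, self.nobs)
                means = np.array(
                    [
                        np.average(
                            ys[bounds[j]:bounds[j + 1]],
                            weights=inv_var[bounds[j]:bounds[j + 1]],
                        )
                        for j in range(k)
                    ]
                )
                sizes = np.diff(bounds) / self.nobs
                starts.append((means, sizes.astype(float)))
        return starts

    def _em_batch(self, mu: np.ndarray, pi: np.ndarray, iters: int = 400) -> np.ndarray:
        """Vectorized EM over many starts at once; returns final loglik per
        start.  ``mu``/``pi`` have shape (P, k) and are updated in place."""
        y = self.y
        var = self.s * self.s
        norm = np.sqrt(2 * np.pi * var)
        ll = np.full(mu.shape[0], -np.inf)
        for _ in range(iters):
            diff = y[None, :, None] - mu[:, None, :]
            dens = (
                pi[:, None, :]
                * np.exp(-0.5 * diff * diff / var[None, :, None])
                / norm[None, :, None]
            )
            # far-off starts can underflow to zero density; clamp so they
            # simply score very low instead of polluting the batch with NaNs
            tot = np.clip(dens.sum(axis=2), 1e-300, None)
            new_ll = np.log(tot).sum(axis=1)
            done = np.abs(new_ll - ll) <= _EM_TOL * np.maximum(1.0, np.abs(new_ll))
            ll = new_ll
            if done.all():
                break
            resp = dens / tot[:, :, None]
            w = resp / var[None, :, None]
            denom = w.sum(axis=1)
            numer = (w * y[None, :, None]).sum(axis=1)
            good = denom > 0
            mu = np.where(good, np.divide(numer, denom, where=good, out=mu.copy()), mu)
            pi = resp.mean(axis=1)
        self._batch_mu, self._batch_pi = mu, pi
        return ll

    def fit(self, k: int, seed: int | None = None) -> "QtlMixtureResults":
        """Fit the K-component mixture by multi-start EM.

        Deterministic given ``seed``.  Raises on ``k`` outside ``[1, n]``; a
        start that fails to converge contributes its best iterate.
        """
        if not (1 <= k <= self.nobs):
            raise InvalidInputError(
                f"K must lie in [1, {self.nobs}], got {k}"
            )
        starts = self._starts(k, seed)
        if len(starts) > 16:
            # exhaustive multistart: run all starts as one vectorized batch,
            # then polish the winner with the scalar path
            mu0 = np.array([np.sort(m) for m, _ in starts])
            pi0 = np.array(
                [w[np.argsort(m, kind="stable")] for m, w in starts]
            )
            lls = self._em_batch(mu0, pi0)
            j = int(np.argmax(lls))
            starts = [(self._batch_mu[j], self._batch_pi[j])]
        best = None
        for means0, weights0 in starts:
            start_order = np.argsort(means0, kind="stable")
            ll, means, weights, resp, conv = self._em(
                means0[start_order], weights0[start_order]
            )
            if best is None or ll > best[0] + 1e-12:
                best = (ll, means, weights, resp, conv)
        ll, means, weights, resp, conv = best
        # canonical component order: ascending mean
        order = np.argsort(means, kind="stable")
        return QtlMixtureResults(
            model=self,
            k=k,
            loglike=ll,
            means=means[order],
            weights=weights[order],
            responsibilities=resp[:, order],
            converged=bool(conv),
        )


@dataclass(frozen=True)
class QtlMixtureResults:
    """Fitted mixture: estimates, criteria and cluster assignments."""

    model: QtlMixtureModel
    k: int
    loglike: float
    means: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    converged: bool

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_params(self) -> int:
        """K free means plus K-1 free weights."""
        return 2 * self.k - 1

    @property
    def assignments(self) -> np.ndarray:
        """Hard cluster labels (argmax posterior per observation)."""
        return np.argmax(self.responsibilities, axis=1)

    # ---- information criteria -------------------------------------------

    @property
    def aic(self) -> float:
        return -2.0 * self.loglike + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        """Small-sample corrected AIC; NaN when n <= p + 1."""
        p = self.n_params
        if self.nobs <= p + 1:
            return float("nan")
        return self.aic + 2.0 * p * (p + 1) / (self.nobs - p - 1)

    @property
    def aic3(self) -> float:
        return -2.0 * self.loglike + 3.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglike + self.n_params * np.log(self.nobs)

    @property
    def awe(self) -> float:
        """Average weight of evidence: ``-2 lnL + 2p (ln n + 1.5)``."""
        return -2.0 * self.loglike + 2.0 * self.n_params * (np.log(self.nobs) + 1.5)

    def criteria(self) -> dict[str, float]:
        return {
            "AIC": self.aic,
            "AICc": self.aicc,
            "AIC3": self.aic3,
            "BIC": self.bic,
            "AWE": self.awe,
        }

    def classification_loglike(self) -> float:
        """Hard-assignment log-likelihood of the fitted clustering.

        The hard partition is re-scored with its own partition-ML
        parameters (inverse-variance cluster means, proportional weights),
        which makes the value directly comparable with exhaustive
        enumeration over set partitions.
        """
        return _partition_loglike(
            self.model.y, self.model.s, self.assignments
        )

    def summary(self) -> pd.DataFrame:
        """Per-component table: mean, weight, cluster size."""
        labels = self.assignments
        return pd.DataFrame(
            {
                "component": np.arange(1, self.k + 1),
                "mean_cM": self.means,
                "weight": self.weights,
                "n_assigned": [int(np.sum(labels == j)) for j in range(self.k)],
            }
        )


def _partition_loglike(y: np.ndarray, s: np.ndarray, labels: np.ndarray) -> float:
    """Classification log-likelihood of a labelled partition under
    partition-ML parameters."""
    y = np.asarray(y, float)
    s = np.asarray(s, float)
    n = y.size
    ll = 0.0
    for lab in np.unique(labels):
        idx = labels == lab
        w = 1.0 / s[idx] ** 2
        mu = np.average(y[idx], weights=w)
        pi = idx.sum() / n
        z = (y[idx] - mu) / s[idx]
        ll += np.sum(
            np.log(pi) - 0.5 * z * z - np.log(s[idx]) - 0.5 * np.log(2 * np.pi)
        )
    return float(ll)


# --------------------------------------------------------------------------
# model selection
# --------------------------------------------------------------------------


@dataclass
class ModelSelectionResult:
    """Criterion trace and majority-vote choice of the number of loci."""

    table: pd.DataFrame  # columns: K, loglik, AIC, AICc, AIC3, BIC, AWE
    chosen_k_per_criterion: dict[str, int | None]
    final_k: int
    fits: dict[int, QtlMixtureResults] = field(repr=False, default_factory=dict)

    @property
    def best_fit(self) -> QtlMixtureResults:
        return self.fits[self.final_k]


def select_model(
    obs: Sequence[QtlObservation] | QtlMixtureModel,
    kmax: int | None = None,
    seed: int | None = None,
) -> ModelSelectionResult:
    """Fit K = 1..Kmax and choose K by majority vote of five criteria.

    Each criterion votes for its minimising K; a criterion that could not
    be evaluated at every K (AICc when ``n <= p + 1``) abstains.  The final
    K is the modal vote, ties broken toward the smaller K (parsimony).
    ``kmax`` defaults to ``min(n, 10)``.
    """
    model = obs if isinstance(obs, QtlMixtureModel) else QtlMixtureModel.from_observations(obs)
    n = model.nobs
    kmax = min(n, 10) if kmax is None else min(kmax, n)
    if kmax < 1:
        raise InvalidInputError("Kmax must be >= 1")

    fits: dict[int, QtlMixtureResults] = {}
    rows = []
    for k in range(1, kmax + 1):
        res = model.fit(k, seed=seed)
        fits[k] = res
        rows.append({"K": k, "loglik": res.loglike, **res.criteria()})
    table = pd.DataFrame(rows)

    votes: dict[str, int | None] = {}
    for crit in CRITERIA:
        col = table[crit]
        if col.isna().any():
            votes[crit] = None  # abstains: did not evaluate every K
            continue
        votes[crit] = int(table.loc[col.idxmin(), "K"])

    cast = [v for v in votes.values() if v is not None]
    if not cast:  # all abstained (cannot happen for AIC/BIC, kept for safety)
        final_k = 1
    else:
        counts = Counter(cast)
        top = max(counts.values())
        final_k = min(k for k, c in counts.items() if c == top)
    return ModelSelectionResult(
        table=table, chosen_k_per_criterion=votes, final_k=final_k, fits=fits
    )


# --------------------------------------------------------------------------
# MQTL summaries
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaQtl:
    """A consolidated consensus locus."""

    name: str
    chromosome: str
    position: float
    ci_lo: float
    ci_hi: float
    members: tuple[str, ...]
    traits: frozenset[str]
    left_marker: str | None = None
    right_marker: str | None = None

    @property
    def ci_width(self) -> float:
        return self.ci_hi - self.ci_lo

    @property
    def n_members(self) -> int:
        return len(self.members)


def _flanking_markers(
    consensus: GeneticMap | None, chromosome: str, ci_lo: float, ci_hi: float
) -> tuple[str | None, str | None]:
    """Nearest consensus markers at or outside each CI bound; chromosome
    ends clamp to the terminal markers."""
    if consensus is None or not consensus.has_group(chromosome):
        return None, None
    loci = consensus.loci(chromosome)
    left = None
    for m in loci:
        if m.position <= ci_lo:
            left = m.name
        else:
            break
    if left is None:
        left = loci[0].name
    right = None
    for m in reversed(loci):
        if m.position >= ci_hi:
            right = m.name
        else:
            break
    if right is None:
        right = loci[-1].name
    return left, right


def summarize_mqtl(
    cluster: Sequence[QtlObservation],
    chromosome: str,
    consensus: GeneticMap | None = None,
    name: str = "MQTL",
) -> MetaQtl:
    """Inverse-variance pooling of one hard cluster.

    Position ``= sum(y_i/s_i^2) / sum(1/s_i^2)``; 95% CI width
    ``= 3.92 / sqrt(sum 1/s_i^2)`` centred on the position (pooling always
    shrinks the CI below the narrowest member's).
    """
    if not cluster:
        raise InvalidInputError("empty cluster")
    w = np.array([o.weight_inverse_variance for o in cluster])
    y = np.array([o.y for o in cluster])
    position = float(np.sum(w * y) / np.sum(w))
    half = 0.5 * CI_TO_SD_FACTOR / np.sqrt(np.sum(w))
    ci_lo, ci_hi = position - half, position + half
    left, right = _flanking_markers(consensus, chromosome, ci_lo, ci_hi)
    return MetaQtl(
        name=name,
        chromosome=chromosome,
        position=position,
        ci_lo=float(ci_lo),
        ci_hi=float(ci_hi),
        members=tuple(o.qtl_id for o in cluster),
        traits=frozenset(o.trait for o in cluster if o.trait),
        left_marker=left,
        right_marker=right,
    )


def run_meta_analysis(
    projected: Sequence[ProjectedQtl],
    consensus: GeneticMap | None = None,
    seed: int | None = None,
    kmax: int | None = None,
) -> tuple[list[MetaQtl], dict[str, ModelSelectionResult]]:
    """Per-chromosome model selection and cluster summarisation.

    MQTLs are named ``MQTL_<chrom>_<i>`` in ascending consensus position
    (1-based).  Chromosomes without any projected QTL are simply absent
    from the output.  Returns the MQTL list plus the per-chromosome
    selection traces.
    """
    by_chrom = observations_from_projected(projected)
    mqtls: list[MetaQtl] = []
    traces: dict[str, ModelSelectionResult] = {}
    for chrom in sorted(by_chrom):
        obs = by_chrom[chrom]
        sel = select_model(obs, kmax=kmax, seed=seed)
        traces[chrom] = sel
        labels = sel.best_fit.assignments
        clusters = [
            [o for o, lab in zip(obs, labels) if lab == j]
            for j in range(sel.final_k)
        ]
        clusters = [c for c in clusters if c]
        summaries = [
            summarize_mqtl(c, chrom, consensus=consensus) for c in clusters
        ]
        summaries.sort(key=lambda m: m.position)
        for i, m in enumerate(summaries, start=1):
            mqtls.append(
                MetaQtl(
                    name=f"MQTL_{chrom}_{i}",
                    chromosome=m.chromosome,
                    position=m.position,
                    ci_lo=m.ci_lo,
                    ci_hi=m.ci_hi,
                    members=m.members,
                    traits=m.traits,
                    left_marker=m.left_marker,
                    right_marker=m.right_marker,
                )
            )
    return mqtls, traces


def mqtl_table(mqtls: Sequence[MetaQtl]) -> pd.DataFrame:
    """Catalog-style table: one row per MQTL."""
    return pd.DataFrame(
        [
            {
                "name": m.name,
                "chrom": m.chromosome,
                "left_marker": m.left_marker,
                "right_marker": m.right_marker,
                "position_cM": m.position,
                "ci_width_cM": m.ci_width,
                "n_member_qtls": m.n_members,
                "traits": ";".join(sorted(m.traits)),
            }
            for m in mqtls
        ],
        columns=[
            "name", "chrom", "left_marker", "right_marker", "position_cM",
            "ci_width_cM", "n_member_qtls", "traits",
        ],
    )
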