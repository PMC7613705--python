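"""Estimator-style front end: discretizer transform and EPR estimator.

``TrajectoryDiscretizer`` turns a continuous observed coordinate into a
jump chain (a transform); ``SemiMarkovEPR`` fits second-order semi-Markov
statistics to a jump chain and exposes the irreversibility estimates as
fitted attributes.  Both follow the scikit-learn parameter conventions
(``get_params`` / ``set_params``, constructor stores hyper-parameters
unchanged, fitted attributes carry a trailing underscore), so they can be
cloned and composed in pipelines; the inputs are domain objects rather
than feature matrices.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from wtdepr import coarse_grain, semimarkov
from wtdepr.bundle_model import Trajectory
from wtdepr.chains import JumpChain

__all__ = ["TrajectoryDiscretizer", "SemiMarkovEPR"]


def _extract_series(X):
    """Accept a Trajectory or a (times_s, x1_nm) pair."""
    if isinstance(X, Trajectory):
        return X.times, X.x1
    times, x1 = X
    return np.asarray(times, dtype=float), np.asarray(x1, dtype=float)


class TrajectoryDiscretizer(TransformerMixin, BaseEstimator):
    """Coarse-grain a continuous observed coordinate into N discrete states.

    Parameters
    ----------
    n_states : int
        Number of coarse-grained states (>= 3).
    scheme : {'equal', 'unequal'}
        Bin-width scheme: equal widths, or wide boundary bins with
        interior widths 1/(N-2) relative to the boundaries.
    span_mode : {'minmax', 'mean3std'}
        How the reference span is taken from the fitted series.
    min_triplet_count : int
        Coverage threshold below which a warning is emitted for
        under-sampled triplets after transform.

    Attributes
    ----------
    partition_ : Partition
        The fitted binning (interior edges and span).
    """

    def __init__(
        self,
        n_states: int = 3,
        scheme: str = "equal",
        span_mode: str = "minmax",
        min_triplet_count: int = 50,
    ):
        self.n_states = n_states
        self.scheme = scheme
        self.span_mode = span_mode
        self.min_triplet_count = min_triplet_count

    def fit(self, X, y=None):
        """Determine the partition span and edges from the series."""
        _, x1 = _extract_series(X)
        self.partition_ = coarse_grain.partition_from_series(
            x1, self.n_states, self.scheme, self.span_mode
        )
        return self

    def transform(self, X) -> JumpChain:
        """Threshold the series through the fitted partition."""
        if not hasattr(self, "partition_"):
            raise RuntimeError("TrajectoryDiscretizer is not fitted")
        times, x1 = _extract_series(X)
        chain = coarse_grain.discretize(times, x1, self.partition_)
        if len(chain) >= 3:
            coarse_grain.check_triplet_coverage(chain, self.min_triplet_count)
        return chain


class SemiMarkovEPR(BaseEstimator):
    """Irreversibility estimates from second-order semi-Markov statistics.

    Fitting a jump chain collects triplet statistics and computes the
    affinity EPR, the waiting-time-distribution EPR and the mean
    dwell-time asymmetry factor.

    Parameters
    ----------
    method : {'knn', 'hist'}
        KLD estimator for the conditional dwell densities.
    k : int
        Neighbour order for the k-NN divergence estimator.
    n_bins : int
        Bin count for the histogram method (log-time axis).
    min_samples : int
        Minimum dwell samples per triplet direction; sparser triplets are
        excluded and listed in ``report_.excluded_triplets``.
    mdaf_normalizer : {'pairs', 'n_states'}
        Denominator of the total MDAF: observed direction pairs, or the
        number of coarse-grained states.
    n_boot_kld, n_boot_mdaf : int
        Bootstrap replicates for the per-triplet KLD and MDAF errors
        (0 disables the KLD bootstrap).
    linearity_threshold : float
        Maximum tolerated fraction of non-adjacent jumps.
    seed : int
        Seed for dithering and bootstrap resampling.

    Attributes
    ----------
    stats_ : TripletStats
    epr_aff_, epr_wtd_, mdaf_ : float
    report_ : EPRReport
    """

    def __init__(
        self,
        method: str = "knn",
        k: int = 5,
        n_bins: int = 30,
        min_samples: int = 50,
        mdaf_normalizer: str = "pairs",
        n_boot_kld: int = 0,
        n_boot_mdaf: int = 200,
        linearity_threshold: float = 1e-3,
        seed: int = 0,
    ):
        self.method = method
        self.k = k
        self.n_bins = n_bins
        self.min_samples = min_samples
        self.mdaf_normalizer = mdaf_normalizer
        self.n_boot_kld = n_boot_kld
        self.n_boot_mdaf = n_boot_mdaf
        self.linearity_threshold = linearity_threshold
        self.seed = seed

    def fit(self, X: JumpChain, y=None):
        chain = X
        if not isinstance(chain, JumpChain):
            raise TypeError("SemiMarkovEPR.fit expects a JumpChain")
        if chain.meta.get("degenerate"):
            raise ValueError("degenerate chain (never left one state); cannot estimate")
        n_states = len(np.unique(chain.states))
        lin = coarse_grain.validate_linear(chain, n_states, self.linearity_threshold)
        if not lin.ok:
            raise ValueError(
                f"{lin.fraction_nonadjacent:.2%} of jumps skip a state "
                f"(threshold {lin.threshold:.2%}): the series is under-sampled"
            )
        self.linearity_ = lin
        self.stats_ = semimarkov.collect_triplets(chain)
        self.epr_aff_ = semimarkov.epr_aff(self.stats_)
        wtd, per_kld, excl_wtd, se_wtd = semimarkov.epr_wtd(
            self.stats_,
            method=self.method,
            k=self.k,
            n_bins=self.n_bins,
            min_samples=self.min_samples,
            n_boot=self.n_boot_kld,
            seed=self.seed,
        )
        total_mdaf, per_mdaf, excl_mdaf, se_mdaf = semimarkov.mdaf(
            self.stats_,
            min_samples=self.min_samples,
            normalizer=self.mdaf_normalizer,
            n_boot=self.n_boot_mdaf,
            seed=self.seed,
        )
        self.epr_wtd_ = wtd
        self.mdaf_ = total_mdaf
        self.report_ = semimarkov.EPRReport(
            epr_aff=self.epr_aff_,
            epr_wtd=wtd,
            mdaf=total_mdaf,
            per_triplet_kld=per_kld,
            per_triplet_mdaf=per_mdaf,
            stderr_epr_aff=0.0,
            stderr_epr_wtd=se_wtd,
            stderr_mdaf=se_mdaf,
            excluded_triplets=excl_wtd + excl_mdaf,
        )
        return self

    def bootstrap_stderr(self, chain: JumpChain, n_boot: int = 200, n_blocks: int = 50) -> float:
        """Block-bootstrap standard error of the fitted EPR_WTD."""

        def _estimate(c: JumpChain) -> float:
            stats = semimarkov.collect_triplets(c)
            value, _, _, _ = semimarkov.epr_wtd(
                stats,
                method=self.method,
                k=self.k,
                n_bins=self.n_bins,
                min_samples=self.min_samples,
                n_boot=0,
                seed=self.seed,
            )
            return value

        return semimarkov.bootstrap_errors(
            chain, _estimate, n_boot=n_boot, n_blocks=n_blocks, seed=self.seed
        )
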