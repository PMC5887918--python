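"""Community-level summaries of prey availability and diet composition.

Bray-Curtis dissimilarity (optionally fourth-root transformed to
down-weight dominant taxa), two-dimensional nonmetric multidimensional
scaling, one-way PERMANOVA, permutation-tested gradient vector fitting
onto ordination scores, individual-based species accumulation curves
with an incidence-based (Chao2) total-richness estimate, and
hypergeometric rarefied richness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from sklearn.manifold import MDS


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray
    transform: str = "none"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
        self.values = v

    def to_skbio(self) -> DistanceMatrix:
        return DistanceMatrix(self.values, ids=self.labels)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x k axes
    stress: float
    n_restarts: int
    converged: bool


@dataclass
class AccumulationCurve:
    """Expected richness as a function of the number of individuals."""

    n_individuals: np.ndarray
    expected_richness: np.ndarray
    estimated_total_richness: float  # bias-corrected Chao2
    observed_richness: int
    #: fraction -> smallest whole number of individuals reaching it
    n_for_fraction: dict[float, int]
    #: fraction -> linearly interpolated effort
    n_for_fraction_interpolated: dict[float, float]
    mode: str = "exact"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n_individuals, "expected_richness": self.expected_richness})


def bray_curtis(counts: pd.DataFrame, transform: str = "fourth_root") -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample rows.

    ``transform="fourth_root"`` (the default) applies x -> x**0.25
    before computing BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i),
    down-weighting the most abundant taxa.
    """
    if transform not in ("none", "fourth_root"):
        raise ValueError(f"unknown transform {transform!r}")
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if (x.sum(axis=1) == 0).any():
        bad = counts.index[x.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero rows: {bad}")
    if transform == "fourth_root":
        x = x**0.25
    d = squareform(pdist(x, metric="braycurtis"))
    labels = [str(i) for i in counts.index]
    return DissimilarityMatrix(labels=labels, values=d, transform=transform)


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int = 0,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling in ``k`` dimensions.

    SMACOF majorization with isotonic regression of the configuration
    distances on the input dissimilarities; the best of ``n_restarts``
    random starts is returned with its Kruskal stress-1.  Scores are
    centred.  Non-convergence is flagged, the best configuration found
    is still returned.
    """
    n = len(d.labels)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for {k}-dimensional NMDS")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_restarts,
        init="random",
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        scores = model.fit_transform(d.values)
    scores = scores - scores.mean(axis=0)
    df = pd.DataFrame(scores, index=d.labels, columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(
        scores=df,
        stress=float(model.stress_),
        n_restarts=n_restarts,
        converged=bool(model.n_iter_ < max_iter),
    )


def permanova(
    d: DissimilarityMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA on a dissimilarity matrix.

    Pseudo-F from the partitioning of squared dissimilarities between
    and within groups; the p-value counts permutations with F at least
    the observed, with the usual +1 correction:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    groups = pd.Series(list(groups), index=d.labels)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        singletons = sizes[sizes < 2].index.tolist()
        raise ValueError(f"singleton groups not allowed: {singletons}")
    result = _skbio_permanova(d.to_skbio(), list(groups), permutations=n_perm, seed=seed)
    return float(result["test statistic"]), float(result["p-value"])


def vector_fit(
    ordination: OrdinationResult,
    covariate,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Fit a gradient vector to ordination scores.

    r is the multiple correlation between the covariate and its best
    linear predictor in score space (the length of the fitted
    environmental vector); the p-value permutes the covariate across
    samples with the +1 correction.
    """
    y = np.asarray(covariate, dtype=float)
    x = ordination.scores.to_numpy()
    if len(y) != x.shape[0]:
        raise ValueError("covariate length must equal the number of samples")
    if np.ptp(y) == 0:
        raise ValueError("constant covariate cannot be fitted")
    xc = x - x.mean(axis=0)

    def r_squared(yy: np.ndarray) -> float:
        yc = yy - yy.mean()
        beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        fitted = xc @ beta
        ss_tot = float(yc @ yc)
        return float(fitted @ fitted) / ss_tot if ss_tot > 0 else 0.0

    obs = r_squared(y)
    rng = np.random.default_rng(seed)
    exceed = sum(r_squared(rng.permutation(y)) >= obs for _ in range(n_perm))
    p = (1 + exceed) / (1 + n_perm)
    return float(np.sqrt(obs)), float(p)


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


def chao2(incidence: pd.DataFrame | np.ndarray) -> float:
    """Bias-corrected Chao2 incidence-based total-richness estimate.

    S_chao2 = S_obs + ((M-1)/M) * q1(q1-1) / (2(q2+1)), where q1 and q2
    are the numbers of taxa found in exactly one and exactly two of the
    M sampling units.
    """
    inc = np.asarray(incidence, dtype=int)
    m = inc.shape[0]
    freq = inc.sum(axis=0)
    s_obs = int((freq > 0).sum())
    q1 = int((freq == 1).sum())
    q2 = int((freq == 2).sum())
    return s_obs + (m - 1) / m * q1 * (q1 - 1) / (2 * (q2 + 1))


def accumulation_curve(
    incidence: pd.DataFrame | np.ndarray,
    mode: str = "exact",
    fractions: tuple[float, ...] = (0.5, 0.9),
    n_perm: int = 1000,
    seed: int = 0,
    fraction_of: str = "observed",
) -> AccumulationCurve:
    """Individual-based (sample-based) species accumulation curve.

    ``exact`` mode computes the analytical expectation over random
    orderings of individuals: E[S_n] = sum_t [1 - C(M - M_t, n)/C(M, n)]
    with M individuals of which M_t contain taxon t.  ``permutation``
    mode averages ``n_perm`` random orderings.  The total richness is
    estimated by bias-corrected Chao2, and the efforts needed to reach
    each requested fraction of the observed (or, with
    ``fraction_of="chao2"``, estimated) richness are reported both as
    the smallest whole n and linearly interpolated.
    """
    inc = np.asarray(incidence, dtype=int)
    if inc.size == 0 or inc.shape[0] < 1:
        raise ValueError("empty incidence matrix")
    if mode not in ("exact", "permutation"):
        raise ValueError(f"unknown mode {mode!r}")
    m = inc.shape[0]
    freq = inc.sum(axis=0)
    freq = freq[freq > 0]
    s_obs = len(freq)
    ns = np.arange(1, m + 1)
    if mode == "exact":
        # P(taxon t absent from a random subset of n individuals)
        log_tot = _log_comb(m, ns)
        expected = np.empty(m)
        for i, n in enumerate(ns):
            with np.errstate(invalid="ignore"):
                log_absent = _log_comb(m - freq, n) - log_tot[i]
            p_absent = np.where(m - freq >= n, np.exp(log_absent), 0.0)
            expected[i] = float((1.0 - p_absent).sum())
    else:
        rng = np.random.default_rng(seed)
        acc = np.zeros(m)
        present = inc > 0
        for _ in range(n_perm):
            order = rng.permutation(m)
            seen = np.cumsum(present[order], axis=0) > 0
            acc += seen.sum(axis=1)
        expected = acc / n_perm

    total = chao2(inc)
    denom = total if fraction_of == "chao2" else s_obs
    n_for: dict[float, int] = {}
    n_interp: dict[float, float] = {}
    for f in fractions:
        target = f * denom
        idx = np.nonzero(expected >= target - 1e-12)[0]
        if idx.size:
            i = int(idx[0])
            n_for[f] = int(ns[i])
            if i == 0 or expected[i] == target:
                n_interp[f] = float(ns[i])
            else:
                frac = (target - expected[i - 1]) / (expected[i] - expected[i - 1])
                n_interp[f] = float(ns[i - 1] + frac)
        else:
            n_for[f] = -1
            n_interp[f] = float("nan")
    return AccumulationCurve(
        n_individuals=ns,
        expected_richness=expected,
        estimated_total_richness=float(total),
        observed_richness=s_obs,
        n_for_fraction=n_for,
        n_for_fraction_interpolated=n_interp,
        mode=mode,
    )


def rarefied_richness(counts, depth: int) -> float:
    """Expected taxon richness in a random subsample of ``depth``
    individuals, by the hypergeometric formula
    E[S] = sum_i [1 - C(N - N_i, depth)/C(N, depth)]."""
    c = np.asarray(pd.Series(counts, dtype=float).to_numpy())
    c = c[c > 0]
    n_total = int(c.sum())
    if depth > n_total:
        raise ValueError(f"depth {depth} exceeds total count {n_total}")
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    with np.errstate(invalid="ignore"):
        log_absent = _log_comb(n_total - c, depth) - _log_comb(n_total, depth)
    p_absent = np.where(n_total - c >= depth, np.exp(log_absent), 0.0)
    return float((1.0 - p_absent).sum())
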