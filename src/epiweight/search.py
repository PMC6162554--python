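"""Seed-guided, interaction-weight-driven forward search for k-way epistasis.

The search keeps one modified-SU score and one multiplicative weight
coefficient W per SNP. A seed is the available SNP maximising SU×W; a
combination grows from the seed by repeatedly scoring every remaining SNP
s_i against the most recently added member s_a with the interaction weight
factor IWF(s_i, s_a), folding it into W(s_i), and adding the SNP with the
largest relevance R = W·(1+SU). Selected SNPs are consumed: they leave the
available pool F and their weight drops to 0, and W updates persist across
the whole run, so later combinations depend on the search history. The
candidate set is deduplicated on sorted index tuples and capped at T;
candidates are then verified with the improved G-test and those with
p-value below θ are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import gtest as _gtest
from .info import interaction_weight_factor, symmetrical_uncertainty
from .io import Dataset

log = logging.getLogger(__name__)


class SearchExhausted(Exception):
    """No seed can be selected: every SNP weight is zero or unavailable."""


class PartialCombinationError(Exception):
    """The pool F ran out of SNPs before a combination reached size k."""


@dataclass
class SearchConfig:
    """Tunable parameters of the forward search.

    ``K`` (combinations per seed) and ``T`` (candidate-set size) default
    to the simulation-study conventions K = k and T = 2k when left None.
    ``theta`` is the G-test p-value threshold; None selects the adaptive
    per-combination default 0.01·MAF/C(N,k) with MAF the smallest sample
    minor-allele frequency among the combination's SNPs.
    """

    k: int = 2
    K: Optional[int] = None
    T: Optional[int] = None
    theta: Optional[float] = None
    xi: int = _gtest.XI_DEFAULT
    tie_break: str = "lowest_index"
    expectation_mode: str = "independence"
    seed_reuse: str = "literal"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("combination order k must be >= 2")
        if self.K is None:
            self.K = self.k
        if self.T is None:
            self.T = 2 * self.k
        if self.K < 1 or self.T < 1:
            raise ValueError("K and T must be >= 1")
        if self.theta is not None and not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if self.seed_reuse not in ("literal", "reselect"):
            raise ValueError(f"unknown seed_reuse policy {self.seed_reuse!r}")
        if self.tie_break != "lowest_index":
            raise ValueError(f"unknown tie_break rule {self.tie_break!r}")


@dataclass
class WeightState:
    """Per-SNP modified-SU scores, weight coefficients W and the pool F."""

    su: np.ndarray
    w: np.ndarray
    available: np.ndarray  # boolean mask: membership in F

    def n_available(self) -> int:
        return int(self.available.sum())


@dataclass
class SNPCombination:
    """An ordered k-tuple of distinct SNP indices with score metadata."""

    indices: tuple
    relevance_trace: list = field(default_factory=list)
    gtest: Optional[_gtest.GTestResult] = None
    theta: Optional[float] = None
    significant: Optional[bool] = None

    @property
    def key(self) -> tuple:
        return tuple(sorted(self.indices))


@dataclass
class SearchResult:
    candidates: list
    iwf_evaluations: int
    exhausted: bool
    state: WeightState


def score_all_su(dataset: Dataset) -> WeightState:
    """Step one of the search: modified SU for every SNP, all weights 1."""
    n = dataset.n_snps
    su = np.empty(n)
    for i in range(n):
        su[i] = symmetrical_uncertainty(i, dataset, mode="modified")
    return WeightState(su=su, w=np.ones(n), available=np.ones(n, dtype=bool))


def select_seed(state: WeightState) -> int:
    """The available SNP with maximum SU×W (ties to the lowest index)."""
    score = np.where(state.available, state.su * state.w, -np.inf)
    usable = state.available & (state.w > 0)
    if not usable.any():
        raise SearchExhausted("no available SNP with positive weight")
    score[~usable] = -np.inf
    return int(np.argmax(score))  # argmax ties -> lowest index


def expand_combination(
    seed: int,
    state: WeightState,
    dataset: Dataset,
    k: int,
    _counter: Optional[list] = None,
) -> SNPCombination:
    """Grow a k-way combination from ``seed`` by maximum relevance R.

    Mutates ``state`` in place: the seed and every selected SNP leave F
    with weight 0, and every IWF evaluation updates the candidate's
    persistent weight coefficient. ``_counter`` (a one-element list)
    accumulates the number of IWF evaluations performed.
    """
    members = [seed]
    state.available[seed] = False
    state.w[seed] = 0.0
    trace = []
    while len(members) < k:
        pool = np.flatnonzero(state.available)
        if pool.size == 0:
            raise PartialCombinationError(
                f"pool exhausted with |S|={len(members)} < k={k}"
            )
        anchor = members[-1]
        for si in pool:
            iw = interaction_weight_factor(int(si), anchor, dataset)
            state.w[si] *= iw
            if _counter is not None:
                _counter[0] += 1
        relevance = state.w[pool] * (1.0 + state.su[pool])
        if np.all(state.su[pool] == 0.0) and np.all(relevance == relevance[0]):
            # every candidate is uninformative (e.g. all remaining SNPs constant)
            raise PartialCombinationError("no informative SNP left in the pool")
        chosen = int(pool[int(np.argmax(relevance))])  # ties -> lowest index
        trace.append(float(relevance.max()))
        members.append(chosen)
        state.available[chosen] = False
        state.w[chosen] = 0.0
    return SNPCombination(indices=tuple(members), relevance_trace=trace)


def run_search(dataset: Dataset, config: SearchConfig) -> SearchResult:
    """Full candidate-generation stage: seeds, expansions, dedup, cap at T.

    Deterministic for a given dataset and configuration. Returns fewer
    than T combinations (with a warning) when the SNP pool is exhausted
    first. With ``seed_reuse='literal'`` the 2nd..K-th combination of a
    seed group starts from the last SNP selected into the previous
    combination; ``'reselect'`` re-runs seed selection instead.
    """
    if dataset.has_missing():
        raise ValueError("dataset has missing genotypes; impute first")
    if dataset.n_snps < config.k:
        raise ValueError(f"need at least k={config.k} SNPs, have {dataset.n_snps}")
    state = score_all_su(dataset)
    counter = [0]
    candidates: list[SNPCombination] = []
    seen: set[tuple] = set()
    exhausted = False

    while len(candidates) < config.T and not exhausted:
        try:
            seed = select_seed(state)
        except SearchExhausted:
            exhausted = True
            break
        for m in range(config.K):
            if m > 0:
                if config.seed_reuse == "literal":
                    seed = last_member  # noqa: F821 - bound on every m=0 pass
                else:
                    try:
                        seed = select_seed(state)
                    except SearchExhausted:
                        exhausted = True
                        break
            try:
                combo = expand_combination(seed, state, dataset, config.k, counter)
            except PartialCombinationError:
                exhausted = True
                break
            last_member = combo.indices[-1]
            if combo.key not in seen:
                seen.add(combo.key)
                candidates.append(combo)
            if len(candidates) >= config.T:
                break

    if len(candidates) < config.T:
        log.warning(
            "search exhausted after %d of %d requested candidates",
            len(candidates), config.T,
        )
    bound = dataset.n_snps * math.factorial(config.k) * config.K
    if counter[0] > bound:
        log.warning(
            "IWF evaluation count %d exceeded the nominal bound N*k!*K = %d",
            counter[0], bound,
        )
    return SearchResult(
        candidates=candidates,
        iwf_evaluations=counter[0],
        exhausted=exhausted,
        state=state,
    )


def default_theta(maf: float, n_snps: int, k: int) -> float:
    """Adaptive significance threshold θ = 0.01·MAF / C(N, k).

    Computed in log space so that astronomically large binomial
    coefficients underflow gracefully to 0 instead of overflowing.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("MAF must be in (0, 0.5]")
    if not 1 <= k <= n_snps:
        raise ValueError("need 1 <= k <= N")
    log_c = (
        math.lgamma(n_snps + 1) - math.lgamma(k + 1) - math.lgamma(n_snps - k + 1)
    )
    log_theta = math.log(0.01 * maf) - log_c
    try:
        return math.exp(log_theta)
    except OverflowError:  # pragma: no cover - log_theta is always <= log(0.005)
        return 0.0


def annotate_candidates(
    candidates: Sequence[SNPCombination],
    dataset: Dataset,
    config: SearchConfig,
) -> list[SNPCombination]:
    """Annotate every candidate with its G-test result and significance."""
    for combo in candidates:
        combo.gtest = _gtest.g_test(
            dataset, list(combo.indices), xi=config.xi, mode=config.expectation_mode
        )
        if config.theta is not None:
            combo.theta = config.theta
        else:
            maf = min(dataset.sample_maf(i) for i in combo.indices)
            # fully monomorphic SNPs have MAF 0; fall back to the tightest bound
            maf = max(maf, 1.0 / (2.0 * dataset.n_samples))
            combo.theta = default_theta(maf, dataset.n_snps, config.k)
        combo.significant = combo.gtest.p_value < combo.theta
    return list(candidates)


def filter_candidates(
    candidates: Sequence[SNPCombination],
    dataset: Dataset,
    config: SearchConfig,
) -> list[SNPCombination]:
    """G-test verification stage: survivors with p < θ, ascending p."""
    annotated = annotate_candidates(candidates, dataset, config)
    survivors = [c for c in annotated if c.significant]
    survivors.sort(key=lambda c: (c.gtest.p_value, c.key))
    return survivors


def detect(dataset: Dataset, config: SearchConfig) -> tuple[SearchResult, list]:
    """Search then verify: returns the search result and the survivors."""
    result = run_search(dataset, config)
    survivors = filter_candidates(result.candidates, dataset, config)
    return result, survivors
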