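"""Hierarchical Dirichlet process inference of chromatin maintainer networks.

The corpus of edge bags is modelled as grouped data: each bag (one ChIA-PET
interaction) is a mixture over a shared, unbounded set of CMNs, where a CMN
``beta_k`` is a distribution over the edge vocabulary.  Three layers govern
the model: a symmetric Dirichlet base measure H over edges (concentration
``eta``), a global stick-breaking measure G_0 over CMNs (concentration
``gamma``), and per-bag measures G_j drawn around G_0 (concentration
``alpha``).

Inference is collapsed direct-assignment Gibbs sampling.  Each edge-token
occurrence z_jn is reassigned with probability

    p(z_jn = k) ∝ (n_jk + alpha * g_k) * (n_ke + eta) / (n_k + V * eta)

for active CMNs k, and ∝ alpha * g_new / V for a brand-new CMN, where g are
the G_0 stick weights and g_new the unallocated stick mass.  The sticks are
periodically resampled from their Dirichlet posterior given auxiliary table
counts (the standard auxiliary-variable scheme).  During the burn-in sweep
the sticks are resampled after every ``burnin_resample_every`` documents;
afterwards once per full sweep.  All tokens start in a single CMN and the
number of CMNs grows (and shrinks) as sampling proceeds.

Smaller ``eta`` concentrates each CMN on few edges (sparser edge-per-CMN
distributions); ``gamma`` > 1 spreads G_0 mass over more CMNs; ``alpha``
controls how many CMNs a single interaction may draw from.

The per-token inner loop is compiled with numba; runs are deterministic
given (corpus, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .corpus import Corpus

logger = logging.getLogger(__name__)

__all__ = [
    "HDPConfig",
    "HDPState",
    "gibbs_fit",
    "posterior_beta",
    "posterior_theta",
    "sparsity_metrics",
]


@dataclass(frozen=True)
class HDPConfig:
    """Hyperparameters and sampler settings.

    eta
        Symmetric Dirichlet concentration of the base measure over edge
        tokens; 0.01 favours sparse edge-per-CMN distributions.
    gamma
        Concentration of the global measure G_0; values above 1 allow more
        CMNs.
    alpha
        Concentration of the per-interaction measures G_j.
    sweeps
        Post-burn-in Gibbs sweeps (1000 in the motivating analysis).
    burnin_sweeps
        Number of initial sweeps run with intra-sweep stick resampling.
    burnin_resample_every
        During burn-in, resample the G_0 sticks after this many documents.
    max_cmns
        Hard cap on active CMNs (sampler working-array size).
    """

    eta: float = 0.01
    gamma: float = 1.0
    alpha: float = 1.0
    sweeps: int = 1000
    burnin_sweeps: int = 1
    burnin_resample_every: int = 10
    seed: int = 0
    max_cmns: int = 512

    def __post_init__(self) -> None:
        if min(self.eta, self.gamma, self.alpha) <= 0:
            raise ValueError("eta, gamma and alpha must all be > 0")
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")
        if self.burnin_sweeps < 0 or self.burnin_resample_every < 1:
            raise ValueError("invalid burn-in settings")


@dataclass
class HDPState:
    """Final Gibbs-sampler state.

    z
        Per-document arrays of token-occurrence CMN assignments (counts in
        the bag are expanded to individual tokens, ordered by token id).
    n_jk, n_ke, n_k
        Count tables (documents x CMNs, CMNs x vocabulary, CMNs).
    g, g_new
        G_0 stick weights of the active CMNs and the unallocated mass.
    """

    z: list[np.ndarray]
    n_jk: np.ndarray
    n_ke: np.ndarray
    n_k: np.ndarray
    K: int
    g: np.ndarray
    g_new: float
    doc_ids: list[str]
    vocab_size: int

    def validate(self) -> None:
        assert self.n_ke.sum(axis=1).tolist() == self.n_k.tolist()
        assert (self.n_k >= 1).all(), "active CMNs must be non-empty"
        for j, zj in enumerate(self.z):
            assert np.bincount(zj, minlength=self.K).tolist() == self.n_jk[j].tolist()
        total = self.g.sum() + self.g_new
        assert abs(total - 1.0) < 1e-9, "stick weights must sum to 1"


@njit(cache=True)
def _remove_topic(k, K, z, n_jk, n_ke, n_k, g, g_new):  # pragma: no cover
    g_new += g[k]
    last = K - 1
    if k != last:
        n_ke[k, :] = n_ke[last, :]
        n_jk[:, k] = n_jk[:, last]
        n_k[k] = n_k[last]
        g[k] = g[last]
        for i in range(z.size):
            if z[i] == last:
                z[i] = k
    n_ke[last, :] = 0
    n_jk[:, last] = 0
    n_k[last] = 0
    g[last] = 0.0
    return K - 1, g_new


@njit(cache=True)
def _resample_sticks(n_jk, K, D, alpha, gamma, g, g_new):  # pragma: no cover
    # auxiliary table counts m_jk ~ Antoniak(alpha * g_k, n_jk)
    m = np.zeros(K)
    for j in range(D):
        for k in range(K):
            njk = n_jk[j, k]
            if njk > 0:
                a = alpha * g[k]
                tables = 1
                for i in range(1, njk):
                    if np.random.random() < a / (a + i):
                        tables += 1
                m[k] += tables
    total = 0.0
    for k in range(K):
        draw = np.random.gamma(m[k], 1.0)
        g[k] = draw
        total += draw
    tail = np.random.gamma(gamma, 1.0)
    total += tail
    for k in range(K):
        g[k] /= total
    return tail / total


@njit(cache=True)
def _gibbs_kernel(
    words,
    doc_starts,
    V,
    eta,
    gamma,
    alpha,
    total_sweeps,
    burnin_sweeps,
    resample_every,
    seed,
    Kmax,
):  # pragma: no cover - compiled
    np.random.seed(seed)
    D = doc_starts.size - 1
    N = words.size
    z = np.zeros(N, np.int64)
    n_jk = np.zeros((D, Kmax), np.int64)
    n_ke = np.zeros((Kmax, V), np.int64)
    n_k = np.zeros(Kmax, np.int64)
    g = np.zeros(Kmax)
    # all tokens start in a single CMN; K grows as sampling proceeds
    K = 1
    for j in range(D):
        n_jk[j, 0] = doc_starts[j + 1] - doc_starts[j]
    for i in range(N):
        n_ke[0, words[i]] += 1
    n_k[0] = N
    g[0] = 0.5
    g_new = 0.5

    p = np.empty(Kmax)
    for sweep in range(total_sweeps):
        for j in range(D):
            for i in range(doc_starts[j], doc_starts[j + 1]):
                w = words[i]
                k = z[i]
                n_jk[j, k] -= 1
                n_ke[k, w] -= 1
                n_k[k] -= 1
                if n_k[k] == 0:
                    K, g_new = _remove_topic(k, K, z, n_jk, n_ke, n_k, g, g_new)
                total = 0.0
                for kk in range(K):
                    val = (n_jk[j, kk] + alpha * g[kk]) * (
                        (n_ke[kk, w] + eta) / (n_k[kk] + V * eta)
                    )
                    p[kk] = val
                    total += val
                p_new = alpha * g_new / V
                total += p_new
                u = np.random.random() * total
                chosen = K
                acc = 0.0
                for kk in range(K):
                    acc += p[kk]
                    if u <= acc:
                        chosen = kk
                        break
                if chosen == K:
                    if K >= Kmax:
                        raise RuntimeError(
                            "exceeded max_cmns; raise HDPConfig.max_cmns"
                        )
                    b = np.random.beta(1.0, gamma)
                    g[K] = b * g_new
                    g_new = (1.0 - b) * g_new
                    K += 1
                z[i] = chosen
                n_jk[j, chosen] += 1
                n_ke[chosen, w] += 1
                n_k[chosen] += 1
            if sweep < burnin_sweeps and (j + 1) % resample_every == 0:
                g_new = _resample_sticks(n_jk, K, D, alpha, gamma, g, g_new)
        g_new = _resample_sticks(n_jk, K, D, alpha, gamma, g, g_new)
    return z, n_jk, n_ke, n_k, K, g, g_new


def _flatten(corpus: Corpus) -> tuple[np.ndarray, np.ndarray, list[str]]:
    words: list[int] = []
    starts = [0]
    ids = []
    for bag in corpus.bags:
        for tok in sorted(bag.counts):
            words.extend([tok] * bag.counts[tok])
        starts.append(len(words))
        ids.append(bag.interaction_id)
    return (
        np.asarray(words, dtype=np.int64),
        np.asarray(starts, dtype=np.int64),
        ids,
    )


def gibbs_fit(corpus: Corpus, cfg: HDPConfig | None = None) -> HDPState:
    """Run the collapsed Gibbs sampler and return the final state.

    Token occurrences with count c are treated as c independent tokens.
    Deterministic given (corpus, cfg.seed).
    """
    cfg = cfg or HDPConfig()
    if len(corpus.bags) == 0:
        raise ValueError("empty corpus")
    words, doc_starts, doc_ids = _flatten(corpus)
    V = len(corpus.vocabulary)
    total_sweeps = cfg.burnin_sweeps + cfg.sweeps
    z, n_jk, n_ke, n_k, K, g, g_new = _gibbs_kernel(
        words,
        doc_starts,
        V,
        float(cfg.eta),
        float(cfg.gamma),
        float(cfg.alpha),
        total_sweeps,
        cfg.burnin_sweeps,
        cfg.burnin_resample_every,
        int(cfg.seed) & 0x7FFFFFFF,
        cfg.max_cmns,
    )
    z_docs = [
        z[doc_starts[j] : doc_starts[j + 1]].copy() for j in range(len(doc_ids))
    ]
    state = HDPState(
        z=z_docs,
        n_jk=n_jk[:, :K].copy(),
        n_ke=n_ke[:K, :].copy(),
        n_k=n_k[:K].copy(),
        K=int(K),
        g=g[:K].copy(),
        g_new=float(g_new),
        doc_ids=doc_ids,
        vocab_size=V,
    )
    logger.info("HDP fit finished with K=%d active CMNs", state.K)
    return state


def posterior_beta(state: HDPState, cfg: HDPConfig) -> np.ndarray:
    """Per-CMN edge distributions beta_k(e) = (n_ke + eta) / (n_k + V*eta)."""
    V = state.vocab_size
    beta = (state.n_ke + cfg.eta) / (state.n_k[:, None] + V * cfg.eta)
    return beta


def posterior_theta(state: HDPState, cfg: HDPConfig) -> np.ndarray:
    """Per-interaction mixing proportions over CMNs (rows sum to 1).

    theta_j(k) = (n_jk + alpha * g_k) / (size_j + alpha * (1 - g_new)).
    """
    sizes = state.n_jk.sum(axis=1)
    theta = (state.n_jk + cfg.alpha * state.g[None, :]) / (
        sizes[:, None] + cfg.alpha * (1.0 - state.g_new)
    )
    theta /= theta.sum(axis=1, keepdims=True)
    return theta


@dataclass(frozen=True)
class SparsitySummary:
    edge_level: float
    doc_level: float
    K: int
    mean_cmns_per_doc: float


def sparsity_metrics(
    state: HDPState, cfg: HDPConfig, threshold: float = 1e-3
) -> SparsitySummary:
    """Sparsity diagnostics of a fit.

    edge_level: fraction of (edge, CMN) cells with beta below ``threshold``.
    doc_level: mean over documents of the fraction of CMNs with theta below
    ``threshold``.  Also reports K and the mean number of CMNs with at least
    one token per document.
    """
    beta = posterior_beta(state, cfg)
    theta = posterior_theta(state, cfg)
    edge_level = float((beta < threshold).mean())
    doc_level = float((theta < threshold).mean(axis=1).mean())
    mean_cmns = float((state.n_jk >= 1).sum(axis=1).mean())
    return SparsitySummary(edge_level, doc_level, state.K, mean_cmns)
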