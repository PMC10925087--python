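"""Feasibility models for tumour-only somatic mutation calling.

A tumour sample is a mixture of cancer cells (fraction ``alpha``, the tumour
purity) and normal cells.  At a somatic mutation the mutant allele is carried
only by the cancer cells, so the expected fraction of mutant reads sits between
the sequencing-error rate and the heterozygous-SNP expectation.  This module
implements count-level simulation of pileups over a diploid genome and two
closed-form Bayesian classifiers over {somatic, het, reference}:

* the *unphased* classifier sees total reference/alternate counts ``(a, r)``
  and models the mutant-read probability as ``(1-eps)*alpha/2 + eps*(1-alpha/2)``;
* the *phased* classifier sees per-haplotype counts and models it as
  ``(1-eps)*alpha + eps*(1-alpha)``, with the het class expecting essentially
  every read on the haplotype to carry the alternate allele.

Both use binomial likelihoods with priors ``(mu, pi, 1-mu-pi)`` for the
somatic, het and reference classes.  Sweep utilities measure F1 of each
classifier over grids of depth, error rate and purity.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

BASES = "ACGT"

#: class labels, in posterior column order (argmax ties resolve left-to-right,
#: so somatic beats het and het beats reference on exact posterior ties)
LABELS = ("somatic", "het", "reference")

# integer truth-label codes used in columnar output
REF, HET, SOM = 0, 1, 2
_CODE_TO_LABEL = {REF: "reference", HET: "het", SOM: "somatic"}


class ParameterError(ValueError):
    """A simulation or classifier parameter is outside its domain."""


class UndefinedSiteError(ValueError):
    """A site with zero informative reads cannot be classified."""


@dataclasses.dataclass(frozen=True)
class SimParams:
    """Parameters of the pileup simulation.

    Parameters
    ----------
    G : genome length in bases.
    lam : mean sequencing depth (reads per site), Poisson distributed.
    alpha : tumour purity in [0, 1].
    epsilon : per-base sequencing error rate in [0, 1).
    mu : somatic mutation rate per base per haplotype.
    pi : heterozygous SNP rate per base.
    seed : RNG seed; the same seed reproduces the pileup stream exactly.
    """

    G: int
    lam: float
    alpha: float
    epsilon: float
    mu: float = 5e-6
    pi: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ParameterError(f"G must be >= 1, got {self.G}")
        if not self.lam > 0:
            raise ParameterError(f"lambda must be > 0, got {self.lam}")
        for name in ("alpha", "mu", "pi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.epsilon < 1.0:
            raise ParameterError(f"epsilon must be in [0, 1), got {self.epsilon}")
        if self.mu + self.pi >= 1.0:
            raise ParameterError("mu + pi must be < 1")


@dataclasses.dataclass(frozen=True)
class SitePileup:
    """Observed allele counts at one genome position, with the truth label."""

    position: int
    ref_base: str
    a: int  # reads supporting the modal non-reference base
    r: int  # reads supporting the reference base
    per_haplotype: Optional[tuple[tuple[int, int], tuple[int, int]]] = None
    label: str = "reference"

    @property
    def depth(self) -> int:
        return self.a + self.r


@dataclasses.dataclass(frozen=True)
class ClassPosterior:
    """Posterior over {somatic, het, reference} for one site (or haplotype)."""

    p_somatic: float
    p_het: float
    p_reference: float

    @property
    def label(self) -> str:
        probs = (self.p_somatic, self.p_het, self.p_reference)
        return LABELS[int(np.argmax(probs))]


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


def _check_classifier_params(alpha: float, epsilon: float, mu: float, pi: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    if not 0.0 <= epsilon < 1.0:
        raise ParameterError(f"epsilon must be in [0, 1), got {epsilon}")
    if not (0.0 < mu and 0.0 < pi and mu + pi < 1.0):
        raise ParameterError("priors require mu > 0, pi > 0, mu + pi < 1")


def _posterior_array(
    a: np.ndarray, n: np.ndarray, success: Sequence[float], log_prior: np.ndarray
) -> np.ndarray:
    """Normalized posteriors, shape (..., 3), columns in ``LABELS`` order."""
    a = np.asarray(a)
    n = np.asarray(n)
    loglik = np.stack([binom.logpmf(a, n, p) for p in success], axis=-1)
    logpost = loglik + log_prior
    with np.errstate(invalid="ignore"):
        logpost = logpost - logsumexp(logpost, axis=-1, keepdims=True)
    return np.exp(logpost)


def unphased_success_probabilities(alpha: float, epsilon: float) -> tuple[float, float, float]:
    """Binomial success probability of an alternate read per class, unphased."""
    return ((1 - epsilon) * alpha / 2 + epsilon * (1 - alpha / 2), 0.5, epsilon)


def phased_success_probabilities(alpha: float, epsilon: float) -> tuple[float, float, float]:
    """Binomial success probability of an alternate read per class, per haplotype."""
    return ((1 - epsilon) * alpha + epsilon * (1 - alpha), 1 - epsilon, epsilon)


def unphased_posteriors(
    a, r, alpha: float, epsilon: float, mu: float, pi: float
) -> np.ndarray:
    """Vectorized unphased posterior matrix with columns (somatic, het, reference)."""
    _check_classifier_params(alpha, epsilon, mu, pi)
    log_prior = np.log(np.array([mu, pi, 1.0 - mu - pi]))
    a = np.asarray(a)
    r = np.asarray(r)
    return _posterior_array(a, a + r, unphased_success_probabilities(alpha, epsilon), log_prior)


def phased_posteriors(
    a, r, alpha: float, epsilon: float, mu: float, pi: float
) -> np.ndarray:
    """Vectorized per-haplotype posterior matrix, columns (somatic, het, reference)."""
    _check_classifier_params(alpha, epsilon, mu, pi)
    log_prior = np.log(np.array([mu, pi, 1.0 - mu - pi]))
    a = np.asarray(a)
    r = np.asarray(r)
    return _posterior_array(a, a + r, phased_success_probabilities(alpha, epsilon), log_prior)


def _scalar_posterior(post: np.ndarray) -> ClassPosterior:
    return ClassPosterior(float(post[0]), float(post[1]), float(post[2]))


def classify_unphased(
    a: int, r: int, alpha: float, epsilon: float, mu: float, pi: float
) -> ClassPosterior:
    """Classify a site from its total alternate/reference counts."""
    if a < 0 or r < 0:
        raise UndefinedSiteError("counts must be non-negative")
    if a + r == 0:
        raise UndefinedSiteError("site has no informative reads")
    return _scalar_posterior(unphased_posteriors(a, r, alpha, epsilon, mu, pi))


def classify_phased(
    a_j: int, r_j: int, alpha: float, epsilon: float, mu: float, pi: float
) -> ClassPosterior:
    """Classify one haplotype of a site from its per-haplotype counts."""
    if a_j < 0 or r_j < 0:
        raise UndefinedSiteError("counts must be non-negative")
    if a_j + r_j == 0:
        raise UndefinedSiteError("haplotype has no informative reads")
    return _scalar_posterior(phased_posteriors(a_j, r_j, alpha, epsilon, mu, pi))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PileupArrays:
    """Columnar pileup over all ``G`` sites (position = array index).

    ``a``/``r`` are the combined (unphased) modal-alternate and reference
    counts; ``a0, r0, a1, r1`` are the per-haplotype counts.  ``label`` holds
    the truth code (0 = reference, 1 = het, 2 = somatic).  Reads whose base is
    neither the reference base nor the modal non-reference base (stray errors)
    are not counted, matching the classifiers' observation model.
    """

    params: SimParams
    label: np.ndarray
    a: np.ndarray
    r: np.ndarray
    a0: np.ndarray
    r0: np.ndarray
    a1: np.ndarray
    r1: np.ndarray

    def __len__(self) -> int:
        return self.label.shape[0]


def _split_errors(rng: np.random.Generator, errors: np.ndarray) -> np.ndarray:
    """Distribute per-site error counts uniformly over the 3 non-ref bases."""
    out = np.zeros((errors.shape[0], 3), dtype=np.int32)
    pos = errors > 0
    if np.any(pos):
        out[pos] = rng.multinomial(errors[pos], [1 / 3, 1 / 3, 1 / 3])
    return out


def _simulate_marked_sites(
    rng: np.random.Generator,
    d0: np.ndarray,
    d1: np.ndarray,
    het: np.ndarray,
    het_hap: np.ndarray,
    som0: np.ndarray,
    som1: np.ndarray,
    alpha: float,
    epsilon: float,
) -> tuple[np.ndarray, ...]:
    """Per-base counts for sites carrying a het SNP and/or somatic mutation.

    Bases are tracked as site-local letter indices with the reference at 0.
    The het alternate letter is drawn from {1,2,3}; a somatic mutation changes
    the haplotype's germline letter to one of the three other letters (which
    can be the reference letter when the germline is a het alternate).
    Returns ``(a0, r0, a1, r1, a, r)`` for the marked sites.
    """
    k = d0.shape[0]
    het_alt = rng.integers(1, 4, size=k)
    counts = []
    for j, (dj, somj) in enumerate(((d0, som0), (d1, som1))):
        germ = np.where(het & (het_hap == j), het_alt, 0)
        # somatic letter: uniform over the 3 letters != germline
        shift = rng.integers(1, 4, size=k)
        som_letter = (germ + shift) % 4
        p_true = np.zeros((k, 4))
        rows = np.arange(k)
        p_true[rows, germ] = 1.0
        if np.any(somj):
            p_true[somj, germ[somj]] -= alpha
            p_true[somj, som_letter[somj]] += alpha
        p4 = p_true * (1 - epsilon) + (1 - p_true) * (epsilon / 3)
        counts.append(rng.multinomial(dj, p4))
    c0, c1 = counts
    total = c0 + c1
    a0 = c0[:, 1:].max(axis=1)
    r0 = c0[:, 0]
    a1 = c1[:, 1:].max(axis=1)
    r1 = c1[:, 0]
    a = total[:, 1:].max(axis=1)
    r = total[:, 0]
    return a0, r0, a1, r1, a, r


def simulate_pileup(params: SimParams, rng: Optional[np.random.Generator] = None) -> PileupArrays:
    """Simulate per-site allele counts for the whole genome, vectorized.

    Per site: a het SNP is placed on a random haplotype with probability
    ``pi`` and each haplotype acquires a somatic mutation with probability
    ``mu``; total depth is Poisson(``lam``) and is split across haplotypes by
    Binomial(d, 1/2); reads on a mutated haplotype carry the somatic base with
    probability ``alpha`` (the chance of sampling a cancer cell); finally each
    read base is flipped to one of the three other bases with probability
    ``epsilon``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    G, lam, eps = params.G, params.lam, params.epsilon

    het = rng.random(G) < params.pi
    som0 = rng.random(G) < params.mu
    som1 = rng.random(G) < params.mu
    het_hap = np.zeros(G, dtype=np.int8)
    het_hap[het] = rng.integers(0, 2, size=int(het.sum()))

    d = rng.poisson(lam, G)
    d0 = rng.binomial(d, 0.5)
    d1 = d - d0

    marked = het | som0 | som1
    plain = ~marked

    a0 = np.zeros(G, dtype=np.int32)
    r0 = np.zeros(G, dtype=np.int32)
    a1 = np.zeros(G, dtype=np.int32)
    r1 = np.zeros(G, dtype=np.int32)
    a = np.zeros(G, dtype=np.int32)
    r = np.zeros(G, dtype=np.int32)

    # reference-only sites: only sequencing errors generate alternate bases
    e0 = rng.binomial(d0[plain], eps)
    e1 = rng.binomial(d1[plain], eps)
    s0 = _split_errors(rng, e0)
    s1 = _split_errors(rng, e1)
    a0[plain] = s0.max(axis=1)
    r0[plain] = d0[plain] - e0
    a1[plain] = s1.max(axis=1)
    r1[plain] = d1[plain] - e1
    a[plain] = (s0 + s1).max(axis=1)
    r[plain] = (d0[plain] - e0) + (d1[plain] - e1)

    if np.any(marked):
        res = _simulate_marked_sites(
            rng,
            d0[marked],
            d1[marked],
            het[marked],
            het_hap[marked],
            som0[marked],
            som1[marked],
            params.alpha,
            eps,
        )
        for dst, src in zip((a0, r0, a1, r1, a, r), res):
            dst[marked] = src

    label = np.zeros(G, dtype=np.int8)
    label[het] = HET
    label[som0 | som1] = SOM
    return PileupArrays(params, label, a, r, a0, r0, a1, r1)


def sim_pileup(
    params: SimParams, reference: Optional[str] = None
) -> Iterator[SitePileup]:
    """Stream :class:`SitePileup` records with truth labels for every covered site.

    ``reference`` optionally supplies the reference bases (length >= G);
    otherwise uniform-random bases are reported.  The classifiers depend only
    on counts, so the base content is cosmetic.  Sites with zero depth are
    skipped as uncallable.
    """
    if reference is not None and len(reference) < params.G:
        raise ParameterError("reference shorter than genome length G")
    arrays = simulate_pileup(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xB45E]))
    ref_idx = (
        None if reference is not None else rng.integers(0, 4, size=params.G)
    )
    for i in range(params.G):
        depth = int(arrays.a[i] + arrays.r[i])
        if depth == 0:
            continue
        base = reference[i] if reference is not None else BASES[ref_idx[i]]
        yield SitePileup(
            position=i,
            ref_base=base,
            a=int(arrays.a[i]),
            r=int(arrays.r[i]),
            per_haplotype=(
                (int(arrays.a0[i]), int(arrays.r0[i])),
                (int(arrays.a1[i]), int(arrays.r1[i])),
            ),
            label=_CODE_TO_LABEL[int(arrays.label[i])],
        )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _f1_from_counts(tp: int, fp: int, fn: int) -> dict:
    if tp + fn == 0 and fp == 0:
        # no somatic truth and nothing predicted: perfect by convention
        return {"precision": 1.0, "recall": 1.0, "f1": 1.0}
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}


def evaluate_calls(truth, predicted) -> dict:
    """Precision/recall/F1 on the somatic class.

    ``truth`` and ``predicted`` are equal-length label sequences (strings from
    ``LABELS`` or integer codes).  With no somatic sites in the truth and none
    predicted all three metrics are 1.0 by convention.
    """
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("truth and predicted streams differ in length")
    t_pos = (t == "somatic") | (t == SOM) if t.dtype.kind in "UO" else t == SOM
    p_pos = (p == "somatic") | (p == SOM) if p.dtype.kind in "UO" else p == SOM
    tp = int(np.sum(t_pos & p_pos))
    fp = int(np.sum(~t_pos & p_pos))
    fn = int(np.sum(t_pos & ~p_pos))
    return _f1_from_counts(tp, fp, fn)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _unique_pairs(key: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, counts = np.unique(key, return_counts=True)
    return uniq, counts


def _phased_somatic_flag(
    a0, r0, a1, r1, alpha, epsilon, mu, pi
) -> np.ndarray:
    """Site is predicted somatic if either covered haplotype argmax-labels somatic."""
    flag = np.zeros(np.shape(a0), dtype=bool)
    for aj, rj in ((a0, r0), (a1, r1)):
        n = np.asarray(aj) + np.asarray(rj)
        covered = n > 0
        if np.any(covered):
            post = phased_posteriors(
                np.asarray(aj)[covered], np.asarray(rj)[covered], alpha, epsilon, mu, pi
            )
            sub = np.zeros(np.shape(a0), dtype=bool)
            sub[covered] = np.argmax(post, axis=-1) == 0
            flag |= sub
    return flag


def _unphased_somatic_flag(a, r, alpha, epsilon, mu, pi) -> np.ndarray:
    n = np.asarray(a) + np.asarray(r)
    covered = n > 0
    flag = np.zeros(np.shape(a), dtype=bool)
    if np.any(covered):
        post = unphased_posteriors(
            np.asarray(a)[covered], np.asarray(r)[covered], alpha, epsilon, mu, pi
        )
        flag[covered] = np.argmax(post, axis=-1) == 0
    return flag


class _BackgroundTables:
    """Compressed (count-pattern, multiplicity) tables for non-somatic sites.

    The background (reference and het) pileup does not depend on tumour
    purity, so one simulation serves every purity in a sweep; only the
    classifier (which does depend on ``alpha``) is re-run, over the unique
    count patterns.  Phased patterns join the two haplotypes so the
    either-haplotype calling rule is evaluated per site.
    """

    _B = 2048  # packing radix; counts are < 2048 for all supported depths

    def __init__(self, arrays: PileupArrays, truth_mask: np.ndarray):
        B = self._B
        a0 = arrays.a0[truth_mask].astype(np.int64)
        r0 = arrays.r0[truth_mask].astype(np.int64)
        a1 = arrays.a1[truth_mask].astype(np.int64)
        r1 = arrays.r1[truth_mask].astype(np.int64)
        a = arrays.a[truth_mask].astype(np.int64)
        r = arrays.r[truth_mask].astype(np.int64)
        key_ph = ((a0 * B + r0) * B + a1) * B + r1
        key_un = a * B + r
        self.ph_key, self.ph_n = _unique_pairs(key_ph)
        self.un_key, self.un_n = _unique_pairs(key_un)

    def phased_positive(self, alpha, epsilon, mu, pi) -> int:
        B = self._B
        k = self.ph_key
        r1 = k % B
        a1 = (k // B) % B
        r0 = (k // B**2) % B
        a0 = k // B**3
        flag = _phased_somatic_flag(a0, r0, a1, r1, alpha, epsilon, mu, pi)
        return int(self.ph_n[flag].sum())

    def unphased_positive(self, alpha, epsilon, mu, pi) -> int:
        r = self.un_key % self._B
        a = self.un_key // self._B
        flag = _unphased_somatic_flag(a, r, alpha, epsilon, mu, pi)
        return int(self.un_n[flag].sum())


def purity_sweep(
    depths: Sequence[float],
    epsilons: Sequence[float],
    purities: Sequence[float],
    params: SimParams,
) -> pd.DataFrame:
    """F1 of both classifiers over a (depth, error rate, purity) grid.

    For each (depth, epsilon) cell the purity-independent background
    (reference and het sites) is simulated once and shared across the purity
    grid as common random numbers; somatic sites are re-simulated at each
    purity.  Classifier priors are matched to the simulation's ``(mu, pi)``
    and its ``alpha`` is set to each grid purity.  Returns one row per
    (depth, error_rate, purity, mode) with precision, recall, F1 and the
    somatic truth count.
    """
    purities = list(purities)
    if any(not 0 <= x <= 1 for x in purities):
        raise ParameterError("purity grid must lie within [0, 1]")
    rows = []
    root = np.random.SeedSequence(params.seed)
    for cell_seq, (lam, eps) in zip(
        root.spawn(len(depths) * len(epsilons)),
        ((d, e) for d in depths for e in epsilons),
    ):
        bg_seq, som_seq = cell_seq.spawn(2)
        cell_params = dataclasses.replace(
            params, lam=lam, epsilon=eps, alpha=0.0, mu=0.0
        )
        rng = np.random.default_rng(bg_seq)
        background = simulate_pileup(cell_params, rng)
        ref_tab = _BackgroundTables(background, background.label == REF)
        het_tab = _BackgroundTables(background, background.label == HET)

        # somatic sites: how many, and their depths, are drawn per purity
        for pur_seq, alpha in zip(som_seq.spawn(len(purities)), purities):
            srng = np.random.default_rng(pur_seq)
            n_som = int(srng.binomial(params.G, 1 - (1 - params.mu) ** 2))
            som_hap = srng.integers(0, 2, size=n_som)
            het = srng.random(n_som) < params.pi
            het_hap = srng.integers(0, 2, size=n_som)
            d = srng.poisson(lam, n_som)
            d0 = srng.binomial(d, 0.5)
            d1 = d - d0
            sa0, sr0, sa1, sr1, sa, sr = _simulate_marked_sites(
                srng, d0, d1, het, het_hap, som_hap == 0, som_hap == 1, alpha, eps
            )
            for mode in ("phased", "unphased"):
                if mode == "phased":
                    fp = ref_tab.phased_positive(alpha, eps, params.mu, params.pi)
                    fp += het_tab.phased_positive(alpha, eps, params.mu, params.pi)
                    tp_flag = _phased_somatic_flag(
                        sa0, sr0, sa1, sr1, alpha, eps, params.mu, params.pi
                    )
                else:
                    fp = ref_tab.unphased_positive(alpha, eps, params.mu, params.pi)
                    fp += het_tab.unphased_positive(alpha, eps, params.mu, params.pi)
                    tp_flag = _unphased_somatic_flag(
                        sa, sr, alpha, eps, params.mu, params.pi
                    )
                tp = int(tp_flag.sum())
                fn = n_som - tp
                metrics = _f1_from_counts(tp, fp, fn)
                rows.append(
                    {
                        "depth": lam,
                        "error_rate": eps,
                        "purity": alpha,
                        "mode": mode,
                        **metrics,
                        "n_truth_somatic": n_som,
                    }
                )
    return pd.DataFrame(rows)


def f1_interval(
    purities: Sequence[float], f1s: Sequence[float], threshold: float = 0.9
) -> Optional[tuple[float, float]]:
    """Smallest and largest purity whose F1 exceeds ``threshold`` (None if none)."""
    purities = np.asarray(purities, dtype=float)
    f1s = np.asarray(f1s, dtype=float)
    above = purities[f1s > threshold]
    if above.size == 0:
        return None
    return float(above.min()), float(above.max())
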