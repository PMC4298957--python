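"""Category enrichment by degree-preserving randomization.

Categories produced by multi-assignment are not independent — one gene may
sit in several — so instead of a hypergeometric test the null model
re-randomizes the background: each background gene keeps its number of
assigned categories (its *degree* k_i) but receives k_i distinct categories
drawn with probability proportional to the background category frequencies

    p(c) = Σ_i f_i(c) / Σ_c' Σ_i f_i(c'),

then L genes (the test-set size) are drawn uniformly without replacement
and per-category gene counts recorded.  Repeating this (1000 times by
default) gives a mean μ(c) and standard deviation σ(c) per category, from
which

    z(c) = (observed(c) − μ(c)) / σ(c)

and one-sided normal p-values for enrichment (upper tail) and depletion
(lower tail) are computed.

Drawing k distinct categories by sequential sampling without replacement
with renormalization is the Plackett–Luce model; it is implemented here via
the equivalent Gumbel top-k trick (add iid Gumbel noise to log p(c), keep
the k largest), which vectorizes over genes and replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_REPS = 1000


class EnrichmentInputError(ValueError):
    """Raised for empty or inconsistent enrichment inputs."""


@dataclass
class EnrichmentResult:
    """Observed count, randomization moments and test statistics for one category."""

    category: str
    observed: int
    mu: float
    sigma: float
    z: float
    p_enrich: float
    p_deplete: float
    degenerate: bool = False  # sigma == 0 with observed != mu


@dataclass
class RandomizedNull:
    """Per-category randomization mean and SD, with the sampling settings."""

    categories: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    reps: int
    L: int
    seed: int


def _degrees_and_probs(assignments) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Extract category list, p(c) vector and per-gene degree vector."""
    cat_assign_counts: dict[str, int] = {}
    degrees = []
    for a in assignments:
        degrees.append(a.degree)
        for c in a.categories:
            cat_assign_counts[c] = cat_assign_counts.get(c, 0) + 1
    total = sum(cat_assign_counts.values())
    if total == 0:
        raise EnrichmentInputError("no gene in the background is assigned to any category")
    categories = sorted(cat_assign_counts)
    p = np.array([cat_assign_counts[c] / total for c in categories])
    return categories, p, np.asarray(degrees, dtype=np.intp)


def category_probabilities(assignments) -> dict[str, float]:
    """Background category probabilities p(c), normalized over all assignments."""
    categories, p, _ = _degrees_and_probs(assignments)
    return dict(zip(categories, p))


def randomized_null(
    assignments,
    L: int,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> RandomizedNull:
    """Degree-preserving randomization of the background.

    Every replicate reassigns each background gene k_i distinct categories
    ∝ p(c) (degrees are conserved exactly and asserted), draws L genes
    uniformly without replacement, and counts genes per category.  Returns
    per-category mean and SD over ``reps`` replicates; fully reproducible
    for a given ``seed``.
    """
    n = len(assignments)
    if not 0 < L <= n:
        raise EnrichmentInputError(f"L must be in (0, {n}], got {L}")
    if reps < 2:
        raise EnrichmentInputError(f"reps must be >= 2, got {reps}")
    categories, p, degrees = _degrees_and_probs(assignments)
    m = len(categories)
    if int(degrees.max(initial=0)) > m:
        raise EnrichmentInputError(
            f"a gene has degree {int(degrees.max())} > {m} categories"
        )

    rng = np.random.default_rng(seed)
    log_p = np.full(m, -np.inf)
    nz = p > 0
    log_p[nz] = np.log(p[nz])

    counts = np.empty((reps, m), dtype=np.intp)
    # replicate batches bound peak memory for large backgrounds
    batch = max(1, min(reps, int(2e7 // max(1, n * m))))
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        # Gumbel top-k: per gene, the k_i largest perturbed log-probs are a
        # without-replacement sample ∝ p(c)
        noise = rng.gumbel(size=(b, n, m))
        order = np.argsort(-(log_p + noise), axis=2, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(m)[None, None, :], axis=2)
        assigned = ranks < degrees[None, :, None]
        assert (assigned.sum(axis=2) == degrees[None, :]).all(), \
            "degree conservation violated in randomization"
        # L distinct genes per replicate, uniform without replacement
        pick = np.argsort(rng.random((b, n)), axis=1)[:, :L]
        chosen = np.zeros((b, n), dtype=bool)
        np.put_along_axis(chosen, pick, True, axis=1)
        counts[done:done + b] = (assigned & chosen[:, :, None]).sum(axis=1)
        done += b

    return RandomizedNull(
        categories=categories,
        mu=counts.mean(axis=0),
        sigma=counts.std(axis=0, ddof=0),
        reps=reps,
        L=L,
        seed=seed,
    )


def observed_counts(assignments, categories: list[str]) -> np.ndarray:
    """Per-category gene counts in a test set (a gene counts once per category)."""
    counts = dict.fromkeys(categories, 0)
    for a in assignments:
        for c in a.categories:
            if c in counts:
                counts[c] += 1
    return np.array([counts[c] for c in categories], dtype=np.intp)


def zscores_from_null(observed: np.ndarray, null: RandomizedNull) -> list[EnrichmentResult]:
    """Compare observed counts against a precomputed randomization null."""
    results = []
    for j, cat in enumerate(null.categories):
        obs, mu, sigma = int(observed[j]), float(null.mu[j]), float(null.sigma[j])
        degenerate = False
        if sigma == 0.0:
            if obs == mu:
                z, p_hi, p_lo = 0.0, 0.5, 0.5
            else:
                degenerate = True
                z = np.inf if obs > mu else -np.inf
                # never observed among `reps` replicates
                p_hi = 1.0 / null.reps if obs > mu else 1.0
                p_lo = 1.0 / null.reps if obs < mu else 1.0
        else:
            z = (obs - mu) / sigma
            p_hi = float(stats.norm.sf(z))
            p_lo = float(stats.norm.cdf(z))
        results.append(
            EnrichmentResult(
                category=cat, observed=obs, mu=mu, sigma=sigma, z=float(z),
                p_enrich=p_hi, p_deplete=p_lo, degenerate=degenerate,
            )
        )
    return results


def enrichment_test(
    test_assignments,
    background_assignments,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Full enrichment test of a categorized test set against its background.

    Test genes must be a subset of the background; otherwise they are
    intersected with a warning.  ``fdr`` adds Benjamini–Hochberg adjusted
    enrichment p-values (off by default; the method itself reports raw
    one-sided p-values).
    """
    if not test_assignments:
        raise EnrichmentInputError("empty test set")
    bg_genes = {a.gene for a in background_assignments}
    test = [a for a in test_assignments if a.gene in bg_genes]
    if len(test) < len(test_assignments):
        logger.warning(
            "%d test genes not in background; intersecting",
            len(test_assignments) - len(test),
        )
        if not test:
            raise EnrichmentInputError("no test gene present in the background")
    null = randomized_null(background_assignments, L=len(test), reps=reps, seed=seed)
    observed = observed_counts(test, null.categories)
    results = zscores_from_null(observed, null)
    if fdr:
        order = np.argsort([r.p_enrich for r in results])
        m = len(results)
        adj = np.empty(m)
        running = 1.0
        for rank, idx in enumerate(reversed(order), start=0):
            i = m - rank
            running = min(running, results[idx].p_enrich * m / i)
            adj[idx] = running
        for r, q in zip(results, adj):
            r.p_enrich_fdr = float(q)  # type: ignore[attr-defined]
    return results


def write_enrichment(
    results: list[EnrichmentResult], path, reps: int | None = None, seed: int | None = None
) -> None:
    """Write enrichment results as TSV with reps/seed echoed in header comments."""
    with open(path, "w") as fh:
        if reps is not None:
            fh.write(f"# reps={reps}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("category\tobserved\tmu\tsigma\tz\tp_enrich\tp_deplete\n")
        for r in results:
            fh.write(
                f"{r.category}\t{r.observed}\t{r.mu:.4f}\t{r.sigma:.4f}\t"
                f"{r.z:.4f}\t{r.p_enrich:.6g}\t{r.p_deplete:.6g}\n"
            )
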