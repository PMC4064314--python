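"""Seeded synthetic data with the statistical structure the method assumes.

The generator emulates the one property the transformation exploits: groups
of functionally related genes differ systematically in baseline tolerance,
i.e. in the location of their germline score distributions. It produces

* a germline variant catalog whose MutationAssessor-like scores are drawn
  per gene from the Normal(mu_g, sigma_g) of the gene's group, and whose
  SIFT/PPH2-like raw scores are drawn from per-group Beta distributions in
  raw [0, 1] space (so the logit path is exercised end-to-end);
* a flat gene-set collection with one term per group, plus a configurable
  fraction of genes annotated to a second term;
* somatic mutation sets in which driver mutations carry a shifted oriented
  score and are placed preferentially in the least tolerant groups, mirroring
  the observed overrepresentation of cancer genes there, while passengers
  follow the germline-like distribution of their gene.

All draws come from one ``numpy.random.default_rng`` stream, so outputs are
fully determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .errors import ConfigurationError
from .models import GeneSetCollection, ScoredVariant

__all__ = ["SimConfig", "GeneTruth", "simulate_universe", "simulate_somatic"]


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass
class SimConfig:
    """Parameters of the synthetic universe.

    Defaults describe ten functional groups of five genes with group
    tolerance means spread linearly over [0, 2] oriented-MA units (echoing
    the observed spread between the least and most tolerant functional
    categories), sigma 0.3, and about eight germline SNVs per gene — roughly
    forty pooled SNVs behind each gene's baseline. Somatic benchmarks default
    to 2000 mutations, 20% drivers shifted by +2 oriented units and
    concentrated in the least tolerant groups.
    """

    n_groups: int = 10
    genes_per_group: int | Tuple[int, int] = 5
    snvs_per_gene: float = 8.0
    group_tolerance_means: Sequence[float] | None = None
    group_tolerance_stds: Sequence[float] | None = None
    sift_beta_params: Sequence[Tuple[float, float]] | None = None
    pph2_beta_params: Sequence[Tuple[float, float]] | None = None
    driver_fraction: float = 0.2
    driver_shift: float = 2.0
    driver_group_concentration: float = 2.0
    driver_recurrence_mean: float = 2.5
    n_somatic: int = 2000
    overlap_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if self.group_tolerance_means is None:
            self.group_tolerance_means = list(np.linspace(0.0, 2.0, self.n_groups))
        if self.group_tolerance_stds is None:
            self.group_tolerance_stds = [0.3] * self.n_groups
        if self.sift_beta_params is None:
            # least tolerant groups harbor benign germline SNVs: SIFT raw high
            self.sift_beta_params = [
                (8.0 - 6.0 * g / max(self.n_groups - 1, 1), 2.0 + 6.0 * g / max(self.n_groups - 1, 1))
                for g in range(self.n_groups)
            ]
        if self.pph2_beta_params is None:
            self.pph2_beta_params = [(b, a) for a, b in self.sift_beta_params]
        for name in ("group_tolerance_means", "group_tolerance_stds", "sift_beta_params", "pph2_beta_params"):
            if len(getattr(self, name)) != self.n_groups:
                raise ConfigurationError(f"{name} must have length n_groups={self.n_groups}")
        if any(s <= 0 for s in self.group_tolerance_stds):
            raise ConfigurationError("group_tolerance_stds must all be positive")
        if not (0.0 <= self.driver_fraction <= 1.0):
            raise ConfigurationError("driver_fraction must lie in [0, 1]")
        if self.driver_shift < 0:
            raise ConfigurationError("driver_shift must be non-negative")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ConfigurationError("overlap_fraction must lie in [0, 1]")
        if self.snvs_per_gene <= 0:
            raise ConfigurationError("snvs_per_gene must be positive")


@dataclass
class GeneTruth:
    """Generating parameters of one synthetic gene."""

    group: int
    ma_mean: float
    ma_std: float
    terms: Tuple[str, ...]


def _genes_per_group(cfg: SimConfig, rng: np.random.Generator) -> List[int]:
    if isinstance(cfg.genes_per_group, tuple):
        lo, hi = cfg.genes_per_group
        return [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_groups)]
    return [int(cfg.genes_per_group)] * cfg.n_groups


def simulate_universe(
    cfg: SimConfig,
) -> Tuple[List[ScoredVariant], GeneSetCollection, Dict[str, GeneTruth]]:
    """Generate (germline catalog, gene-set collection, per-gene truth)."""
    rng = np.random.default_rng(cfg.seed)
    term_ids = [f"T{g:03d}" for g in range(cfg.n_groups)]
    term_members: Dict[str, Set[str]] = {t: set() for t in term_ids}
    truth: Dict[str, GeneTruth] = {}
    catalog: List[ScoredVariant] = []

    counts = _genes_per_group(cfg, rng)
    for g in range(cfg.n_groups):
        mu = float(cfg.group_tolerance_means[g])
        sigma = float(cfg.group_tolerance_stds[g])
        sift_a, sift_b = cfg.sift_beta_params[g]
        pph2_a, pph2_b = cfg.pph2_beta_params[g]
        for i in range(counts[g]):
            gene = f"G{g:03d}_{i:03d}"
            terms = [term_ids[g]]
            if cfg.n_groups > 1 and rng.random() < cfg.overlap_fraction:
                terms.append(term_ids[(g + 1) % cfg.n_groups])
            for t in terms:
                term_members[t].add(gene)
            truth[gene] = GeneTruth(group=g, ma_mean=mu, ma_std=sigma, terms=tuple(terms))
            n_v = int(rng.poisson(cfg.snvs_per_gene))
            for k in range(n_v):
                catalog.append(
                    ScoredVariant(
                        variant_id=f"{gene}:v{k:04d}",
                        gene_id=gene,
                        scores={
                            "sift": float(np.clip(rng.beta(sift_a, sift_b), 0.0, 1.0)),
                            "pph2": float(np.clip(rng.beta(pph2_a, pph2_b), 0.0, 1.0)),
                            "ma": float(rng.normal(mu, sigma)),
                        },
                    )
                )
    terms = {
        t: (f"synthetic functional group {g}", members)
        for g, (t, members) in enumerate(term_members.items())
        if members
    }
    collection = GeneSetCollection("SYN", terms)
    return catalog, collection, truth


def _shifted_bounded(rng: np.random.Generator, a: float, b: float, shift: float, invert: bool) -> float:
    """Draw a Beta raw score, shift it on the logit (oriented) scale, map back."""
    raw = float(np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6))
    p = 1.0 - raw if invert else raw
    oriented = math.log(p / (1.0 - p)) + shift
    p_new = _expit(oriented)
    return 1.0 - p_new if invert else p_new


def simulate_somatic(
    cfg: SimConfig,
    truth: Dict[str, GeneTruth],
    n_mutations: int | None = None,
    labels: bool = True,
    rng: np.random.Generator | None = None,
) -> Tuple[List[ScoredVariant], Set[str], Set[str]]:
    """Generate a somatic benchmark from a simulated universe's truth.

    Drivers (a ``driver_fraction`` share of mutations) receive oriented
    scores shifted by ``driver_shift`` and genes sampled with weight
    ``exp(-concentration * mu_g)`` — concentration 0 places them uniformly.
    Driver sample counts are ``1 + Poisson(driver_recurrence_mean)`` so most
    drivers recur in two or more samples; passengers appear once and draw
    their scores from the germline-like distribution of a uniformly chosen
    gene.

    Returns
    -------
    (mutations, positive_ids, negative_ids)
        The id sets are empty when ``labels`` is false.
    """
    if n_mutations is None:
        n_mutations = cfg.n_somatic
    if n_mutations < 1:
        raise ConfigurationError("n_mutations must be >= 1")
    if not truth:
        raise ConfigurationError("truth is empty; run simulate_universe first")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    genes = sorted(truth)
    mus = np.array([truth[g].ma_mean for g in genes])
    w = np.exp(-cfg.driver_group_concentration * mus)
    driver_weights = w / w.sum()

    n_drivers = int(round(cfg.driver_fraction * n_mutations))
    mutations: List[ScoredVariant] = []
    positives: Set[str] = set()
    negatives: Set[str] = set()
    for i in range(n_mutations):
        is_driver = i < n_drivers
        if is_driver:
            gene = genes[int(rng.choice(len(genes), p=driver_weights))]
        else:
            gene = genes[int(rng.integers(len(genes)))]
        t = truth[gene]
        g = t.group
        shift = cfg.driver_shift if is_driver else 0.0
        sift_a, sift_b = cfg.sift_beta_params[g]
        pph2_a, pph2_b = cfg.pph2_beta_params[g]
        vid = f"som{i:05d}"
        mutations.append(
            ScoredVariant(
                variant_id=vid,
                gene_id=gene,
                scores={
                    "sift": _shifted_bounded(rng, sift_a, sift_b, shift, invert=True),
                    "pph2": _shifted_bounded(rng, pph2_a, pph2_b, shift, invert=False),
                    "ma": float(rng.normal(t.ma_mean + shift, t.ma_std)),
                },
                sample_count=1 + int(rng.poisson(cfg.driver_recurrence_mean)) if is_driver else 1,
            )
        )
        if labels:
            (positives if is_driver else negatives).add(vid)
    return mutations, positives, negatives
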