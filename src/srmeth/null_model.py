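"""Stochastic per-site reference model for region methylation features.

The null hypothesis for a region's read-level variation is that every site
of every read is methylated independently with probability equal to the
region's mean methylation. Under this model (independent Bernoulli(p) per
site per read; the read score is then Binomial(n, p)):

* expected mean read methylation = p
* expected read stochasticity     = 2·p·(1 − p)
  (each adjacent site pair differs with probability 2p(1−p))
* asymptotic SD of read methylation = sqrt(p·(1 − p)/n_sites)

A sample whose observed feature distributions match this null is explained
by site-level stochastic variation; systematic departures (e.g. an excess
of fully methylated reads driving read-methylation SD above the null)
indicate differential methylation among the cells of the sample.

Matched simulations reuse each observed region's read count so that
finite-sample inflation of the SDs is shared between data and null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import RegionFeatures, region_features
from .reads import ReadVector

__all__ = [
    "NullSpec",
    "simulate_null_region",
    "null_expectations",
    "null_feature_distribution",
]


@dataclass(frozen=True)
class NullSpec:
    """Parameters of one simulated null region."""

    p: float
    n_sites: int = 5
    n_reads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")


def simulate_null_region(spec: NullSpec) -> list[ReadVector]:
    """Draw ``n_reads`` iid Bernoulli(p) read vectors; seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    matrix = (rng.random((spec.n_reads, spec.n_sites)) < spec.p).astype(int)
    return [
        ReadVector(read_id=f"null{i}", region_id="null", states=tuple(row))
        for i, row in enumerate(matrix)
    ]


def null_expectations(p: float, n_sites: int) -> tuple[float, float, float]:
    """Closed forms: (E mean read meth, E stochasticity, asymptotic read-meth SD)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return p, 2.0 * p * (1.0 - p), float(np.sqrt(p * (1.0 - p) / n_sites))


def null_feature_distribution(
    observed_regions: Sequence[RegionFeatures],
    seed: int = 0,
    replicates: int = 1,
) -> list[RegionFeatures]:
    """One (or more) matched null simulations per observed region.

    Each simulated region copies the observed region's mean methylation,
    site count and read count, and its features are computed through the
    same code path as the observed features.
    """
    children = np.random.SeedSequence(seed).spawn(len(observed_regions) * replicates)
    out: list[RegionFeatures] = []
    for i, obs in enumerate(observed_regions):
        for rep in range(replicates):
            child = children[i * replicates + rep]
            spec = NullSpec(
                p=obs.mean_read_meth,
                n_sites=obs.n_sites,
                n_reads=obs.n_reads,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            vectors = simulate_null_region(spec)
            feats = region_features(
                vectors,
                region_id=f"{obs.region_id}:null{rep}",
                element_id=obs.element_id,
                gc=obs.gc,
                min_reads=1,
            )
            assert feats is not None  # n_reads >= 1 by construction
            out.append(feats)
    return out
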