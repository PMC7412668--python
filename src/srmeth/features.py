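"""Per-region methylation variation features and element-level aggregation.

Each aligned read that covers all of a region's context sites yields a
binary state vector. Three kinds of variation are computed from the
read × site state matrix of a region:

* **read-methylation variation** — the SD across reads of each read's
  methylation fraction; interpreted as cell-to-cell heterogeneity, since
  each read derives from one DNA molecule of one cell;
* **among-site variation** — the SD of the per-site mean methylation
  fractions, i.e. of the averaged (bulk) signal at each site;
* **stochasticity** — per read, the fraction of adjacent site pairs whose
  states differ; averaged over reads.

All SDs are population (uncorrected) SDs, so a region at the minimum read
count is as well-defined as any other. Elements (TEs, genes, exons)
aggregate the unweighted mean of their surviving regions' features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionFeatures",
    "ElementSummary",
    "read_stochasticity",
    "region_features",
    "read_state_histogram",
    "meth_stoch_grid",
    "aggregate_elements",
    "select_hypermethylated",
    "linreg",
    "features_to_frame",
    "frame_to_features",
    "write_features_table",
    "read_features_table",
]

#: the four region features used downstream (classifier order)
FEATURE_NAMES = ("mean_read_meth", "sd_read_meth", "mean_stochasticity", "sd_site_meth")


def read_stochasticity(states: Sequence[int]) -> float:
    """Fraction of adjacent site pairs within one read that change state.

    A fully alternating read scores 1, a constant read 0. Undefined for
    fewer than two sites.
    """
    n = len(states)
    if n < 2:
        raise ValueError("stochasticity requires at least 2 sites")
    arr = np.asarray(states)
    return float(np.mean(arr[1:] != arr[:-1]))


@dataclass(frozen=True)
class RegionFeatures:
    """Summary features of one region's read × site state matrix."""

    region_id: str
    element_id: str
    n_reads: int
    mean_read_meth: float
    sd_read_meth: float
    mean_stochasticity: float
    sd_site_meth: float
    per_site_meth: tuple[float, ...]
    gc: float = float("nan")

    @property
    def n_sites(self) -> int:
        return len(self.per_site_meth)


@dataclass(frozen=True)
class ElementSummary:
    """Unweighted mean of a functional element's surviving regions."""

    element_id: str
    n_regions_used: int
    mean_read_meth: float
    sd_read_meth: float
    mean_stochasticity: float
    sd_site_meth: float
    gc: float = float("nan")
    pattern_score: float | None = None


def region_features(
    vectors: Sequence,
    region_id: str | None = None,
    element_id: str = "",
    gc: float = float("nan"),
    min_reads: int = 4,
) -> RegionFeatures | None:
    """Compute region features from its read vectors, or ``None`` if the
    region has fewer than ``min_reads`` reads (filtered out).

    The methylation threshold (default 10%) is applied downstream by the
    caller, so that unfiltered feature tables remain available.
    """
    if len(vectors) < max(min_reads, 1):
        return None
    matrix = np.asarray([v.states for v in vectors], dtype=float)
    read_meth = matrix.mean(axis=1)
    per_site = matrix.mean(axis=0)
    stoch = np.mean(matrix[:, 1:] != matrix[:, :-1], axis=1)
    if region_id is None:
        region_id = getattr(vectors[0], "region_id", "")
    return RegionFeatures(
        region_id=region_id,
        element_id=element_id,
        n_reads=matrix.shape[0],
        mean_read_meth=float(read_meth.mean()),
        sd_read_meth=float(read_meth.std(ddof=0)),
        mean_stochasticity=float(stoch.mean()),
        sd_site_meth=float(per_site.std(ddof=0)),
        per_site_meth=tuple(float(x) for x in per_site),
        gc=gc,
    )


def read_state_histogram(vectors: Sequence, n_sites: int = 5) -> np.ndarray:
    """Histogram of read scores (methylated-site counts), bins 0..n_sites.

    The caller restricts ``vectors`` to regions in a methylation bin of
    interest (e.g. regions with mean methylation ≥ 5%, ≥ 20%, ≥ 40%).
    """
    counts = np.zeros(n_sites + 1, dtype=int)
    for v in vectors:
        score = int(sum(v.states))
        if len(v.states) != n_sites:
            raise ValueError("vector length does not match n_sites")
        counts[score] += 1
    return counts


def meth_stoch_grid(
    vectors: Sequence,
    meth_bins: Sequence[float],
    stoch_bins: Sequence[float],
) -> pd.DataFrame:
    """Joint histogram of read methylation × read stochasticity.

    Returns a tidy frame with one row per occupied cell (empty cells are
    absent, mirroring the blank areas of the published heat maps): columns
    meth_bin_left, stoch_bin_left, count.
    """
    meth = np.array([np.mean(v.states) for v in vectors], dtype=float)
    stoch = np.array([read_stochasticity(v.states) for v in vectors], dtype=float)
    counts, m_edges, s_edges = np.histogram2d(meth, stoch, bins=[meth_bins, stoch_bins])
    rows = []
    for i, j in zip(*np.nonzero(counts)):
        rows.append(
            {
                "meth_bin_left": m_edges[i],
                "stoch_bin_left": s_edges[j],
                "count": int(counts[i, j]),
            }
        )
    return pd.DataFrame(rows, columns=["meth_bin_left", "stoch_bin_left", "count"])


def aggregate_elements(
    features: Iterable[RegionFeatures],
    min_meth: float = 0.10,
    min_reads: int = 4,
    min_regions: int = 2,
) -> list[ElementSummary]:
    """Average surviving regions' features per element.

    A region survives with at least ``min_reads`` reads and mean read
    methylation ≥ ``min_meth``; elements keeping fewer than ``min_regions``
    such regions are dropped. The average is unweighted — low- and
    high-coverage regions count equally.
    """
    groups: dict[str, list[RegionFeatures]] = {}
    for f in features:
        if f is None or f.n_reads < min_reads or f.mean_read_meth < min_meth:
            continue
        groups.setdefault(f.element_id, []).append(f)
    summaries = []
    for element_id in sorted(groups):
        members = groups[element_id]
        if len(members) < min_regions:
            continue
        summaries.append(
            ElementSummary(
                element_id=element_id,
                n_regions_used=len(members),
                mean_read_meth=float(np.mean([f.mean_read_meth for f in members])),
                sd_read_meth=float(np.mean([f.sd_read_meth for f in members])),
                mean_stochasticity=float(
                    np.mean([f.mean_stochasticity for f in members])
                ),
                sd_site_meth=float(np.mean([f.sd_site_meth for f in members])),
                gc=float(np.mean([f.gc for f in members])),
            )
        )
    return summaries


def select_hypermethylated(
    sample_a: Mapping[str, RegionFeatures] | Iterable[RegionFeatures],
    sample_b: Mapping[str, RegionFeatures] | Iterable[RegionFeatures],
    delta: float = 0.10,
) -> set[str]:
    """Region ids whose methylation rises by strictly more than ``delta``
    from sample A to sample B; ids absent from either sample are skipped."""
    a = _by_id(sample_a)
    b = _by_id(sample_b)
    return {
        rid
        for rid in a.keys() & b.keys()
        if b[rid].mean_read_meth - a[rid].mean_read_meth > delta
    }


def _by_id(sample) -> dict[str, RegionFeatures]:
    if isinstance(sample, Mapping):
        return dict(sample)
    return {f.region_id: f for f in sample}


def linreg(x: Sequence[float], y: Sequence[float]):
    """Ordinary least-squares simple regression.

    Returns ``(slope, intercept, r_squared, p_value)``; requires ≥ 3 points.
    Degenerate (constant) y gives slope 0 and r² 0.
    """
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("linreg requires >= 3 paired points")
    if np.ptp(y) == 0:
        return 0.0, float(np.mean(y)), 0.0, 1.0
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2, res.pvalue


# --- tabular round trip -----------------------------------------------------

def features_to_frame(features: Iterable[RegionFeatures]) -> pd.DataFrame:
    rows = []
    for f in features:
        rows.append(
            {
                "region_id": f.region_id,
                "element_id": f.element_id,
                "n_reads": f.n_reads,
                "mean_read_meth": f.mean_read_meth,
                "sd_read_meth": f.sd_read_meth,
                "mean_stochasticity": f.mean_stochasticity,
                "sd_site_meth": f.sd_site_meth,
                "per_site_meth": ",".join(f"{x:.6g}" for x in f.per_site_meth),
                "gc": f.gc,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "element_id",
            "n_reads",
            "mean_read_meth",
            "sd_read_meth",
            "mean_stochasticity",
            "sd_site_meth",
            "per_site_meth",
            "gc",
        ],
    )


def frame_to_features(frame: pd.DataFrame) -> list[RegionFeatures]:
    out = []
    for row in frame.itertuples(index=False):
        per_site = tuple(float(x) for x in str(row.per_site_meth).split(","))
        out.append(
            RegionFeatures(
                region_id=row.region_id,
                element_id=row.element_id,
                n_reads=int(row.n_reads),
                mean_read_meth=float(row.mean_read_meth),
                sd_read_meth=float(row.sd_read_meth),
                mean_stochasticity=float(row.mean_stochasticity),
                sd_site_meth=float(row.sd_site_meth),
                per_site_meth=per_site,
                gc=float(row.gc),
            )
        )
    return out


def write_features_table(features: Iterable[RegionFeatures], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, sep="\t", index=False)


def read_features_table(path: str | Path) -> list[RegionFeatures]:
    return frame_to_features(pd.read_csv(path, sep="\t"))
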