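"""Per-function taxonomic richness and rarefaction curves.

Richness of a functional gene is the number of distinct taxa (at a chosen
rank) containing at least one read annotated to it.  Rarefaction gives the
expected richness in a random subsample of n reads, computed exactly from
the hypergeometric distribution:

    E[R(n)] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]

where N_i is the read count of taxon i and N their total.  Binomial
coefficients are evaluated through log-gamma so deep libraries do not
overflow.  A Monte-Carlo subsampler (sampling without replacement) is
provided as an independent check of the analytic curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .matrices import TaxonFunctionMatrix

__all__ = [
    "RichnessRecord",
    "RarefactionCurve",
    "functional_richness",
    "rarefaction_curve",
    "rarefaction_by_subsampling",
    "saturation_flag",
    "write_curves_tsv",
]


@dataclass(frozen=True)
class RichnessRecord:
    """Number of distinct taxa at ``rank`` containing a functional gene."""

    function_label: str
    rank: str
    richness: int


@dataclass(frozen=True)
class RarefactionCurve:
    """Expected richness at each subsampling depth for one function."""

    function_label: str
    depths: tuple[int, ...]
    expected_richness: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.depths) != len(self.expected_richness):
            raise ValueError("depths and expected_richness must align")
        if any(b <= a for a, b in zip(self.depths, self.depths[1:])):
            raise ValueError("depths must be strictly increasing")


def functional_richness(m: TaxonFunctionMatrix, function_label: str) -> RichnessRecord:
    """Count taxa with at least one read of ``function_label``."""
    if function_label not in m.counts.columns:
        return RichnessRecord(function_label, m.rank, 0)
    return RichnessRecord(
        function_label, m.rank, int((m.counts[function_label] > 0).sum())
    )


def _expected_richness(counts: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Vectorized hypergeometric expectation over (taxon, depth)."""
    counts = counts[counts > 0]
    total = counts.sum()
    # log C(N - N_i, n) - log C(N, n), with C(m, n) = 0 when n > m
    n = depths[None, :].astype(float)
    m = (total - counts)[:, None].astype(float)
    with np.errstate(invalid="ignore"):
        log_ratio = (
            gammaln(m + 1)
            - gammaln(n + 1)
            - gammaln(m - n + 1)
            - (gammaln(total + 1) - gammaln(n + 1) - gammaln(total - n + 1))
        )
    prob_absent = np.where(n > m, 0.0, np.exp(log_ratio))
    return (1.0 - prob_absent).sum(axis=0)


def default_depth_grid(total: int, n_depths: int = 20) -> tuple[int, ...]:
    """Log-spaced grid of ``n_depths`` unique depths from 1 to ``total``."""
    if total < 1:
        raise ValueError("total count must be >= 1")
    grid = np.unique(
        np.round(np.logspace(0, np.log10(total), n_depths)).astype(int)
    )
    return tuple(int(d) for d in grid)


def rarefaction_curve(
    per_taxon_counts,
    depths=None,
    *,
    function_label: str = "all",
) -> RarefactionCurve:
    """Exact expected-richness rarefaction curve for a per-taxon count vector.

    ``depths`` defaults to 20 log-spaced depths from 1 to the total count.
    The curve ends exactly at the observed richness when the final depth
    equals the total.
    """
    counts = np.asarray(list(per_taxon_counts), dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("per-taxon counts must be non-negative")
    total = int(counts.sum())
    if total < 1:
        raise ValueError("cannot rarefy an empty count vector")
    if depths is None:
        depths = default_depth_grid(total)
    depths_arr = np.asarray(sorted(set(int(d) for d in depths)), dtype=np.int64)
    if depths_arr[0] < 1:
        raise ValueError("depths must be >= 1")
    if depths_arr[-1] > total:
        raise ValueError(f"depth {depths_arr[-1]} exceeds total count {total}")
    expected = _expected_richness(counts, depths_arr)
    return RarefactionCurve(
        function_label=function_label,
        depths=tuple(int(d) for d in depths_arr),
        expected_richness=tuple(float(e) for e in expected),
    )


def rarefaction_by_subsampling(
    per_taxon_counts,
    depth: int,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte-Carlo rarefaction: mean and sd of richness over random subsamples.

    Each replicate draws ``depth`` reads without replacement from the pooled
    counts (a multivariate hypergeometric draw) and counts the taxa hit.
    Exists as an independent check of :func:`rarefaction_curve`.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    counts = np.asarray(list(per_taxon_counts), dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(counts, depth, size=reps, method="count")
    richness = (draws > 0).sum(axis=1)
    return float(richness.mean()), float(richness.std(ddof=1)) if reps > 1 else 0.0


def saturation_flag(
    curve: RarefactionCurve,
    tail_fraction: float = 0.1,
    slope_tol: float | None = None,
) -> bool:
    """Whether the curve has flattened: has sequencing depth saturated richness?

    Computes the mean slope (new taxa per read) over the last
    ``tail_fraction`` of the depth range.  The default tolerance admits less
    than one new taxon per ten times the final depth step.
    """
    if len(curve.depths) < 3:
        raise ValueError("need at least 3 depths to assess saturation")
    depths = np.asarray(curve.depths, dtype=float)
    rich = np.asarray(curve.expected_richness, dtype=float)
    if slope_tol is None:
        final_step = depths[-1] - depths[-2]
        slope_tol = 1.0 / (10.0 * final_step)
    cutoff = depths[-1] - tail_fraction * (depths[-1] - depths[0])
    tail = depths >= cutoff
    if tail.sum() < 2:
        tail[-2:] = True
    d, r = depths[tail], rich[tail]
    mean_slope = (r[-1] - r[0]) / (d[-1] - d[0])
    return bool(mean_slope < slope_tol)


def write_curves_tsv(curves, path) -> None:
    """Export curves as long TSV: function, depth, expected_richness."""
    with open(path, "w") as fh:
        fh.write("function\tdepth\texpected_richness\n")
        for c in curves:
            for d, e in zip(c.depths, c.expected_richness):
                fh.write(f"{c.function_label}\t{d}\t{e:.6f}\n")
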