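"""Per-gene local false discovery rates and seed selection.

Gene-level p-values are converted to z-scores, z = Phi^-1(1 - p), and the
two-groups empirical Bayes model is fit: the marginal density f(z) is
estimated by Lindsey's method (Poisson regression of histogram counts on a
polynomial basis), the null component f0 is the standard normal density
(or an empirical null fit on the central window), and the local FDR of a
gene is lfdr(z) = min(1, pi0 * f0(z) / f(z)).  A subnetwork's FDR is the
mean lfdr of its distinct physical genes; genes with lfdr below the bound
B become seeds for the subnetwork search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .multiplex import LayerNetwork

__all__ = [
    "GeneScoreTable",
    "SeedList",
    "estimate_local_fdr",
    "subnetwork_fdr",
    "select_and_order_seeds",
    "combine_min_lfdr",
]

P_CLIP = 1e-15  # avoids infinite z at p = 0 or 1


@dataclass
class GeneScoreTable:
    """Per-gene p-value, z-score and local FDR."""

    table: pd.DataFrame  # columns: gene, pvalue, zscore, lfdr
    pi0: float = 1.0

    def __post_init__(self) -> None:
        self._lfdr = dict(zip(self.table["gene"], self.table["lfdr"]))

    def lfdr(self, gene: str) -> float:
        """Local FDR of ``gene``; unscored genes count as null (lfdr = 1)."""
        return self._lfdr.get(gene, 1.0)

    def has(self, gene: str) -> bool:
        return gene in self._lfdr

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    @classmethod
    def from_lfdr(cls, lfdrs: Mapping[str, float]) -> "GeneScoreTable":
        """Wrap precomputed local FDRs (no p-values available)."""
        df = pd.DataFrame(
            {
                "gene": list(lfdrs),
                "pvalue": np.nan,
                "zscore": np.nan,
                "lfdr": [float(v) for v in lfdrs.values()],
            }
        )
        if ((df["lfdr"] < 0) | (df["lfdr"] > 1)).any():
            raise ValueError("local FDRs must lie in [0, 1]")
        return cls(table=df)


@dataclass
class SeedList:
    """Seeds ordered by how many other seeds sit among their neighbours."""

    seeds: list[str]
    ordering_key: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.seeds)

    def __len__(self) -> int:
        return len(self.seeds)


def _lindsey_density(
    z: np.ndarray, bins: int, degree: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the marginal density f(z) by Lindsey's method.

    Histogram counts are modelled as Poisson with log-mean polynomial in
    the bin centre; returns (bin centres, fitted density at centres,
    polynomial coefficients in the scaled variable).  Falls back to a
    unimodal isotonic fit if the GLM fails.
    """
    import statsmodels.api as sm

    lo, hi = z.min() - 0.1, z.max() + 0.1
    edges = np.linspace(lo, hi, bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    # scale to [-1, 1] for a well-conditioned polynomial basis
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    t = (centers - mid) / half
    X = np.vander(t, degree + 1, increasing=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit(maxiter=200)
        if not np.all(np.isfinite(fit.params)):
            raise RuntimeError("non-finite GLM coefficients")
        mu = fit.predict(X)
        coef = fit.params
    except Exception:  # density fit failed; unimodal monotone fallback
        warnings.warn(
            "Poisson density regression failed; falling back to a monotone "
            "(unimodal isotonic) density estimate",
            stacklevel=2,
        )
        from scipy.optimize import isotonic_regression

        logc = np.log(counts + 0.5)
        kmode = int(np.argmax(np.convolve(counts, np.ones(5) / 5, mode="same")))
        left = isotonic_regression(logc[: kmode + 1], increasing=True).x
        right = isotonic_regression(logc[kmode:], increasing=False).x
        mu = np.exp(np.concatenate([left, right[1:]]))
        coef = None
    dens = mu / (len(z) * width)
    return centers, dens, (coef, mid, half, len(z), width)


def _eval_density(z: np.ndarray, model) -> np.ndarray:
    coef, mid, half, n, width = model
    t = (np.asarray(z, dtype=float) - mid) / half
    X = np.vander(t, len(coef), increasing=True)
    return np.exp(X @ coef) / (n * width)


def _empirical_null_central_matching(
    centers: np.ndarray, dens: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """Null centre and scale by central matching.

    Fits a quadratic to log f(z) (the smoothed marginal density) over the
    central half of the z range; if the null dominates there, the marginal
    is proportional to the null density, so the quadratic coefficients
    yield the null mean and standard deviation directly.  Falls back to the
    theoretical N(0, 1) null if the fitted curvature is not concave.
    """
    zmin, zmax = z.min(), z.max()
    span = zmax - zmin
    win = (
        (centers >= zmin + 0.25 * span)
        & (centers <= zmax - 0.25 * span)
        & (dens > 0)
    )
    if win.sum() < 5:
        warnings.warn("central window too small for an empirical null; using N(0,1)",
                      stacklevel=3)
        return 0.0, 1.0
    c2, c1, _ = np.polyfit(
        centers[win], np.log(dens[win]), deg=2, w=np.sqrt(dens[win])
    )
    if c2 >= 0:
        warnings.warn(
            "empirical-null curvature is not concave; using N(0,1)", stacklevel=3
        )
        return 0.0, 1.0
    sd0 = float(np.sqrt(-1.0 / (2.0 * c2)))
    mu0 = float(c1 * sd0**2)
    return mu0, sd0


def estimate_local_fdr(
    pvalues: Mapping[str, float],
    null: str = "theoretical",
    df: int = 7,
    bins: int = 120,
) -> GeneScoreTable:
    """Estimate per-gene local FDRs from p-values by the two-groups model.

    Parameters
    ----------
    pvalues
        Map gene -> p-value in [0, 1].
    null
        ``"theoretical"`` uses the standard normal null; ``"empirical"``
        fits the null centre and scale by central matching on the smoothed
        marginal density.
    df
        Degree of the polynomial basis in Lindsey's Poisson regression.
    bins
        Number of histogram bins.
    """
    genes = list(pvalues)
    p = np.asarray([pvalues[g] for g in genes], dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(genes) < 200:
        warnings.warn(
            f"only {len(genes)} p-values; local FDR density estimation may be "
            "unstable below ~200 genes",
            stacklevel=2,
        )
    if np.ptp(p) == 0:
        raise ValueError("degenerate input: all p-values identical")
    pc = np.clip(p, P_CLIP, 1 - P_CLIP)
    z = stats.norm.isf(pc)  # Phi^-1(1 - p): large z = significant

    centers, dens, model = _lindsey_density(z, bins=bins, degree=df)
    coef = model[0]

    if null == "theoretical":
        mu0, sd0 = 0.0, 1.0
    elif null == "empirical":
        mu0, sd0 = _empirical_null_central_matching(centers, dens, z)
    else:
        raise ValueError(f"unknown null model {null!r}")
    f0_centers = stats.norm.pdf(centers, mu0, sd0)
    f0_z = stats.norm.pdf(z, mu0, sd0)

    # pi0: largest constant with pi0 * f0 <= f over the central half of the
    # z range (signal lives in the right tail, so the centre is null-driven)
    zmin, zmax = z.min(), z.max()
    span = zmax - zmin
    wlo, whi = zmin + 0.25 * span, zmax - 0.25 * span
    win = (centers >= wlo) & (centers <= whi) & (f0_centers > 0) & (dens > 0)
    if not win.any():
        win = (f0_centers > 0) & (dens > 0)
    pi0 = float(min(1.0, np.min(dens[win] / f0_centers[win])))

    if coef is not None:
        f_z = _eval_density(z, model)
    else:  # fallback fit: interpolate the histogram-level density
        f_z = np.interp(z, centers, dens)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfdr = np.where(f_z > 0, pi0 * f0_z / f_z, 1.0)
    lfdr = np.minimum(1.0, lfdr)
    # enforce right-tail monotonicity: beyond the null mode a larger z never
    # gets a larger lfdr (removes polynomial edge wiggle)
    order = np.argsort(z)
    lf_sorted = lfdr[order].copy()
    tail = z[order] > mu0
    lf_sorted[tail] = np.minimum.accumulate(lf_sorted[tail])
    lfdr = np.empty_like(lf_sorted)
    lfdr[order] = lf_sorted

    table = pd.DataFrame({"gene": genes, "pvalue": p, "zscore": z, "lfdr": lfdr})
    return GeneScoreTable(table=table, pi0=pi0)


def subnetwork_fdr(S_physical: Iterable[str], table: GeneScoreTable) -> float:
    """FDR of a subnetwork: mean lfdr over its distinct physical genes."""
    genes = set(S_physical)
    if not genes:
        raise ValueError("subnetwork is empty")
    missing = [g for g in genes if not table.has(g)]
    if missing:
        warnings.warn(
            f"{len(missing)} unscored gene(s) treated as lfdr = 1", stacklevel=2
        )
    return float(np.mean([table.lfdr(g) for g in genes]))


def select_and_order_seeds(
    table: GeneScoreTable,
    B: float,
    aggregate: LayerNetwork,
    walkable: Iterable[str] | None = None,
) -> SeedList:
    """Seeds are genes with lfdr < B, ordered by descending count of other
    seeds among their direct neighbours in the aggregated network (ties
    broken lexicographically)."""
    if not 0 < B < 1:
        raise ValueError("B must be in (0, 1)")
    walk_ok = set(walkable) if walkable is not None else None
    seeds = {
        g
        for g, lf in zip(table.table["gene"], table.table["lfdr"])
        if lf < B and (walk_ok is None or g in walk_ok)
    }
    if not seeds:
        return SeedList(seeds=[], ordering_key={})
    neighbors: dict[str, set[str]] = {}
    for e in aggregate.edges:
        a, b = tuple(e)
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    key = {s: len(neighbors.get(s, set()) & seeds) for s in seeds}
    ordered = sorted(seeds, key=lambda g: (-key[g], g))
    return SeedList(seeds=ordered, ordering_key=key)


def combine_min_lfdr(tables: Iterable[GeneScoreTable]) -> GeneScoreTable:
    """Per-gene minimum lfdr across data types (lfdrs are comparable
    across data types, unlike raw p-values)."""
    combined: dict[str, float] = {}
    for t in tables:
        for g, lf in zip(t.table["gene"], t.table["lfdr"]):
            combined[g] = min(combined.get(g, 1.0), float(lf))
    return GeneScoreTable.from_lfdr(combined)
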