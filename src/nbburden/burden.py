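"""Region-level burden testing.

A fitted background model predicts, for every training bin, the pooled
mutation mean ``mu`` (per bin length ``l``) and overdispersion
``sigma``.  A test region of length ``l_k <= l`` inherits parameters
either from the training bin whose center is nearest its midpoint
(approximation scheme, the default) or from a fresh covariate
evaluation on an ``l``-long window centered on the region (optimal
scheme); the mean is then scaled by ``l_k / l``.  Observed counts in
the region give a one-sided upper-tail p-value, Benjamini-Hochberg
adjustment controls the FDR within a disease, and Fisher's method
(-2 sum ln p ~ chi^2 with 2D df) combines evidence across diseases or
across the member genes of a pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nbmodel import P_FLOOR, NBRegressionModel, nb_tail_pvalue

logger = logging.getLogger(__name__)


@dataclass
class TestRegion:
    """A target element: single interval or a merged multi-interval set."""

    chrom: str
    start: int
    end: int
    name: str
    intervals: list[tuple[int, int]] | None = None

    def __post_init__(self):
        if self.intervals is None:
            self.intervals = [(self.start, self.end)]
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad region bounds for {self.name}")

    @property
    def length(self) -> int:
        """Summed interval length l_k."""
        return sum(e - s for s, e in self.intervals)

    @property
    def midpoint(self) -> float:
        """Midpoint of the bounding span, used as the covariate anchor."""
        return (self.start + self.end) / 2.0


@dataclass
class RegionParams:
    """Length-adjusted NB parameters for one region."""

    mu: float
    sigma: float
    source_bin: int | str


def extend_region(region: TestRegion, l: int, chrom_length: int) -> tuple[int, int]:
    """Window of length ``l`` centered on the region, clipped to the chromosome.

    Used by the optimal scheme to recompute covariates at training
    resolution.  Near a chromosome end the window is shifted inward so
    it keeps full length.
    """
    if chrom_length < l:
        raise ValueError("chromosome shorter than the training bin length")
    if region.length > l:
        raise ValueError("region longer than the training bin length")
    mid = region.midpoint
    start = int(round(mid - l / 2.0))
    start = max(0, min(start, chrom_length - l))
    return start, start + l


def nearest_training_bin(region: TestRegion, bins: pd.DataFrame) -> int:
    """Usable bin whose center is closest to the region midpoint.

    Ties break toward the lower coordinate.
    """
    cand = bins[(bins["chrom"] == region.chrom) & bins["usable"]]
    if not len(cand):
        raise ValueError(f"no usable training bin on chromosome {region.chrom}")
    centers = (cand["start"].to_numpy() + cand["end"].to_numpy()) / 2.0
    dist = np.abs(centers - region.midpoint)
    best = np.flatnonzero(dist == dist.min())
    starts = cand["start"].to_numpy()[best]
    return int(cand["index"].to_numpy()[best[np.argmin(starts)]])


def region_params(
    region: TestRegion,
    model: NBRegressionModel,
    bins: pd.DataFrame,
    bin_mu: np.ndarray,
    scheme: str = "approx",
    covariate_fn=None,
    pca=None,
    chrom_sizes: dict[str, int] | None = None,
) -> RegionParams:
    """Length-adjusted (mu_k, sigma_k) for one region.

    ``bin_mu`` holds the model's per-bin predicted means, indexed by the
    global bin index.  The approx scheme copies the nearest usable
    bin's prediction; the optimal scheme recomputes covariates on the
    extended window with ``covariate_fn(chrom, start, end) -> raw
    feature vector`` and projects through ``pca``.  The mean is scaled
    by ``l_k / l``; sigma is not length-adjusted (it captures
    population heterogeneity, not exposure).
    """
    lengths = (bins["end"] - bins["start"]).unique()
    l = int(lengths[0])
    factor = region.length / l
    if scheme == "optimal":
        if covariate_fn is None or pca is None or chrom_sizes is None:
            logger.warning(
                "optimal scheme requires covariate_fn/pca/chrom_sizes; "
                "falling back to nearest-bin approximation for %s",
                region.name,
            )
            scheme = "approx"
        else:
            start, end = extend_region(region, l, chrom_sizes[region.chrom])
            x = covariate_fn(region.chrom, start, end)
            if x is None:
                logger.warning(
                    "covariates unavailable for extended bin of %s; using approx",
                    region.name,
                )
                scheme = "approx"
            else:
                scores = pca.transform(np.asarray(x, dtype=float))
                mu_bin = float(model.predict_mu(scores)[0])
                sigma = float(model.predict_sigma(scores)[0])
                return RegionParams(mu=mu_bin * factor, sigma=sigma, source_bin="extended")
    idx = nearest_training_bin(region, bins)
    mu_bin = float(bin_mu[idx])
    if model.constant_sigma:
        sigma = model.sigma
    else:
        sigma = float(model.predict_sigma(np.zeros((1, len(model.beta) - 1)))[0])
    return RegionParams(mu=mu_bin * factor, sigma=sigma, source_bin=idx)


def count_in_regions(catalog: pd.DataFrame, regions: list[TestRegion]) -> pd.DataFrame:
    """Observed pooled counts per (region, disease), half-open intersection."""
    diseases = sorted(catalog["disease"].unique()) if len(catalog) else []
    out = pd.DataFrame(
        0, index=[r.name for r in regions], columns=diseases, dtype=np.int64
    )
    by_chrom: dict[str, dict[str, np.ndarray]] = {}
    for (chrom, disease), grp in catalog.groupby(["chrom", "disease"]):
        by_chrom.setdefault(chrom, {})[disease] = np.sort(grp["pos"].to_numpy())
    for region in regions:
        per_d = by_chrom.get(region.chrom, {})
        for d, pos in per_d.items():
            y = 0
            for s, e in region.intervals:
                y += int(
                    np.searchsorted(pos, e, "left") - np.searchsorted(pos, s, "left")
                )
            out.loc[region.name, d] = y
    return out


def region_pvalue(y_obs: int, params: RegionParams) -> float:
    """Upper-tail NB p-value for the observed region count."""
    return float(nb_tail_pvalue(y_obs, mu=params.mu, sigma=params.sigma))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(pvalues) -> tuple[float, float, int]:
    """Fisher combination: T = -2 sum ln p, p_comb from chi^2 with 2D df.

    Missing entries (NaN) are skipped and the effective number of
    combined p-values D is returned alongside.  Zeros are floored at
    1e-300 before the log.
    """
    p = np.asarray(pvalues, dtype=float)
    keep = ~np.isnan(p)
    if keep.sum() == 0:
        raise ValueError("no p-values to combine")
    p = np.clip(p[keep], P_FLOOR, 1.0)
    D = int(keep.sum())
    T = float(-2.0 * np.log(p).sum()) + 0.0  # avoid negative zero
    return T, float(stats.chi2.sf(T, 2 * D)), D


def network_pvalue(member_pvalues) -> tuple[float, float, int]:
    """Pathway-level Fisher combination over member-gene p-values.

    Members without a p-value (NaN) are dropped and the effective M
    returned; with M = 1 the result equals the single input p exactly.
    """
    return fisher_combine(member_pvalues)


@dataclass
class BurdenResult:
    """Per-disease and combined burden table for a set of regions."""

    per_disease: pd.DataFrame  # region, disease, y, mu, sigma, p, p_bh
    combined: pd.DataFrame  # region, T, fisher_p, fisher_p_bh, n_diseases
    floored: int = 0


def test_regions(
    regions: list[TestRegion],
    catalog: pd.DataFrame,
    model: NBRegressionModel | dict[str, NBRegressionModel],
    bins: pd.DataFrame,
    bin_mu_by_disease: dict[str, np.ndarray],
    scheme: str = "approx",
    **scheme_kwargs,
) -> BurdenResult:
    """Full burden test: parameters, p-values, BH, Fisher combination.

    ``bin_mu_by_disease`` maps each disease to its per-bin predicted
    means (global bin index ordering); ``model`` is one shared model or
    a per-disease mapping.  BH families are per disease across the
    supplied region set; the combined table applies BH to the Fisher
    p-values across regions.
    """
    counts = count_in_regions(catalog, regions)
    diseases = list(counts.columns)
    rows = []
    for d in diseases:
        d_model = model[d] if isinstance(model, dict) else model
        for region in regions:
            params = region_params(
                region, d_model, bins, bin_mu_by_disease[d], scheme=scheme, **scheme_kwargs
            )
            y = int(counts.loc[region.name, d])
            rows.append(
                {
                    "region": region.name,
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "disease": d,
                    "y": y,
                    "mu": params.mu,
                    "sigma": params.sigma,
                    "p": region_pvalue(y, params),
                }
            )
    per_disease = pd.DataFrame(rows)
    per_disease["p_bh"] = np.nan
    for d in diseases:
        mask = per_disease["disease"] == d
        per_disease.loc[mask, "p_bh"] = bh_adjust(per_disease.loc[mask, "p"])

    floored = int((per_disease["p"] <= P_FLOOR).sum())
    combined_rows = []
    for region in regions:
        ps = per_disease.loc[per_disease["region"] == region.name, "p"].to_numpy()
        T, p_comb, D = fisher_combine(ps)
        combined_rows.append(
            {"region": region.name, "T": T, "fisher_p": p_comb, "n_diseases": D}
        )
    combined = pd.DataFrame(combined_rows)
    combined["fisher_p_bh"] = bh_adjust(combined["fisher_p"])
    order = {r.name: (r.chrom, r.start, r.name) for r in regions}
    per_disease = per_disease.sort_values(
        ["disease", "chrom", "start", "region"], kind="stable"
    ).reset_index(drop=True)
    combined = (
        combined.assign(_k=combined["region"].map(order))
        .sort_values("_k")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    return BurdenResult(per_disease=per_disease, combined=combined, floored=floored)


def test_networks(
    gene_sets: dict[str, list[str]], per_gene_p: pd.DataFrame
) -> pd.DataFrame:
    """Pathway burden: Fisher-combine member-gene p-values per disease.

    ``per_gene_p`` is regions x diseases; members missing from the table
    are dropped with a warning.  BH is applied across pathways within
    each disease.
    """
    rows = []
    for name, members in gene_sets.items():
        known = [m for m in members if m in per_gene_p.index]
        missing = len(members) - len(known)
        if missing:
            logger.warning("gene set %s: %d members without p-values", name, missing)
        if not known:
            logger.warning("gene set %s empty after dropping; skipped", name)
            continue
        for d in per_gene_p.columns:
            T, p, M = network_pvalue(per_gene_p.loc[known, d].to_numpy())
            rows.append(
                {"pathway": name, "disease": d, "T": T, "p": p, "n_members": M}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = np.nan
        for d in out["disease"].unique():
            mask = out["disease"] == d
            out.loc[mask, "p_bh"] = bh_adjust(out.loc[mask, "p"])
    return out.reset_index(drop=True)
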