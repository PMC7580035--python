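"""Synthetic data generation for end-to-end pipeline testing.

The generator emulates the full input stack: correlated genomic signal
tracks driven by a low-rank latent factor field, a per-bin true mean
``mu_i = exp(beta . x'_i)`` defined on the PCA scores of those tracks,
per-sample Gamma-distributed rates, Poisson counts, and variant
positions scattered uniformly within bins.  All randomness flows from a
single seed through named substreams (tracks, rates, positions,
permutation) so each component is independently reproducible.

Defaults describe a cohort of 50 whole genomes over a 2 Gb two-
chromosome genome gridded at 1 Mb (2000 training bins), three covariate
tracks from a rank-2 latent field, regression coefficients
(1.0, 0.5, -0.3, 0.2) and overdispersion sigma = 0.2 — a sparsely
mutated cohort of a few variants per Mb.  ``cohort_config`` scales the
intercept up to a heavily pooled cohort (~2000 pooled mutations per Mb)
for burden-calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .covariates import fit_pca
from .grid import make_bins

_SUBSTREAMS = ("tracks", "rates", "positions", "permutation", "hotspots")


@dataclass
class SyntheticConfig:
    """Generating conditions for one synthetic study."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000_000, "chr2": 1_000_000_000}
    )
    bin_length: int = 1_000_000
    n_features: int = 3
    factor_rank: int = 2
    noise_sd: float = 0.5
    samples: dict[str, int] = field(default_factory=lambda: {"D1": 50})
    beta: dict[str, tuple] | tuple = (1.0, 0.5, -0.3, 0.2)
    sigma: dict[str, float] | float = 0.2

    def beta_for(self, disease: str) -> np.ndarray:
        b = self.beta[disease] if isinstance(self.beta, dict) else self.beta
        return np.asarray(b, dtype=float)

    def sigma_for(self, disease: str) -> float:
        return float(
            self.sigma[disease] if isinstance(self.sigma, dict) else self.sigma
        )


def cohort_config(**overrides) -> SyntheticConfig:
    """A heavily pooled cohort: ~100 genomes, ~2000 pooled mutations/Mb."""
    cfg = SyntheticConfig(
        samples={"D1": 100}, beta=(7.6, 0.3, -0.2, 0.1), sigma=0.2
    )
    return replace(cfg, **overrides)


@dataclass
class SimulatedData:
    """Tracks, catalog and the generating truth for recovery tests."""

    bins: pd.DataFrame
    tracks: dict[str, pd.DataFrame]
    catalog: pd.DataFrame
    truth: dict


def _substreams(seed) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_SUBSTREAMS, children)}


def simulate_dataset(config: SyntheticConfig, seed: int = 0) -> SimulatedData:
    """Generate tracks, a variant catalog and the truth record.

    Covariate tracks are rendered as per-bin-constant bedGraph frames;
    the true per-bin mean is ``exp(beta . [1, x'_1..x'_k])`` on the PCA
    scores of the generated covariate matrix, so refitting the same
    pipeline on the emitted tracks targets exactly the stored ``beta``.
    """
    rngs = _substreams(seed)
    bins = make_bins(config.chrom_sizes, config.bin_length)
    n = len(bins)
    if n == 0:
        raise ValueError("configuration produces no bins")

    rng_t = rngs["tracks"]
    Z = rng_t.standard_normal((n, config.factor_rank))
    W = rng_t.standard_normal((config.factor_rank, config.n_features))
    F = Z @ W + config.noise_sd * rng_t.standard_normal((n, config.n_features))
    tracks = {
        f"track{j}": pd.DataFrame(
            {
                "chrom": bins["chrom"],
                "start": bins["start"],
                "end": bins["end"],
                "value": F[:, j],
            }
        )
        for j in range(config.n_features)
    }
    pca = fit_pca(pd.DataFrame(F, columns=[f"track{j}" for j in range(config.n_features)]))
    scores = pca.scores

    rng_r = rngs["rates"]
    rng_p = rngs["positions"]
    bin_starts = bins["start"].to_numpy()
    bin_chroms = bins["chrom"].to_numpy()
    records = []
    truth_mu = {}
    for disease, s_d in config.samples.items():
        beta = config.beta_for(disease)
        sigma = config.sigma_for(disease)
        k = len(beta) - 1
        if k > scores.shape[1]:
            raise ValueError("beta longer than available PCs")
        eta = beta[0] + scores[:, :k] @ beta[1:]
        if eta.max() > 50:
            raise ValueError(
                "linear predictor overflows exp(); rescale the coefficients"
            )
        mu = np.exp(eta)
        truth_mu[disease] = mu
        if sigma > 0:
            lam = rng_r.gamma(
                1.0 / (sigma * s_d), (mu * sigma)[:, None], size=(n, s_d)
            )
        else:
            lam = np.repeat((mu / s_d)[:, None], s_d, axis=1)
        counts = rng_r.poisson(lam)  # n x s_d
        bin_idx, sample_idx = np.nonzero(counts)
        reps = counts[bin_idx, sample_idx]
        bin_rep = np.repeat(bin_idx, reps)
        sample_rep = np.repeat(sample_idx, reps)
        offsets = rng_p.integers(0, config.bin_length, size=len(bin_rep))
        records.append(
            pd.DataFrame(
                {
                    "chrom": bin_chroms[bin_rep],
                    "pos": bin_starts[bin_rep] + offsets,
                    "sample": pd.Series(sample_rep).map(lambda s: f"{disease}_s{s}"),
                    "disease": disease,
                }
            )
        )
    catalog = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["chrom", "pos", "sample", "disease"])
    )
    catalog = catalog.sort_values(["disease", "sample", "chrom", "pos"]).reset_index(
        drop=True
    )
    truth = {
        "beta": {d: config.beta_for(d).tolist() for d in config.samples},
        "sigma": {d: config.sigma_for(d) for d in config.samples},
        "mu": truth_mu,
        "scores": scores,
        "pca": pca,
        "config": config,
    }
    return SimulatedData(bins=bins, tracks=tracks, catalog=catalog, truth=truth)


def inject_hotspots(
    data: SimulatedData,
    elements: list,
    fold: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Return a catalog with extra mutations concentrated in elements.

    For each element and disease, the expected element-level mean
    ``mu_k = mu_bin * l_k / l`` is raised by ``(fold - 1) * mu_k``
    additional Poisson-distributed variants placed uniformly inside the
    element and assigned to random samples.
    """
    rng = _substreams(seed)["hotspots"]
    cfg = data.truth["config"]
    l = cfg.bin_length
    bin_lookup = {
        (row.chrom, row.start // l): row.index
        for row in data.bins.itertuples(index=False)
    }
    extra = []
    for element in elements:
        key = (element.chrom, element.start // l)
        idx = bin_lookup.get(key)
        if idx is None:
            continue
        for disease in cfg.samples:
            mu_k = data.truth["mu"][disease][idx] * element.length / l
            n_extra = rng.poisson((fold - 1.0) * mu_k)
            if n_extra == 0:
                continue
            pos = rng.integers(element.start, element.end, size=n_extra)
            samples = rng.integers(0, cfg.samples[disease], size=n_extra)
            extra.append(
                pd.DataFrame(
                    {
                        "chrom": element.chrom,
                        "pos": pos,
                        "sample": [f"{disease}_s{s}" for s in samples],
                        "disease": disease,
                    }
                )
            )
    if not extra:
        return data.catalog.copy()
    return pd.concat([data.catalog] + extra, ignore_index=True)


def permute_variants(
    catalog: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Relocate each variant uniformly within +/- ``window`` bp.

    The new position is drawn uniformly from
    ``[pos - window, pos + window]`` intersected with the chromosome,
    same chromosome/sample/disease.  Catalog size and per-chromosome
    totals are preserved exactly.
    """
    rng = _substreams(seed)["permutation"]
    out = catalog.copy()
    pos = out["pos"].to_numpy(dtype=np.int64)
    sizes = out["chrom"].map(chrom_sizes).to_numpy(dtype=np.int64)
    lo = np.maximum(pos - window, 0)
    hi = np.minimum(pos + window, sizes - 1)
    out["pos"] = lo + (rng.random(len(out)) * (hi - lo + 1)).astype(np.int64)
    return out
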