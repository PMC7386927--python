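"""Population-genetic summaries: Weir-Cockerham F_ST, windowed nucleotide
diversity, homozygosity, MAF, LD pruning, and PCA.

All estimators operate directly on the dosage matrix and treat the missing
sentinel as unobserved.  The F_ST estimator is the Weir & Cockerham (1984)
variance-components form, which partitions allelic variance at each
biallelic site into among-population (a), among-individuals-within-
population (b), and within-individual (c) components; theta = a/(a+b+c).
Negative per-site (and even genome-wide) estimates are expected when true
differentiation is near zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# simple per-sample / per-site summaries
# ---------------------------------------------------------------------------


def homozygosity(G: GenotypeMatrix) -> pd.Series:
    """Per-sample fraction of non-missing genotypes that are homozygous."""
    obs = ~G.missing_mask
    hom = np.isin(G.dosages, (0, 2)) & obs
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_obs > 0, hom.sum(axis=1) / n_obs, np.nan)
    return pd.Series(frac, index=G.sample_ids, name="homozygosity")


def maf(G: GenotypeMatrix) -> np.ndarray:
    """Per-site minor-allele frequency among non-missing alleles.

    NaN for sites with no observed genotypes.
    """
    obs = ~G.missing_mask
    alt = np.where(obs, G.dosages, 0).sum(axis=0)
    n_alleles = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / n_alleles, np.nan)
    return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    """Per-site W&C variance components and the two genome-wide summaries.

    ``theta_weighted`` is the ratio-of-sums (sum a / sum (a+b+c)), the
    headline estimate; ``theta_mean`` is the mean of per-site ratios.
    """

    per_site: pd.DataFrame  # chrom, pos, a, b, c, theta
    theta_weighted: float
    theta_mean: float
    n_sites_used: int
    n_sites_skipped: int

    def windowed(self, window_bp: int = 500_000) -> pd.DataFrame:
        """Mean per-site theta over non-overlapping windows."""
        df = self.per_site.dropna(subset=["theta"]).copy()
        df["start"] = ((df["pos"] - 1) // window_bp) * window_bp + 1
        out = (
            df.groupby(["chrom", "start"], sort=True)["theta"]
            .agg(["mean", "size"])
            .reset_index()
            .rename(columns={"mean": "theta", "size": "n_sites"})
        )
        out["end"] = out["start"] + window_bp - 1
        return out[["chrom", "start", "end", "n_sites", "theta"]]


def weir_cockerham_fst(
    G: GenotypeMatrix, pop_labels: Sequence[Optional[str]]
) -> FstResult:
    """Weir & Cockerham (1984) F_ST over two or more populations.

    ``pop_labels`` aligns with ``G.samples``; ``None`` excludes a sample.
    Sites where fewer than two populations have a genotyped sample (or where
    the average sample size is 1) are skipped and counted.
    """
    labels = np.array([l if l is not None else "" for l in pop_labels], dtype=object)
    if len(labels) != G.n_samples:
        raise ValueError("pop_labels length must match number of samples")
    pops = sorted({l for l in labels if l})
    r = len(pops)
    if r < 2:
        raise ValueError("need at least 2 populations")

    obs = ~G.missing_mask
    # per population, per site: sample counts, alt freq, observed het freq
    n_i = np.empty((r, G.n_sites))
    p_i = np.empty((r, G.n_sites))
    h_i = np.empty((r, G.n_sites))
    for k, pop in enumerate(pops):
        rows = labels == pop
        if not rows.any():
            raise ValueError(f"population {pop!r} has no samples")
        o = obs[rows]
        d = np.where(o, G.dosages[rows], 0)
        n_i[k] = o.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = d.sum(axis=0) / (2 * n_i[k])
            h_i[k] = ((d == 1) & o).sum(axis=0) / n_i[k]

    usable = (n_i > 0).sum(axis=0) >= 2
    nbar = np.where(usable, n_i.mean(axis=0), np.nan)
    usable &= nbar > 1  # the b component divides by nbar - 1
    N = r * nbar
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (N - (n_i**2).sum(axis=0) / N) / (r - 1)
        pbar = (n_i * np.nan_to_num(p_i)).sum(axis=0) / N
        s2 = (n_i * (np.nan_to_num(p_i) - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * np.nan_to_num(h_i)).sum(axis=0) / N

        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
        a = nbar / n_c * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)

    per_site = pd.DataFrame(
        {
            "chrom": G.sites["chrom"],
            "pos": G.sites["pos"],
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )
    informative = usable & (denom != 0) & np.isfinite(denom)
    theta_weighted = float(
        np.nansum(np.where(informative, a, 0.0))
        / np.nansum(np.where(informative, denom, np.nan))
    )
    theta_mean = float(np.nanmean(np.where(informative, theta, np.nan)))
    return FstResult(
        per_site,
        theta_weighted,
        theta_mean,
        int(informative.sum()),
        int(G.n_sites - informative.sum()),
    )


# ---------------------------------------------------------------------------
# windowed nucleotide diversity
# ---------------------------------------------------------------------------


@dataclass
class PiWindows:
    """Nucleotide diversity per fixed-size genomic window.

    Window pi sums per-site pairwise-difference probabilities over the
    window's variant sites and divides by the full window length in bp
    (also for the final partial window), yielding per-bp diversity.
    """

    windows: pd.DataFrame  # chrom, start, end, n_sites, pi
    window_bp: int

    def by_chromosome(self) -> pd.Series:
        """Mean window pi per chromosome."""
        return self.windows.groupby("chrom")["pi"].mean()

    @property
    def mean_pi(self) -> float:
        return float(self.windows["pi"].mean())

    def write(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)


def windowed_pi(G: GenotypeMatrix, window_bp: int = 500_000) -> PiWindows:
    """Nucleotide diversity in non-overlapping windows tiling each chromosome.

    Per site, with ``c_ref`` and ``c_alt`` the allele counts among
    non-missing calls and ``n = c_ref + c_alt``, the unbiased per-site value
    is ``2 * c_ref * c_alt / (n * (n - 1))``.  Windows start at position 1
    and tile through the last genotyped position of each chromosome; windows
    with no variant site report pi = 0.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    obs = ~G.missing_mask
    c_alt = np.where(obs, G.dosages, 0).sum(axis=0).astype(float)
    n = 2.0 * obs.sum(axis=0)
    c_ref = n - c_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(n >= 2, 2.0 * c_ref * c_alt / (n * (n - 1.0)), np.nan)

    rows = []
    chroms = G.sites["chrom"].astype(str).to_numpy()
    pos = G.sites["pos"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        max_pos = int(pos[sel].max())
        n_windows = (max_pos - 1) // window_bp + 1
        widx = (pos[sel] - 1) // window_bp
        p = np.nan_to_num(pi_site[sel], nan=0.0)
        variant = p > 0
        sums = np.bincount(widx, weights=p, minlength=n_windows)
        counts = np.bincount(widx[variant], minlength=n_windows)
        for w in range(n_windows):
            rows.append(
                (chrom, w * window_bp + 1, (w + 1) * window_bp,
                 int(counts[w]), sums[w] / window_bp)
            )
    return PiWindows(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi"]),
        window_bp,
    )


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage columns, pairwise-complete.

    ``X`` is samples x sites with NaN for missing.  Pairs with fewer than 2
    jointly observed samples or zero variance get r^2 = 0.
    """
    M = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X)
    n = M.T @ M
    sx = X0.T @ M
    sxx = (X0**2).T @ M
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        r2 = cov**2 / (varx * varx.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(
    G: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.3,
    maf_min: float = 0.01,
) -> np.ndarray:
    """Indices of sites retained after sliding-window LD pruning.

    Sites with MAF below ``maf_min`` are removed first.  Windows of
    ``window_snps`` surviving sites advance by ``step_snps`` within each
    chromosome; while any retained pair in the window has r^2 above
    ``r2_max``, the member of the worst pair with the lower MAF is removed
    (tie: the later position).  Deterministic by construction.
    """
    m = maf(G)
    keep = np.nan_to_num(m, nan=0.0) >= maf_min
    chroms = G.sites["chrom"].astype(str).to_numpy()
    pos = G.sites["pos"].to_numpy()
    X = np.where(G.missing_mask, np.nan, G.dosages.astype(float))

    for chrom in dict.fromkeys(chroms):
        cidx = np.flatnonzero((chroms == chrom) & keep)
        if cidx.size < 2:
            continue
        start = 0
        while start < cidx.size:
            widx = cidx[start : start + window_snps]
            live = keep[widx]
            if live.sum() >= 2:
                r2 = _pairwise_r2(X[:, widx])
                np.fill_diagonal(r2, 0.0)
                while True:
                    r2w = np.where(np.outer(live, live), r2, 0.0)
                    worst = r2w.max()
                    if worst <= r2_max:
                        break
                    i, j = np.unravel_index(np.argmax(r2w), r2w.shape)
                    si, sj = widx[i], widx[j]
                    # drop the lower-MAF member; tie -> later position
                    if (m[si], -pos[si]) < (m[sj], -pos[sj]):
                        drop = i
                    else:
                        drop = j
                    live[drop] = False
                    keep[widx[drop]] = False
            if start + window_snps >= cidx.size:
                break
            start += step_snps
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    """Sample scores and per-component variance fractions."""

    scores: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray
    n_sites_used: int


def pca(
    G: GenotypeMatrix,
    n_components: int | None = None,
    maf_min: float | None = 0.01,
) -> PcaResult:
    """PCA of the column-standardised dosage matrix (center and scale).

    Sites with MAF below ``maf_min`` and monomorphic sites are removed
    first; the remaining matrix must be complete (impute or filter missing
    data beforehand).  Each component's loading vector is oriented so that
    its largest-magnitude entry is positive, fixing the arbitrary signs.
    """
    m = maf(G)
    keep = np.nan_to_num(m, nan=0.0) > 0.0
    if maf_min is not None:
        keep &= np.nan_to_num(m, nan=0.0) >= maf_min
    X = G.dosages[:, keep].astype(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 polymorphic sites for PCA")
    if (X == MISSING).any():
        raise ValueError("missing genotypes present; impute or filter first")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance site after MAF filtering")
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total = float((s**2).sum())
    ratio = s**2 / total

    k = n_components if n_components is not None else len(s)
    k = min(k, len(s))
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * s[:k]
    cols = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        pd.DataFrame(scores, index=G.sample_ids, columns=cols),
        ratio[:k],
        int(keep.sum()),
    )
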