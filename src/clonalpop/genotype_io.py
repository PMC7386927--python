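"""Genotype input/output and quality filtering.

The central container is :class:`GenotypeMatrix`: a samples x sites matrix of
diploid alternate-allele dosages (0, 1, 2, or missing) together with site
coordinates and per-sample metadata.  Coordinates are 1-based (VCF
convention).  Missing genotypes are stored as the sentinel :data:`MISSING`
(-1) and every downstream computation treats them as unobserved, never as
dosage zero.

Site filters mirror the standard GBS quality pipeline for clonal crop
collections: drop multiallelic sites, sites with excess missingness, sites
in extreme Hardy-Weinberg disequilibrium, and optionally low-MAF and
monomorphic sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing (uncalled) genotype in the dosage matrix.
MISSING: int = -1

#: Recognised source populations for a sample.
POPULATIONS = ("farmer", "breeding", "check")

#: Column order of the metadata table dialect.
METADATA_COLUMNS = (
    "sample_id",
    "district",
    "population",
    "replicate_group",
    "reported_name",
    "farmer_id",
)


@dataclass
class SampleMeta:
    """Metadata for one sampled plant.

    ``replicate_group`` is only set for check samples: independently sampled
    plants of a known genotype, used to calibrate the clonal-distance
    threshold.
    """

    sample_id: str
    district: Optional[str] = None
    population: str = "farmer"
    replicate_group: Optional[str] = None
    reported_name: Optional[str] = None
    farmer_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(
                f"population must be one of {POPULATIONS}, got {self.population!r}"
            )
        if self.replicate_group is not None and self.population != "check":
            raise ValueError(
                f"sample {self.sample_id}: replicate_group set but population "
                f"is {self.population!r}, not 'check'"
            )


@dataclass
class FilterReport:
    """Accounting for one filtering pass.

    A site (or sample) removed by several rules is attributed to the first
    rule applied, so ``removed_by`` sums to ``n_in - n_out``.
    """

    axis: str  # "sites" or "samples"
    n_in: int
    n_out: int
    removed_by: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError("n_out exceeds n_in")
        if sum(self.removed_by.values()) != self.n_in - self.n_out:
            raise ValueError("per-rule removal counts do not sum to n_in - n_out")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_in), ("output", self.n_out)]
        rows += [(f"removed_{rule}", n) for rule, n in self.removed_by.items()]
        return pd.DataFrame(rows, columns=["key", "count"]).assign(axis=self.axis)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid dosage matrix with site and sample metadata.

    Parameters
    ----------
    dosages
        Integer array of shape ``(n_samples, n_sites)`` with values in
        ``{0, 1, 2}`` or :data:`MISSING`.
    sites
        DataFrame with columns ``chrom, pos, ref, alt``, sorted by
        ``(chrom, pos)`` with unique coordinate pairs.  ``alt`` may contain a
        comma-joined allele list for multiallelic records, which survive
        reading but are removed by :func:`filter_sites`.
    samples
        One :class:`SampleMeta` per dosage row, unique sample ids.
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        self.sites = self.sites.reset_index(drop=True)
        self.validate()

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where a genotype is missing."""
        return self.dosages == MISSING

    def validate(self) -> None:
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage rows do not match number of samples")
        if self.dosages.shape[1] != len(self.sites):
            raise ValueError("dosage columns do not match number of sites")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.dosages[~ok])
            raise ValueError(f"invalid dosage values: {bad}")
        ids = self.sample_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated sample id")
        key = list(zip(self.sites["chrom"].astype(str), self.sites["pos"]))
        if len(set(key)) != len(key):
            raise ValueError("duplicated (chrom, pos) site coordinates")
        if key != sorted(key):
            raise ValueError("sites not sorted by (chrom, pos)")

    # -- subsetting ------------------------------------------------------

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset sites by positional index (order must stay sorted)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.sites.iloc[index].reset_index(drop=True),
            list(self.samples),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.sites.copy(),
            [self.samples[i] for i in index],
        )

    def subset_ids(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        """Subset samples by id, preserving the requested order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample id: {e.args[0]}") from None
        return self.take_samples(idx)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(s, c) for c in METADATA_COLUMNS] for s in self.samples],
            columns=list(METADATA_COLUMNS),
        )


# ---------------------------------------------------------------------------
# metadata table
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, SampleMeta]:
    """Read the tab-separated sample metadata dialect into a dict by id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"metadata table missing columns: {sorted(missing_cols)}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise ValueError(f"duplicated sample id in metadata: {sid}")
        out[sid] = SampleMeta(
            sample_id=sid,
            district=row["district"] or None,
            population=row["population"] or "farmer",
            replicate_group=row["replicate_group"] or None,
            reported_name=row["reported_name"] or None,
            farmer_id=row["farmer_id"] or None,
        )
    return out


def write_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [[getattr(s, c) or "" for c in METADATA_COLUMNS] for s in samples],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, metadata_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF (GT field) into a :class:`GenotypeMatrix`.

    Dosage counts non-reference alleles; ``./.`` becomes :data:`MISSING`;
    phasing is ignored.  Multiallelic records are retained at read time
    (``alt`` is comma-joined) and removed later by :func:`filter_sites`.
    Samples absent from the metadata table default to
    ``population='farmer'`` with all other fields unset; metadata ids that
    match no VCF sample produce a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if len(set(vcf_samples)) != len(vcf_samples):
        raise ValueError("duplicated sample id in VCF")

    rows = []
    dosage_cols = []
    for v in vcf:
        gts = v.genotype.array()  # (n_samples, ploidy+1); last col = phasing
        alleles = gts[:, :-1]
        miss = (alleles < 0).any(axis=1)
        dos = (alleles > 0).sum(axis=1).astype(np.int8)
        dos[miss] = MISSING
        dosage_cols.append(dos)
        rows.append((str(v.CHROM), int(v.POS), v.REF, ",".join(v.ALT) if v.ALT else "."))
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = np.column_stack(dosage_cols)

    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]

    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        unknown = set(meta) - set(vcf_samples)
        if unknown:
            warnings.warn(
                f"{len(unknown)} metadata ids match no VCF sample: "
                f"{sorted(unknown)[:5]}..."
            )
        samples = [meta.get(s, SampleMeta(sample_id=s)) for s in vcf_samples]
    else:
        samples = [SampleMeta(sample_id=s) for s in vcf_samples]

    return GenotypeMatrix(dosages, sites, samples)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 (GT only) representation of ``G``."""
    chroms = list(dict.fromkeys(G.sites["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            max_pos = int(G.sites.loc[G.sites["chrom"].astype(str) == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={max_pos + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, site in enumerate(G.sites.itertuples(index=False)):
            gts = "\t".join(_GT[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_chisq(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square deviation from Hardy-Weinberg proportions.

    Expected counts use the observed allele frequency
    ``p = (2*n_AA + n_Aa) / (2n)``: ``n*p^2, 2n*p*q, n*q^2``.  No continuity
    correction is applied, and any genotype class with expected count zero
    contributes zero (so monomorphic sites score 0).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n < 1:
        raise ValueError("no observed genotypes")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _hwe_chisq_array(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Vectorised :func:`hwe_chisq` over sites (dosage-class counts)."""
    n0 = n0.astype(float)
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n)  # alt-allele frequency
        q = 1.0 - p
        e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
        chi = np.zeros_like(n)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            chi += np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    chi[n == 0] = np.nan
    return chi


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_sites(
    G: GenotypeMatrix,
    max_missing_frac: float = 0.80,
    hwe_chisq_max: float | None = 20.0,
    biallelic_only: bool = True,
    maf_min: float | None = None,
    drop_monomorphic: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply site quality filters in a fixed order.

    Rules run in the order biallelic -> missingness -> HWE -> MAF ->
    monomorphic; each removed site is attributed to the first rule it fails.
    Thresholds are strict: a site is removed only if its missing fraction
    *exceeds* ``max_missing_frac``, its chi-square *exceeds*
    ``hwe_chisq_max``, or its MAF is strictly *below* ``maf_min``.
    """
    if G.n_sites == 0:
        raise ValueError("empty genotype matrix")
    n = G.n_sites
    alive = np.ones(n, dtype=bool)
    removed_by: dict[str, int] = {}

    def apply(rule: str, fails: np.ndarray) -> None:
        hit = alive & fails
        removed_by[rule] = int(hit.sum())
        alive[hit] = False

    if biallelic_only:
        alt = G.sites["alt"].astype(str)
        apply("multiallelic", (alt.str.contains(",") | (alt == ".")).to_numpy())

    miss_frac = (G.dosages == MISSING).mean(axis=0)
    apply("missingness", miss_frac > max_missing_frac)

    if hwe_chisq_max is not None:
        n0 = (G.dosages == 0).sum(axis=0)
        n1 = (G.dosages == 1).sum(axis=0)
        n2 = (G.dosages == 2).sum(axis=0)
        chi = _hwe_chisq_array(n0, n1, n2)
        apply("hwe", np.nan_to_num(chi, nan=0.0) > hwe_chisq_max)

    if maf_min is not None or drop_monomorphic:
        from .popgen_stats import maf as _maf

        m = _maf(G)
        if maf_min is not None:
            apply("maf", np.nan_to_num(m, nan=0.0) < maf_min)
        if drop_monomorphic:
            apply("monomorphic", np.nan_to_num(m, nan=0.0) == 0.0)

    if not alive.any():
        raise ValueError(f"all sites removed by filters: {removed_by}")

    report = FilterReport("sites", n, int(alive.sum()), removed_by)
    return G.take_sites(np.flatnonzero(alive)), report


def filter_samples(
    G: GenotypeMatrix, max_missing_frac: float = 0.80
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove samples whose missing-genotype fraction exceeds the threshold."""
    if G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    miss_frac = (G.dosages == MISSING).mean(axis=1)
    alive = miss_frac <= max_missing_frac
    if not alive.any():
        raise ValueError("all samples removed by missingness filter")
    report = FilterReport(
        "samples",
        G.n_samples,
        int(alive.sum()),
        {"missingness": int((~alive).sum())},
    )
    return G.take_samples(np.flatnonzero(alive)), report


def naive_impute(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage with the site's rounded mean dosage.

    A deliberately simple, deterministic mean-imputation used as plumbing
    before analyses that require complete data (PCA).  Halves round up.
    """
    miss = G.missing_mask
    if not miss.any():
        return replace(G, dosages=G.dosages.copy())
    obs = np.ma.masked_array(G.dosages, mask=miss)
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = np.flatnonzero(n_obs == 0)
        raise ValueError(
            f"{bad.size} sites are 100% missing (first: {bad[:5]}); "
            "run filter_sites before imputing"
        )
    means = obs.mean(axis=0).filled(0.0)
    fill = np.floor(means + 0.5).astype(G.dosages.dtype)  # round half up
    dosages = G.dosages.copy()
    dosages[miss] = np.broadcast_to(fill, G.dosages.shape)[miss]
    return replace(G, dosages=dosages)
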