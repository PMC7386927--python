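"""Wild-relative introgression scoring from diagnostic markers.

At an introgression-diagnostic marker one allele is characteristic of the
wild donor species (M. glaziovii), so summed donor-allele dosage over
diagnostic markers measures the fraction of wild ancestry a sample carries.
Profiles are reported genome-wide and inside focal regions where large
donor segments segregate in cassava germplasm (by default chromosome 1 from
25 Mb to the chromosome end and chromosome 4 from 5 to 25 Mb).  A
predominantly heterozygous donor-allele profile near 50% flags a putative
F1 hybrid between the crop and the wild donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, MISSING


@dataclass(frozen=True)
class FocalRegion:
    """Genomic interval; ``end=None`` means through the chromosome end."""

    label: str
    chrom: str
    start: int
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end is not None and self.start >= self.end:
            raise ValueError(f"region {self.label}: start must be < end")


#: Default focal regions of known donor segments.
DEFAULT_REGIONS = (
    FocalRegion("chr1", "1", 25_000_000, None),
    FocalRegion("chr4", "4", 5_000_000, 25_000_000),
)


@dataclass
class DiagnosticMarkerSet:
    """Introgression-diagnostic loci and the focal regions to score.

    ``table`` columns: ``chrom, pos, donor_allele`` with ``donor_allele`` in
    {'ref', 'alt'} naming which VCF allele is the wild-donor allele.
    """

    table: pd.DataFrame
    regions: tuple[FocalRegion, ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "donor_allele"}
        if not required <= set(self.table.columns):
            raise ValueError(f"marker table needs columns {sorted(required)}")
        bad = ~self.table["donor_allele"].isin(["ref", "alt"])
        if bad.any():
            raise ValueError("donor_allele must be 'ref' or 'alt'")
        key = list(zip(self.table["chrom"].astype(str), self.table["pos"]))
        if len(set(key)) != len(key):
            raise ValueError("duplicated (chrom, pos) in marker table")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @classmethod
    def read(cls, path: str | Path, regions: Sequence[FocalRegion] = DEFAULT_REGIONS):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int})
        return cls(df, tuple(regions))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class IntrogressionProfile:
    """Per-sample donor-allele dosage summaries.

    Columns of ``table``: ``sample_id``, ``genome_prop``, one
    ``prop_<region>`` per focal region, ``het_frac`` (fraction heterozygous
    among donor-carrying diagnostic genotypes), ``n_markers`` (non-missing
    diagnostic genotypes), and marker counts per scope.
    """

    table: pd.DataFrame
    region_labels: tuple[str, ...]
    n_markers_total: int
    n_markers_by_region: dict[str, int] = field(default_factory=dict)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _region_mask(sites: pd.DataFrame, region: FocalRegion) -> np.ndarray:
    chrom = sites["chrom"].astype(str).to_numpy()
    pos = sites["pos"].to_numpy()
    mask = chrom == region.chrom
    mask &= pos >= region.start
    if region.end is not None:
        mask &= pos <= region.end
    return mask


def donor_dosage_profile(
    G: GenotypeMatrix, M: DiagnosticMarkerSet
) -> IntrogressionProfile:
    """Per-sample donor-allele proportion genome-wide and per focal region.

    For each sample the proportion is ``sum(donor dosage) / (2 * n)`` over
    its non-missing diagnostic genotypes; markers missing in a sample are
    excluded from that sample's denominator.  ``het_frac`` is the fraction
    heterozygous among diagnostic genotypes where the sample carries at
    least one donor allele.
    """
    site_key = pd.MultiIndex.from_arrays(
        [G.sites["chrom"].astype(str), G.sites["pos"]]
    )
    marker_key = pd.MultiIndex.from_arrays(
        [M.table["chrom"].astype(str), M.table["pos"]]
    )
    pos_of = pd.Series(np.arange(len(site_key)), index=site_key)
    hit = marker_key.isin(site_key)
    if not hit.any():
        raise ValueError(
            f"none of the {M.n_markers} diagnostic markers overlap the "
            f"{G.n_sites} genotyped sites"
        )
    cols = pos_of.loc[marker_key[hit]].to_numpy()
    donor_is_alt = (M.table.loc[hit, "donor_allele"] == "alt").to_numpy()

    dos = G.dosages[:, cols].astype(float)
    miss = dos == MISSING
    donor = np.where(donor_is_alt, dos, 2.0 - dos)
    donor[miss] = np.nan

    sub_sites = G.sites.iloc[cols].reset_index(drop=True)
    scopes: dict[str, np.ndarray] = {"genome": np.ones(len(cols), dtype=bool)}
    for region in M.regions:
        scopes[region.label] = _region_mask(sub_sites, region)

    out = {"sample_id": G.sample_ids}
    n_by_region: dict[str, int] = {}
    for label, mask in scopes.items():
        d = donor[:, mask]
        n_obs = (~np.isnan(d)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.nansum(d, axis=1) / (2.0 * n_obs)
        prop = np.where(n_obs > 0, prop, np.nan)
        key = "genome_prop" if label == "genome" else f"prop_{label}"
        out[key] = prop
        n_by_region[label] = int(mask.sum())

    carrying = donor >= 1
    het = donor == 1
    n_carry = np.nansum(carrying, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_carry > 0, np.nansum(het, axis=1) / n_carry, np.nan)
    out["het_frac"] = het_frac
    out["n_markers"] = (~np.isnan(donor)).sum(axis=1)

    labels = tuple(r.label for r in M.regions)
    return IntrogressionProfile(
        pd.DataFrame(out), labels, int(len(cols)), n_by_region
    )


def flag_f1_hybrids(
    P: IntrogressionProfile,
    prop_range: tuple[float, float] = (0.30, 0.60),
    het_min: float = 0.80,
) -> pd.Series:
    """Flag putative F1 crop x wild-donor hybrids.

    A first-generation hybrid carries one donor haplotype genome-wide, so
    its donor-allele proportion sits near 0.5 with the donor alleles almost
    all heterozygous.  Flags samples with genome-wide proportion inside
    ``prop_range`` (inclusive) and heterozygous fraction >= ``het_min``.
    """
    lo, hi = prop_range
    t = P.table
    flag = (
        (t["genome_prop"] >= lo)
        & (t["genome_prop"] <= hi)
        & (t["het_frac"] >= het_min)
    )
    flag = flag.fillna(False)
    return pd.Series(flag.to_numpy(), index=t["sample_id"].to_numpy(), name="f1_flag")
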