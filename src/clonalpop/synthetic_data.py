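"""Synthetic clonal crop collections with known ground truth.

Emulates the statistical structure of a smallholder field survey of a
vegetatively propagated crop genotyped at SNP markers:

- district allele frequencies drawn around ancestral frequencies under the
  Balding-Nichols model, so a target F_ST between districts is induced;
- founder (variety) genotypes drawn site-wise Binomial(2, p), cloned into
  several field samples each, some varieties shared across districts as
  literal clonal copies;
- replicated check genotypes of known identity (default five checks with
  17, 12, 19, 18, and 6 replicates) for threshold calibration;
- genotype-level miscalls and missing calls at configurable rates;
- wild-donor introgression: a subset of varieties carry donor alleles at
  diagnostic markers inside focal donor regions (the donor allele is absent
  from the crop background, which is what makes a marker diagnostic);
- noisy farmer naming with synonyms (same clone, extra name) and homonyms
  (name reused for a different clone).

Everything is driven by a single seed; the emitted VCF + metadata + marker
table round-trip through :mod:`clonalpop.genotype_io`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    SampleMeta,
    write_metadata,
    write_vcf,
)
from .introgression import DEFAULT_REGIONS, DiagnosticMarkerSet, FocalRegion


@dataclass
class SimulationConfig:
    """Parameters of the synthetic collection.

    Defaults mirror the field-survey conditions the package is designed
    around: four districts with weak differentiation (target F_ST 0.003), 60
    founder varieties carrying 1-5 clonal field samples each, five
    replicated checks, a 0.5% genotype miscall rate and 10% missing calls.
    """

    n_chromosomes: int = 18
    chromosome_length_bp: int = 30_000_000
    n_sites: int = 5_000
    n_districts: int = 4
    fst_target: float = 0.003
    n_varieties_per_district: int = 15
    sharing_prob: float = 0.2
    clone_count_dist: str = "uniform"  # "uniform" or "geometric"
    clone_count_min: int = 1
    clone_count_max: int = 5
    clone_count_mean: float = 3.0  # geometric only
    n_farmers_per_district: int = 10
    check_replicates: tuple[int, ...] = (17, 12, 19, 18, 6)
    error_rate: float = 0.005
    missing_rate: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    introgression_fraction: float = 0.1
    diagnostic_marker_fraction: float = 0.05
    donor_regions: tuple[FocalRegion, ...] = DEFAULT_REGIONS
    donor_hom_prob: float = 0.25
    synonym_rate: float = 0.3
    homonym_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sharing_prob",
            "error_rate",
            "missing_rate",
            "introgression_fraction",
            "diagnostic_marker_fraction",
            "donor_hom_prob",
            "synonym_rate",
            "homonym_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if self.chromosome_length_bp <= 0 or self.n_chromosomes <= 0:
            raise ValueError("chromosome dimensions must be positive")
        if any(r < 2 for r in self.check_replicates):
            raise ValueError("check replicate counts must be >= 2")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["donor_regions"] = [asdict(r) for r in self.donor_regions]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "donor_regions" in d:
            d["donor_regions"] = tuple(FocalRegion(**r) for r in d["donor_regions"])
        for key in ("check_replicates", "ancestral_maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth for parameter-recovery tests."""

    samples: pd.DataFrame  # sample_id, clonal_group, district, population, ...
    ancestral_freqs: np.ndarray
    district_freqs: pd.DataFrame  # district x site frequencies
    founder_genotypes: dict[str, np.ndarray]
    carriers: set[str] = field(default_factory=set)  # clonal groups with donor segments

    def clone_labels(self, sample_ids: list[str]) -> list[str]:
        s = self.samples.set_index("sample_id")["clonal_group"]
        return [s[sid] for sid in sample_ids]


def simulate_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-district allele frequencies (Balding-Nichols).

    Ancestral frequencies are uniform on ``ancestral_maf_range``.  With
    differentiation parameter ``F = fst_target``, district frequencies are
    independent draws ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` per district and
    locus, which has mean p and variance ``p(1-p)F``.  ``F = 0`` copies the
    ancestral frequencies exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_maf_range
    p = rng.uniform(lo, hi, size=config.n_sites)
    F = config.fst_target
    if F == 0.0:
        district = np.tile(p, (config.n_districts, 1))
    else:
        scale = (1.0 - F) / F
        district = rng.beta(
            p * scale, (1.0 - p) * scale, size=(config.n_districts, config.n_sites)
        )
    return p, district


def _draw_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniformly placed SNP coordinates with random ref/alt alleles."""
    chrom_ids = [str(c + 1) for c in range(config.n_chromosomes)]
    chrom = rng.integers(config.n_chromosomes, size=config.n_sites)
    pos = rng.integers(1, config.chromosome_length_bp + 1, size=config.n_sites)
    df = pd.DataFrame(
        {"chrom": [chrom_ids[c] for c in chrom], "pos": pos}
    ).drop_duplicates()
    while len(df) < config.n_sites:  # top up collisions
        extra = config.n_sites - len(df)
        c2 = rng.integers(config.n_chromosomes, size=extra)
        p2 = rng.integers(1, config.chromosome_length_bp + 1, size=extra)
        df = pd.concat(
            [df, pd.DataFrame({"chrom": [chrom_ids[c] for c in c2], "pos": p2})]
        ).drop_duplicates()
    df = df.iloc[: config.n_sites]
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    bases = np.array(list("ACGT"))
    ref = rng.integers(4, size=config.n_sites)
    alt = (ref + rng.integers(1, 4, size=config.n_sites)) % 4
    df["ref"] = bases[ref]
    df["alt"] = bases[alt]
    return df


def _clone_counts(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if config.clone_count_dist == "uniform":
        counts = rng.integers(config.clone_count_min, config.clone_count_max + 1, size=n)
    elif config.clone_count_dist == "geometric":
        counts = rng.geometric(1.0 / config.clone_count_mean, size=n)
        counts = np.clip(counts, config.clone_count_min, None)
    else:
        raise ValueError(f"unknown clone_count_dist {config.clone_count_dist!r}")
    if (counts <= 0).all():
        raise ValueError("clone count distribution yielded zero copies everywhere")
    return counts


def _corrupt(
    g: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply genotype-level miscalls then missingness to one dosage vector."""
    out = g.copy()
    if config.error_rate > 0:
        err = rng.random(out.size) < config.error_rate
        if err.any():
            # resample uniformly from the other two dosage classes
            shift = rng.integers(1, 3, size=int(err.sum()))
            out[err] = (out[err] + shift) % 3
    if config.missing_rate > 0:
        out[rng.random(out.size) < config.missing_rate] = MISSING
    return out


def simulate_collection(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Generate a full synthetic collection with ground truth.

    Founder genotypes are drawn site-wise Binomial(2, p_district); every
    field sample is a corrupted copy of its founder, so with zero error and
    missingness clones are identical to their founder.  Donor-introgression
    is written at the founder level (clones share it).  All randomness
    derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sites = _draw_sites(config, rng)
    ancestral, district_freqs = simulate_frequencies(config, rng)
    districts = [f"D{d + 1}" for d in range(config.n_districts)]

    # diagnostic markers: the donor allele (alt) is absent from the crop
    # background, so background dosage there is 0
    n_diag = int(round(config.diagnostic_marker_fraction * config.n_sites))
    diag_idx = np.sort(rng.choice(config.n_sites, size=n_diag, replace=False))
    diag_mask = np.zeros(config.n_sites, dtype=bool)
    diag_mask[diag_idx] = True
    in_region = np.zeros(config.n_sites, dtype=bool)
    for region in config.donor_regions:
        m = (sites["chrom"].astype(str) == region.chrom).to_numpy()
        m &= (sites["pos"] >= region.start).to_numpy()
        if region.end is not None:
            m &= (sites["pos"] <= region.end).to_numpy()
        in_region |= m
    donor_sites = diag_mask & in_region

    # founders per district, with cross-district sharing as literal copies
    founders: dict[str, np.ndarray] = {}
    presence: dict[str, list[str]] = {}  # variety -> districts planted
    carriers: set[str] = set()
    for d, dist in enumerate(districts):
        for k in range(config.n_varieties_per_district):
            vid = f"V{d + 1:02d}_{k + 1:02d}"
            g = rng.binomial(2, district_freqs[d]).astype(np.int8)
            g[diag_mask] = 0
            if rng.random() < config.introgression_fraction:
                carriers.add(vid)
                hom = rng.random(int(donor_sites.sum())) < config.donor_hom_prob
                g[donor_sites] = np.where(hom, 2, 1)
            founders[vid] = g
            presence[vid] = [dist]
            if config.n_districts > 1 and rng.random() < config.sharing_prob:
                other = districts[
                    (d + 1 + rng.integers(config.n_districts - 1)) % config.n_districts
                ]
                presence[vid].append(other)

    # field samples: clones of founders, attributed to farmers
    rows = []
    dosage_rows = []
    samples: list[SampleMeta] = []
    farmer_ids = {
        dist: [f"{dist}_F{j + 1:02d}" for j in range(config.n_farmers_per_district)]
        for dist in districts
    }
    for vid in sorted(founders):
        for dist in presence[vid]:
            n_clones = int(_clone_counts(config, rng, 1)[0])
            for c in range(n_clones):
                sid = f"S_{vid}_{dist}_{c + 1}"
                farmer = farmer_ids[dist][rng.integers(config.n_farmers_per_district)]
                dosage_rows.append(_corrupt(founders[vid], config, rng))
                samples.append(
                    SampleMeta(sid, district=dist, population="farmer", farmer_id=farmer)
                )
                rows.append((sid, vid, dist, "farmer", None, vid in carriers))

    # replicated checks, drawn from the ancestral pool
    for i, n_rep in enumerate(config.check_replicates):
        cid = f"CHK{i + 1}"
        g = rng.binomial(2, ancestral).astype(np.int8)
        g[diag_mask] = 0
        if rng.random() < config.introgression_fraction:
            carriers.add(cid)
            hom = rng.random(int(donor_sites.sum())) < config.donor_hom_prob
            g[donor_sites] = np.where(hom, 2, 1)
        founders[cid] = g
        for rep in range(n_rep):
            sid = f"S_{cid}_r{rep + 1}"
            dosage_rows.append(_corrupt(g, config, rng))
            samples.append(
                SampleMeta(sid, population="check", replicate_group=cid)
            )
            rows.append((sid, cid, None, "check", cid, cid in carriers))

    truth_df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "clonal_group",
            "district",
            "population",
            "replicate_group",
            "introgression_carrier",
        ],
    )

    # farmer naming: one base name per variety, perturbed by synonym /
    # homonym processes (mutually exclusive per sample)
    variety_ids = sorted(v for v in founders if v.startswith("V"))
    base_name = {vid: f"Name{j + 1:03d}" for j, vid in enumerate(variety_ids)}
    synonym_counter: dict[str, int] = {}
    name_class = {}
    for s, meta in zip(truth_df.itertuples(index=False), samples):
        if meta.population != "farmer":
            continue
        vid = s.clonal_group
        u = rng.random()
        if u < config.synonym_rate:
            synonym_counter[vid] = synonym_counter.get(vid, 0) + 1
            # reuse one of a couple of per-variety synonyms
            k = 1 + (synonym_counter[vid] % 2)
            meta.reported_name = f"{base_name[vid]}-syn{k}"
            name_class[meta.sample_id] = "synonym"
        elif u < config.synonym_rate + config.homonym_rate and len(variety_ids) > 1:
            other = variety_ids[rng.integers(len(variety_ids))]
            if other == vid:
                other = variety_ids[(variety_ids.index(vid) + 1) % len(variety_ids)]
            meta.reported_name = base_name[other]
            name_class[meta.sample_id] = "homonym"
        else:
            meta.reported_name = base_name[vid]
            name_class[meta.sample_id] = "base"
    truth_df["reported_name"] = [
        m.reported_name for m in samples
    ]
    truth_df["name_class"] = [name_class.get(m.sample_id) for m in samples]

    G = GenotypeMatrix(np.vstack(dosage_rows), sites, samples)
    truth = SimulationTruth(
        samples=truth_df,
        ancestral_freqs=ancestral,
        district_freqs=pd.DataFrame(
            district_freqs, index=districts, columns=range(config.n_sites)
        ),
        founder_genotypes=founders,
        carriers=carriers,
    )
    # stash the marker table for export
    truth.diagnostic_markers = DiagnosticMarkerSet(  # type: ignore[attr-defined]
        pd.DataFrame(
            {
                "chrom": sites.loc[diag_mask, "chrom"].to_numpy(),
                "pos": sites.loc[diag_mask, "pos"].to_numpy(),
                "donor_allele": "alt",
            }
        ),
        tuple(config.donor_regions),
    )
    return G, truth


def export(
    G: GenotypeMatrix,
    truth: SimulationTruth,
    outdir: str | Path,
    config: Optional[SimulationConfig] = None,
) -> dict[str, Path]:
    """Write VCF, metadata, truth, diagnostic-marker, and config files.

    Re-reading the VCF + metadata with :func:`clonalpop.genotype_io.read_vcf`
    reproduces the matrix exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "collection.vcf",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
        "markers": outdir / "diagnostic_markers.tsv",
    }
    write_vcf(G, paths["vcf"])
    write_metadata(G.samples, paths["metadata"])
    truth.samples.to_csv(paths["truth"], sep="\t", index=False)
    markers = getattr(truth, "diagnostic_markers", None)
    if markers is not None:
        markers.write(paths["markers"])
    if config is not None:
        paths["config"] = outdir / "config.yaml"
        config.to_yaml(paths["config"])
    return paths
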