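"""Clonal-group identification from SNP genotypes.

Vegetatively propagated crops accumulate no recombination between plantings,
so two samples of the same variety differ only by genotyping error.  The
pipeline here turns that into an operational definition of "variety":

1. pairwise identity-by-state (IBS) similarity over jointly genotyped sites,
2. conversion to a dissimilarity matrix (1 - IBS by default),
3. Ward's minimum-variance hierarchical clustering (Lance-Williams
   recurrence on the unsquared dissimilarities, the classic ``ward.D``
   convention),
4. a distance threshold calibrated on replicated check genotypes - plants of
   known identity sampled several times - chosen inside the interval of cut
   heights that exactly reproduces the replicate structure,
5. cutting the tree at that threshold to label clonal groups, and
6. reduction to one randomly chosen representative per group per district.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleMeta

# ---------------------------------------------------------------------------
# IBS similarity
# ---------------------------------------------------------------------------


@dataclass
class SimilarityMatrix:
    """Pairwise IBS similarities with per-pair shared-site counts.

    ``values[i, j]`` is the mean over jointly non-missing sites of
    ``1 - |g_i - g_j| / 2``; pairs with no shared sites are NaN.
    """

    values: np.ndarray
    n_shared: np.ndarray
    sample_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def ibs_similarity(G: GenotypeMatrix) -> SimilarityMatrix:
    """Pairwise identity-by-state similarity between all samples.

    Computed exactly over jointly non-missing sites via dosage-class
    indicator products: a pair of genotypes contributes 1 if the dosages are
    equal, 1/2 if they differ by one allele, 0 for opposite homozygotes.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    ind = [(G.dosages == d).astype(np.float64) for d in (0, 1, 2)]
    shared = (ind[0] + ind[1] + ind[2])  # 1 where non-missing
    n_shared = shared @ shared.T
    # sum over pairs of |g_i - g_j|: distance 1 for (0,1),(1,2); 2 for (0,2)
    diff1 = ind[0] @ ind[1].T + ind[1] @ ind[0].T + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    diff2 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - (0.5 * diff1 + diff2) / n_shared
    sim[n_shared == 0] = np.nan
    np.fill_diagonal(sim, np.where(np.diag(n_shared) > 0, 1.0, np.nan))
    return SimilarityMatrix(sim, n_shared.astype(np.int64), G.sample_ids)


def to_dissimilarity(S: SimilarityMatrix, mode: str = "one-minus") -> np.ndarray:
    """Convert IBS similarity to a dissimilarity matrix.

    ``mode='one-minus'`` (default) is ``D = 1 - S``.  ``mode='rows-euclidean'``
    instead takes Euclidean distances between rows of the similarity matrix
    (the literal behaviour of running a distance function on the similarity
    matrix itself); the calibrated-threshold design makes downstream group
    calls robust to this choice.
    """
    off = ~np.eye(S.n, dtype=bool)
    if np.isnan(S.values[off]).any():
        bad = int(np.isnan(S.values[off]).sum() // 2)
        raise ValueError(
            f"{bad} sample pairs share no genotyped sites; cannot build distances"
        )
    if mode == "one-minus":
        D = 1.0 - S.values
    elif mode == "rows-euclidean":
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(S.values, metric="euclidean"))
    else:
        raise ValueError(f"unknown dissimilarity mode {mode!r}")
    D = np.clip(D, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# Ward clustering (Lance-Williams, ward.D convention)
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomeration history from hierarchical clustering.

    ``merges`` has one row per merge: ``(left, right, height, size)`` using
    the linkage convention (leaves ``0..n-1``, the k-th merge creates node
    ``n+k``).  Heights are non-decreasing in merge order.
    """

    merges: np.ndarray  # (n-1, 4) float
    leaf_ids: list[str]
    variant: str = "ward.D"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def root_height(self) -> float:
        return float(self.merges[-1, 2]) if len(self.merges) else 0.0

    def validate(self) -> None:
        n = self.n_leaves
        if self.merges.shape != (n - 1, 4):
            raise ValueError("expected n-1 merges for n leaves")
        if np.any(np.diff(self.heights) < -1e-9):
            raise ValueError("merge heights not non-decreasing")
        sizes = np.concatenate([np.ones(n), self.merges[:, 3]])
        for k, (a, b, _, s) in enumerate(self.merges):
            if sizes[int(a)] + sizes[int(b)] != s:
                raise ValueError(f"merge {k}: size bookkeeping inconsistent")

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences to children."""
        n = self.n_leaves
        node_h = np.concatenate([np.zeros(n), self.heights])

        def render(node: int) -> str:
            if node < n:
                return self.leaf_ids[node]
            a, b, h, _ = self.merges[node - n]
            parts = []
            for child in (int(a), int(b)):
                bl = max(node_h[node] - node_h[child], 0.0)
                parts.append(f"{render(child)}:{bl:.6g}")
            return "(" + ",".join(parts) + ")"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * n + 100))
        try:
            return render(2 * n - 2) + ";"
        finally:
            sys.setrecursionlimit(old)


def ward_cluster(
    D: np.ndarray, leaf_ids: Sequence[str] | None = None, variant: str = "ward.D"
) -> Dendrogram:
    """Agglomerative Ward clustering of a precomputed dissimilarity matrix.

    Applies the Lance-Williams minimum-variance update directly to the
    supplied dissimilarities (``ward.D``), or to their squares with
    square-root heights (``ward.D2``).  Ties in merge height are broken by
    the lexicographically smallest pair of smallest-leaf-index
    representatives, making the dendrogram deterministic.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if not np.isfinite(D).all():
        raise ValueError("non-finite entries in distance matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be symmetric")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    if len(leaf_ids) != n:
        raise ValueError("leaf_ids length mismatch")
    if n < 2:
        raise ValueError("need at least 2 leaves")

    squared = variant == "ward.D2"
    if variant not in ("ward.D", "ward.D2"):
        raise ValueError(f"unknown Ward variant {variant!r}")

    d = D.astype(np.float64) ** 2 if squared else D.astype(np.float64).copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=np.float64)
    node_id = np.arange(n)  # linkage node id housed in each slot
    rep = np.arange(n)  # smallest original leaf index in each slot

    merges = np.empty((n - 1, 4), dtype=np.float64)
    for k in range(n - 1):
        sub = d[np.ix_(active, active)]
        m = sub.min()
        # tie-break: smallest (rep_i, rep_j) among exact-minimum pairs
        ii, jj = np.nonzero(d == m)
        best = None
        for a, b in zip(ii, jj):
            if a >= b or not (active[a] and active[b]):
                continue
            key = tuple(sorted((rep[a], rep[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, i, j = best

        height = math.sqrt(m) if squared else m
        merges[k] = (node_id[i], node_id[j], height, sizes[i] + sizes[j])

        si, sj = sizes[i], sizes[j]
        sk = sizes
        with np.errstate(invalid="ignore"):
            new = ((si + sk) * d[i] + (sj + sk) * d[j] - sk * m) / (si + sj + sk)
        new[~active] = np.inf
        d[i, :] = new
        d[:, i] = new
        d[i, i] = np.inf
        active[j] = False
        d[j, :] = np.inf
        d[:, j] = np.inf
        sizes[i] = si + sj
        node_id[i] = n + k
        rep[i] = min(rep[i], rep[j])

    # put smaller linkage id first, for a stable representation
    swap = merges[:, 0] > merges[:, 1]
    merges[swap, 0], merges[swap, 1] = merges[swap, 1].copy(), merges[swap, 0].copy()
    tree = Dendrogram(merges, list(leaf_ids), variant=variant)
    tree.validate()
    return tree


def cut_tree(T: Dendrogram, h: float) -> np.ndarray:
    """Cluster labels from cutting the dendrogram at height ``h``.

    Clusters are the connected components formed by all merges with height
    <= ``h``; labels are integers assigned in order of first leaf
    appearance (leaf 0's cluster is 0, and so on).
    """
    if h < 0:
        raise ValueError("cut height must be non-negative")
    n = T.n_leaves
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, height, _) in enumerate(T.merges):
        if height <= h:
            node = n + k
            parent[find(int(a))] = node
            parent[find(int(b))] = node
    roots = [find(i) for i in range(n)]
    label_of: dict[int, int] = {}
    labels = np.empty(n, dtype=np.int64)
    for i, r in enumerate(roots):
        if r not in label_of:
            label_of[r] = len(label_of)
        labels[i] = label_of[r]
    return labels


# ---------------------------------------------------------------------------
# replicate-based threshold calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Valid cut-height interval derived from replicated check genotypes.

    Any threshold in ``[h_min, h_max)`` groups every replicate set into a
    single cluster while keeping different replicate sets apart.
    """

    h_min: float
    h_max: float
    threshold: float
    group_uniting_height: dict[str, float]
    first_cross_height: Optional[float]
    rule: str

    def to_frame(self) -> pd.DataFrame:
        rows = [("h_min", self.h_min), ("h_max", self.h_max),
                ("threshold", self.threshold)]
        rows += [(f"uniting_height_{g}", h) for g, h in self.group_uniting_height.items()]
        return pd.DataFrame(rows, columns=["key", "value"])


class CalibrationError(ValueError):
    pass


def calibrate_threshold(
    T: Dendrogram,
    replicate_groups: Mapping[str, str],
    rule: str = "geometric",
) -> CalibrationResult:
    """Find the cut-height interval that reproduces the replicate partition.

    ``replicate_groups`` maps sample id -> replicate-group label for the
    check samples (others absent).  ``h_min`` is the largest height at which
    some replicate group first becomes a single cluster; ``h_max`` is the
    height of the first merge uniting members of two different groups (the
    root height if that never happens below the root).

    The reported ``threshold`` is a point inside ``[h_min, h_max)``:

    - ``rule='geometric'`` (default): the geometric mean of the interval
      ends.  Ward heights of merges between *distinct* large clusters sit
      orders of magnitude above replicate noise, so the arithmetic midpoint
      lands on the between-variety scale and over-merges singletons; the
      geometric mean stays on the noise side of the gap.
    - ``rule='midpoint'``: the arithmetic midpoint ``(h_min + h_max) / 2``.
    """
    idx = {s: i for i, s in enumerate(T.leaf_ids)}
    groups: dict[str, set[int]] = {}
    for sid, g in replicate_groups.items():
        if sid in idx:
            groups.setdefault(g, set()).add(idx[sid])
    groups = {g: m for g, m in groups.items() if len(m) >= 2}
    if not groups:
        raise CalibrationError("no replicate group with >= 2 members in the tree")

    n = T.n_leaves
    # per node, count of members of each group it contains
    member_counts: list[dict[str, int]] = [dict() for _ in range(2 * n - 1)]
    for g, members in groups.items():
        for i in members:
            member_counts[i][g] = 1

    uniting: dict[str, float] = {}
    first_cross: Optional[float] = None
    for k, (a, b, height, _) in enumerate(T.merges):
        ca, cb = member_counts[int(a)], member_counts[int(b)]
        if first_cross is None:
            ga = {g for g in ca if ca[g] > 0}
            gb = {g for g in cb if cb[g] > 0}
            # uniting members of two different groups: each side non-empty
            # and more than one group involved overall
            if ga and gb and len(ga | gb) >= 2:
                first_cross = float(height)
        merged = dict(ca)
        for g, c in cb.items():
            merged[g] = merged.get(g, 0) + c
        member_counts[n + k] = merged
        for g, c in merged.items():
            if g not in uniting and c == len(groups[g]):
                uniting[g] = float(height)

    h_min = max(uniting.values())
    h_max = first_cross if first_cross is not None else T.root_height
    if h_min >= h_max:
        offenders = [g for g, h in uniting.items() if h >= h_max]
        raise CalibrationError(
            f"replicates not separable: groups {offenders} unite at or above "
            f"the first cross-group merge height {h_max:.6g}"
        )

    if rule == "midpoint":
        threshold = 0.5 * (h_min + h_max)
    elif rule == "geometric":
        lo = h_min if h_min > 0 else 1e-4 * h_max
        threshold = math.sqrt(lo * h_max)
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    return CalibrationResult(h_min, h_max, threshold, uniting, first_cross, rule)


# ---------------------------------------------------------------------------
# group assignment, deduplication, sharing summaries
# ---------------------------------------------------------------------------


@dataclass
class ClonalAssignment:
    """Sample -> clonal-group labels plus optional per-district representatives.

    Group labels follow ``C_<i>`` where ``i`` is the 1-based input-order
    index of the group's first member; the labels are identifiers only.
    """

    labels: dict[str, str]
    threshold: float
    representatives: dict[tuple[str, str], str] = field(default_factory=dict)
    seed: Optional[int] = None

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, g in self.labels.items():
            out.setdefault(g, []).append(sid)
        return out

    def group_sizes(self) -> pd.Series:
        sizes = {g: len(m) for g, m in self.groups.items()}
        return pd.Series(sizes, name="n_members").sort_values(ascending=False)

    @property
    def n_groups(self) -> int:
        return len(set(self.labels.values()))

    def to_frame(self, samples: Sequence[SampleMeta] | None = None) -> pd.DataFrame:
        meta = {s.sample_id: s for s in samples} if samples else {}
        rep_ids = set(self.representatives.values())
        rows = []
        for sid, g in self.labels.items():
            m = meta.get(sid)
            rows.append(
                (sid, g, m.district if m else None, sid in rep_ids)
            )
        return pd.DataFrame(
            rows, columns=["sample_id", "group", "district", "representative"]
        )


def assign_clonal_groups(
    G: GenotypeMatrix,
    threshold: float,
    scope: Sequence[str] | None = None,
    dist_mode: str = "one-minus",
    ward_variant: str = "ward.D",
) -> ClonalAssignment:
    """Label clonal groups by the full IBS -> Ward -> cut pipeline.

    ``scope`` restricts the analysis to a subset of sample ids (default:
    all samples).
    """
    sub = G.subset_ids(scope) if scope is not None else G
    S = ibs_similarity(sub)
    D = to_dissimilarity(S, mode=dist_mode)
    T = ward_cluster(D, leaf_ids=sub.sample_ids, variant=ward_variant)
    ints = cut_tree(T, threshold)
    first_member = {}
    for i, lab in enumerate(ints):
        if lab not in first_member:
            first_member[lab] = i + 1  # 1-based
    labels = {
        sid: f"C_{first_member[lab]}" for sid, lab in zip(sub.sample_ids, ints)
    }
    return ClonalAssignment(labels, threshold)


def dedupe_by_district(
    A: ClonalAssignment, samples: Sequence[SampleMeta], seed: int = 0
) -> dict[tuple[str, str], str]:
    """Choose one random representative per (clonal group, district).

    A group planted in k districts contributes k representatives.  Uses a
    dedicated generator seeded with ``seed``, so the choice is reproducible.
    Samples in scope must carry district metadata.
    """
    meta = {s.sample_id: s for s in samples}
    missing = [sid for sid in A.labels if meta.get(sid) is None or meta[sid].district is None]
    if missing:
        raise ValueError(f"samples without district metadata: {sorted(missing)[:10]}")
    cells: dict[tuple[str, str], list[str]] = {}
    for sid, g in A.labels.items():
        cells.setdefault((g, meta[sid].district), []).append(sid)
    rng = np.random.default_rng(seed)
    reps: dict[tuple[str, str], str] = {}
    for key in sorted(cells):
        members = sorted(cells[key])
        reps[key] = members[rng.integers(len(members))]
    A.representatives = reps
    A.seed = seed
    return reps


def district_sharing_summary(
    A: ClonalAssignment, samples: Sequence[SampleMeta]
) -> pd.DataFrame:
    """Count clonal groups found in exactly / at least k districts."""
    meta = {s.sample_id: s for s in samples}
    group_districts: dict[str, set[str]] = {}
    for sid, g in A.labels.items():
        d = meta[sid].district if sid in meta else None
        if d is not None:
            group_districts.setdefault(g, set()).add(d)
    counts = pd.Series({g: len(ds) for g, ds in group_districts.items()})
    max_k = int(counts.max()) if len(counts) else 0
    rows = [
        (k, int((counts == k).sum()), int((counts >= k).sum()))
        for k in range(1, max_k + 1)
    ]
    return pd.DataFrame(rows, columns=["k_districts", "exactly_k", "at_least_k"])


def varieties_per_farmer(
    A: ClonalAssignment, samples: Sequence[SampleMeta]
) -> pd.Series:
    """Number of distinct clonal groups grown by each farmer."""
    meta = {s.sample_id: s for s in samples}
    per: dict[str, set[str]] = {}
    for sid, g in A.labels.items():
        m = meta.get(sid)
        if m is not None and m.farmer_id is not None:
            per.setdefault(m.farmer_id, set()).add(g)
    return pd.Series({f: len(gs) for f, gs in per.items()}, name="n_varieties")
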