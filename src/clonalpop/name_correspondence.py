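"""Correspondence between farmer-reported variety names and clonal groups.

Farmers name varieties by provenance, morphology, or taste, so one clone
often carries many names (synonymy) and one name may cover several clones
(homonymy).  This module cross-tabulates reported names against genetic
clonal groups, summarises per-name purity (largest group share) and
per-group name richness, and exports the membership-filtered table used for
chord-diagram rendering by external tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd


@dataclass
class NameContingency:
    """Cross-tabulation of reported variety names against clonal groups.

    ``table`` rows are clonal groups, columns are normalised names (trimmed,
    case-folded; the most frequent raw spelling is kept in ``raw_names`` for
    reporting).  ``purity[name]`` is the largest single-group share of that
    name's mentions; ``richness[group]`` counts distinct names applied to
    the group's members.
    """

    table: pd.DataFrame
    purity: pd.Series
    richness: pd.Series
    n_dropped_unnamed: int
    raw_names: dict[str, str]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def _normalise(name: str) -> str:
    return name.strip().casefold()


def build_contingency(
    labels: Mapping[str, str], names: Mapping[str, Optional[str]]
) -> NameContingency:
    """Cross-tabulate clonal-group labels against reported names.

    ``labels`` maps sample id -> clonal group; ``names`` maps sample id ->
    farmer-reported name (None / empty names are dropped, with the count
    recorded).  Names are compared after trimming and case-folding only -
    distinct spellings are deliberately kept distinct.
    """
    rows = []
    raw_count: dict[str, dict[str, int]] = {}
    dropped = 0
    for sid, group in labels.items():
        raw = names.get(sid)
        if raw is None or not str(raw).strip():
            dropped += 1
            continue
        norm = _normalise(str(raw))
        raw_count.setdefault(norm, {})
        raw_count[norm][str(raw).strip()] = raw_count[norm].get(str(raw).strip(), 0) + 1
        rows.append((group, norm))
    if not rows:
        raise ValueError("no named samples in scope")
    df = pd.DataFrame(rows, columns=["group", "name"])
    table = pd.crosstab(df["group"], df["name"])
    purity = table.max(axis=0) / table.sum(axis=0)
    richness = (table > 0).sum(axis=1)
    raw_names = {
        norm: max(variants, key=lambda v: (variants[v], v))
        for norm, variants in raw_count.items()
    }
    return NameContingency(
        table, purity.rename("purity"), richness.rename("n_names"), dropped, raw_names
    )


def filter_for_export(
    C: NameContingency,
    min_group_members: int = 21,
    min_name_mentions: int = 12,
    other_label: str = "Other_names",
) -> pd.DataFrame:
    """Membership-filtered contingency table for chord-diagram export.

    Keeps clonal groups with at least ``min_group_members`` members (i.e.
    strictly more than ``min_group_members - 1``) and names with at least
    ``min_name_mentions`` mentions in the full table; the mentions of
    excluded names within retained groups are pooled into an
    ``Other_names`` column, so every retained group's row sum equals its
    member count.  Returns an empty frame (with a warning) if nothing
    survives.
    """
    group_sizes = C.table.sum(axis=1)
    name_mentions = C.table.sum(axis=0)
    keep_groups = group_sizes[group_sizes >= min_group_members].index
    keep_names = name_mentions[name_mentions >= min_name_mentions].index
    if len(keep_groups) == 0:
        import warnings

        warnings.warn("no clonal group survives the membership filter")
        return pd.DataFrame()
    sub = C.table.loc[keep_groups]
    kept = sub[[c for c in sub.columns if c in set(keep_names)]].copy()
    other = sub[[c for c in sub.columns if c not in set(keep_names)]].sum(axis=1)
    if (other > 0).any() or kept.shape[1] < sub.shape[1]:
        kept[other_label] = other
    # restore reporting spellings on retained name columns
    kept = kept.rename(
        columns={c: C.raw_names.get(c, c) for c in kept.columns if c != other_label}
    )
    return kept
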