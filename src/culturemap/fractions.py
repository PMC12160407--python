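"""Culturability fraction binning and diversity/abundance statistics.

Community ASVs are assigned to culturability bins from their best-hit identity
to the cultured isolate set:

* ``cultured`` — identity strictly above the species-level threshold (99%),
* ``close_uncultured`` — identity between the distant threshold and the
  species threshold (optionally sub-tiered by a ladder of cutpoints),
* ``distant`` — identity strictly below the distant threshold (85.93%, the
  upper 95% CI of median 16S identity at the class level),
* ``unmatched`` — no hit satisfying the full-coverage contract.

All summary statistics (bin shares, cumulative identity curves, taxonomic
rank coverage, per-taxon fraction profiles, prevalence) are computed from a
samples x ASVs count table via per-ASV mean relative abundance: the unweighted
mean over samples of the per-sample count proportion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .identity import IdentityHit

CULTURED = "cultured"
CLOSE = "close_uncultured"
DISTANT = "distant"
UNMATCHED = "unmatched"

BINS = (CULTURED, CLOSE, DISTANT, UNMATCHED)

RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class ThresholdConfig:
    """Identity thresholds separating culturability bins.

    ``cultured_min`` is an exclusive lower bound (identity must be strictly
    greater to count as cultured); ``distant_max`` is an exclusive upper bound
    (identity strictly below is distant).  ``ladder`` optionally subdivides
    the close-uncultured interval into tiers by strictly increasing cutpoints
    within ``(distant_max, cultured_min]``.
    """

    cultured_min: float = 99.0
    distant_max: float = 85.93
    ladder: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.distant_max < self.cultured_min <= 100.0:
            raise ValueError(
                "require 0 <= distant_max < cultured_min <= 100, got "
                f"{self.distant_max} / {self.cultured_min}"
            )
        lad = tuple(self.ladder)
        if lad != tuple(sorted(set(lad))):
            raise ValueError("ladder must be strictly increasing")
        if lad and (lad[0] <= self.distant_max or lad[-1] > self.cultured_min):
            raise ValueError("ladder cutpoints must lie in (distant_max, cultured_min]")


@dataclass(frozen=True)
class FractionLabel:
    """Culturability bin assignment of one community ASV."""

    asv_id: str
    bin: str
    tier: Optional[str] = None


def bin_by_identity(
    hits: Iterable[IdentityHit], thresholds: ThresholdConfig | None = None
) -> list[FractionLabel]:
    """Assign each ASV's best hit to a culturability bin (strict boundaries)."""
    cfg = thresholds or ThresholdConfig()
    labels = []
    for hit in hits:
        if hit.identity is None:
            labels.append(FractionLabel(hit.query_id, UNMATCHED))
            continue
        if not 0.0 <= hit.identity <= 100.0:
            raise ValueError(
                f"identity {hit.identity} for {hit.query_id!r} outside [0, 100]"
            )
        if hit.identity > cfg.cultured_min:
            labels.append(FractionLabel(hit.query_id, CULTURED))
        elif hit.identity < cfg.distant_max:
            labels.append(FractionLabel(hit.query_id, DISTANT))
        else:
            tier = None
            if cfg.ladder:
                edges = (cfg.distant_max, *cfg.ladder, cfg.cultured_min)
                # tiers: [e0, e1], then (e1, e2], ... up to cultured_min
                for lo, hi in itertools.pairwise(dict.fromkeys(edges)):
                    if hit.identity <= hi:
                        tier = f"({lo:g},{hi:g}]"
                        break
            labels.append(FractionLabel(hit.query_id, CLOSE, tier))
    return labels


def mean_relative_abundance(table: pd.DataFrame) -> pd.Series:
    """Per-ASV mean over samples of the per-sample count proportion.

    ``table`` is ASVs (rows) x samples (columns), non-negative counts.
    Samples with zero depth are rejected; zero counts in a sample contribute
    zero proportion to the ASV's mean.  The result sums to 1 over ASVs.
    """
    counts = table.to_numpy(dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("feature table is empty or all-zero")
    if (counts < 0).any():
        raise ValueError("feature table contains negative counts")
    depths = counts.sum(axis=0)
    if (depths == 0).any():
        bad = table.columns[depths == 0].tolist()
        raise ValueError(f"samples with zero depth: {bad}")
    props = counts / depths
    return pd.Series(props.mean(axis=1), index=table.index, name="mean_rel_abundance")


def _check_same_asvs(labels: Sequence[FractionLabel], mra: pd.Series) -> None:
    label_ids = {l.asv_id for l in labels}
    if label_ids != set(mra.index):
        missing = label_ids.symmetric_difference(mra.index)
        raise ValueError(f"label / abundance ASV sets differ, e.g. {sorted(missing)[:5]}")


def fraction_summary(
    labels: Sequence[FractionLabel], mra: pd.Series
) -> pd.DataFrame:
    """Per-bin ASV share and abundance share, both in percent.

    Returns a DataFrame indexed by bin with columns ``n_asvs``, ``asv_pct``
    and ``abundance_pct``; each percentage column sums to 100 over bins.
    """
    _check_same_asvs(labels, mra)
    total_mra = float(mra.sum())
    rows = []
    by_bin: dict[str, list[str]] = {b: [] for b in BINS}
    for lab in labels:
        by_bin[lab.bin].append(lab.asv_id)
    n_total = len(labels)
    for b in BINS:
        ids = by_bin[b]
        rows.append(
            {
                "bin": b,
                "n_asvs": len(ids),
                "asv_pct": 100.0 * len(ids) / n_total,
                "abundance_pct": 100.0 * float(mra.loc[ids].sum()) / total_mra,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def cumulative_curve(
    hits: Sequence[IdentityHit], mra: pd.Series, grid: Sequence[float]
) -> pd.DataFrame:
    """Cumulative ASV and abundance shares at descending identity cutpoints.

    At each cutpoint ``c`` the row reports the share of ASVs whose best-hit
    identity is ``>= c`` (and their summed mean relative abundance share).
    Unmatched ASVs enter only at a terminal no-hit row, which always closes
    the curve at 100% / 100%.
    """
    grid = list(grid)
    if any(not 0.0 <= c <= 100.0 for c in grid):
        raise ValueError("grid cutpoints must lie in [0, 100]")
    if grid != sorted(grid, reverse=True) or len(set(grid)) != len(grid):
        raise ValueError("grid must be strictly descending")
    ids = [h.query_id for h in hits]
    if set(ids) != set(mra.index):
        raise ValueError("hits and abundance cover different ASV sets")
    ident = {h.query_id: h.identity for h in hits}
    total_mra = float(mra.sum())
    n = len(hits)
    rows = []
    for c in grid:
        sel = [i for i in ids if ident[i] is not None and ident[i] >= c]
        rows.append(
            {
                "cutpoint": c,
                "cum_asv_pct": 100.0 * len(sel) / n,
                "cum_abundance_pct": 100.0 * float(mra.loc[sel].sum()) / total_mra,
            }
        )
    rows.append({"cutpoint": np.nan, "cum_asv_pct": 100.0, "cum_abundance_pct": 100.0})
    return pd.DataFrame(rows)


def rank_coverage(
    labels: Sequence[FractionLabel], taxonomy: pd.DataFrame
) -> pd.DataFrame:
    """Percent of named taxa per rank containing at least one cultured ASV.

    ``taxonomy`` is indexed by ASV id with the rank columns
    ``phylum .. genus``; empty cells (NaN or "") are unclassified and are
    excluded from both numerator and denominator.  A rank where every ASV is
    unclassified yields NaN coverage rather than an error.
    """
    label_ids = [l.asv_id for l in labels]
    missing = set(label_ids) - set(taxonomy.index)
    if missing:
        raise ValueError(f"taxonomy missing ASVs, e.g. {sorted(missing)[:5]}")
    cultured_ids = [l.asv_id for l in labels if l.bin == CULTURED]
    rows = []
    for rank in RANKS:
        col = taxonomy.loc[label_ids, rank]
        named = col[col.notna() & (col.astype(str).str.strip() != "")]
        taxa = set(named)
        cultured_taxa = set(named.loc[named.index.intersection(cultured_ids)])
        rows.append(
            {
                "rank": rank,
                "n_taxa": len(taxa),
                "n_cultured_taxa": len(cultured_taxa),
                "coverage_pct": (
                    100.0 * len(cultured_taxa) / len(taxa) if taxa else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("rank")


def group_fraction_profile(
    labels: Sequence[FractionLabel],
    taxonomy: pd.DataFrame,
    mra: pd.Series,
    rank: str,
    top_k: int = 25,
    order_by: str = "abundance",
) -> pd.DataFrame:
    """Stacked bin composition of the top-k taxa at one rank.

    Taxa are ranked by total mean relative abundance (``order_by="abundance"``)
    or by ASV count (``order_by="diversity"``).  For each taxon the bin
    composition is reported both as abundance shares and as ASV-count shares
    (percent; each set of shares sums to 100 per taxon).  Unclassified ASVs at
    the rank are grouped under the placeholder ``"unclassified"``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if order_by not in ("abundance", "diversity"):
        raise ValueError("order_by must be 'abundance' or 'diversity'")
    _check_same_asvs(labels, mra)

    bin_of = {l.asv_id: l.bin for l in labels}
    taxa = taxonomy.loc[list(bin_of), rank].astype(object)
    taxa = taxa.where(taxa.notna() & (taxa.astype(str).str.strip() != ""), "unclassified")

    df = pd.DataFrame(
        {
            "taxon": taxa.values,
            "bin": [bin_of[a] for a in taxa.index],
            "mra": mra.loc[taxa.index].values,
        },
        index=taxa.index,
    )
    totals = df.groupby("taxon").agg(total_mra=("mra", "sum"), n_asvs=("bin", "size"))
    key = "total_mra" if order_by == "abundance" else "n_asvs"
    top = totals.sort_values([key, "total_mra"], ascending=False).head(top_k)

    rows = []
    for taxon in top.index:
        sub = df[df["taxon"] == taxon]
        t_mra = float(sub["mra"].sum())
        n = len(sub)
        for b in BINS:
            sb = sub[sub["bin"] == b]
            rows.append(
                {
                    "taxon": taxon,
                    "bin": b,
                    "n_asvs": len(sb),
                    "asv_share_pct": 100.0 * len(sb) / n,
                    "abundance_share_pct": (
                        100.0 * float(sb["mra"].sum()) / t_mra if t_mra > 0 else np.nan
                    ),
                    "taxon_total_mra": t_mra,
                    "taxon_n_asvs": n,
                }
            )
    return pd.DataFrame(rows)


def prevalence(presence: pd.DataFrame) -> pd.Series:
    """Percent of genotypes in which each taxon is detected.

    ``presence`` is genotypes (rows) x taxa (columns), boolean or 0/1.
    """
    if presence.size == 0:
        raise ValueError("presence table is empty")
    vals = presence.to_numpy()
    if not np.isin(vals, (0, 1, True, False)).all():
        raise ValueError("presence table must be binary")
    return 100.0 * presence.astype(bool).mean(axis=0).rename("prevalence_pct")


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The p-value is exact (full enumeration) when the smaller sample has at
    most 8 observations and there are no ties across samples; otherwise the
    normal approximation with tie and continuity corrections is used.
    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
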