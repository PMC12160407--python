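"""Readers, writers, run configuration and the end-to-end report pipeline.

All canonical formats are plain text: FASTA for sequences, TSV for the
feature table (first column ASV id, remaining columns sample counts),
taxonomy (ASV id + five rank columns, empty cell = unclassified) and edge
lists (node_a, node_b, sign, weight), JSON for metadata.  Percentages in
written reports carry two decimals (half-up); counts are unrounded.
"""

from __future__ import annotations

import decimal
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from . import __version__
from .fractions import (
    RANKS,
    FractionLabel,
    ThresholdConfig,
    bin_by_identity,
    cumulative_curve,
    fraction_summary,
    group_fraction_profile,
    mean_relative_abundance,
    rank_coverage,
)
from .identity import IdentityHit, best_hits
from .network import (
    HubCriteria,
    InteractionNetwork,
    centrality_group_test,
    centrality_pca,
    compute_profiles,
    edge_sharing_classification,
    infer_network,
)
from .records import SequenceRecord, SequenceSet

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file failed validation; the message names the offending location."""


def round_pct(x: float, ndigits: int = 2) -> float:
    """Half-up rounding for reported percentages."""
    if x != x:  # NaN
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file; ids are headers up to the first whitespace,
    sequences are uppercased; duplicate ids are an error."""
    path = Path(path)
    records = SequenceSet()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            records.add(SequenceRecord(rec.id, str(rec.seq).upper()))
        except ValueError as exc:
            raise ParseError(f"{path}, record {i + 1}: {exc}") from exc
    if len(records) == 0:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: SequenceSet, path: str | Path, width: int = 80) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """ASVs x samples integer count table (first column = ASV id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate ASV id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ParseError(f"{path}: non-numeric count at ({row!r}, {col!r})")
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise ParseError(f"{path}: negative count at ({row!r}, {col!r})")
        if (vals % 1 != 0).any():
            row = df.index[vals % 1 != 0][0]
            raise ParseError(f"{path}: non-integer count at ({row!r}, {col!r})")
    return df.astype(np.int64)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = out.index.name or "asv_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """ASV id + phylum..genus lineage table; empty cells = unclassified."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = [c.lower() for c in df.columns]
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing rank columns {missing}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate ASV id {dup!r}")
    return df[list(RANKS)]


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    out = taxonomy.fillna("")
    out.index.name = out.index.name or "asv_id"
    out.to_csv(path, sep="\t")


def read_edge_list(path: str | Path) -> list[tuple[str, str, str, float]]:
    """Edge list TSV with header: node_a, node_b, sign (+/-), weight."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 4:
        raise ParseError(f"{path}: expected 4 columns (node_a, node_b, sign, weight)")
    edges = []
    for i, row in df.iterrows():
        sign = str(row.iloc[2]).strip()
        # tolerate unicode minus from spreadsheet exports
        sign = {"−": "-", "–": "-"}.get(sign, sign)
        if sign not in ("+", "-"):
            raise ParseError(f"{path}, line {i + 2}: bad sign token {row.iloc[2]!r}")
        try:
            weight = float(row.iloc[3])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}, line {i + 2}: bad weight {row.iloc[3]!r}") from exc
        edges.append((str(row.iloc[0]), str(row.iloc[1]), sign, weight))
    return edges


def write_edge_list(
    edges: Iterable[tuple[str, str, str, float]], path: str | Path
) -> None:
    df = pd.DataFrame(edges, columns=["node_a", "node_b", "sign", "weight"])
    df.to_csv(path, sep="\t", index=False)


def read_network(
    path: str | Path,
    node_attrs: Optional[pd.DataFrame] = None,
    known_asvs: Optional[set[str]] = None,
    allow_partial: bool = False,
) -> InteractionNetwork:
    """Read an edge-list TSV into an :class:`InteractionNetwork`.

    When ``known_asvs`` is given, edges touching unknown ASVs abort the read
    unless ``allow_partial`` is set, in which case they are dropped with a
    logged count.
    """
    edges = read_edge_list(path)
    if known_asvs is not None:
        unknown = sorted(
            {n for a, b, _, _ in edges for n in (a, b) if n not in known_asvs}
        )
        if unknown:
            if not allow_partial:
                raise ParseError(
                    f"{path}: {len(unknown)} edge nodes absent from the feature "
                    f"table, e.g. {unknown[:5]} (use allow_partial to drop them)"
                )
            before = len(edges)
            edges = [
                e for e in edges if e[0] not in unknown and e[1] not in unknown
            ]
            logger.warning(
                "dropped %d/%d edges touching %d unknown nodes",
                before - len(edges), before, len(unknown),
            )
    return InteractionNetwork.from_edges(edges, node_attrs)


def write_graphml(network: InteractionNetwork, path: str | Path) -> None:
    import networkx as nx

    g = network.graph.copy()
    for _, data in g.nodes(data=True):  # GraphML cannot carry None values
        for k in list(data):
            if data[k] is None:
                del data[k]
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# run configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed for an end-to-end run."""

    isolates_fasta: str
    community_fasta: str
    feature_table: str
    taxonomy: str
    out_dir: str
    edge_list: Optional[str] = None
    infer: bool = False
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    hub_criteria: HubCriteria = field(default_factory=HubCriteria)
    min_obs: int = 20
    alpha: float = 0.05
    n_perm: int = 1000
    top_k: int = 25
    allow_partial: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in raw:
            raw["thresholds"] = ThresholdConfig(
                **{
                    k: tuple(v) if k == "ladder" else v
                    for k, v in raw["thresholds"].items()
                }
            )
        if "hub_criteria" in raw:
            raw["hub_criteria"] = HubCriteria(**raw["hub_criteria"])
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = [self.isolates_fasta, self.community_fasta, self.feature_table,
                 self.taxonomy]
        if self.edge_list:
            paths.append(self.edge_list)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class ReportBundle:
    """All derived tables of one end-to-end run."""

    hits: list[IdentityHit]
    labels: list[FractionLabel]
    mra: pd.Series
    fraction_summary: pd.DataFrame
    cumulative_curve: pd.DataFrame
    rank_coverage: pd.DataFrame
    class_profile: pd.DataFrame
    genus_profile: pd.DataFrame
    network: Optional[InteractionNetwork]
    profiles: Optional[pd.DataFrame]
    group_tests: Optional[pd.DataFrame]
    edge_sharing: Optional[pd.DataFrame]
    edge_sharing_chi2: Optional[tuple[float, float]]
    pca_loadings: Optional[pd.DataFrame]
    pca_variance: Optional[np.ndarray]
    metadata: dict


def _pct_cols(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if str(col).endswith("pct"):
            out[col] = out[col].map(round_pct)
    return out


def _validate_ids(
    table: pd.DataFrame,
    community: SequenceSet,
    taxonomy: pd.DataFrame,
    allow_partial: bool,
) -> None:
    problems = []
    table_ids = set(table.index)
    fasta_ids = set(community.ids)
    if table_ids - fasta_ids:
        problems.append(
            f"{len(table_ids - fasta_ids)} table ASVs missing from community FASTA"
        )
    if fasta_ids - table_ids:
        problems.append(
            f"{len(fasta_ids - table_ids)} community FASTA ASVs missing from table"
        )
    if table_ids - set(taxonomy.index):
        problems.append(
            f"{len(table_ids - set(taxonomy.index))} table ASVs missing from taxonomy"
        )
    if problems:
        msg = "; ".join(problems)
        if allow_partial:
            logger.warning("id validation: %s (continuing, allow_partial)", msg)
        else:
            raise ParseError(f"cross-file id validation failed: {msg}")


def run_all(config: RunConfig) -> ReportBundle:
    """Execute the full pipeline and write every report table.

    Stages: identity mapping -> binning -> fraction statistics -> network
    topology; identical config + seed reproduce identical outputs.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    isolates = read_fasta(config.isolates_fasta)
    community = read_fasta(config.community_fasta)
    table = read_feature_table(config.feature_table)
    taxonomy = read_taxonomy(config.taxonomy)
    logger.info("inputs: %d isolates, %d community ASVs, %d samples",
                len(isolates), len(community), table.shape[1])
    _validate_ids(table, community, taxonomy, config.allow_partial)

    common = [a for a in table.index if a in community]
    community = SequenceSet(community[a] for a in common)
    table = table.loc[common]
    taxonomy = taxonomy.reindex(common).fillna("")

    hits = best_hits(community, isolates)
    labels = bin_by_identity(hits, config.thresholds)
    mra = mean_relative_abundance(table)
    summary = fraction_summary(labels, mra)
    curve = cumulative_curve(
        hits, mra, [100.0, config.thresholds.cultured_min,
                    config.thresholds.distant_max, 0.0]
    )
    coverage = rank_coverage(labels, taxonomy)
    class_profile = group_fraction_profile(
        labels, taxonomy, mra, "class", top_k=config.top_k
    )
    genus_profile = group_fraction_profile(
        labels, taxonomy, mra, "genus", top_k=config.top_k
    )
    logger.info("fractions: %s", summary["n_asvs"].to_dict())

    cultured_flags = {l.asv_id: l.bin == "cultured" for l in labels}
    network = None
    if config.edge_list:
        attrs = pd.DataFrame(
            {
                "class_name": taxonomy["class"],
                "mean_rel_abundance": mra,
                "cultured": pd.Series(cultured_flags),
            }
        )
        network = read_network(
            config.edge_list, known_asvs=set(table.index),
            allow_partial=config.allow_partial,
        )
        network.set_cultured_flags(cultured_flags)
        for node in network.graph.nodes:
            if node in attrs.index:
                network.graph.nodes[node]["class_name"] = attrs.loc[node, "class_name"]
                network.graph.nodes[node]["mean_rel_abundance"] = float(
                    attrs.loc[node, "mean_rel_abundance"]
                )
    elif config.infer:
        network = infer_network(
            table, min_obs=config.min_obs, alpha=config.alpha,
            n_perm=config.n_perm, seed=config.seed,
        )
        network.set_cultured_flags(cultured_flags)

    profiles = group_tests = sharing = None
    chi2_result = None
    loadings = None
    variance = None
    if network is not None and network.n_edges > 0:
        profiles = compute_profiles(network, config.hub_criteria)
        profiles["mean_rel_abundance"] = mra.reindex(profiles.index)
        flags = {n: bool(cultured_flags.get(n, False)) for n in profiles.index}
        if 0 < sum(flags.values()) < len(flags):
            group_tests = centrality_group_test(profiles, flags)
            sharing, _, chi2, chi2_p = edge_sharing_classification(network)
            chi2_result = (chi2, chi2_p)
        try:
            loadings, _, variance = centrality_pca(profiles)
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)

    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_isolates": len(isolates),
        "n_community_asvs": len(community),
        "n_samples": int(table.shape[1]),
        "n_network_nodes": network.n_nodes if network else None,
        "n_network_edges": network.n_edges if network else None,
    }

    # write everything
    _pct_cols(summary.reset_index()).to_csv(out / "fraction_summary.tsv",
                                            sep="\t", index=False)
    _pct_cols(curve).to_csv(out / "cumulative_curve.tsv", sep="\t", index=False)
    _pct_cols(coverage.reset_index()).to_csv(out / "rank_coverage.tsv",
                                             sep="\t", index=False)
    _pct_cols(class_profile).to_csv(out / "class_profile.tsv", sep="\t", index=False)
    _pct_cols(genus_profile).to_csv(out / "genus_profile.tsv", sep="\t", index=False)
    hits_df = pd.DataFrame(
        [
            {
                "asv_id": h.query_id, "subject_id": h.subject_id,
                "identity": h.identity, "offset": h.offset, "strand": h.strand,
                "bin": lab.bin,
            }
            for h, lab in zip(hits, labels)
        ]
    )
    hits_df.to_csv(out / "identity_hits.tsv", sep="\t", index=False)
    if profiles is not None:
        profiles.rename_axis("asv_id").to_csv(out / "network_metrics.tsv", sep="\t")
        if group_tests is not None:
            group_tests.reset_index().to_csv(out / "group_tests.tsv",
                                             sep="\t", index=False)
        if loadings is not None:
            loadings.rename_axis("feature").to_csv(out / "pca_loadings.tsv", sep="\t")
            pd.DataFrame(
                {"component": [f"PC{i+1}" for i in range(len(variance))],
                 "variance_fraction": variance}
            ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
        write_graphml(network, out / "network.graphml")
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=1,
                                                      sort_keys=True))

    return ReportBundle(
        hits=hits, labels=labels, mra=mra, fraction_summary=summary,
        cumulative_curve=curve, rank_coverage=coverage,
        class_profile=class_profile, genus_profile=genus_profile,
        network=network, profiles=profiles, group_tests=group_tests,
        edge_sharing=sharing, edge_sharing_chi2=chi2_result,
        pca_loadings=loadings, pca_variance=variance, metadata=metadata,
    )
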