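"""Synthetic amplicon-survey bundles with planted culturability ground truth.

The generator emulates the statistical structure of a seed-endophyte style
study: a community of a few thousand V4-length ASVs with log-normal
rank-abundance, a small isolate set whose full-length 16S sequences contain
the V4 of a minority of community ASVs at controlled identities, strong
abundance enrichment of the cultured bin, a ranked taxonomy with a
configurable unclassified rate, and a latent interaction network with planted
hub nodes that modulates per-sample abundances.

Every bundle ships with a machine-readable truth manifest so each downstream
stage (identity mapping, binning, fraction statistics, network topology) has
a recovery test without any external data.

Community ASVs are planted in identity bins by substituting bases of an
isolate's V4 (substitution-only, so the ungapped best-hit identity is exact
by construction); "de novo" ASVs (planted identity = none) are independent
random sequences and land in the phylogenetically-distant bin under the
exact-scan contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .fractions import CULTURED, CLOSE, DISTANT, RANKS, ThresholdConfig
from .records import SequenceRecord, SequenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# number of distinct genera reachable by isolates vs de-novo ASVs; the
# hierarchy above genus is derived arithmetically (2 genera/family,
# 2 families/order, 2 orders/class, 3 classes/phylum)
_N_ISOLATE_GENERA = 36
_N_TOTAL_GENERA = 196


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle.

    Defaults emulate a community of 2000 ASVs over 40 samples at 50k reads
    per sample, with 6.32% of ASVs in the cultured bin carrying 89.2% of the
    mean relative abundance, and a 103-node latent network with 7 hubs and
    ~151 edges.
    """

    n_species: int = 2000
    v4_length: int = 250
    n_samples: int = 40
    depth_per_sample: int = 50_000
    n_isolates: int = 150
    isolate_flank_length: int = 600
    cultured_fraction_of_species: float = 0.0632
    # (identity %, proportion); identity None -> de-novo (distant) ASVs.
    # None -> a default ladder derived from cultured_fraction_of_species.
    identity_bin_targets: Optional[list[tuple[Optional[float], float]]] = None
    # exactly-planted cultured abundance share; set to None to use a fixed
    # multiplicative enrichment factor instead
    cultured_abundance_share: Optional[float] = 0.892
    cultured_abundance_enrichment: Optional[float] = None
    lognormal_sigma: float = 1.0
    n_hubs: int = 7
    edge_density: float = 0.0288
    n_network_nodes: int = 103
    network_cultured_fraction: float = 0.28
    hub_uncultured_bias: float = 0.8
    positive_edge_fraction: float = 0.907
    laplacian_beta: float = 0.5
    unclassified_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_species", "v4_length", "n_samples", "depth_per_sample",
                     "n_isolates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v4_length < 50:
            raise ValueError("v4_length must be >= 50")
        if not 0.0 <= self.cultured_fraction_of_species <= 1.0:
            raise ValueError("cultured_fraction_of_species must be in [0, 1]")
        if self.cultured_abundance_enrichment is not None:
            if self.cultured_abundance_enrichment < 1.0:
                raise ValueError("cultured_abundance_enrichment must be >= 1")
        if self.identity_bin_targets is not None:
            props = [p for _, p in self.identity_bin_targets]
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("identity_bin_targets proportions must sum to 1")
        if not 0 <= self.n_hubs <= self.n_network_nodes:
            raise ValueError("n_hubs must be within the network node count")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")

    def resolved_bin_targets(self) -> list[tuple[Optional[float], float]]:
        if self.identity_bin_targets is not None:
            return list(self.identity_bin_targets)
        cf = self.cultured_fraction_of_species
        close = [(97.0, 0.10), (92.0, 0.14), (87.0, 0.1006)]
        close_total = sum(p for _, p in close)
        rest = 1.0 - cf - close_total
        if rest < 0:
            raise ValueError("cultured fraction too large for default bin targets")
        return [(100.0, cf / 2), (99.6, cf - cf / 2), *close, (None, rest)]


@dataclass
class AsvTruth:
    """Planted ground truth for one community ASV."""

    asv_id: str
    source_isolate: Optional[str]
    planted_identity: Optional[float]
    planted_bin: str
    expected_mean_rel_abundance: Optional[float] = None


@dataclass
class TruthManifest:
    """Machine-readable ground truth of a synthetic bundle."""

    asvs: dict[str, AsvTruth]
    hubs: list[str]
    network_nodes: list[str]
    edges: list[tuple[str, str, str, float]]
    isolate_v4_offset: int
    config: dict

    def __post_init__(self) -> None:
        if len(self.asvs) != len({t.asv_id for t in self.asvs.values()}):
            raise ValueError("manifest ASV ids are not unique")

    @property
    def cultured_abundance_share(self) -> float:
        return sum(
            t.expected_mean_rel_abundance or 0.0
            for t in self.asvs.values()
            if t.planted_bin == CULTURED
        )

    def bin_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.asvs.values():
            counts[t.planted_bin] = counts.get(t.planted_bin, 0) + 1
        return counts

    def to_json(self, path: str | Path) -> None:
        payload = {
            "asvs": {k: asdict(v) for k, v in self.asvs.items()},
            "hubs": self.hubs,
            "network_nodes": self.network_nodes,
            "edges": [list(e) for e in self.edges],
            "isolate_v4_offset": self.isolate_v4_offset,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            asvs={k: AsvTruth(**v) for k, v in payload["asvs"].items()},
            hubs=list(payload["hubs"]),
            network_nodes=list(payload["network_nodes"]),
            edges=[(a, b, s, float(w)) for a, b, s, w in payload["edges"]],
            isolate_v4_offset=int(payload["isolate_v4_offset"]),
            config=payload["config"],
        )


def _sub_seed(root_seed: int, stream: int) -> int:
    """Derived per-stage seed (< 2**31), stable for a fixed root seed."""
    return int(np.random.SeedSequence([root_seed, stream]).generate_state(1)[0]
               & 0x7FFFFFFF)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def make_species_pool(
    n: int, length: int, seed: int, prefix: str = "SP"
) -> SequenceSet:
    """``n`` distinct uniform-composition random sequences of ``length`` nt."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        s = _random_seq(rng, length)
        if s not in seen:  # collisions are astronomically rare but cheap to guard
            seen.add(s)
            seqs.append(s)
    width = max(4, len(str(n)))
    return SequenceSet(
        SequenceRecord(f"{prefix}_{i + 1:0{width}d}", s) for i, s in enumerate(seqs)
    )


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mutate_to_identity(seq: str, target: float, seed: int) -> str:
    """Copy of ``seq`` with exactly ``round((1 - target/100) * len)`` substitutions.

    Substitutions hit distinct positions and always change the base, so the
    achieved ungapped identity is exactly ``matches / length`` (within
    ``1/length`` of the requested target).
    """
    if not 0.0 < target <= 100.0:
        raise ValueError(f"target identity must be in (0, 100], got {target}")
    n_sub = round_half_up((1.0 - target / 100.0) * len(seq))
    if n_sub > len(seq):
        raise ValueError("target implies more substitutions than positions")
    if n_sub == 0:
        return seq
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = bytearray(seq, "ascii")
    for pos in positions:
        alternatives = [b for b in b"ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return out.decode("ascii")


def achieved_identity(length: int, target: float) -> float:
    """The exact identity :func:`mutate_to_identity` realizes for a target."""
    n_sub = round_half_up((1.0 - target / 100.0) * length)
    return 100.0 * (length - n_sub) / length


def embed_in_full_length(v4: str, flank_length: int, seed: int) -> str:
    """Random 5' flank + V4 + random 3' flank (the V4 sits at ``flank_length``)."""
    if flank_length < 0:
        raise ValueError("flank_length must be >= 0")
    if flank_length == 0:
        return v4
    rng = np.random.default_rng(seed)
    return _random_seq(rng, flank_length) + v4 + _random_seq(rng, flank_length)


def largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` items to proportions, largest fractional remainder
    first (ties by position)."""
    quotas = [p * total for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    short = total - sum(counts)
    remainders = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


def _lineage(genus_idx: int) -> dict[str, str]:
    fam = genus_idx // 2
    order = fam // 2
    cls = order // 2
    phy = cls // 3
    return {
        "phylum": f"p{phy:02d}",
        "class": f"c{cls:02d}",
        "order": f"o{order:03d}",
        "family": f"f{fam:03d}",
        "genus": f"g{genus_idx:03d}",
    }


def _make_taxonomy(
    asv_genus: dict[str, int], unclassified_rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    rows = {}
    for asv_id, genus_idx in asv_genus.items():
        lineage = _lineage(genus_idx)
        if unclassified_rate > 0 and rng.random() < unclassified_rate:
            cut = int(rng.integers(1, len(RANKS)))  # keep at least the phylum
            for rank in RANKS[cut:]:
                lineage[rank] = ""
        rows[asv_id] = lineage
    tax = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    tax.index.name = "asv_id"
    return tax


# ---------------------------------------------------------------------------
# latent network
# ---------------------------------------------------------------------------


def _make_latent_network(
    nodes: list[str],
    cultured_nodes: set[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[tuple[str, str, str, float]]]:
    """Hub-and-spoke latent graph with random extra edges.

    Hubs form a ring and each receives 8-12 spokes, preferentially to
    uncultured nodes; edges are then topped up at random to the target
    density.  Returns (hubs, signed weighted edge list).
    """
    n = len(nodes)
    target_edges = round(config.edge_density * n * (n - 1) / 2)
    hubs = [nodes[i] for i in rng.choice(n, size=config.n_hubs, replace=False)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(len(hubs)):
        if len(hubs) > 1:
            g.add_edge(hubs[i], hubs[(i + 1) % len(hubs)])
    non_hubs = [v for v in nodes if v not in hubs]
    uncultured_pool = [v for v in non_hubs if v not in cultured_nodes]
    cultured_pool = [v for v in non_hubs if v in cultured_nodes]
    for h in hubs:
        n_spokes = int(rng.integers(8, 13))
        for _ in range(n_spokes):
            pool = (
                uncultured_pool
                if (rng.random() < config.hub_uncultured_bias and uncultured_pool)
                else (cultured_pool or uncultured_pool)
            )
            v = pool[int(rng.integers(len(pool)))]
            if v != h and not g.has_edge(h, v):
                g.add_edge(h, v)
    attempts = 0
    while g.number_of_edges() < target_edges and attempts < 50 * target_edges:
        a, b = rng.choice(n, size=2, replace=False)
        va, vb = nodes[int(a)], nodes[int(b)]
        if not g.has_edge(va, vb):
            g.add_edge(va, vb)
        attempts += 1
    edges = []
    for a, b in sorted(g.edges()):
        sign = "+" if rng.random() < config.positive_edge_fraction else "-"
        weight = float(np.round(rng.uniform(0.2, 0.9), 6))
        edges.append((a, b, sign, weight))
    return hubs, edges


# ---------------------------------------------------------------------------
# abundances and counts
# ---------------------------------------------------------------------------


def simulate_feature_table(
    config: SimConfig, manifest: TruthManifest
) -> pd.DataFrame:
    """Draw the samples x ASVs count table and fill the manifest's expected
    mean relative abundances.

    Base abundances are log-normal; the cultured bin is multiplied by either a
    fixed enrichment factor or the factor that plants the configured cultured
    abundance share exactly.  Per-sample modulation comes from a latent-graph
    Gaussian (precision ``I + beta * Laplacian``), exponentiated and
    standardized to mean 1 per node so the planted expectations are preserved;
    counts are multinomial at the configured depth.
    """
    if config.depth_per_sample <= 0:
        raise ValueError("depth_per_sample must be positive")
    asv_ids = list(manifest.asvs)
    n = len(asv_ids)
    rng_ab = np.random.default_rng(_sub_seed(config.seed, 20))
    base = rng_ab.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n)

    cultured_mask = np.array(
        [manifest.asvs[a].planted_bin == CULTURED for a in asv_ids]
    )
    if cultured_mask.any() and not cultured_mask.all():
        if config.cultured_abundance_share is not None:
            s = config.cultured_abundance_share
            cur_c = base[cultured_mask].sum()
            cur_u = base[~cultured_mask].sum()
            enrich = s * cur_u / ((1.0 - s) * cur_c)
        else:
            enrich = config.cultured_abundance_enrichment or 1.0
        base[cultured_mask] *= enrich
    expected = base / base.sum()
    for a, e in zip(asv_ids, expected):
        manifest.asvs[a].expected_mean_rel_abundance = float(e)

    # latent-graph per-sample modulation on network nodes
    factors = np.ones((n, config.n_samples))
    net_nodes = manifest.network_nodes
    if net_nodes and manifest.edges:
        idx = {a: i for i, a in enumerate(asv_ids)}
        g = nx.Graph()
        g.add_nodes_from(net_nodes)
        g.add_edges_from((a, b) for a, b, _, _ in manifest.edges)
        lap = nx.laplacian_matrix(g, nodelist=net_nodes).toarray()
        precision = np.eye(len(net_nodes)) + config.laplacian_beta * lap
        chol = np.linalg.cholesky(precision)
        rng_lat = np.random.default_rng(_sub_seed(config.seed, 21))
        z = rng_lat.standard_normal((len(net_nodes), config.n_samples))
        from scipy.linalg import solve_triangular

        gvals = solve_triangular(chol.T, z, lower=False)
        f = np.exp(gvals)
        f /= f.mean(axis=1, keepdims=True)
        rows = [idx[a] for a in net_nodes]
        factors[rows, :] = f

    rng_cnt = np.random.default_rng(_sub_seed(config.seed, 22))
    counts = np.empty((n, config.n_samples), dtype=np.int64)
    for s in range(config.n_samples):
        w = expected * factors[:, s]
        counts[:, s] = rng_cnt.multinomial(config.depth_per_sample, w / w.sum())
    table = pd.DataFrame(
        counts,
        index=pd.Index(asv_ids, name="asv_id"),
        columns=[f"S{j + 1:02d}" for j in range(config.n_samples)],
    )
    return table


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    """In-memory synthetic inputs plus their ground truth."""

    isolates: SequenceSet
    community: SequenceSet
    table: pd.DataFrame
    taxonomy: pd.DataFrame
    manifest: TruthManifest


def generate_bundle(config: SimConfig | None = None) -> SyntheticBundle:
    """Generate a complete synthetic input bundle with planted truth."""
    cfg = config or SimConfig()
    thresholds = ThresholdConfig()

    iso_v4 = make_species_pool(
        cfg.n_isolates, cfg.v4_length, _sub_seed(cfg.seed, 0), prefix="ISO"
    )
    iso_ids = iso_v4.ids
    isolates = SequenceSet(
        SequenceRecord(
            rec.id,
            embed_in_full_length(
                rec.sequence, cfg.isolate_flank_length, _sub_seed(cfg.seed, 1000 + i)
            ),
        )
        for i, rec in enumerate(iso_v4)
    )

    targets = cfg.resolved_bin_targets()
    counts = largest_remainder([p for _, p in targets], cfg.n_species)
    rng_assign = np.random.default_rng(_sub_seed(cfg.seed, 1))
    order = rng_assign.permutation(cfg.n_species)
    width = max(4, len(str(cfg.n_species)))
    asv_ids = [f"ASV_{i + 1:0{width}d}" for i in range(cfg.n_species)]

    truth: dict[str, AsvTruth] = {}
    community_records: list[SequenceRecord] = []
    asv_genus: dict[str, int] = {}
    rng_tax = np.random.default_rng(_sub_seed(cfg.seed, 2))
    pos = 0
    for bin_idx, ((target, _), n_bin) in enumerate(zip(targets, counts)):
        for k in range(n_bin):
            asv_id = asv_ids[order[pos]]
            pos += 1
            if target is None:
                seq = _random_seq(
                    np.random.default_rng(_sub_seed(cfg.seed, 5_000_000 + pos)),
                    cfg.v4_length,
                )
                truth[asv_id] = AsvTruth(asv_id, None, None, DISTANT)
                asv_genus[asv_id] = int(
                    rng_tax.integers(_N_ISOLATE_GENERA, _N_TOTAL_GENERA)
                )
            else:
                iso_idx = int(rng_assign.integers(cfg.n_isolates))
                src = iso_ids[iso_idx]
                seq = mutate_to_identity(
                    iso_v4[src].sequence, target, _sub_seed(cfg.seed, 2_000_000 + pos)
                )
                ident = achieved_identity(cfg.v4_length, target)
                if ident > thresholds.cultured_min:
                    planted_bin = CULTURED
                elif ident < thresholds.distant_max:
                    planted_bin = DISTANT
                else:
                    planted_bin = CLOSE
                truth[asv_id] = AsvTruth(asv_id, src, ident, planted_bin)
                asv_genus[asv_id] = iso_idx % _N_ISOLATE_GENERA
            community_records.append(SequenceRecord(asv_id, seq))

    community_records.sort(key=lambda r: r.id)
    community = SequenceSet(community_records)
    taxonomy = _make_taxonomy(asv_genus, cfg.unclassified_rate, rng_tax).loc[
        [r.id for r in community_records]
    ]

    # latent network over a subset of ASVs with a planted cultured quota
    rng_net = np.random.default_rng(_sub_seed(cfg.seed, 3))
    cultured_ids = [a for a, t in truth.items() if t.planted_bin == CULTURED]
    other_ids = [a for a in truth if truth[a].planted_bin != CULTURED]
    n_net = min(cfg.n_network_nodes, cfg.n_species)
    n_cult = min(round(cfg.network_cultured_fraction * n_net), len(cultured_ids))
    net_nodes = sorted(
        list(rng_net.choice(sorted(cultured_ids), size=n_cult, replace=False))
        + list(rng_net.choice(sorted(other_ids), size=n_net - n_cult, replace=False))
    )
    hubs, edges = _make_latent_network(net_nodes, set(cultured_ids), cfg, rng_net)

    manifest = TruthManifest(
        asvs=truth,
        hubs=sorted(hubs),
        network_nodes=net_nodes,
        edges=edges,
        isolate_v4_offset=cfg.isolate_flank_length,
        config=asdict(cfg),
    )
    table = simulate_feature_table(cfg, manifest)
    return SyntheticBundle(isolates, community, table, taxonomy, manifest)


def write_bundle(config: SimConfig, out_dir: str | Path) -> TruthManifest:
    """Generate a bundle and write its six files; returns the manifest.

    Files: ``isolates.fasta``, ``community.fasta``, ``feature_table.tsv``,
    ``taxonomy.tsv``, ``network_edges.tsv``, ``truth_manifest.json``.
    Re-running with the same config and seed reproduces identical content.
    """
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)
    pio.write_fasta(bundle.isolates, out / "isolates.fasta")
    pio.write_fasta(bundle.community, out / "community.fasta")
    pio.write_feature_table(bundle.table, out / "feature_table.tsv")
    pio.write_taxonomy(bundle.taxonomy, out / "taxonomy.tsv")
    pio.write_edge_list(bundle.manifest.edges, out / "network_edges.tsv")
    bundle.manifest.to_json(out / "truth_manifest.json")
    return bundle.manifest
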