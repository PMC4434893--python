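"""Synthetic regulatory networks with planted paths, plus the STS example.

The generator emulates the structure of curated TF-miRNA-gene networks:
three node strata with TF->gene, TF->miRNA, miRNA->gene and miRNA->TF
regulation drawn independently at per-pair densities, and optional planted
source-to-sink chains whose nodes are marked known/differentially expressed
at controlled rates.  Because genes never regulate, sinks always exist, and
TFs untouched by miRNA edges provide sources, mirroring the skewed
source/sink structure of real curated networks.  Everything is a pure
function of the spec (same seed, same output).

``sts_example`` returns a small curated example: the composite TF-miRNA
regulatory path reported in soft tissue sarcoma metastasis (12 ten-node
chains sharing components, merging into a 15-node, 18-edge graph), with
its known-disease and differential-expression annotations and the
candidate-path population (127 nodes, 27 known) they were scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import ContractError
from .netio import RegulationRecord
from .network import RegulatoryNetwork, build_network
from .pathfind import AcyclicPath, PathPopulation


def _default_density() -> dict[str, float]:
    return {"tf_gene": 0.07, "tf_mirna": 0.10, "mirna_gene": 0.05, "mirna_tf": 0.02}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic network draw.

    Defaults produce a 140-node background whose candidate-path node
    population lands near 115 nodes with a known fraction near 0.21 once a
    planted 10-node chain with 8 known nodes is included — the regime in
    which a high-coverage path is detectable at alpha = 0.001.
    """

    n_tf: int = 20
    n_mirna: int = 20
    n_gene: int = 100
    edge_density: dict[str, float] = field(default_factory=_default_density)
    n_planted_paths: int = 1
    planted_path_len: int = 10
    planted_known_fraction: float = 0.8
    background_known_fraction: float = 0.17
    de_fraction_on_path: float = 1.0
    de_fraction_background: float = 0.3
    seed_background_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_tf", "n_mirna", "n_gene", "n_planted_paths", "planted_path_len"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be >= 0")
        fractions = (
            "planted_known_fraction", "background_known_fraction",
            "de_fraction_on_path", "de_fraction_background",
            "seed_background_fraction",
        )
        for name in fractions:
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ContractError(f"{name} must be in [0, 1]")
        for key, value in self.edge_density.items():
            if not 0.0 <= value <= 1.0:
                raise ContractError(f"edge_density[{key!r}] must be in [0, 1]")
        if self.n_planted_paths and self.planted_path_len > (
            self.n_tf + self.n_mirna + self.n_gene
        ):
            raise ContractError("planted_path_len exceeds the total node count")

    def with_seed(self, rng_seed: int) -> "SyntheticSpec":
        return replace(self, rng_seed=rng_seed)


@dataclass
class SyntheticDataset:
    """Everything one draw of the generator produces."""

    records: list[RegulationRecord]
    seeds: set[str]
    known_ids: set[str]
    de_ids: set[str]
    planted_paths: list[AcyclicPath]


def _bernoulli_subset(rng: np.random.Generator, items: list[str], p: float) -> set[str]:
    if not items or p == 0.0:
        return set()
    mask = rng.random(len(items)) < p
    return {x for x, m in zip(items, mask) if m}


def generate_network(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one synthetic network + seed/known/DE annotation sets.

    Background edges connect the three strata at the spec'd densities.
    Each planted chain alternates TF and miRNA nodes and ends in a gene;
    its nodes are fresh (disjoint from the background), so the chain head
    is a genuine source and the tail a genuine sink.  All planted nodes
    are seeds; a fraction of background nodes are seeds too.
    """
    rng = np.random.default_rng(spec.rng_seed)
    tfs = [f"TF{i:03d}" for i in range(spec.n_tf)]
    mirs = [f"hsa-miR-s{i:03d}" for i in range(spec.n_mirna)]
    genes = [f"G{i:03d}" for i in range(spec.n_gene)]

    records: list[RegulationRecord] = []

    def wire(sources, src_class, targets, tgt_class, density):
        if not sources or not targets or density == 0.0:
            return
        mask = rng.random((len(sources), len(targets))) < density
        for i, j in np.argwhere(mask):
            records.append(
                RegulationRecord(sources[i], src_class, targets[j], tgt_class, "sim")
            )

    wire(tfs, "TF", genes, "gene", spec.edge_density.get("tf_gene", 0.0))
    wire(tfs, "TF", mirs, "miRNA", spec.edge_density.get("tf_mirna", 0.0))
    wire(mirs, "miRNA", genes, "gene", spec.edge_density.get("mirna_gene", 0.0))
    wire(mirs, "miRNA", tfs, "TF", spec.edge_density.get("mirna_tf", 0.0))

    planted_paths: list[AcyclicPath] = []
    planted_nodes: list[str] = []
    for j in range(spec.n_planted_paths):
        chain: list[str] = []
        chain_classes: list[str] = []
        for pos in range(spec.planted_path_len):
            if pos == spec.planted_path_len - 1:
                cls = "gene"
            elif pos % 2 == 0:
                cls = "TF"
            else:
                cls = "miRNA"
            prefix = {"TF": "pTF", "miRNA": "hsa-miR-p", "gene": "pG"}[cls]
            chain.append(f"{prefix}{j:02d}-{pos:02d}")
            chain_classes.append(cls)
        for (u, cu), (v, cv) in zip(
            zip(chain, chain_classes), zip(chain[1:], chain_classes[1:])
        ):
            records.append(RegulationRecord(u, cu, v, cv, "planted"))
        planted_paths.append(AcyclicPath(tuple(chain)))
        planted_nodes.extend(chain)

    background = tfs + mirs + genes
    known = _bernoulli_subset(rng, background, spec.background_known_fraction)
    de = _bernoulli_subset(rng, background, spec.de_fraction_background)
    seeds = _bernoulli_subset(rng, background, spec.seed_background_fraction)

    for chain_path in planted_paths:
        chain = list(chain_path.nodes)
        n_known = round(spec.planted_known_fraction * len(chain))
        known.update(map(str, rng.choice(chain, size=n_known, replace=False)))
        n_de = round(spec.de_fraction_on_path * len(chain))
        de.update(map(str, rng.choice(chain, size=n_de, replace=False)))
        seeds.update(chain)

    return SyntheticDataset(
        records=records,
        seeds=seeds,
        known_ids=known,
        de_ids=de,
        planted_paths=planted_paths,
    )


# --- curated STS metastasis example ---------------------------------------

# The 12 significant ten-node chains: two upstream entries (AP2 directly to
# MYC, or BMP-2 via hsa-miR-24), two MYC-repressed miRNAs relaying to PTEN,
# three PTEN-regulated miRNAs relaying to ESR1, and a common tail
# TP53 -> hsa-miR-215 -> TYMS (ESR1 acts on TP53 via FOS on the AP2 side,
# directly on the BMP-2 side).
_MYC_MIRS = ("hsa-miR-26a", "hsa-miR-221")
_PTEN_MIRS = ("hsa-miR-22", "hsa-miR-19a", "hsa-miR-302c")

_STS_CLASSES = {
    "AP2": "TF", "BMP-2": "TF", "MYC": "TF", "PTEN": "TF", "ESR1": "TF",
    "FOS": "TF", "TP53": "TF", "TYMS": "gene",
    "hsa-miR-24": "miRNA", "hsa-miR-26a": "miRNA", "hsa-miR-221": "miRNA",
    "hsa-miR-22": "miRNA", "hsa-miR-19a": "miRNA", "hsa-miR-302c": "miRNA",
    "hsa-miR-215": "miRNA",
}

#: the 9 path entities with prior soft-tissue-sarcoma association
_STS_KNOWN = frozenset(
    {"AP2", "BMP-2", "MYC", "hsa-miR-26a", "hsa-miR-221", "PTEN", "ESR1", "TP53", "TYMS"}
)


def sts_chains() -> list[AcyclicPath]:
    """The 12 significant ten-node STS metastasis chains."""
    chains = []
    for m in _MYC_MIRS:
        for x in _PTEN_MIRS:
            chains.append(AcyclicPath((
                "AP2", "MYC", m, "PTEN", x, "ESR1", "FOS", "TP53",
                "hsa-miR-215", "TYMS",
            )))
    for m in _MYC_MIRS:
        for x in _PTEN_MIRS:
            chains.append(AcyclicPath((
                "BMP-2", "hsa-miR-24", "MYC", m, "PTEN", x, "ESR1", "TP53",
                "hsa-miR-215", "TYMS",
            )))
    return chains


@dataclass
class StsExample:
    """The merged STS composite-path network and its annotations."""

    network: RegulatoryNetwork
    chains: list[AcyclicPath]
    known_ids: frozenset[str]
    de_ids: frozenset[str]
    population: PathPopulation


def sts_example() -> StsExample:
    """The 15-node / 18-edge composite STS metastasis path network.

    Known ids are the 9 path entities with direct STS association (each
    original chain holds exactly 7 of them, the merged 15-node set 9).
    The DE set equals the known set — a documented convention giving every
    chain a DE fraction of 0.7, comfortably past the 50% filter.  The
    population (127 candidate-path nodes, 27 known) is the one the chains
    were scored against.
    """
    chains = sts_chains()
    records: list[RegulationRecord] = []
    for chain in chains:
        for u, v in zip(chain.nodes, chain.nodes[1:]):
            records.append(
                RegulationRecord(u, _STS_CLASSES[u], v, _STS_CLASSES[v], "sts")
            )
    return StsExample(
        network=build_network(records),
        chains=chains,
        known_ids=_STS_KNOWN,
        de_ids=_STS_KNOWN,
        population=PathPopulation(n_total=127, n_known=27),
    )
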