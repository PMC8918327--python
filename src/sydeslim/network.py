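"""Tiered SYDE interaction-network assembly and export.

Nodes are SYDE hubs plus interactor entities; edges carry an evidence tier:

- ``curated-low-throughput`` — published low-throughput experiments
  (coIP, pull-down, Y2H, ITC, FLAP);
- ``high-throughput-or-predicted`` — high-throughput screens (AP-MS) and
  linear-motif predictions;
- ``conserved-inferred`` — motifs inferred from conservation with a partner
  proven in a lower organism (the GSK3 site);
- ``structural-prediction`` — docking-derived RhoGTPase substrate edges.

Entity convention: proteins listed together in one curated row ("Cyclin
B/CDK1", "P38alpha, p38beta") are one entity; the same protein appearing in
several rows is merged into a single node keyed by the row listing's first-
named protein.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .catalog import Catalog

TIERS = (
    "curated-low-throughput",
    "high-throughput-or-predicted",
    "conserved-inferred",
    "structural-prediction",
)
CATEGORIES = (
    "Rho-family modulator", "synaptogenesis", "intracellular homeostasis",
    "neuronal differentiation", "uncategorized",
)
MOLECULE_CLASSES = ("kinase", "phosphatase", "adaptor", "degradation machinery",
                    "GTPase", "other")
METHOD_VOCAB = frozenset({"AP-MS", "FLAP", "Y2H", "coIP", "pull-down", "ITC"})
_LOW_THROUGHPUT = frozenset({"FLAP", "Y2H", "coIP", "pull-down", "ITC"})

#: classes whose predicted edge is inferred from conservation with a partner
#: demonstrated in a lower organism (dotted tier)
CONSERVED_INFERRED_CLASSES = frozenset({"mod_gsk3_1"})

HUBS = ("SYDE1", "SYDE2", "DmSyd1")


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkNode:
    name: str
    kind: str  # "SYDE hub" | "interactor"
    category: str = "uncategorized"
    molecule_class: str = "other"


@dataclass(frozen=True)
class NetworkEdge:
    hub: str  # SYDE1 | SYDE2 | DmSyd1
    interactor: str  # canonical node name
    tier: str
    motif_id: str = ""  # required for predicted-SLiM edges
    region: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise NetworkError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class CuratedInteraction:
    """One lower-panel row of the curated interaction table."""

    protein: str
    interactor: str
    domain_architecture: str = ""
    pathway: str = ""
    methods: tuple[str, ...] = ()
    ref: str = ""
    region: str = ""
    category: str = "uncategorized"
    molecule_class: str = "other"

    def __post_init__(self) -> None:
        bad = set(self.methods) - METHOD_VOCAB
        if bad:
            raise NetworkError(f"{self.interactor}: unknown method(s) {sorted(bad)}")


@dataclass(frozen=True)
class InteractionNetwork:
    nodes: tuple[NetworkNode, ...]
    edges: tuple[NetworkEdge, ...]


def _primary(name: str) -> str:
    """First-named protein of a row listing, the canonical merge key."""
    return name.replace("/", ",").split(",")[0].strip().casefold()


def load_curated(path: str | Path | None = None) -> list[CuratedInteraction]:
    src = (
        Path(path)
        if path is not None
        else Path(resources.files("sydeslim").joinpath("data/curated_interactions.tsv"))  # type: ignore[arg-type]
    )
    df = pd.read_csv(src, sep="\t").fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            CuratedInteraction(
                protein=row["protein"],
                interactor=row["interactor"],
                domain_architecture=row["domain_architecture"],
                pathway=row["pathway"],
                methods=tuple(m for m in str(row["methods"]).split(";") if m),
                ref=row["ref"],
                region=row["region"],
                category=row["category"],
                molecule_class=row["molecule_class"],
            )
        )
    return out


def candidates_from_catalog(catalog: Catalog) -> pd.DataFrame:
    """Candidate table synthesized from the packaged motif instances.

    Used to assemble the published network without re-running the scanner:
    every packaged instance is a retained candidate.
    """
    rows = []
    for inst in catalog.instances:
        cls = catalog.get_class(inst.motif_id)
        rows.append(
            {
                "protein_id": inst.protein_id,
                "motif_id": inst.motif_id,
                "start": inst.start,
                "end": inst.end,
                "peptide": inst.peptide,
                "site_probability": cls.elm_score_printed,
                "in_disorder": True,
                "conserved_fraction": float("nan"),
                "retained": True,
                "reasons": "packaged instance",
            }
        )
    return pd.DataFrame(rows)


def assemble(
    curated: list[CuratedInteraction],
    candidates: pd.DataFrame | None,
    catalog: Catalog,
    include_structural: bool = True,
) -> InteractionNetwork:
    """Merge curated rows, retained SLiM candidates and docking edges.

    Every predicted edge must name a catalog motif class (unknown ids are
    an error); duplicate (hub, entity, tier, motif) combinations collapse.
    Node order is lexicographic, so assembly is deterministic and
    idempotent.
    """
    known_ids = {c.motif_id for c in catalog.classes}
    # primary-key -> display name + attributes; first writer wins on name,
    # later rows may upgrade category/class from "uncategorized"/"other"
    entities: dict[str, NetworkNode] = {}
    edges: list[NetworkEdge] = []

    def add_entity(name: str, category: str, molecule_class: str) -> str:
        key = _primary(name)
        existing = entities.get(key)
        if existing is None:
            entities[key] = NetworkNode(name, "interactor", category, molecule_class)
        else:
            name_new = existing.name
            # when two rows list different groupings sharing a primary
            # protein, the node keeps the shared primary protein's name
            if _primary(existing.name) == key and existing.name.casefold() != name.casefold():
                shorter = min((existing.name, name), key=len)
                name_new = (
                    shorter
                    if _primary(shorter) == key
                    else existing.name
                )
            category_new = existing.category
            if category_new == "uncategorized" and category != "uncategorized":
                category_new = category
            mc_new = existing.molecule_class
            if mc_new == "other" and molecule_class != "other":
                mc_new = molecule_class
            entities[key] = replace(existing, name=name_new, category=category_new,
                                    molecule_class=mc_new)
        return key

    for row in curated:
        key = add_entity(row.interactor, row.category, row.molecule_class)
        tier = (
            "curated-low-throughput"
            if set(row.methods) & _LOW_THROUGHPUT
            else "high-throughput-or-predicted"
        )
        edges.append(
            NetworkEdge(hub=row.protein, interactor=key, tier=tier,
                        region=row.region, reference=row.ref)
        )

    if candidates is not None and len(candidates):
        retained = candidates[candidates["retained"]]
        for _, row in retained.iterrows():
            motif_id = row["motif_id"]
            if motif_id not in known_ids:
                raise NetworkError(f"candidate row names unknown motif_id {motif_id!r}")
            cls = catalog.get_class(motif_id)
            key = add_entity(cls.interactor, cls.category, cls.molecule_class)
            tier = (
                "conserved-inferred"
                if motif_id in CONSERVED_INFERRED_CLASSES
                else "high-throughput-or-predicted"
            )
            edges.append(
                NetworkEdge(hub=row["protein_id"], interactor=key, tier=tier,
                            motif_id=motif_id,
                            region=f"{row['start']}-{row['end']} {row['peptide']}")
            )

    if include_structural:
        for sp in catalog.structural:
            key = add_entity(sp.interactor, sp.category, sp.molecule_class)
            for hub in sp.proteins:
                edges.append(
                    NetworkEdge(hub=hub, interactor=key, tier="structural-prediction",
                                region=sp.region)
                )

    # canonicalize edge interactor display names, dedupe, sort
    name_of = {key: node.name for key, node in entities.items()}
    final_edges = []
    seen = set()
    for e in edges:
        e = replace(e, interactor=name_of[e.interactor])
        sig = (e.hub, e.interactor, e.tier, e.motif_id, e.region)
        if sig not in seen:
            seen.add(sig)
            final_edges.append(e)
    final_edges.sort(key=lambda e: (e.hub, e.interactor, e.tier, e.motif_id))

    hubs = [NetworkNode(h, "SYDE hub") for h in ("SYDE1", "SYDE2")]
    if any(e.hub == "DmSyd1" for e in final_edges):
        hubs.append(NetworkNode("DmSyd1", "SYDE hub"))
    interactors = sorted(entities.values(), key=lambda n: n.name)
    return InteractionNetwork(tuple(hubs + interactors), tuple(final_edges))


def predicted_entities(network: InteractionNetwork, hub: str) -> list[str]:
    """Distinct interactor entities linked to a hub by predicted evidence
    (linear-motif, conserved-inferred or docking tiers)."""
    predicted_tiers = {
        "high-throughput-or-predicted", "conserved-inferred", "structural-prediction",
    }
    names = {
        e.interactor
        for e in network.edges
        if e.hub == hub and e.tier in predicted_tiers and (e.motif_id or
                                                           e.tier == "structural-prediction")
    }
    return sorted(names)


def summarize(network: InteractionNetwork) -> pd.DataFrame:
    """Edge counts per hub x tier, and node counts per category."""
    rows = []
    for hub in sorted({e.hub for e in network.edges}):
        for tier in TIERS:
            n = sum(1 for e in network.edges if e.hub == hub and e.tier == tier)
            if n:
                rows.append({"level": "hub-tier", "key": f"{hub}|{tier}", "count": n})
        rows.append({
            "level": "hub-predicted-entities",
            "key": hub,
            "count": len(predicted_entities(network, hub)),
        })
    for cat in CATEGORIES:
        n = sum(1 for nd in network.nodes if nd.kind == "interactor" and nd.category == cat)
        if n:
            rows.append({"level": "category", "key": cat, "count": n})
    return pd.DataFrame(rows, columns=["level", "key", "count"])


def to_networkx(network: InteractionNetwork) -> nx.MultiGraph:
    g = nx.MultiGraph()
    for node in network.nodes:
        g.add_node(node.name, kind=node.kind, category=node.category,
                   molecule_class=node.molecule_class)
    for e in network.edges:
        g.add_edge(e.hub, e.interactor, tier=e.tier, motif_id=e.motif_id,
                   region=e.region, reference=e.reference)
    return g


def export(network: InteractionNetwork, out_prefix: str | Path, fmt: str = "tsv") -> list[Path]:
    """Write the network: ``tsv`` (node/edge pair) or ``gml``."""
    out_prefix = Path(out_prefix)
    if fmt == "tsv":
        nodes_path = out_prefix.with_suffix(".nodes.tsv")
        edges_path = out_prefix.with_suffix(".edges.tsv")
        pd.DataFrame([n.__dict__ for n in network.nodes]).to_csv(
            nodes_path, sep="\t", index=False)
        pd.DataFrame([e.__dict__ for e in network.edges]).to_csv(
            edges_path, sep="\t", index=False)
        return [nodes_path, edges_path]
    if fmt == "gml":
        path = out_prefix.with_suffix(".gml")
        nx.write_gml(to_networkx(network), path)
        return [path]
    raise NetworkError(f"unknown export format {fmt!r}")


def import_tsv(out_prefix: str | Path) -> InteractionNetwork:
    out_prefix = Path(out_prefix)
    nodes_df = pd.read_csv(out_prefix.with_suffix(".nodes.tsv"), sep="\t").fillna("")
    edges_df = pd.read_csv(out_prefix.with_suffix(".edges.tsv"), sep="\t").fillna("")
    nodes = tuple(
        NetworkNode(r["name"], r["kind"], r["category"], r["molecule_class"])
        for _, r in nodes_df.iterrows()
    )
    edges = tuple(
        NetworkEdge(r["hub"], r["interactor"], r["tier"], r["motif_id"],
                    r["region"], str(r["reference"]))
        for _, r in edges_df.iterrows()
    )
    return InteractionNetwork(nodes, edges)
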