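"""Food source -> food compound -> drug network of concentration-
altering drug-food interactions.

Only validated interactions with the food compound as subject and a
type in the eight-member concentration set {1,2,4,5,6,7,9,10} enter the
network; each is labeled as a decrease ({1,4,7,9}) or increase
({2,5,6,10}) of the drug's in vivo concentration.  Each compound is
linked to at most its top-k (default 10) richest food sources.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .config import (CONC_DECREASE_TYPES, CONC_INCREASE_TYPES,
                     CONCENTRATION_TYPES, TOP_SOURCES_K)
from .corpus import InteractionRecord
from .interaction_predictor import classify_dfi_orientation


def concentration_effect(type_id: int) -> str:
    """'decrease' or 'increase' of drug concentration for a type of the
    concentration set; pure table lookup."""
    if type_id in CONC_DECREASE_TYPES:
        return "decrease"
    if type_id in CONC_INCREASE_TYPES:
        return "increase"
    raise ValueError(f"type {type_id} is not concentration-altering")


def filter_concentration_dfis(validated: Iterable[InteractionRecord],
                              food_ids: set[str]) -> list[InteractionRecord]:
    """Validated records with a concentration-altering type and the
    food compound as subject."""
    out = []
    for rec in validated:
        if rec.type_id not in CONCENTRATION_TYPES:
            continue
        if classify_dfi_orientation(rec, food_ids) != "compound_affects_drug":
            continue
        out.append(rec)
    return out


def top_sources(compound_id: str, contents: pd.DataFrame,
                k: int = TOP_SOURCES_K, by: str = "max") -> pd.DataFrame:
    """Up to k food sources richest in the compound.

    Ranked by the per-source maximum reported amount (``by='mean'``
    averages instead); ties break lexicographically by source name.
    Returns an empty frame for compounds absent from the table.
    """
    sub = contents[contents["compound_id"] == compound_id]
    if sub.empty:
        return sub.iloc[0:0]
    agg = (sub.groupby(["source_id", "source_name"], as_index=False)
           ["amount_mg_per_100g"].agg(by))
    agg = agg.sort_values(["amount_mg_per_100g", "source_name"],
                          ascending=[False, True], kind="mergesort")
    return agg.head(k).reset_index(drop=True)


def build_network(filtered: Sequence[InteractionRecord],
                  contents: pd.DataFrame, food_ids: set[str],
                  k: int = TOP_SOURCES_K, by: str = "max",
                  drug_class: Mapping[str, str] | None = None) -> nx.DiGraph:
    """Assemble the typed graph; nodes appear only on retained edges.

    Node attribute ``kind`` is one of food_source / food_compound /
    drug; ``alters`` edges carry ``type_id`` and ``effect``; ``contains``
    edges carry the ranking ``amount``.
    """
    g = nx.DiGraph()
    drug_class = drug_class or {}
    compounds_used = set()
    for rec in filtered:
        food, drug = rec.subject_id, rec.object_id
        g.add_node(food, kind="food_compound")
        g.add_node(drug, kind="drug", drug_class=drug_class.get(drug, ""))
        g.add_edge(food, drug, relation="alters", type_id=rec.type_id,
                   effect=concentration_effect(rec.type_id),
                   score=round(rec.score, 6))
        compounds_used.add(food)
    for comp in sorted(compounds_used):
        for row in top_sources(comp, contents, k=k, by=by).itertuples(index=False):
            g.add_node(row.source_id, kind="food_source", name=row.source_name)
            g.add_edge(row.source_id, comp, relation="contains",
                       amount=float(row.amount_mg_per_100g))
    return g


def subnetwork_by_drug_class(g: nx.DiGraph, drug_class: str) -> nx.DiGraph:
    """Restrict the network to one drug class (e.g. all S1P modulators
    or all BTK inhibitors) plus its compounds and their sources."""
    drugs = {n for n, d in g.nodes(data=True)
             if d.get("kind") == "drug" and d.get("drug_class") == drug_class}
    compounds = {u for u, v, d in g.edges(data=True)
                 if d["relation"] == "alters" and v in drugs}
    sources = {u for u, v, d in g.edges(data=True)
               if d["relation"] == "contains" and v in compounds}
    return g.subgraph(drugs | compounds | sources).copy()


def export_graphml(g: nx.DiGraph, path) -> None:
    nx.write_graphml(g, path)


def export_sif(g: nx.DiGraph, path) -> None:
    """Simple-interaction-format edge list (source relation target)."""
    with open(path, "w") as fh:
        for u, v, d in g.edges(data=True):
            fh.write(f"{u}\t{d['relation']}\t{v}\n")


def export_attribute_tables(g: nx.DiGraph, node_path, edge_path) -> None:
    nodes = pd.DataFrame([{"node": n, **d} for n, d in g.nodes(data=True)])
    edges = pd.DataFrame([{"source": u, "target": v, **d}
                          for u, v, d in g.edges(data=True)])
    nodes.to_csv(node_path, index=False)
    edges.to_csv(edge_path, index=False)
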