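"""Weighted directed class networks from peer-nomination records.

Each class yields one static directed graph pooling all four waves.  An edge
u -> v exists when u nominated v on at least one of the six sociometric
questions; its weight is the number of *distinct* questions on which u ever
nominated v, divided by six, so weights live on the grid {1/6, ..., 6/6}.
Duplicate nominations (same nominator, nominee and question in different
waves) count once.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import pandas as pd

from .cohort import N_QUESTIONS, N_WAVES, NominationRecord

__all__ = ["build_class_network", "mutual_dyads", "networks_from_tables"]


def _iter_nominations(nominations) -> Iterable[tuple[str, str, int, int]]:
    if isinstance(nominations, pd.DataFrame):
        cols = ["nominator_id", "nominee_id", "question_id", "wave"]
        yield from nominations[cols].itertuples(index=False, name=None)
    else:
        for nm in nominations:
            if isinstance(nm, NominationRecord):
                yield nm.nominator_id, nm.nominee_id, nm.question_id, nm.wave
            else:
                yield tuple(nm)


def build_class_network(nominations, roster, class_id: str | None = None) -> nx.DiGraph:
    """Build the weighted directed network of one class.

    Parameters
    ----------
    nominations
        Nomination records for this class: a DataFrame with columns
        nominator_id, nominee_id, question_id, wave, or an iterable of
        :class:`~peerspread.cohort.NominationRecord`.
    roster
        Participant ids of the class.  Every id becomes a node, including
        pupils who never nominated and were never nominated; their activity
        still evolves through the environment term of the simulation.

    Raises
    ------
    ValueError
        On off-roster ids, self-nominations, or out-of-range question/wave.
    """
    roster = list(roster)
    roster_set = set(roster)
    if len(roster_set) != len(roster):
        raise ValueError("duplicate ids on roster")
    g = nx.DiGraph(class_id=class_id)
    g.add_nodes_from(roster)
    seen: set[tuple[str, str, int]] = set()
    for u, v, q, w in _iter_nominations(nominations):
        if u not in roster_set or v not in roster_set:
            raise ValueError(f"nomination {u!r}->{v!r} involves an id not on the roster")
        if u == v:
            raise ValueError(f"self-nomination by {u!r}")
        if not 1 <= q <= N_QUESTIONS:
            raise ValueError(f"question_id {q} outside 1..{N_QUESTIONS}")
        if not 1 <= w <= N_WAVES:
            raise ValueError(f"wave {w} outside 1..{N_WAVES}")
        seen.add((u, v, int(q)))
    counts: dict[tuple[str, str], int] = {}
    for u, v, _ in seen:
        counts[(u, v)] = counts.get((u, v), 0) + 1
    for (u, v), k in counts.items():
        g.add_edge(u, v, weight=k / N_QUESTIONS)
    return g


def mutual_dyads(network: nx.DiGraph) -> set[frozenset]:
    """Unordered pairs with nominations in both directions."""
    out = set()
    for u, v in network.edges:
        if network.has_edge(v, u):
            out.add(frozenset((u, v)))
    return out


def networks_from_tables(participants: pd.DataFrame,
                         nominations: pd.DataFrame) -> dict[str, nx.DiGraph]:
    """One network per class from the cohort tables, keyed by class_id."""
    networks: dict[str, nx.DiGraph] = {}
    nom_by_nominator_class = nominations.assign(
        class_id=nominations["nominator_id"].map(
            participants.set_index("participant_id")["class_id"]
        )
    )
    for class_id, group in participants.groupby("class_id", sort=True):
        roster = group["participant_id"].tolist()
        class_noms = nom_by_nominator_class[nom_by_nominator_class["class_id"] == class_id]
        networks[class_id] = build_class_network(class_noms, roster, class_id=class_id)
    return networks
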