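"""Compact letter displays from pairwise decision matrices.

Groups sharing a letter are not significantly different.  Letters are the
maximal cliques of the "not significantly different" graph, ordered so that
the letter ``a`` goes to the clique containing the best (largest-mean)
group.  This is consistent with the pairwise decisions by construction:
every non-significant pair shares some maximal clique, and a significant
pair can never co-occur in a clique because the graph has no edge for it.
"""

from __future__ import annotations

import string

import networkx as nx
import numpy as np

__all__ = ["compact_letters"]


def compact_letters(means, significant) -> list[str]:
    """Assign letters to groups.

    Parameters
    ----------
    means : sequence of float
        Group means (used only for ordering: larger mean sorts earlier).
    significant : (k, k) boolean array
        ``significant[i, j]`` is True when groups i and j differ at the
        chosen alpha.  Must be symmetric with a False diagonal.

    Returns
    -------
    list of str
        Letter string per group, e.g. ``["a", "ab", "b"]``.
    """
    means = np.asarray(means, dtype=float)
    sig = np.asarray(significant, dtype=bool)
    k = len(means)
    if sig.shape != (k, k):
        raise ValueError(f"significance matrix shape {sig.shape} != ({k}, {k})")
    if np.any(sig != sig.T) or np.any(np.diag(sig)):
        raise ValueError("significance matrix must be symmetric with a False diagonal")

    graph = nx.Graph()
    graph.add_nodes_from(range(k))
    graph.add_edges_from(
        (i, j) for i in range(k) for j in range(i + 1, k) if not sig[i, j]
    )
    cliques = [frozenset(c) for c in nx.find_cliques(graph)]
    # letter order: by the best group in each clique, best mean first
    cliques.sort(key=lambda c: (-max(means[i] for i in c), sorted(c)))

    alphabet = string.ascii_lowercase
    labels: list[list[str]] = [[] for _ in range(k)]
    for idx, clique in enumerate(cliques):
        letter = alphabet[idx] if idx < 26 else f"l{idx}"
        for g in clique:
            labels[g].append(letter)
    return ["".join(sorted(ls)) for ls in labels]
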