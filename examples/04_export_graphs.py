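"""Export one molecule as adjacency matrix, connection table and
attribute-labeled graph, and hand the graph to networkx.

The three views describe the same molecular graph: the binary adjacency
row sums are the vertex degrees, and for benzene every degree is 2
(a six-cycle).
"""

import networkx as nx

from molstream import (adjacency_matrix, canned_fixture, connection_table,
                       to_labeled_graph)

_, benzene = canned_fixture("benzene_kekulized")

am = adjacency_matrix(benzene, mode="weighted")
print("weighted adjacency matrix (aromatic would be 1.5):")
print(am.values)
print(f"binary row sums (= degrees): "
      f"{adjacency_matrix(benzene).values.sum(axis=1)}")

print("\nconnection table:")
for row in connection_table(benzene).rows:
    print(" ", row)

g = to_labeled_graph(benzene)
print(f"\nlabeled graph: {g.number_of_nodes()} vertices, "
      f"{g.number_of_edges()} edges, "
      f"{nx.number_connected_components(g)} component(s)")
print(f"vertex 1 attributes: {g.nodes[1]}")
# From here any networkx/igraph-style topological analysis applies, e.g.
# the Wiener index as the sum of all shortest-path lengths:
wiener = sum(nx.shortest_path_length(g, u, v)
             for u in g for v in g if u < v)
print(f"Wiener index of benzene: {wiener}")

# hydrogen suppression: methane with explicit hydrogens collapses to C
_, methane = canned_fixture("methane_full_H")
hs = to_labeled_graph(methane, hydrogen_policy="suppress")
print(f"\nmethane H-suppressed: {hs.number_of_nodes()} vertex, "
      f"{hs.number_of_edges()} edges")
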