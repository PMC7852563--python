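import numpy as np
import pandas as pd
import pytest

from mdmnet import CommunityTable, CooccurrenceNetwork, parse_lineage


def make_table(counts, otu_ids=None, sample_ids=None, lineages=None, environment=""):
    """Build a CommunityTable from a plain array and optional lineages."""
    counts = np.asarray(counts)
    p, n = counts.shape
    otu_ids = otu_ids or [f"OTU{i}" for i in range(p)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n)]
    lineages = lineages or [f"Bacteria;P{i};C{i};O{i};F{i};G{i}" for i in range(p)]
    taxonomy = {o: parse_lineage(lin, o) for o, lin in zip(otu_ids, lineages)}
    return CommunityTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
        taxonomy=taxonomy,
        environment=environment,
    )


def make_net(nodes, edges, unknown=(), class_labels=None, method="mb"):
    """Build a CooccurrenceNetwork directly from an edge list.

    ``unknown`` nodes get an "uncultured" genus (Unknown at genus);
    ``class_labels`` optionally sets the class-rank label per node.
    """
    taxonomy = {}
    for node in nodes:
        cls = (class_labels or {}).get(node, f"C_{node}")
        genus = "uncultured" if node in unknown else f"G_{node}"
        taxonomy[node] = parse_lineage(
            f"Bacteria;P;{cls};O;F;{genus}", node
        )
    return CooccurrenceNetwork(
        nodes=list(nodes),
        edges={tuple(sorted(e)) for e in edges},
        taxonomy=taxonomy,
        method=method,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
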