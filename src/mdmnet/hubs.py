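"""Hub-score ranking, Known-vs-Unknown hub tests and sequence export.

Taxa with the highest hub scores are the prioritization output of the
pipeline: candidate keystone organisms whose 16S sequences are worth
using as probes against metagenome databases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import CentralityTable
from .stats import welch_ttest

__all__ = [
    "HubRanking",
    "rank_hubs",
    "hub_score_ttest",
    "export_top_hub_sequences",
    "read_fasta",
]


@dataclass
class HubRanking:
    """Full hub-score ordering of one network's nodes.

    Sorted by hub score descending; ties broken by degree (descending)
    then otu_id, so re-runs produce identical orderings.
    """

    table: pd.DataFrame  # columns: position, otu_id, hub_score, degree, unknown, label
    rank: str

    def top_unknown_proportion(self, n: int = 20) -> float:
        top = self.table.head(n)
        return float(top["unknown"].mean()) if len(top) else float("nan")

    def top_ids(self, unknown: bool | None = None, n: int = 5) -> list[str]:
        sub = self.table
        if unknown is not None:
            sub = sub[sub["unknown"] == unknown]
        return list(sub.head(n)["otu_id"])


def rank_hubs(cent: CentralityTable, rank: str) -> HubRanking:
    """Order all nodes by hub score (deterministic tie-breaks)."""
    net = cent.network
    flags = net.unknown_flags(rank)
    labels = net.labels(rank)
    df = pd.DataFrame(
        {
            "otu_id": cent.table.index,
            "hub_score": cent.table["hub_score"].to_numpy(),
            "degree": cent.table["degree"].to_numpy(),
            "unknown": flags.reindex(cent.table.index).to_numpy(),
            "label": labels.reindex(cent.table.index).to_numpy(),
        }
    )
    df = df.sort_values(
        ["hub_score", "degree", "otu_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df.insert(0, "position", np.arange(1, len(df) + 1))
    return HubRanking(df, rank)


def hub_score_ttest(
    known_scores, unknown_scores, *, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test of Known vs Unknown hub scores.

    Welch (unequal variance) by default; ``equal_var=True`` gives the
    classic pooled test.  Returns ``(t, p)``.
    """
    known = np.asarray(known_scores, dtype=float)
    unknown = np.asarray(unknown_scores, dtype=float)
    if known.size < 2 or unknown.size < 2:
        raise ValueError("both groups need at least two hub scores")
    if (known.size == 2 and np.ptp(known) == 0) or (
        unknown.size == 2 and np.ptp(unknown) == 0
    ):
        warnings.warn("zero-variance group of size 2 in hub_score_ttest")
    return welch_ttest(known, unknown, equal_var=equal_var)


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an id -> sequence map (Biopython-backed)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def export_top_hub_sequences(
    ranking: HubRanking,
    sequences: Mapping[str, str],
    out_path,
    n_per_class: int = 5,
) -> list[str]:
    """Write the top-n Known and top-n Unknown hub sequences to FASTA.

    Headers are the otu_ids.  A class with fewer than ``n_per_class``
    members yields a shortfall warning; a selected id with no sequence
    is an error listing every missing id.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    known = ranking.top_ids(unknown=False, n=n_per_class)
    unknown = ranking.top_ids(unknown=True, n=n_per_class)
    if len(known) < n_per_class or len(unknown) < n_per_class:
        warnings.warn(
            f"fewer than {n_per_class} hubs in a class: "
            f"{len(known)} Known, {len(unknown)} Unknown exported"
        )
    selected = known + unknown
    missing = [o for o in selected if o not in sequences]
    if missing:
        raise KeyError(f"no sequence for ids: {missing}")
    records = [
        SeqRecord(Seq(sequences[o]), id=o, description="") for o in selected
    ]
    SeqIO.write(records, str(out_path), "fasta")
    return selected
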