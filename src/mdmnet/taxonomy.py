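"""Lineage parsing and Unknown ("microbial dark matter") designation.

An OTU is treated as Unknown at a taxonomic rank when the reference
database could not assign it a meaningful label there: the label is
empty, or one of a small set of placeholder tokens emitted by
SILVA-style open-reference picking ("uncultured", "Unassigned",
"Ambiguous taxa", ...).  Unknown status propagates downward: an OTU that
is Unknown at family is necessarily Unknown at genus, regardless of any
deeper label text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RANKS",
    "DEFAULT_UNKNOWN_TOKENS",
    "TaxonomyAssignment",
    "parse_lineage",
    "unknown_mask",
    "render_lineage",
    "lineage_blacklist_filter",
]

#: Ranks analysed by the pipeline, ordered from the most inclusive down.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Placeholder labels that mark a rank as Unknown (compared after prefix
#: stripping, case folding and underscore/space normalization).
DEFAULT_UNKNOWN_TOKENS: frozenset[str] = frozenset(
    {
        "uncultured",
        "uncultured bacterium",
        "unknown",
        "unassigned",
        "ambiguous taxa",
        "na",
    }
)

# SILVA exports carry rank prefixes like "D_0__Bacteria" or "k__Bacteria".
_PREFIX_RE = re.compile(r"^(?:[A-Za-z]__|D_\d+__)")


def _normalize(label: str) -> str:
    label = _PREFIX_RE.sub("", label.strip())
    return re.sub(r"[\s_]+", " ", label).strip().lower()


def strip_rank_prefix(label: str) -> str:
    """Remove a leading SILVA/greengenes rank prefix, keep the label text."""
    return _PREFIX_RE.sub("", label.strip()).strip()


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Per-OTU lineage with a per-rank Unknown flag.

    ``unknown_at`` is monotone: once an OTU is Unknown at some rank it is
    Unknown at every rank below it.  Every rank in ``ranks`` is present
    in both maps even when the input lineage was shorter (a missing rank
    is Unknown).
    """

    otu_id: str
    rank_labels: Mapping[str, str]
    unknown_at: Mapping[str, bool]
    ranks: tuple[str, ...] = RANKS

    def __post_init__(self) -> None:
        unknown = False
        for rank in self.ranks:
            if rank not in self.rank_labels or rank not in self.unknown_at:
                raise ValueError(f"rank {rank!r} missing from assignment {self.otu_id!r}")
            if unknown and not self.unknown_at[rank]:
                raise ValueError(
                    f"non-monotone Unknown flags for {self.otu_id!r} at rank {rank!r}"
                )
            unknown = unknown or self.unknown_at[rank]

    def label(self, rank: str) -> str:
        """Display label at ``rank``: the raw label, or ``"Unknown"``."""
        if rank not in self.unknown_at:
            raise KeyError(f"unsupported rank {rank!r}")
        return "Unknown" if self.unknown_at[rank] else self.rank_labels[rank]

    def truncated_lineage(self, rank: str) -> str:
        """Lineage rendered down to ``rank`` using display labels."""
        if rank not in self.unknown_at:
            raise KeyError(f"unsupported rank {rank!r}")
        upto = self.ranks[: self.ranks.index(rank) + 1]
        return ";".join(self.label(r) for r in upto)


def parse_lineage(
    lineage: str,
    otu_id: str,
    *,
    delimiter: str = ";",
    ranks: Sequence[str] = RANKS,
    unknown_tokens: Iterable[str] = DEFAULT_UNKNOWN_TOKENS,
) -> TaxonomyAssignment:
    """Parse one delimited lineage string into a :class:`TaxonomyAssignment`.

    A rank is flagged Unknown when its label (after rank-prefix stripping
    and case/underscore normalization) is empty or matches one of
    ``unknown_tokens``; the flag then propagates to every lower rank.
    Fewer fields than ranks is legal (missing ranks are Unknown); more
    fields than ranks is an error.
    """
    tokens = {_normalize(t) for t in unknown_tokens}
    fields = [f for f in (s.strip() for s in lineage.split(delimiter))]
    # Trailing empty fields from "...;;" style exports are just missing ranks.
    while fields and fields[-1] == "":
        fields.pop()
    if len(fields) > len(ranks):
        raise ValueError(
            f"lineage {lineage!r} for {otu_id!r} has {len(fields)} fields "
            f"but only {len(ranks)} ranks are configured"
        )
    labels: dict[str, str] = {}
    unknown: dict[str, bool] = {}
    flag = False
    for i, rank in enumerate(ranks):
        raw = strip_rank_prefix(fields[i]) if i < len(fields) else ""
        labels[rank] = raw
        norm = _normalize(raw)
        flag = flag or norm == "" or norm in tokens
        unknown[rank] = flag
    return TaxonomyAssignment(otu_id, labels, unknown, tuple(ranks))


def unknown_mask(assignments: Sequence[TaxonomyAssignment], rank: str):
    """Boolean vector aligned with ``assignments``: Unknown status at ``rank``."""
    import numpy as np

    for a in assignments:
        if rank not in a.unknown_at:
            raise KeyError(f"unsupported rank {rank!r}")
    return np.array([a.unknown_at[rank] for a in assignments], dtype=bool)


def render_lineage(assignment: TaxonomyAssignment, delimiter: str = ";") -> str:
    """Render the raw labels back into a delimited lineage string."""
    return delimiter.join(assignment.rank_labels[r] for r in assignment.ranks)


def lineage_blacklist_filter(
    assignments: Sequence[TaxonomyAssignment],
    blacklist: Iterable[str] = ("archaea", "chloroplast", "mitochondria"),
) -> list[TaxonomyAssignment]:
    """Drop assignments whose lineage mentions a blacklisted term.

    Replicates the usual upstream removal of Archaea, chloroplast and
    mitochondrial OTUs before a Bacteria-targeted analysis.  Matching is
    case-insensitive substring over every raw rank label.
    """
    terms = [t.lower() for t in blacklist]
    kept = []
    for a in assignments:
        joined = ";".join(a.rank_labels[r] for r in a.ranks).lower()
        if not any(t in joined for t in terms):
            kept.append(a)
    return kept
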