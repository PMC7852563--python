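"""OTU count-table container, prevalence filtering and cross-environment tests.

The central object is :class:`CommunityTable`: a nonnegative integer
OTU x sample matrix plus one :class:`~mdmnet.taxonomy.TaxonomyAssignment`
per OTU and a free-text environment tag.  Prevalence is the fraction of
samples in which an OTU has a nonzero count; networks are built only on
OTUs above a prevalence threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import RANKS, TaxonomyAssignment, parse_lineage

__all__ = [
    "CommunityTable",
    "PrevalenceProfile",
    "SharedOTUs",
    "prevalence",
    "filter_by_prevalence",
    "filter_min_total_count",
    "shared_otus",
    "unknown_enrichment",
    "collapse_to_rank",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
    "read_biom",
]


@dataclass
class CommunityTable:
    """OTU x sample count matrix with taxonomy.

    ``counts`` is indexed by OTU id (rows) and sample id (columns);
    entries are nonnegative integers.  ``taxonomy`` must cover every row.
    ``meta`` carries provenance (prevalence threshold applied, retained
    fraction, ...) and is propagated by the filtering operations.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, TaxonomyAssignment]
    environment: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate OTU ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be nonnegative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")
        missing = [o for o in self.counts.index if o not in self.taxonomy]
        if missing:
            raise ValueError(f"taxonomy missing for OTUs: {missing[:5]}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def assignments(self) -> list[TaxonomyAssignment]:
        return [self.taxonomy[o] for o in self.counts.index]

    def unknown_flags(self, rank: str) -> pd.Series:
        return pd.Series(
            [self.taxonomy[o].unknown_at[rank] for o in self.counts.index],
            index=self.counts.index,
            dtype=bool,
        )

    def subset_otus(self, otu_ids: Sequence[str]) -> "CommunityTable":
        ids = list(otu_ids)
        return CommunityTable(
            counts=self.counts.loc[ids].copy(),
            taxonomy={o: self.taxonomy[o] for o in ids},
            environment=self.environment,
            meta=dict(self.meta),
        )

    def present_otus(self) -> set[str]:
        """OTUs detected (nonzero) in at least one sample."""
        nz = (self.counts.to_numpy() > 0).any(axis=1)
        return set(self.counts.index[nz])


@dataclass
class PrevalenceProfile:
    """Per-OTU prevalence plus the cumulative prevalence curve.

    ``curve[k-1]`` is the number of OTUs detected in at least ``k``
    samples, for ``k = 1..n_samples``; it is nonincreasing.
    """

    fraction: pd.Series
    nonzero_samples: pd.Series
    n_samples: int
    curve: np.ndarray


def prevalence(table: CommunityTable) -> PrevalenceProfile:
    """Exact nonzero-sample fractions and the prevalence curve."""
    n = table.n_samples
    if n == 0:
        raise ValueError("prevalence undefined for a table with zero samples")
    nonzero = (table.counts.to_numpy() > 0).sum(axis=1)
    ks = np.arange(1, n + 1)
    curve = (nonzero[:, None] >= ks[None, :]).sum(axis=0)
    return PrevalenceProfile(
        fraction=pd.Series(nonzero / n, index=table.counts.index),
        nonzero_samples=pd.Series(nonzero, index=table.counts.index),
        n_samples=n,
        curve=curve,
    )


def _samples_threshold(min_fraction: float, n_samples: int) -> int:
    # Guard against float fuzz: 0.4 * 260 must give 104, not ceil(104.0000001).
    return int(math.ceil(round(min_fraction * n_samples, 9)))


def filter_by_prevalence(
    table: CommunityTable,
    min_fraction: float | None = None,
    min_samples: int | None = None,
) -> CommunityTable:
    """Retain OTUs detected in at least the given number/fraction of samples.

    Exactly one of ``min_fraction`` / ``min_samples`` must be given.  The
    fraction form converts to a sample count by ``ceil(fraction * n)``;
    both forms are inclusive (``>=``).  The retained fraction of the
    initial OTU set is recorded in ``meta["retained_fraction"]``.
    """
    if (min_fraction is None) == (min_samples is None):
        raise ValueError("give exactly one of min_fraction or min_samples")
    if min_fraction is not None:
        if not 0 <= min_fraction <= 1:
            raise ValueError("min_fraction must lie in [0, 1]")
        threshold = _samples_threshold(min_fraction, table.n_samples)
    else:
        threshold = int(min_samples)
    nonzero = (table.counts.to_numpy() > 0).sum(axis=1)
    keep = table.counts.index[nonzero >= threshold]
    out = table.subset_otus(keep)
    n_initial = table.counts.shape[0]
    out.meta.update(
        prevalence_threshold_samples=threshold,
        retained_fraction=(len(keep) / n_initial) if n_initial else float("nan"),
        n_initial_otus=n_initial,
    )
    return out


def filter_min_total_count(table: CommunityTable, min_total: int = 2) -> CommunityTable:
    """Drop low-total OTUs (default removes singletons, as done upstream)."""
    totals = table.counts.sum(axis=1)
    return table.subset_otus(table.counts.index[totals >= min_total])


@dataclass
class SharedOTUs:
    """Venn-style membership accounting over several environments."""

    #: count of OTUs present in exactly this subset of environments
    exact_counts: dict[frozenset, int]
    #: per environment: (known, unknown) split of its environment-unique OTUs
    unique_split: dict[str, tuple[int, int]]
    union_size: int


def shared_otus(
    tables: Sequence[CommunityTable], rank: str = "genus"
) -> SharedOTUs:
    """Count OTUs present in each exact subset of environments.

    "Present" means nonzero in at least one sample.  Also reports, for
    each environment, the Known/Unknown split (at ``rank``) of the OTUs
    unique to it.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    names = [t.environment or f"table_{i}" for i, t in enumerate(tables)]
    if len(set(names)) != len(names):
        raise ValueError("environment tags must be distinct")
    present = {name: t.present_otus() for name, t in zip(names, tables)}
    membership: dict[str, frozenset] = {}
    for name in names:
        for otu in present[name]:
            membership[otu] = membership.get(otu, frozenset()) | {name}
    exact: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            exact[frozenset(combo)] = 0
    for subset in membership.values():
        exact[subset] += 1
    taxonomy: dict[str, TaxonomyAssignment] = {}
    for t in tables:
        taxonomy.update(t.taxonomy)
    unique_split: dict[str, tuple[int, int]] = {}
    for name in names:
        uniques = [o for o, s in membership.items() if s == frozenset({name})]
        unknown = sum(taxonomy[o].unknown_at[rank] for o in uniques)
        unique_split[name] = (len(uniques) - unknown, unknown)
    return SharedOTUs(exact, unique_split, len(membership))


def unknown_enrichment(
    table_a: CommunityTable, table_b: CommunityTable, rank: str
) -> tuple[float, float]:
    """Fisher's exact test for Unknown-OTU enrichment of ``table_a`` vs ``table_b``.

    Counts unique present OTUs in each table, split Known/Unknown at
    ``rank``, and runs a two-sided exact hypergeometric test on the 2x2
    table.  Returns ``(odds_ratio, p_value)``; a zero margin yields p = 1
    with a warning.
    """
    def split(t: CommunityTable) -> tuple[int, int]:
        pres = t.present_otus()
        unknown = sum(t.taxonomy[o].unknown_at[rank] for o in pres)
        return unknown, len(pres) - unknown

    ua, ka = split(table_a)
    ub, kb = split(table_b)
    contingency = np.array([[ua, ka], [ub, kb]])
    if (contingency.sum(axis=0) == 0).any() or (contingency.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margin in unknown_enrichment; p = 1")
        odds, p = stats.fisher_exact(contingency)
        return float(odds), 1.0
    odds, p = stats.fisher_exact(contingency, alternative="two-sided")
    return float(odds), float(p)


def collapse_to_rank(
    table: CommunityTable, rank: str, aggregate: str = "relabel"
) -> CommunityTable:
    """Re-label (default) or aggregate the table at a taxonomic rank.

    ``aggregate="relabel"`` keeps every OTU row and only changes the
    display label each node carries (the level at which Known/Unknown is
    read); ``meta["display_labels"]`` maps otu_id -> truncated-lineage
    label.  ``aggregate="sum"`` instead sums counts of rows sharing a
    truncated lineage, producing one row per collapsed taxon.
    """
    if rank not in RANKS:
        raise KeyError(f"unsupported rank {rank!r}")
    if aggregate == "relabel":
        out = table.subset_otus(table.otu_ids)
        out.meta["display_labels"] = {
            o: table.taxonomy[o].label(rank) for o in table.otu_ids
        }
        out.meta["collapse_rank"] = rank
        return out
    if aggregate == "sum":
        keys = [table.taxonomy[o].truncated_lineage(rank) for o in table.otu_ids]
        grouped = table.counts.groupby(pd.Index(keys, name="lineage")).sum()
        taxonomy = {}
        for key in grouped.index:
            rep = table.otu_ids[keys.index(key)]
            old = table.taxonomy[rep]
            taxonomy[key] = TaxonomyAssignment(
                otu_id=key,
                rank_labels=dict(old.rank_labels),
                unknown_at=dict(old.unknown_at),
                ranks=old.ranks,
            )
        return CommunityTable(
            counts=grouped.astype(int),
            taxonomy=taxonomy,
            environment=table.environment,
            meta={**table.meta, "collapse_rank": rank, "aggregate": "sum"},
        )
    raise ValueError("aggregate must be 'relabel' or 'sum'")


# ---------------------------------------------------------------------------
# I/O


def read_counts_tsv(
    path,
    taxonomy_path=None,
    environment: str = "",
    delimiter: str = ";",
) -> CommunityTable:
    """Read an OTU table TSV (rows OTUs, first column id, columns samples).

    When ``taxonomy_path`` is given it must be a TSV with columns
    ``otu_id`` and ``lineage``; otherwise every OTU gets an empty
    (all-Unknown) lineage.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    counts.index = counts.index.astype(str)
    if taxonomy_path is not None:
        taxonomy = read_taxonomy_tsv(taxonomy_path, delimiter=delimiter)
    else:
        taxonomy = {o: parse_lineage("", o) for o in counts.index}
    return CommunityTable(counts.astype(int), taxonomy, environment=environment)


def write_counts_tsv(table: CommunityTable, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.counts.to_csv(fh, sep="\t", index_label="otu_id")


def read_taxonomy_tsv(path, delimiter: str = ";") -> dict[str, TaxonomyAssignment]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if not {"otu_id", "lineage"} <= set(df.columns):
        raise ValueError("taxonomy TSV needs columns 'otu_id' and 'lineage'")
    return {
        row.otu_id: parse_lineage(row.lineage, row.otu_id, delimiter=delimiter)
        for row in df.itertuples()
    }


def write_taxonomy_tsv(
    taxonomy: Mapping[str, TaxonomyAssignment], path, header_lines: Sequence[str] = ()
) -> None:
    from .taxonomy import render_lineage

    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("otu_id\tlineage\n")
        for otu, a in taxonomy.items():
            fh.write(f"{otu}\t{render_lineage(a)}\n")


def read_biom(path, environment: str = "") -> CommunityTable:
    """Read a BIOM 2.x (HDF5) table, including observation taxonomy metadata.

    Only the dense/CSR layout written by current BIOM tools is supported;
    observation metadata ``taxonomy`` (list of rank labels per OTU) is
    used when present.
    """
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["sample/ids"][:]]
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
        matrix = csr_matrix((data, indices, indptr), shape=(len(obs_ids), len(sample_ids)))
        taxonomy: dict[str, TaxonomyAssignment] = {}
        if "observation/metadata/taxonomy" in fh:
            raw = fh["observation/metadata/taxonomy"][:]
            for otu, labels in zip(obs_ids, raw):
                if isinstance(labels, bytes):
                    lineage = labels.decode()
                else:
                    lineage = ";".join(
                        x.decode() if isinstance(x, bytes) else str(x) for x in labels
                    )
                taxonomy[otu] = parse_lineage(lineage, otu)
        else:
            taxonomy = {o: parse_lineage("", o) for o in obs_ids}
    counts = pd.DataFrame(
        np.asarray(matrix.todense(), dtype=int), index=obs_ids, columns=sample_ids
    )
    return CommunityTable(counts, taxonomy, environment=environment)
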