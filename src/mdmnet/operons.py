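"""BLAST-hit filtering, gene flagging and putative adaptation-operon calling.

Workflow: hub 16S sequences are blasted against metagenomes externally;
the exported tabular results are filtered at >= 95% identity and >= 95%
query cover, matching scaffolds are kept only when gene-rich (>= 50
genes), genes are flagged as hypothetical and/or adaptation-related by
keyword, same-strand genes are chained into operons by intergenic gap
(single linkage, cut at 5000 bp), and an operon is called a putative
adaptation operon when a hypothetical gene has an adaptation-flagged
gene among its ten gap-nearest operon neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BlastHit",
    "GeneRecord",
    "GeneFlags",
    "OperonCall",
    "parse_blast_tabular",
    "write_blast_tabular",
    "filter_hits",
    "filter_scaffolds",
    "flag_genes",
    "cluster_operons",
    "call_putative_adaptation_operons",
    "load_keywords",
    "default_keywords",
    "read_gene_table",
    "write_gene_table",
    "read_gff3",
    "write_operon_report",
    "mine_scaffolds",
]

DEFAULT_HYPOTHETICAL_SYNONYMS = ("hypothetical", "unknown function", "DUF")


@dataclass(frozen=True)
class BlastHit:
    """One row of tabular (outfmt 6) BLAST output, plus query coverage."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    e_value: float
    bitscore: float
    query_coverage: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        if not 0 <= self.query_coverage <= 100 + 1e-9:
            raise ValueError("query_coverage outside [0, 100]")
        if self.e_value < 0:
            raise ValueError("negative e-value")


@dataclass(frozen=True)
class GeneRecord:
    """A gene on a metagenome scaffold; 1-based inclusive coordinates."""

    scaffold_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"bad coordinates for {self.gene_id}: {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GeneFlags:
    hypothetical: bool
    adaptation: bool


@dataclass
class OperonCall:
    """A same-strand run of gap-proximal genes on one scaffold."""

    scaffold_id: str
    strand: str
    members: list[GeneRecord]
    n_hypothetical: int = 0
    n_adaptation: int = 0
    is_putative_adaptation: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.members]


# ---------------------------------------------------------------------------
# BLAST parsing and filtering

_BLAST_COLS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "qstart", "qend", "sstart", "send",
    "e_value", "bitscore",
]


def parse_blast_tabular(
    path, query_lengths: Mapping[str, int] | None = None
) -> list[BlastHit]:
    """Parse outfmt-6 tabular BLAST output (12 or 13 columns).

    A 13th column is taken as the query coverage (blast's ``qcovs``);
    otherwise coverage is computed from the absolute query span as
    ``100 * (|qend - qstart| + 1) / query_lengths[query_id]`` (so
    minus-strand hits cover the same span as forward ones), which
    requires ``query_lengths``.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise ValueError(
                    f"line {lineno}: expected 12 or 13 tab-separated fields, got {len(fields)}"
                )
            try:
                base = dict(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    e_value=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed field ({exc})") from exc
            if len(fields) == 13:
                coverage = float(fields[12])
            else:
                if query_lengths is None or base["query_id"] not in query_lengths:
                    raise ValueError(
                        f"line {lineno}: no coverage column and no query length "
                        f"for {base['query_id']!r}"
                    )
                span = abs(base["qend"] - base["qstart"]) + 1
                coverage = 100.0 * span / query_lengths[base["query_id"]]
            hits.append(BlastHit(**base, query_coverage=coverage))
    return hits


def write_blast_tabular(hits: Sequence[BlastHit], path, include_coverage: bool = True) -> None:
    with open(path, "w") as fh:
        for h in hits:
            row = [
                h.query_id, h.subject_id, f"{h.percent_identity:.3f}",
                str(h.alignment_length), str(h.mismatches), str(h.gap_opens),
                str(h.qstart), str(h.qend), str(h.sstart), str(h.send),
                f"{h.e_value:.2e}", f"{h.bitscore:.1f}",
            ]
            if include_coverage:
                row.append(f"{h.query_coverage:.3f}")
            fh.write("\t".join(row) + "\n")


def filter_hits(
    hits: Iterable[BlastHit], min_identity: float = 95.0, min_coverage: float = 95.0
) -> list[BlastHit]:
    """Retain hits with identity and query coverage at or above the cutoffs."""
    return [
        h
        for h in hits
        if h.percent_identity >= min_identity and h.query_coverage >= min_coverage
    ]


def filter_scaffolds(
    gene_tables: Mapping[str, Sequence[GeneRecord]], min_genes: int = 50
) -> dict[str, list[GeneRecord]]:
    """Keep only gene-rich scaffolds (inclusive gene-count cutoff)."""
    return {
        scaffold: list(genes)
        for scaffold, genes in gene_tables.items()
        if len(genes) >= min_genes
    }


# ---------------------------------------------------------------------------
# Gene flagging


def flag_genes(
    genes: Sequence[GeneRecord],
    adaptation_terms: Sequence[str],
    hypothetical_synonyms: Sequence[str] = DEFAULT_HYPOTHETICAL_SYNONYMS,
) -> dict[str, GeneFlags]:
    """Flag genes as hypothetical and/or adaptation-related by keyword.

    Matching is case-insensitive substring over the product annotation;
    a gene may carry both flags.
    """
    if not adaptation_terms:
        raise ValueError("adaptation keyword list must be nonempty")
    hyp = [s.lower() for s in hypothetical_synonyms]
    adapt = [s.lower() for s in adaptation_terms if s.strip()]
    flags: dict[str, GeneFlags] = {}
    for g in genes:
        product = g.product.lower()
        flags[g.gene_id] = GeneFlags(
            hypothetical=any(s in product for s in hyp),
            adaptation=any(s in product for s in adapt),
        )
    return flags


def load_keywords(path) -> list[str]:
    """Read a keyword list: one term per line, '#' comments allowed."""
    terms = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line)
    return terms


def default_keywords() -> list[str]:
    """The packaged default adaptation keyword list (editable drop-in)."""
    with resources.as_file(
        resources.files("mdmnet").joinpath("data/adaptation_terms.txt")
    ) as p:
        return load_keywords(p)


# ---------------------------------------------------------------------------
# Operon clustering


def _gap(a: GeneRecord, b: GeneRecord) -> int:
    """Intergenic gap between two genes (0 when they touch or overlap)."""
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end - 1)


def cluster_operons(
    genes: Sequence[GeneRecord],
    max_gap: int = 5000,
    size_cap: int | None = None,
) -> list[OperonCall]:
    """Chain same-strand genes into operons by intergenic gap.

    Genes (all on one scaffold) are processed per strand in start order;
    consecutive genes sharing an operon when the gap to the running
    right-most end so far is <= ``max_gap`` - exactly a single-linkage
    dendrogram on the interval-gap distance cut at ``max_gap``.
    Overlapping same-strand genes are merged with a warning (gap clipped
    to 0).  ``size_cap`` optionally splits runs into consecutive chunks
    of at most that many genes (the alternate reading of a ten-gene
    operon rule).  Singleton operons are permitted.
    """
    if not genes:
        return []
    scaffolds = {g.scaffold_id for g in genes}
    if len(scaffolds) != 1:
        raise ValueError(f"genes span multiple scaffolds: {sorted(scaffolds)}")
    scaffold = scaffolds.pop()
    operons: list[OperonCall] = []
    warned_overlap = False
    for strand in ("+", "-"):
        strand_genes = sorted(
            (g for g in genes if g.strand == strand),
            key=lambda g: (g.start, g.end, g.gene_id),
        )
        if not strand_genes:
            continue
        current = [strand_genes[0]]
        right_end = strand_genes[0].end
        for g in strand_genes[1:]:
            if g.start <= right_end and not warned_overlap:
                warnings.warn(f"overlapping same-strand genes on {scaffold}; gap clipped to 0")
                warned_overlap = True
            gap = max(0, g.start - right_end - 1)
            if gap <= max_gap:
                current.append(g)
            else:
                operons.append(OperonCall(scaffold, strand, current))
                current = [g]
            right_end = max(right_end, g.end)
        operons.append(OperonCall(scaffold, strand, current))
    if size_cap is not None:
        chunked = []
        for op in operons:
            for i in range(0, len(op.members), size_cap):
                chunked.append(OperonCall(scaffold, op.strand, op.members[i : i + size_cap]))
        operons = chunked
    return operons


def call_putative_adaptation_operons(
    operons: Sequence[OperonCall],
    flags: Mapping[str, GeneFlags],
    window_genes: int = 10,
    max_gap: int = 5000,
) -> list[OperonCall]:
    """Flag operons holding a hypothetical gene near an adaptation gene.

    An operon is a putative adaptation operon when at least one of its
    hypothetical genes has at least one adaptation-flagged gene among
    its ``window_genes`` nearest same-operon neighbors, nearness being
    the pairwise intergenic gap, and every counted neighbor within
    ``max_gap``.  Hypothetical/adaptation member tallies are filled in
    on the returned calls.
    """
    out = []
    for op in operons:
        members = op.members
        n_hyp = sum(flags[g.gene_id].hypothetical for g in members)
        n_adapt = sum(flags[g.gene_id].adaptation for g in members)
        putative = False
        for g in members:
            if not flags[g.gene_id].hypothetical:
                continue
            neighbors = sorted(
                (h for h in members if h.gene_id != g.gene_id),
                key=lambda h: (_gap(g, h), h.start, h.gene_id),
            )
            window = [h for h in neighbors[:window_genes] if _gap(g, h) <= max_gap]
            if any(flags[h.gene_id].adaptation for h in window):
                putative = True
                break
        out.append(
            OperonCall(
                op.scaffold_id, op.strand, list(members),
                n_hypothetical=n_hyp, n_adaptation=n_adapt,
                is_putative_adaptation=putative,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene table I/O

_GENE_COLS = ["scaffold_id", "gene_id", "start", "end", "strand", "product"]


def read_gene_table(path) -> dict[str, list[GeneRecord]]:
    """Read a gene-table TSV (scaffold_id, gene_id, start, end, strand, product)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"product": str}).fillna(
        {"product": ""}
    )
    missing = set(_GENE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    tables: dict[str, list[GeneRecord]] = {}
    for row in df.itertuples():
        rec = GeneRecord(
            str(row.scaffold_id), str(row.gene_id), int(row.start), int(row.end),
            str(row.strand), str(row.product),
        )
        tables.setdefault(rec.scaffold_id, []).append(rec)
    return tables


def write_gene_table(
    gene_tables: Mapping[str, Sequence[GeneRecord]], path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_GENE_COLS) + "\n")
        for scaffold in sorted(gene_tables):
            for g in gene_tables[scaffold]:
                fh.write(
                    f"{g.scaffold_id}\t{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.product}\n"
                )


def read_gff3(path) -> dict[str, list[GeneRecord]]:
    """Convenience GFF3 reader: gene/CDS features, ``product`` attribute."""
    tables: dict[str, list[GeneRecord]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] not in ("gene", "CDS"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or f"{cols[0]}:{cols[3]}"
            rec = GeneRecord(
                cols[0], gene_id, int(cols[3]), int(cols[4]), cols[6],
                attrs.get("product", ""),
            )
            tables.setdefault(rec.scaffold_id, []).append(rec)
    return tables


def write_operon_report(
    operons: Sequence[OperonCall], path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "scaffold_id\tstrand\tn_genes\tn_hypothetical\tn_adaptation\t"
            "is_putative_adaptation\tgene_ids\n"
        )
        for op in operons:
            fh.write(
                f"{op.scaffold_id}\t{op.strand}\t{len(op.members)}\t"
                f"{op.n_hypothetical}\t{op.n_adaptation}\t"
                f"{int(op.is_putative_adaptation)}\t{','.join(op.gene_ids)}\n"
            )


def mine_scaffolds(
    gene_tables: Mapping[str, Sequence[GeneRecord]],
    adaptation_terms: Sequence[str],
    min_genes: int = 50,
    max_gap: int = 5000,
    window_genes: int = 10,
) -> tuple[list[OperonCall], pd.DataFrame]:
    """Run the full per-scaffold mining: filter, flag, cluster, call.

    Returns all operon calls plus a per-scaffold summary (gene counts,
    hypothetical/adaptation tallies, operon and putative-operon counts).
    """
    retained = filter_scaffolds(gene_tables, min_genes=min_genes)
    all_calls: list[OperonCall] = []
    rows = []
    for scaffold in sorted(retained):
        genes = retained[scaffold]
        flags = flag_genes(genes, adaptation_terms)
        operons = cluster_operons(genes, max_gap=max_gap)
        calls = call_putative_adaptation_operons(
            operons, flags, window_genes=window_genes, max_gap=max_gap
        )
        all_calls.extend(calls)
        rows.append(
            {
                "scaffold_id": scaffold,
                "n_genes": len(genes),
                "n_hypothetical": sum(f.hypothetical for f in flags.values()),
                "n_adaptation": sum(f.adaptation for f in flags.values()),
                "n_operons": len(calls),
                "n_putative_adaptation_operons": sum(
                    c.is_putative_adaptation for c in calls
                ),
            }
        )
    return all_calls, pd.DataFrame(rows)
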