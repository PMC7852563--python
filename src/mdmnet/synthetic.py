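"""Synthetic communities and scaffolds with planted ground truth.

Communities follow a logistic-normal-multinomial model: a latent
multivariate normal whose covariance is the inverse of a planted sparse
precision matrix (hub, band or random topology), pushed through a
per-sample softmax to compositions and a multinomial draw at fixed
sequencing depth.  Zeros arise naturally from depth and composition;
the spread of per-taxon baseline log-abundances is calibrated (via a
Poisson zero-probability approximation) so the realized zero fraction
tracks ``target_sparsity``.  Unknown labels can be planted
preferentially on hub nodes to recreate, as a testable scenario, the
phenomenon of unknown taxa occupying top-hub positions; a uniform-label
null mode supports type-I error checks.

Scaffold generators lay out genes per strand with small intra-operon
gaps and large (> 5000 bp) inter-operon gaps, so the planted operon
structure is exactly recoverable by gap clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityTable
from .operons import BlastHit, GeneFlags, GeneRecord, OperonCall
from .taxonomy import RANKS, TaxonomyAssignment, parse_lineage

__all__ = [
    "CommunitySpec",
    "CommunityTruth",
    "generate_community",
    "OperonTemplate",
    "ScaffoldSpec",
    "generate_scaffold",
    "generate_blast_hits",
]


# ---------------------------------------------------------------------------
# Communities


@dataclass
class CommunitySpec:
    """Study conditions for one synthetic community.

    Defaults describe the planted-hub benchmark used throughout the
    tests: 50 taxa, 400 samples at depth 5e4, a 4-hub conditional
    dependence graph with sparse background edges, 30% Unknown taxa
    planted preferentially (p = 0.8) on the hubs, and a moderate
    (already prevalence-filtered) 30% zero fraction.
    """

    n_taxa: int = 50
    n_samples: int = 400
    depth: int = 50_000
    topology: str = "hub"  # hub | band | random
    n_hubs: int = 4
    edge_strength: float = 0.85
    background_edge_prob: float = 0.02
    spoke_prob: float = 0.25
    band_width: int = 1
    random_edge_prob: float = 0.06
    unknown_fraction: float = 0.3
    plant_unknown_hubs: bool = True
    hub_unknown_prob: float = 0.8
    target_sparsity: float = 0.05
    base_sigma: float | None = None  # calibrated from target_sparsity when None
    environment: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.unknown_fraction <= 1:
            raise ValueError("unknown_fraction must lie in [0, 1]")
        if self.topology not in ("hub", "band", "random"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0 <= self.target_sparsity < 1:
            raise ValueError("target_sparsity must lie in [0, 1)")
        if not 0 < self.edge_strength < 1:
            raise ValueError("edge_strength must lie in (0, 1)")


@dataclass
class CommunityTruth:
    """Planted ground truth accompanying a generated community."""

    otu_ids: list[str]
    adjacency: np.ndarray
    edges: set[tuple[str, str]]
    hub_ids: list[str]
    unknown_ids: list[str]
    precision: np.ndarray
    base_sigma: float
    realized_zero_fraction: float


def _planted_adjacency(spec: CommunitySpec, rng: np.random.Generator) -> np.ndarray:
    p = spec.n_taxa
    a = np.zeros((p, p), dtype=bool)
    if spec.topology == "hub":
        # hubs joined in a ring so the principal eigenvector (hub score)
        # spreads over all of them; a clique would eat too much of the
        # positive-definiteness budget (rho(K_k) = k - 1)
        for i in range(spec.n_hubs):
            a[i, (i + 1) % spec.n_hubs] = True
        # spokes spread round-robin so every hub really is a hub
        spokes = [i for i in range(spec.n_hubs, p) if rng.random() < spec.spoke_prob]
        order = rng.permutation(len(spokes))
        for k, idx in enumerate(order):
            a[spokes[idx], k % spec.n_hubs] = True
        background = rng.random((p, p)) < spec.background_edge_prob
        background = np.triu(background, k=1)
        a |= background | background.T
    elif spec.topology == "band":
        for i in range(p):
            for j in range(i + 1, min(p, i + spec.band_width + 1)):
                a[i, j] = True
    else:  # random
        upper = np.triu(rng.random((p, p)) < spec.random_edge_prob, k=1)
        a |= upper
    a = a | a.T
    np.fill_diagonal(a, False)
    return a


def _precision_from_adjacency(
    a: np.ndarray, strength: float, core: np.ndarray | None = None
) -> np.ndarray:
    """Degree-normalized precision with an optional full-strength core.

    Off-diagonal entries are ``s / sqrt(d_i d_j)`` - a positive-definite
    construction (the normalized adjacency has spectrum in [-1, 1]) in
    which an edge's partial correlation is not crushed by diagonal
    dominance.  Edges between ``core`` nodes (the hub clique) keep the
    full coupling ``s`` so the core remains detectable despite the hubs'
    large degrees; the off-diagonal block is spectrally rescaled when
    that boost would break positive definiteness.
    """
    if not 0 < strength < 1:
        raise ValueError("edge_strength must lie in (0, 1)")
    p = a.shape[0]
    af = a.astype(float)
    deg = np.maximum(af.sum(axis=1), 1.0)
    c = strength * af / np.sqrt(np.outer(deg, deg))
    if core is not None and core.sum() > 1:
        # Hub-incident edges share the hub cluster's spectral budget
        # uniformly: c_hub = 0.9 / rho(cluster adjacency).  This is the
        # largest uniform coupling the cluster can carry while the full
        # matrix stays positive definite, and it keeps hub-spoke and
        # hub-hub edges equally detectable.  Background edges get a flat
        # moderate coupling so chance background pockets cannot outshine
        # the planted hub core in the recovered graph's eigenvector.
        touch = np.zeros_like(af, dtype=bool)
        for h in np.nonzero(core)[0]:
            touch[h, af[h] > 0] = True
            touch[af[h] > 0, h] = True
        rho_cluster = np.abs(np.linalg.eigvalsh(touch.astype(float))).max()
        c_hub = 0.95 * strength / max(rho_cluster, 1.0)
        c[af > 0] = 0.3 * strength / 0.95  # background
        c[touch] = c_hub
    rho = np.abs(np.linalg.eigvalsh(c)).max() if c.any() else 0.0
    if rho >= 0.999:
        c *= 0.95 / rho
    omega = np.eye(p) + c
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - construction guard
        raise ValueError("planted precision matrix is not positive definite") from exc
    return omega


def _cov2cor(sigma: np.ndarray) -> np.ndarray:
    d = 1.0 / np.sqrt(np.diag(sigma))
    return sigma * np.outer(d, d)


def _zero_fraction(
    sigma_base: float, mu_raw: np.ndarray, latent: np.ndarray, depth: int
) -> float:
    """Poisson approximation of the expected zero fraction of the counts."""
    logits = sigma_base * mu_raw[None, :] + latent
    logits = logits - logits.max(axis=1, keepdims=True)
    comp = np.exp(logits)
    comp /= comp.sum(axis=1, keepdims=True)
    return float(np.exp(-depth * comp).mean())


def _calibrate_sigma(
    target: float, mu_raw: np.ndarray, latent_pilot: np.ndarray, depth: int
) -> float:
    lo, hi = 0.0, 10.0
    if _zero_fraction(lo, mu_raw, latent_pilot, depth) >= target:
        return lo
    if _zero_fraction(hi, mu_raw, latent_pilot, depth) <= target:
        return hi
    for _ in range(30):
        mid = (lo + hi) / 2.0
        if _zero_fraction(mid, mu_raw, latent_pilot, depth) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _make_taxonomy(
    otu_ids: Sequence[str], unknown_ids: set[str]
) -> dict[str, TaxonomyAssignment]:
    taxonomy = {}
    for i, otu in enumerate(otu_ids):
        genus = "uncultured" if otu in unknown_ids else f"Genus_{i:03d}"
        lineage = (
            f"Bacteria;Phylum_{i % 5};Class_{i % 8};Order_{i % 12};"
            f"Family_{i % 16};{genus}"
        )
        taxonomy[otu] = parse_lineage(lineage, otu)
    return taxonomy


def generate_community(spec: CommunitySpec) -> tuple[CommunityTable, CommunityTruth]:
    """Draw one community table plus its planted ground truth.

    Deterministic: the same spec (including seed) yields bitwise
    identical tables.  Sample column sums equal ``spec.depth`` exactly.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_graph, rng_mu, rng_latent, rng_counts, rng_labels = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    p, n = spec.n_taxa, spec.n_samples
    adjacency = _planted_adjacency(spec, rng_graph)
    core = None
    if spec.topology == "hub":
        core = np.zeros(p, dtype=bool)
        core[: spec.n_hubs] = True
    precision = _precision_from_adjacency(adjacency, spec.edge_strength, core=core)
    sigma = _cov2cor(np.linalg.inv(precision))
    chol = np.linalg.cholesky(sigma)
    mu_raw = rng_mu.standard_normal(p)
    latent = rng_latent.standard_normal((n, p)) @ chol.T
    if spec.base_sigma is not None:
        sigma_base = spec.base_sigma
    else:
        pilot = latent[: min(n, 60)]
        sigma_base = _calibrate_sigma(spec.target_sparsity, mu_raw, pilot, spec.depth)
    logits = sigma_base * mu_raw[None, :] + latent
    logits -= logits.max(axis=1, keepdims=True)
    comp = np.exp(logits)
    comp /= comp.sum(axis=1, keepdims=True)
    counts = np.empty((p, n), dtype=int)
    for s in range(n):
        counts[:, s] = rng_counts.multinomial(spec.depth, comp[s])
    otu_ids = [f"OTU_{i:04d}" for i in range(p)]
    if spec.topology == "hub":
        hub_ids = otu_ids[: spec.n_hubs]
    else:
        hub_ids = []
    n_unknown = int(round(spec.unknown_fraction * p))
    unknown: set[str] = set()
    if spec.plant_unknown_hubs and hub_ids:
        for h in hub_ids:
            if len(unknown) < n_unknown and rng_labels.random() < spec.hub_unknown_prob:
                unknown.add(h)
    remaining = [o for o in otu_ids if o not in unknown]
    n_more = n_unknown - len(unknown)
    if n_more > 0:
        extra = rng_labels.choice(len(remaining), size=n_more, replace=False)
        unknown.update(remaining[i] for i in extra)
    taxonomy = _make_taxonomy(otu_ids, unknown)
    table = CommunityTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=[f"S{j:04d}" for j in range(n)]),
        taxonomy=taxonomy,
        environment=spec.environment,
        meta={"seed": spec.seed, "generator": "logistic-normal-multinomial"},
    )
    edges = {
        tuple(sorted((otu_ids[i], otu_ids[j])))
        for i in range(p)
        for j in range(i + 1, p)
        if adjacency[i, j]
    }
    truth = CommunityTruth(
        otu_ids=otu_ids,
        adjacency=adjacency,
        edges=edges,
        hub_ids=hub_ids,
        unknown_ids=sorted(unknown),
        precision=precision,
        base_sigma=sigma_base,
        realized_zero_fraction=float((counts == 0).mean()),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Scaffolds


@dataclass(frozen=True)
class OperonTemplate:
    """A planted operon: strand plus per-member (hypothetical, adaptation) flags."""

    strand: str
    member_flags: tuple[tuple[bool, bool], ...]


_ADAPTATION_PRODUCTS = (
    "rubrerythrin",
    "DNA-binding ferritin-like protein DPS",
    "Fe-S oxidoreductase",
    "catalase",
    "cold shock protein CspA",
    "glycine betaine ABC transporter",
)
_NEUTRAL_PRODUCTS = (
    "ABC transporter ATP-binding protein",
    "50S ribosomal protein L3",
    "DNA polymerase III subunit beta",
    "elongation factor Tu",
    "aminotransferase class I",
    "MFS transporter",
    "phenylalanine--tRNA ligase subunit alpha",
    "cell division protein FtsZ",
)


@dataclass
class ScaffoldSpec:
    """Study conditions for one synthetic scaffold.

    Gene-rich by construction (>= 50 genes, matching the scaffold
    retention rule); intra-operon gaps stay well below and inter-operon
    gaps well above the 5000 bp operon cut so planted memberships are
    exactly recoverable.
    """

    scaffold_id: str = "scaffold_1"
    n_genes: int = 60
    gene_length: tuple[int, int] = (200, 1500)
    intra_gap: tuple[int, int] = (20, 400)
    inter_gap: tuple[int, int] = (6000, 20_000)
    operon_templates: tuple[OperonTemplate, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValueError("scaffolds must carry at least 50 genes")
        if self.inter_gap[0] <= 5000:
            raise ValueError("inter-operon gaps must exceed the 5000 bp operon cut")


def _default_templates() -> tuple[OperonTemplate, ...]:
    hyp, adapt, plain = (True, False), (False, True), (False, False)
    return (
        # hypothetical genes flanking oxidative-stress annotations -> putative
        OperonTemplate("+", (hyp, adapt, plain, hyp, adapt)),
        OperonTemplate("-", (plain, hyp, adapt, plain)),
        # hypothetical-only block -> never flagged
        OperonTemplate("+", (hyp, hyp, plain)),
    )


def _window_putative(
    members: list[GeneRecord], flags: dict[str, GeneFlags],
    window_genes: int = 10, max_gap: int = 5000,
) -> bool:
    # direct restatement of the neighbor-window rule, used for planted truth
    def gap(a: GeneRecord, b: GeneRecord) -> int:
        lo, hi = (a, b) if a.start <= b.start else (b, a)
        return max(0, hi.start - lo.end - 1)

    for g in members:
        if not flags[g.gene_id].hypothetical:
            continue
        others = sorted(
            (h for h in members if h.gene_id != g.gene_id),
            key=lambda h: (gap(g, h), h.start, h.gene_id),
        )
        window = [h for h in others[:window_genes] if gap(g, h) <= max_gap]
        if any(flags[h.gene_id].adaptation for h in window):
            return True
    return False


def generate_scaffold(
    spec: ScaffoldSpec,
) -> tuple[list[GeneRecord], list[OperonCall], dict[str, GeneFlags]]:
    """Lay out one scaffold; returns (genes, planted operon truth, flags).

    Planted operons (templates plus singleton filler genes) are laid out
    left to right per strand with intra-operon gaps <= the operon cut
    and inter-operon gaps above it, so ``cluster_operons`` at the
    default cut recovers the memberships exactly.
    """
    rng = np.random.default_rng(spec.seed)
    templates = (
        spec.operon_templates if spec.operon_templates is not None else _default_templates()
    )
    blocks: dict[str, list[tuple[tuple[bool, bool], ...]]] = {"+": [], "-": []}
    for tpl in templates:
        blocks[tpl.strand].append(tuple(tpl.member_flags))
    n_template_genes = sum(len(t.member_flags) for t in templates)
    n_filler = spec.n_genes - n_template_genes
    if n_filler < 0:
        raise ValueError("operon templates hold more genes than n_genes")
    for _ in range(n_filler):
        strand = "+" if rng.random() < 0.5 else "-"
        blocks[strand].append(((False, False),))
    genes: list[GeneRecord] = []
    truth: list[OperonCall] = []
    flags: dict[str, GeneFlags] = {}
    counter = 0
    adapt_cycle = 0
    neutral_cycle = 0
    for strand in ("+", "-"):
        order = rng.permutation(len(blocks[strand]))
        pos = int(rng.integers(1, 1000))
        for bi in order:
            member_flags = blocks[strand][bi]
            members: list[GeneRecord] = []
            for mi, (hyp, adapt) in enumerate(member_flags):
                if mi > 0:
                    pos += int(rng.integers(spec.intra_gap[0], spec.intra_gap[1] + 1)) + 1
                length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
                counter += 1
                gene_id = f"{spec.scaffold_id}_g{counter:04d}"
                if hyp:
                    product = "hypothetical protein"
                elif adapt:
                    product = _ADAPTATION_PRODUCTS[adapt_cycle % len(_ADAPTATION_PRODUCTS)]
                    adapt_cycle += 1
                else:
                    product = _NEUTRAL_PRODUCTS[neutral_cycle % len(_NEUTRAL_PRODUCTS)]
                    neutral_cycle += 1
                rec = GeneRecord(spec.scaffold_id, gene_id, pos, pos + length - 1, strand, product)
                members.append(rec)
                flags[gene_id] = GeneFlags(hypothetical=hyp, adaptation=adapt)
                pos += length
            pos += int(rng.integers(spec.inter_gap[0], spec.inter_gap[1] + 1)) + 1
            genes.extend(members)
            truth.append(
                OperonCall(
                    spec.scaffold_id, strand, members,
                    n_hypothetical=sum(flags[g.gene_id].hypothetical for g in members),
                    n_adaptation=sum(flags[g.gene_id].adaptation for g in members),
                    is_putative_adaptation=_window_putative(members, flags),
                )
            )
    if pos > 2**31 - 1:
        raise ValueError("scaffold layout overflows coordinate range")
    genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return genes, truth, flags


# ---------------------------------------------------------------------------
# BLAST hits


def generate_blast_hits(
    scaffold_ids: Sequence[str],
    query_ids: Sequence[str],
    n_above: int = 30,
    n_below: int = 70,
    min_identity: float = 95.0,
    min_coverage: float = 95.0,
    seed: int = 0,
) -> tuple[list[BlastHit], int]:
    """Emit outfmt-6-valid hits with a planted above/below-threshold split.

    Exactly ``n_above`` hits meet both cutoffs (inclusive); every other
    hit fails at least one.  Returns ``(hits, n_above)``.
    """
    rng = np.random.default_rng(seed)
    hits: list[BlastHit] = []
    qlen = 1510

    def make(identity: float, coverage: float, k: int) -> BlastHit:
        span = max(1, int(round(qlen * coverage / 100.0)))
        return BlastHit(
            query_id=query_ids[k % len(query_ids)],
            subject_id=scaffold_ids[k % len(scaffold_ids)],
            percent_identity=round(identity, 3),
            alignment_length=span,
            mismatches=int(span * (100 - identity) / 100),
            gap_opens=int(rng.integers(0, 3)),
            qstart=1,
            qend=span,
            sstart=1000 + k,
            send=1000 + k + span - 1,
            e_value=1e-30,
            bitscore=float(2 * span),
            query_coverage=round(coverage, 3),
        )

    k = 0
    for _ in range(n_above):
        hits.append(
            make(rng.uniform(min_identity, 100.0), rng.uniform(min_coverage, 100.0), k)
        )
        k += 1
    for _ in range(n_below):
        mode = rng.integers(3)
        identity = (
            rng.uniform(70.0, min_identity - 0.1) if mode in (0, 2) else rng.uniform(min_identity, 100.0)
        )
        coverage = (
            rng.uniform(40.0, min_coverage - 0.1) if mode in (1, 2) else rng.uniform(min_coverage, 100.0)
        )
        hits.append(make(identity, coverage, k))
        k += 1
    perm = rng.permutation(len(hits))
    return [hits[i] for i in perm], n_above
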