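"""Original / Without-Unknown / Bootstrap network comparison.

The core experiment: from one prevalence-filtered table, build (i) the
Original network over all OTUs, (ii) the Without-Unknown network after
deleting every OTU flagged Unknown at a rank and re-running the full
inference, and (iii) an ensemble of Bootstrap null networks, each
re-inferred after deleting an equal-sized random subset of Known OTUs.
Node-level centrality distributions are then contrasted with two-sided
Wilcoxon rank-sum tests under Holm adjustment.

The inference seed is held fixed across all three network types so the
contrast isolates the effect of node removal rather than StARS
subsampling noise; bootstrap replicates differ only in which Known
nodes are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityTable, filter_by_prevalence
from .inference import CooccurrenceNetwork, build_network
from .metrics import CentralityTable, centralities
from .stats import holm_adjust, rank_sum_test

__all__ = [
    "ComparisonResult",
    "without_unknown_network",
    "bootstrap_networks",
    "compare_centralities",
    "run_comparison",
    "threshold_sweep",
]

CONTRASTS = (
    ("original", "without_unknown"),
    ("without_unknown", "bootstrap"),
    ("original", "bootstrap"),
)
DEFAULT_METRICS = ("degree", "betweenness", "closeness")


def without_unknown_network(
    table: CommunityTable, rank: str, method: str = "mb", **params
) -> CooccurrenceNetwork:
    """Re-infer the network after removing all OTUs Unknown at ``rank``.

    This is a full re-run of the inference on the reduced count table,
    not a subgraph deletion.  With no Unknown OTUs the Original network
    is returned (noted in provenance); an all-Unknown table is an error.
    """
    flags = table.unknown_flags(rank)
    if not flags.any():
        net = build_network(table, method, **params)
        net.provenance["note"] = "no Unknown OTUs at rank; identical to Original"
        return net
    if flags.all():
        raise ValueError(f"every OTU is Unknown at rank {rank!r}; nothing to keep")
    reduced = table.subset_otus(table.counts.index[~flags])
    net = build_network(reduced, method, **params)
    net.provenance["removed_unknown_at"] = rank
    return net


def bootstrap_networks(
    table: CommunityTable,
    rank: str,
    method: str = "mb",
    params: dict | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> list[CooccurrenceNetwork]:
    """Null ensemble: re-infer after removing random Known subsets.

    Each replicate removes a uniform random subset of Known OTUs equal
    in size to the Unknown count at ``rank`` and re-runs inference with
    identical parameters.  Which subsets are drawn is a deterministic
    function of ``seed``.
    """
    params = dict(params or {})
    flags = table.unknown_flags(rank)
    n_unknown = int(flags.sum())
    known_ids = list(table.counts.index[~flags])
    if len(known_ids) < n_unknown:
        raise ValueError("fewer Known than Unknown OTUs; bootstrap undefined")
    if n_unknown == 0:
        net = build_network(table, method, **params)
        net.provenance["note"] = "no Unknown OTUs; bootstrap equals Original"
        return [net] * n_reps
    rng = np.random.default_rng(seed)
    nets = []
    for rep in range(n_reps):
        removed = rng.choice(len(known_ids), size=n_unknown, replace=False)
        removed_ids = {known_ids[i] for i in removed}
        keep = [o for o in table.counts.index if o not in removed_ids]
        reduced = table.subset_otus(keep)
        net = build_network(reduced, method, **params)
        net.provenance["bootstrap_replicate"] = rep
        nets.append(net)
    return nets


@dataclass
class ComparisonResult:
    """Wilcoxon/Holm contrasts of centrality distributions.

    ``table`` is long-format with one row per metric x contrast:
    raw and Holm-adjusted p (adjusted within each metric over its three
    contrasts), both group medians and the direction of change
    (``increase``/``decrease``/``none``, read as group B relative to
    group A at adjusted p < 0.05).
    """

    table: pd.DataFrame
    rank: str
    alpha: float = 0.05
    node_values: pd.DataFrame | None = None
    bootstrap_replicate_medians: pd.DataFrame | None = None

    def detects_unknown_effect(
        self, metrics: Sequence[str] = ("degree", "betweenness")
    ) -> bool:
        """Pipeline-level verdict: do Unknown taxa matter beyond node count?

        Removing any 30% of nodes and re-inferring thins every remaining
        node's neighborhood, so a significant Original-vs-Without-Unknown
        drop alone does not implicate the Unknown taxa - that is the
        confound the Bootstrap ensemble controls.  An Unknown effect is
        therefore declared only when, for some metric, the
        Original-vs-Without contrast is a significant decrease AND the
        Without-Unknown network also sits significantly below the
        equal-removal Bootstrap pool.  Under uninformative (random)
        Unknown labels the Without-Unknown network is exchangeable with
        a bootstrap replicate, making this rule a calibrated null.
        """
        t = self.table.set_index(["metric", "group_a", "group_b"])
        for m in metrics:
            try:
                ow = t.loc[(m, "original", "without_unknown")]
                wb = t.loc[(m, "without_unknown", "bootstrap")]
            except KeyError:
                continue
            if (
                ow.p_holm < self.alpha
                and ow.direction == "decrease"
                and wb.p_holm < self.alpha
                and wb.direction == "increase"  # Without sits below Bootstrap
            ):
                return True
        return False

    def summary(self) -> pd.DataFrame:
        """Arrow-style summary of the Original vs Without-Unknown contrast."""
        rows = []
        sub = self.table[
            (self.table.group_a == "original") & (self.table.group_b == "without_unknown")
        ]
        for row in sub.itertuples():
            arrow = {"increase": "up", "decrease": "down", "none": "n.s."}[row.direction]
            rows.append({"rank": self.rank, "metric": row.metric, "effect": arrow,
                         "holm_p": row.p_holm})
        return pd.DataFrame(rows)


def _contrast(a: pd.Series, b: pd.Series) -> tuple[float, float, float, float]:
    """(U, raw p, median_a, median_b); p is NaN when a group has < 3 values."""
    av = a.dropna().to_numpy()
    bv = b.dropna().to_numpy()
    med_a = float(np.median(av)) if av.size else np.nan
    med_b = float(np.median(bv)) if bv.size else np.nan
    if av.size < 3 or bv.size < 3:
        return np.nan, np.nan, med_a, med_b
    u, p = rank_sum_test(av, bv)
    return u, p, med_a, med_b


def compare_centralities(
    original: CentralityTable,
    without: CentralityTable,
    bootstrap_pool: Sequence[CentralityTable],
    metrics: Sequence[str] = DEFAULT_METRICS,
    rank: str = "genus",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Contrast node-level centrality distributions across network types.

    The bootstrap ensemble is pooled into one distribution per metric
    (per-replicate medians are also retained).  Holm adjustment is
    applied within each metric across its three contrasts.  Direction is
    the sign of the median difference (B relative to A) where the
    adjusted p is below ``alpha``.
    """
    groups = {
        "original": original.table,
        "without_unknown": without.table,
        "bootstrap": pd.concat([c.table for c in bootstrap_pool])
        if bootstrap_pool
        else pd.DataFrame(columns=original.table.columns),
    }
    rows = []
    for metric in metrics:
        raw = []
        cells = []
        for name_a, name_b in CONTRASTS:
            a, b = groups[name_a][metric], groups[name_b][metric]
            u, p, med_a, med_b = _contrast(a, b)
            mean_u = a.dropna().size * b.dropna().size / 2.0
            raw.append(p)
            cells.append((name_a, name_b, u, p, med_a, med_b, mean_u))
        adj = holm_adjust(raw)
        for (name_a, name_b, u, p, med_a, med_b, mean_u), p_holm in zip(cells, adj):
            # direction from the rank-sum statistic: robust to tied medians
            if np.isnan(p_holm) or p_holm >= alpha or u == mean_u:
                direction = "none"
            elif u < mean_u:  # group B tends to exceed group A
                direction = "increase"
            else:
                direction = "decrease"
            rows.append(
                {
                    "metric": metric,
                    "group_a": name_a,
                    "group_b": name_b,
                    "u_statistic": u,
                    "p_raw": p,
                    "p_holm": p_holm,
                    "median_a": med_a,
                    "median_b": med_b,
                    "direction": direction,
                }
            )
    node_values = pd.concat(
        [
            groups["original"].assign(network="original"),
            groups["without_unknown"].assign(network="without_unknown"),
            groups["bootstrap"].assign(network="bootstrap"),
        ]
    )
    rep_medians = (
        pd.DataFrame(
            [
                {m: c.table[m].dropna().median() for m in metrics} | {"replicate": i}
                for i, c in enumerate(bootstrap_pool)
            ]
        )
        if bootstrap_pool
        else None
    )
    return ComparisonResult(
        table=pd.DataFrame(rows),
        rank=rank,
        alpha=alpha,
        node_values=node_values,
        bootstrap_replicate_medians=rep_medians,
    )


def run_comparison(
    table: CommunityTable,
    rank: str = "genus",
    method: str = "mb",
    params: dict | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> tuple[ComparisonResult, dict[str, object]]:
    """Full Original / Without-Unknown / Bootstrap experiment on one table.

    ``table`` must already be prevalence-filtered.  ``params`` go to the
    network inference for all three network types unchanged (the
    inference seed stays fixed); ``seed`` drives only the bootstrap node
    draws.  Returns the comparison plus the three network artifacts.
    """
    params = dict(params or {})
    original = build_network(table, method, **params)
    without = without_unknown_network(table, rank, method, **params)
    boots = bootstrap_networks(table, rank, method, params, n_reps=n_bootstrap, seed=seed)
    cent_orig = centralities(original)
    cent_without = centralities(without)
    cent_boots = [centralities(b) for b in boots]
    result = compare_centralities(
        cent_orig, cent_without, cent_boots, metrics=metrics, rank=rank
    )
    artifacts = {
        "original": original,
        "without_unknown": without,
        "bootstrap": boots,
        "centralities": {
            "original": cent_orig,
            "without_unknown": cent_without,
            "bootstrap": cent_boots,
        },
    }
    return result, artifacts


DEFAULT_SWEEP_FRACTIONS = (0.15, 0.20, 0.25, 0.30, 0.35, 0.40)


def threshold_sweep(
    table: CommunityTable,
    fractions: Sequence[float] = DEFAULT_SWEEP_FRACTIONS,
    rank: str = "genus",
    method: str = "mb",
    params: dict | None = None,
    n_bootstrap: int = 20,
    seed: int = 0,
    min_otus: int = 10,
) -> tuple[dict[float, ComparisonResult], pd.DataFrame]:
    """Re-run the full comparison across prevalence thresholds.

    ``table`` is the unfiltered table; each fraction is applied fresh.
    Fractions leaving fewer than ``min_otus`` OTUs are skipped with a
    note.  The stability frame reports the Original-vs-Without direction
    per metric and fraction.
    """
    results: dict[float, ComparisonResult] = {}
    rows = []
    for frac in fractions:
        filtered = filter_by_prevalence(table, min_fraction=frac)
        if filtered.counts.shape[0] < min_otus:
            rows.append({"fraction": frac, "metric": None, "direction": "skipped: <10 OTUs"})
            continue
        result, _ = run_comparison(
            filtered, rank=rank, method=method, params=params,
            n_bootstrap=n_bootstrap, seed=seed,
        )
        results[frac] = result
        for row in result.summary().itertuples():
            rows.append({"fraction": frac, "metric": row.metric, "direction": row.effect})
    return results, pd.DataFrame(rows)
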