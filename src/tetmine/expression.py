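"""Relative expression by the comparative-threshold (Livak ΔΔCT) method,
regulation calls, Venn overlaps, and hierarchical-clustering heatmaps.

Technical replicates are averaged to one Cq per (gene, condition,
biological replicate); ΔCq = Cq_gene − Cq_reference within each replicate;
ΔΔCq compares treated to the mean control ΔCq; log2 fold change = −ΔΔCq
(amplification efficiency fixed at 2). The standard error is taken over
biological replicates only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io import validate_cq


@dataclass
class FoldChangeMatrix:
    """Genes × conditions log2 relative expression with standard errors."""

    log2fc: pd.DataFrame
    se: pd.DataFrame
    n_bio: pd.DataFrame
    absent: pd.DataFrame  # boolean: no measurement for that cell

    @property
    def genes(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.log2fc.columns)


def ddct(
    cq: pd.DataFrame,
    reference_gene: str,
    pairing: dict[str, str],
) -> FoldChangeMatrix:
    """ΔΔCT fold changes from a long-format Cq table.

    ``pairing`` maps each condition to its designated control condition
    (a control may map to itself, giving mean log2fc 0 for every gene).
    The reference gene must be measured in every (condition, bio
    replicate); target genes missing from a condition yield an absent cell
    rather than an error.
    """
    cq = validate_cq(cq)
    tech_avg = (
        cq.groupby(["gene_id", "condition", "bio_rep"], sort=True)["cq"]
        .mean()
        .reset_index()
    )
    ref = tech_avg[tech_avg["gene_id"] == reference_gene].set_index(
        ["condition", "bio_rep"]
    )["cq"]
    genes = sorted(g for g in tech_avg["gene_id"].unique() if g != reference_gene)
    conditions = list(pairing)
    for cond in set(pairing) | set(pairing.values()):
        if cond not in set(tech_avg["condition"]):
            raise ValueError(f"condition {cond!r} absent from Cq table")
        reps = tech_avg[tech_avg["condition"] == cond]["bio_rep"].unique()
        for rep in reps:
            if (cond, rep) not in ref.index:
                raise ValueError(
                    f"reference gene {reference_gene!r} missing in condition {cond!r}, "
                    f"bio replicate {rep}"
                )

    by_gene_cond = tech_avg.set_index(["gene_id", "condition", "bio_rep"])["cq"]

    def delta_cq(gene: str, cond: str) -> pd.Series | None:
        try:
            g = by_gene_cond.loc[gene, cond]
        except KeyError:
            return None
        r = ref.loc[cond]
        return (g - r).dropna()

    log2fc = pd.DataFrame(np.nan, index=genes, columns=conditions)
    se = pd.DataFrame(np.nan, index=genes, columns=conditions)
    n_bio = pd.DataFrame(0, index=genes, columns=conditions, dtype=int)
    absent = pd.DataFrame(True, index=genes, columns=conditions)
    for gene in genes:
        for cond in conditions:
            dcq = delta_cq(gene, cond)
            control_dcq = delta_cq(gene, pairing[cond])
            if dcq is None or control_dcq is None or len(dcq) == 0 or len(control_dcq) == 0:
                continue
            ddcq = dcq - control_dcq.mean()
            vals = -ddcq  # log2 fold change per bio replicate
            n, m = len(vals), len(control_dcq)
            log2fc.at[gene, cond] = vals.mean()
            # SE of a difference of means: the subtracted control mean is
            # itself an estimate, so both replicate spreads propagate
            var_t = dcq.var(ddof=1) / n if n > 1 else 0.0
            var_c = control_dcq.var(ddof=1) / m if m > 1 else 0.0
            se.at[gene, cond] = float(np.sqrt(var_t + var_c))
            n_bio.at[gene, cond] = n
            absent.at[gene, cond] = False
    return FoldChangeMatrix(log2fc=log2fc, se=se, n_bio=n_bio, absent=absent)


@dataclass(frozen=True)
class RegulationSet:
    condition: str
    up: frozenset
    down: frozenset
    threshold: float

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


def flag_regulated(fcm: FoldChangeMatrix, tau: float = 2.0) -> list[RegulationSet]:
    """Per-condition up/down sets at |log2fc| ≥ tau (boundary inclusive).

    The default tau of 2 on the log2 scale (4-fold linear) follows the
    convention of calling a gene regulated at a 2-unit change on a log2
    axis; tau is configurable.
    """
    out = []
    for cond in fcm.conditions:
        col = fcm.log2fc[cond].dropna()
        up = frozenset(col.index[col >= tau])
        down = frozenset(col.index[col <= -tau])
        out.append(RegulationSet(condition=cond, up=up, down=down, threshold=tau))
    return out


@dataclass
class OverlapResult:
    memberships: dict[str, frozenset]
    regions: dict[tuple[str, ...], frozenset]  # exclusive Venn regions

    def region_counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}


def overlap_sets(
    regsets: list[RegulationSet],
    groups: dict[str, list[str]],
    direction: str = "up",
) -> OverlapResult:
    """Venn overlap of regulated genes across named condition groups.

    A gene belongs to a group when it is regulated (in the stated
    direction) in at least one of the group's conditions. All 2^k − 1
    exclusive Venn regions are reported, keyed by the sorted tuple of
    group names the region belongs to.
    """
    if len(groups) < 2:
        raise ValueError("overlap_sets needs at least 2 groups")
    if direction not in ("up", "down"):
        raise ValueError(f"bad direction {direction!r}")
    by_cond = {rs.condition: rs for rs in regsets}
    memberships: dict[str, frozenset] = {}
    for name, conds in groups.items():
        members: set = set()
        for cond in conds:
            rs = by_cond.get(cond)
            if rs is not None:
                members |= rs.up if direction == "up" else rs.down
        memberships[name] = frozenset(members)
    names = sorted(groups)
    regions: dict[tuple[str, ...], frozenset] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(memberships[n]) for n in combo))
            outside = set.union(
                set(), *(set(memberships[n]) for n in names if n not in combo)
            )
            regions[combo] = frozenset(inside - outside)
    return OverlapResult(memberships=memberships, regions=regions)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    row_order: list[str]
    matrix: pd.DataFrame  # imputed matrix in clustered row order
    mask: pd.DataFrame  # True where the cell was imputed


def cluster_heatmap(
    fcm: FoldChangeMatrix,
    metric: str = "euclidean",
    linkage: str = "average",
    out_path: str | None = None,
) -> ClusterResult:
    """Agglomerative clustering of genes on their fold-change profiles.

    Missing cells are imputed as 0 (mask recorded). Rows enter linkage
    sorted by gene id, making leaf order deterministic under ties. When
    ``out_path`` is given a heatmap figure is rendered there.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"bad metric {metric!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"bad linkage {linkage!r}")
    data = fcm.log2fc.sort_index()
    mask = data.isna()
    data = data.fillna(0.0)
    if len(data) < 2:
        raise ValueError("clustering requires at least 2 genes")
    if mask.all(axis=1).any():
        bad = list(data.index[mask.all(axis=1)])
        raise ValueError(f"all-absent rows: {bad}")
    dist = ssd.pdist(data.to_numpy(), metric=metric)
    Z = sch.linkage(dist, method=linkage)
    order = [data.index[i] for i in sch.leaves_list(Z)]
    result = ClusterResult(
        linkage=Z,
        row_order=order,
        matrix=data.loc[order],
        mask=mask.loc[order],
    )
    if out_path is not None:
        _render_heatmap(result, out_path)
    return result


def _render_heatmap(result: ClusterResult, out_path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = result.matrix
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(m.columns) + 2), max(3, 0.3 * len(m.index) + 1))
    )
    vmax = float(np.nanmax(np.abs(m.to_numpy()))) or 1.0
    im = ax.imshow(m.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(m.columns)), m.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(m.index)), m.index, fontsize=7)
    for (i, j), imputed in np.ndenumerate(result.mask.to_numpy()):
        if imputed:
            ax.text(j, i, "x", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
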