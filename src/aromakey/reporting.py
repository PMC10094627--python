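"""Heat-map data export (z-scored, clipped, hierarchically clustered) and the
run-level summary document.

The heat-map contract is data, not pixels: a z-scored samples x compounds
matrix clipped to +/- ``heat_clip``, row/column leaf orders from
agglomerative clustering, and the two dendrograms as Newick text.  Rendering
is left to the caller (seaborn's ``clustermap`` consumes the same pieces).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import ValidationError

__all__ = [
    "zscore_clip",
    "ClusterResult",
    "hierarchical_cluster",
    "HeatmapData",
    "build_heatmap_data",
    "RunSummary",
    "summarize_run",
    "load_summary",
]


def zscore_clip(matrix: pd.DataFrame, clip: float = 4.0) -> pd.DataFrame:
    """Standardize columns (mean 0, sample SD 1) and clamp to [-clip, +clip].

    Constant columns map to zeros.  Idempotent on already-standardized data
    whose values lie within the clip range.
    """
    if len(matrix) < 2:
        raise ValidationError("z-scoring needs at least 2 rows")
    if not clip > 0:
        raise ValidationError("clip must be positive")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    std = values.std(axis=0, ddof=1)
    safe = np.where(std == 0.0, 1.0, std)
    z = (values - mean) / safe
    z[:, std == 0.0] = 0.0
    return pd.DataFrame(
        np.clip(z, -clip, clip), index=matrix.index, columns=matrix.columns
    )


@dataclass
class ClusterResult:
    """Agglomerative clustering of one axis."""

    linkage_matrix: np.ndarray  # scipy (m-1) x 4 merge table
    leaf_order: List[int]  # left-before-right dendrogram traversal
    labels: List[str]
    newick: str

    @property
    def ordered_labels(self) -> List[str]:
        return [self.labels[i] for i in self.leaf_order]


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def hierarchical_cluster(
    matrix: Union[pd.DataFrame, np.ndarray],
    axis: int = 0,
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of rows (``axis=0``) or columns (``axis=1``).

    Supported metrics: ``euclidean`` and ``correlation``; linkages:
    ``average``, ``complete`` and ``ward``.  The correlation metric is
    undefined on constant vectors; when one occurs, the call falls back to
    euclidean distances with a warning.  Leaf order is scipy's deterministic
    left-before-right traversal, with ties broken by item index.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValidationError(f"unsupported metric {metric!r}")
    if linkage not in ("average", "complete", "ward"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if isinstance(matrix, pd.DataFrame):
        data = matrix.to_numpy(dtype=float)
        labels = list(map(str, matrix.index if axis == 0 else matrix.columns))
    else:
        data = np.asarray(matrix, dtype=float)
        labels = None
    if axis == 1:
        data = data.T
    if data.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 items")
    if labels is None:
        labels = [str(i) for i in range(data.shape[0])]

    if metric == "correlation" and (data.std(axis=1) == 0.0).any():
        warnings.warn(
            "correlation distance undefined on constant vectors; "
            "falling back to euclidean",
            stacklevel=2,
        )
        metric = "euclidean"
    distances = pdist(data, metric=metric)
    Z = hierarchy.linkage(distances, method=linkage)
    order = hierarchy.leaves_list(Z).tolist()
    return ClusterResult(
        linkage_matrix=Z,
        leaf_order=order,
        labels=labels,
        newick=_to_newick(Z, labels),
    )


@dataclass
class HeatmapData:
    """Exported heat-map pieces: clipped z-matrix plus both clusterings."""

    matrix: pd.DataFrame
    rows: ClusterResult
    cols: ClusterResult
    clip: float

    @property
    def row_order(self) -> List[int]:
        return self.rows.leaf_order

    @property
    def col_order(self) -> List[int]:
        return self.cols.leaf_order

    def reordered(self) -> pd.DataFrame:
        return self.matrix.iloc[self.row_order, self.col_order]


def build_heatmap_data(
    conc: pd.DataFrame,
    selected: Sequence[str],
    clip: float = 4.0,
    metric: str = "euclidean",
    linkage: str = "average",
) -> HeatmapData:
    """Heat-map export for the model-selected compounds.

    ``conc`` is an injection-level concentration matrix; replicates are
    averaged per sample first, columns restricted to ``selected``, z-scored,
    clipped, and both axes clustered.
    """
    selected = [c for c in selected if c in conc.columns]
    if not selected:
        raise ValidationError("no selected compounds present in the matrix")
    if isinstance(conc.index, pd.MultiIndex):
        per_sample = conc[selected].groupby(level="sample_id", sort=False).mean()
    else:
        per_sample = conc[selected]
    z = zscore_clip(per_sample, clip=clip)
    return HeatmapData(
        matrix=z,
        rows=hierarchical_cluster(z, axis=0, metric=metric, linkage=linkage),
        cols=hierarchical_cluster(z, axis=1, metric=metric, linkage=linkage),
        clip=clip,
    )


@dataclass
class RunSummary:
    """Machine-readable summary of one full pipeline run.

    Any stage may be absent (``None``); the report then carries an explicit
    gap instead of failing.
    """

    class_profile: Optional[Dict[str, Dict[str, float]]] = None
    r2x: Optional[float] = None
    r2y: Optional[float] = None
    q2: Optional[float] = None
    n_components: Optional[int] = None
    permutation_r2_intercept: Optional[float] = None
    permutation_q2_intercept: Optional[float] = None
    n_vip_selected: Optional[int] = None
    key_active: Dict[str, Dict[str, object]] = field(default_factory=dict)
    missing_stages: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Volatile-profile run summary", ""]
        if self.missing_stages:
            lines += ["Missing stages: " + ", ".join(self.missing_stages), ""]
        if self.r2x is not None:
            lines += [
                "## Model diagnostics",
                "",
                f"- components: {self.n_components}",
                f"- R2X = {self.r2x:.3f}, R2Y = {self.r2y:.3f}, Q2 = {self.q2:.3f}",
            ]
            if self.permutation_q2_intercept is not None:
                lines.append(
                    f"- permutation intercepts: R2 = "
                    f"{self.permutation_r2_intercept:.3f}, Q2 = "
                    f"{self.permutation_q2_intercept:.3f}"
                )
            lines.append("")
        if self.n_vip_selected is not None:
            lines += [f"Markers with VIP > 1: {self.n_vip_selected}", ""]
        if self.key_active:
            lines += [f"## Key active differential odorants ({len(self.key_active)})", ""]
            for cid, info in sorted(self.key_active.items()):
                oavs = info.get("oav_by_group", {})
                top = info.get("top_group")
                flag = info.get("flag", "none")
                mark = {"**": " **", "*": " *"}.get(flag, "")
                oav_text = ", ".join(f"{g}: {v:.2f}" for g, v in oavs.items())
                lines.append(f"- {cid} (top: {top}{mark}) OAV {oav_text}")
            lines.append("")
        elif self.n_vip_selected == 0:
            lines += ["No differential compounds were selected.", ""]
        if self.class_profile:
            lines += ["## Class shares (% of total concentration)", ""]
            for group, shares in self.class_profile.items():
                main = max(shares, key=shares.get)
                lines.append(f"- {group}: dominant class {main} ({shares[main]:.2f}%)")
            lines.append("")
        return "\n".join(lines)


def summarize_run(
    class_profile: Optional[pd.DataFrame] = None,
    model=None,
    permutation=None,
    vip: Optional[pd.Series] = None,
    screening=None,
    vip_cutoff: float = 1.0,
) -> RunSummary:
    """Assemble the run-level report from whichever stage outputs exist."""
    summary = RunSummary()
    if class_profile is not None:
        summary.class_profile = {
            g: {c: float(v) for c, v in row.items()}
            for g, row in class_profile.iterrows()
        }
    else:
        summary.missing_stages.append("class_profile")
    if model is not None:
        summary.r2x = float(model.r2x)
        summary.r2y = float(model.r2y)
        summary.q2 = None if model.q2 is None else float(model.q2)
        summary.n_components = int(model.n_components)
    else:
        summary.missing_stages.append("model")
    if permutation is not None:
        summary.permutation_r2_intercept = float(permutation.r2_intercept)
        summary.permutation_q2_intercept = float(permutation.q2_intercept)
    else:
        summary.missing_stages.append("permutation")
    if vip is not None:
        summary.n_vip_selected = int((vip > vip_cutoff).sum())
    else:
        summary.missing_stages.append("vip")
    if screening is not None:
        oav_table = screening.oav.table if screening.oav is not None else None
        for cid in sorted(screening.key_active):
            info: Dict[str, object] = {}
            if oav_table is not None and cid in oav_table.index:
                info["oav_by_group"] = {
                    g: float(v) for g, v in oav_table.loc[cid].items()
                }
            if cid in screening.top_groups:
                top, flag = screening.top_groups[cid]
                info["top_group"] = top
                info["flag"] = flag
            if cid in screening.anova:
                f_stat, p_val = screening.anova[cid]
                info["anova_F"] = float(f_stat)
                info["anova_p"] = float(p_val)
            summary.key_active[cid] = info
    else:
        summary.missing_stages.append("screening")
    return summary


def load_summary(text_or_path) -> RunSummary:
    """Parse a summary previously serialized with :meth:`RunSummary.to_json`."""
    try:
        data = json.loads(text_or_path)
    except (json.JSONDecodeError, TypeError):
        with open(text_or_path, "r", encoding="utf-8") as handle:
            data = json.load(handle)
    return RunSummary(**data)
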