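"""Intermediate pathway-node activations and their class-wise comparison.

A pathway node's activation is the signed outcome of the node for a given
input — under the default identity activation, the cumulative masked
matrix product truncated at that node's level.  Nodes whose activation
distributions differ across CN/MCI/AD (Kruskal-Wallis) point at the
pathways through which the omics inputs drive the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ActivationReport",
    "capture_activations",
    "kruskal_wallis_nodes",
    "kde_summary",
]

_SUBNET_INDEX = {"snp": 0, "expression": 1}


@dataclass
class ActivationReport:
    """Per-node Kruskal-Wallis results over class-grouped activations."""

    table: pd.DataFrame  # node, H, p, significant, degenerate (+ context cols)
    groups: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    alpha: float = 0.05

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)


def capture_activations(
    model,
    X: np.ndarray,
    labels,
    subnetwork: str = "snp",
    level: int = 1,
) -> dict[str, dict[str, np.ndarray]]:
    """Forward ``X`` through one subnetwork, truncated at ``level``, and
    group the node activations by class label.

    Returns ``{node_name: {class_label: activation samples}}``.
    """
    which = _SUBNET_INDEX.get(subnetwork)
    if which is None:
        raise ValueError(f"subnetwork must be one of {sorted(_SUBNET_INDEX)}")
    stack = (model.mask_snp, model.mask_expr)[which]
    if not 1 <= level <= stack.depth:
        raise ValueError(f"level must be in 1..{stack.depth}")
    X = np.asarray(X, dtype=float)
    acts = model.net_.subnet_forward(X, which, training=False, upto_level=level)
    labels = np.asarray(labels)
    nodes = stack.level_orders[level - 1]
    out: dict[str, dict[str, np.ndarray]] = {}
    for j, node in enumerate(nodes):
        out[node] = {
            str(cls): acts[labels == cls, j] for cls in pd.unique(labels)
        }
    return out


def kruskal_wallis_nodes(
    node_groups: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.05,
    context: dict | None = None,
) -> ActivationReport:
    """Kruskal-Wallis H (tie-corrected, chi-square p with groups-1 df) per
    node; nodes sorted by ascending p.

    A node constant across all groups is degenerate: H = 0, p = 1, flagged.
    Requires >= 2 groups with >= 2 observations each.
    """
    rows = []
    for node, groups in node_groups.items():
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
        if len(samples) < 2 or any(len(s) < 2 for s in samples):
            raise ValueError(f"node {node!r}: need >=2 groups with >=2 observations")
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            h, p, degenerate = 0.0, 1.0, True
        else:
            h, p = stats.kruskal(*samples)
            degenerate = False
        row = {"node": node, "H": float(h), "p": float(p),
               "significant": bool(p < alpha), "degenerate": degenerate}
        if context:
            row.update(context)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    return ActivationReport(table=table, groups=node_groups, alpha=alpha)


def kde_summary(
    samples_by_class: dict[str, np.ndarray], grid_size: int = 200
) -> pd.DataFrame:
    """Gaussian-kernel densities on a shared grid spanning the pooled range.

    Bandwidth follows Silverman's rule.  Classes with a single point (or
    zero spread) are flagged degenerate with NaN density.  Long-form
    output: class, x, density, degenerate.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples_by_class.items()}
    pooled = np.concatenate(list(arrays.values()))
    lo, hi = pooled.min(), pooled.max()
    pad = 0.1 * (hi - lo if hi > lo else 1.0)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    frames = []
    for cls, vals in arrays.items():
        if len(vals) < 2 or np.ptp(vals) == 0:
            frames.append(pd.DataFrame({
                "class": cls, "x": grid, "density": np.nan, "degenerate": True,
            }))
            continue
        kde = stats.gaussian_kde(vals, bw_method="silverman")
        frames.append(pd.DataFrame({
            "class": cls, "x": grid, "density": kde(grid), "degenerate": False,
        }))
    return pd.concat(frames, ignore_index=True)
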