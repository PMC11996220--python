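"""Model-agnostic Shapley-value attribution by permutation sampling.

The Shapley value of feature j for a prediction is its marginal
contribution to the model output averaged over all orderings of features.
The estimator draws random permutations; for each it walks the ordering,
switching features one by one from a background row to the target row and
recording the change in every class probability.  One permutation costs
``n_features + 1`` model evaluations and yields a marginal contribution
for *every* feature, so the telescoping sum makes the per-permutation
attributions add up exactly to ``f(x) - f(background_row)``; averaging
over draws therefore satisfies local accuracy up to the sampling of
background rows.  ``permutations="exact"`` enumerates all ``n!`` orderings
against every background row, which equals the exact Shapley value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AttributionSet", "ShapleyExplainer", "top_features", "export_gene_list"]


@dataclass
class AttributionSet:
    """Per-sample, per-feature, per-class Shapley estimates."""

    values: np.ndarray  # (n_samples, n_features, n_classes)
    base_values: np.ndarray  # (n_classes,) expected model output over background
    feature_names: list[str]
    modality: np.ndarray  # per-feature tag: snp | expression | clinical
    residuals: np.ndarray  # (n_samples, n_classes) local-accuracy residuals
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, f, c = self.values.shape
        if f != len(self.feature_names) or c != len(self.base_values):
            raise ValueError("attribution array dimensions do not match names/base values")

    def to_long(self) -> pd.DataFrame:
        n, f, c = self.values.shape
        idx = pd.MultiIndex.from_product(
            [range(n), self.feature_names, range(c)], names=["sample", "feature", "class"]
        )
        return pd.DataFrame({"value": self.values.reshape(-1)}, index=idx).reset_index()

    def save(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)


class ShapleyExplainer:
    """Permutation-sampling Shapley attribution for a probabilistic model.

    Parameters
    ----------
    predict : callable
        Maps (n, n_features) arrays to (n, n_classes) probabilities.
    background : ndarray
        Reference rows; the base value is the mean prediction over them.
        Conventionally ~100 training rows.
    feature_names, modality : optional metadata carried into the result.
    random_state : seed for permutation and background draws.
    """

    def __init__(self, predict, background: np.ndarray,
                 feature_names: list[str] | None = None,
                 modality: np.ndarray | None = None,
                 random_state: int | None = None):
        self.predict = predict
        self.background = np.asarray(background, dtype=float)
        if self.background.ndim != 2 or len(self.background) == 0:
            raise ValueError("background must be a non-empty 2-D array")
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(self.background.shape[1])]
        )
        self.modality = (
            np.asarray(modality)
            if modality is not None
            else np.array(["feature"] * self.background.shape[1])
        )
        self.random_state = random_state

    def attributions(
        self, targets: np.ndarray, n_permutations: int | str = 32
    ) -> AttributionSet:
        """Estimate attributions for ``targets``.

        ``n_permutations`` is the sampling budget per sample (each
        permutation costs ``n_features + 1`` model calls); pass
        ``"exact"`` to enumerate all orderings x all background rows
        (feasible for <= 8 features).
        """
        X = np.atleast_2d(np.asarray(targets, dtype=float))
        n_feat = X.shape[1]
        if n_feat != self.background.shape[1]:
            raise ValueError("targets and background widths differ")
        rng = np.random.default_rng(self.random_state)

        if n_permutations == "exact":
            if n_feat > 8:
                raise ValueError("exact enumeration is limited to <= 8 features")
            perms = [np.array(p) for p in iter_permutations(range(n_feat))]
            bg_idx = np.arange(len(self.background))
            draws = [(p, b) for p in perms for b in bg_idx]
        else:
            n_permutations = int(n_permutations)
            if n_permutations < 1:
                raise ValueError("n_permutations must be >= 1 (or 'exact')")
            # antithetic pairing: each sampled ordering is followed by its
            # reverse, a standard variance-reduction for permutation Shapley
            draws = []
            while len(draws) < n_permutations:
                perm = rng.permutation(n_feat)
                b = rng.integers(len(self.background))
                draws.append((perm, b))
                if len(draws) < n_permutations:
                    draws.append((perm[::-1].copy(), b))

        base_values = self.predict(self.background).mean(axis=0)
        n_classes = len(base_values)
        values = np.zeros((len(X), n_feat, n_classes))

        for x_i, x in enumerate(X):
            acc = np.zeros((n_feat, n_classes))
            for perm, b_i in draws:
                b = self.background[b_i]
                # rows[k] has the first k features (in perm order) from x
                pos = np.empty(n_feat, dtype=int)
                pos[perm] = np.arange(n_feat)
                take_x = pos[None, :] < np.arange(n_feat + 1)[:, None]
                rows = np.where(take_x, x[None, :], b[None, :])
                preds = self.predict(rows)
                acc[perm] += preds[1:] - preds[:-1]
            values[x_i] = acc / len(draws)

        fx = self.predict(X)
        residuals = fx - (base_values[None, :] + values.sum(axis=1))
        return AttributionSet(
            values=values,
            base_values=base_values,
            feature_names=self.feature_names,
            modality=self.modality,
            residuals=residuals,
            meta={
                "n_permutations": "exact" if n_permutations == "exact" else int(n_permutations),
                "n_background": len(self.background),
                "random_state": self.random_state,
            },
        )


def top_features(
    aset: AttributionSet, class_index: int, modality: str | None = None, k: int = 20
) -> pd.DataFrame:
    """Rank features of one modality by mean absolute attribution for a class.

    Ties break lexicographically by feature name.  Returns columns
    ``feature, modality, mean_abs_attribution, positive_fraction``.
    """
    import warnings

    mask = np.ones(len(aset.feature_names), dtype=bool)
    if modality is not None:
        mask = aset.modality == modality
        if not mask.any():
            raise ValueError(f"no features tagged with modality {modality!r}")
    vals = aset.values[:, mask, class_index]
    names = [n for n, m in zip(aset.feature_names, mask) if m]
    df = pd.DataFrame(
        {
            "feature": names,
            "modality": aset.modality[mask],
            "mean_abs_attribution": np.abs(vals).mean(axis=0),
            "positive_fraction": (vals > 0).mean(axis=0),
        }
    )
    df = df.sort_values(
        ["mean_abs_attribution", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if k > len(df):
        warnings.warn(f"k={k} exceeds {len(df)} features; returning all", stacklevel=2)
        return df
    return df.head(k)


def export_gene_list(table: pd.DataFrame, path: str | Path) -> list[str]:
    """Write one gene symbol per line, deduplicated, order preserved.

    Feature names of the ``snp:GENE`` / ``expr:GENE`` form are stripped to
    the bare symbol.
    """
    import warnings

    genes: list[str] = []
    for feat in table.get("feature", pd.Series(dtype=str)):
        symbol = feat.split(":", 1)[1] if ":" in feat else feat
        if symbol not in genes:
            genes.append(symbol)
    if not genes:
        warnings.warn("empty feature table; writing empty gene list", stacklevel=2)
    Path(path).write_text("".join(g + "\n" for g in genes))
    return genes
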