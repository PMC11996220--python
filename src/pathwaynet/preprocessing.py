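"""Preprocessing chain: variant encoding, clinical imputation, stratified
splitting, minority oversampling, and scaling.

The chain mirrors the training protocol of the classifier: additive SNP
codes are summed per gene; clinical features with excessive missingness are
dropped and the rest kNN-imputed with statistics fitted on the training
split only; the cohort is stratified 56/14/30 into train/validation/test;
the training block is SMOTE-balanced on the concatenated multimodal matrix;
min-max scaling is fitted on (balanced) training rows and transferred to
validation and test.  Every fit happens on training rows only so no
information leaks across splits.
"""

from __future__ import annotations

import warnings
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import nan_euclidean_distances
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler

from .cohort import CLASS_CODES, CLASS_ORDER, CohortDataset, ProcessedCohort

__all__ = [
    "encode_snps",
    "parse_plink_text",
    "drop_sparse_features",
    "KNNImputerMixed",
    "split_stratified",
    "smote_balance",
    "minmax_scale",
    "one_hot_labels",
    "encode_clinical",
    "preprocess_cohort",
]


# ---------------------------------------------------------------------------
# genotype
# ---------------------------------------------------------------------------

def encode_snps(
    calls: pd.DataFrame, variant_gene_map: dict[str, str] | pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Aggregate additive variant codes (0/1/2) into per-gene sums.

    ``calls`` is samples x variants.  Missing codes contribute 0; variants
    absent from ``variant_gene_map`` are dropped and reported.  Codes
    outside {0, 1, 2} raise a ``ValueError`` naming the offending sample
    and variant.
    """
    if isinstance(variant_gene_map, pd.Series):
        variant_gene_map = variant_gene_map.to_dict()
    values = calls.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid additive code {values[i, j]!r} for sample "
            f"{calls.index[i]!r}, variant {calls.columns[j]!r}"
        )
    mapped = [v for v in calls.columns if v in variant_gene_map]
    dropped = [v for v in calls.columns if v not in variant_gene_map]
    if not mapped:
        raise ValueError("no variant in calls is present in the variant->gene map")
    filled = calls[mapped].fillna(0.0)
    genes = pd.Index([variant_gene_map[v] for v in mapped], name="gene")
    agg = filled.T.groupby(genes).sum().T.astype(float)
    agg.index = calls.index
    report = {
        "n_variants": len(calls.columns),
        "n_mapped": len(mapped),
        "dropped_variants": dropped,
    }
    return agg, report


def parse_plink_text(bim_path: str | Path, fam_path: str | Path):
    """Read PLINK text .bim/.fam companions (whitespace-delimited, 6 cols).

    Returns ``(variants, samples)`` DataFrames keyed by dbSNP-style variant
    id and by individual id respectively.
    """

    def _read(path, names, key):
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) != 6:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 6 whitespace-delimited fields, got {len(fields)}"
                    )
                rows.append(fields)
        df = pd.DataFrame(rows, columns=names)
        return df.set_index(key, drop=False)

    variants = _read(
        bim_path,
        ["chromosome", "variant_id", "cm_position", "position", "allele1", "allele2"],
        "variant_id",
    )
    samples = _read(
        fam_path,
        ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        "individual_id",
    )
    if len(variants):
        variants["position"] = variants["position"].astype(int)
    return variants, samples


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

def drop_sparse_features(
    clinical: pd.DataFrame,
    train_samples,
    max_missing: float = 0.60,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove features whose missing fraction on *training* rows reaches
    ``max_missing``.  Returns the filtered table and the removal list."""
    frac = clinical.loc[train_samples].isna().mean()
    dropped = list(frac.index[frac >= max_missing])
    kept = clinical.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all clinical features exceed the missingness cutoff")
    return kept, dropped


class KNNImputerMixed(TransformerMixin, BaseEstimator):
    """k-nearest-neighbour imputer for mixed continuous/categorical tables.

    Distances are Euclidean over mutually observed features (missing
    coordinates excluded, the sum rescaled by the fraction observed, i.e.
    the ``nan_euclidean`` convention), with continuous columns standardised
    by training mean/SD.  A missing continuous entry is replaced by the
    distance-weighted mean (``weights='distance'``) or plain mean
    (``'uniform'``) of the ``n_neighbors`` nearest training rows holding
    that feature; a categorical entry by their mode (ties -> smallest
    code).  The neighbour pool is always the training table, so the same
    fitted imputer serves validation and test.

    Parameters
    ----------
    n_neighbors : int, default 5
    feature_types : dict, optional
        Column -> ``"continuous"`` | ``"categorical"``; unlisted columns
        are treated as continuous.
    weights : {"distance", "uniform"}, default "distance"
    """

    def __init__(self, n_neighbors: int = 5, feature_types: dict | None = None,
                 weights: str = "distance"):
        self.n_neighbors = n_neighbors
        self.feature_types = feature_types
        self.weights = weights

    def fit(self, X: pd.DataFrame, y=None):
        if self.n_neighbors > len(X) - 1:
            raise ValueError("n_neighbors must be <= training rows - 1")
        self.columns_ = list(X.columns)
        types = self.feature_types or {}
        self.types_ = {c: types.get(c, "continuous") for c in self.columns_}
        vals = X.to_numpy(dtype=float)
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0)
        sd[sd == 0] = 1.0
        self.center_, self.scale_ = mean, sd
        self.train_index_ = list(X.index)
        self.train_values_ = vals
        self.train_scaled_ = (vals - mean) / sd
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != self.columns_:
            raise ValueError("column mismatch with fitted table")
        out = X.to_numpy(dtype=float).copy()
        all_missing = np.isnan(out).all(axis=1)
        if all_missing.any():
            sample = X.index[np.argmax(all_missing)]
            raise ValueError(f"sample {sample!r} has all clinical features missing")
        scaled = (out - self.center_) / self.scale_
        dist = nan_euclidean_distances(scaled, self.train_scaled_)
        train_ids = {sid: i for i, sid in enumerate(self.train_index_)}
        for i, sid in enumerate(X.index):
            miss = np.isnan(out[i])
            if not miss.any():
                continue
            d = dist[i].copy()
            if sid in train_ids:
                d[train_ids[sid]] = np.inf  # never use a row as its own neighbour
            for j in np.flatnonzero(miss):
                candidates = np.flatnonzero(~np.isnan(self.train_values_[:, j]) & np.isfinite(d))
                if candidates.size == 0:
                    raise ValueError(f"no training donor for feature {self.columns_[j]!r}")
                k = min(self.n_neighbors, candidates.size)
                order = candidates[np.argsort(d[candidates], kind="stable")[:k]]
                donor = self.train_values_[order, j]
                if self.types_[self.columns_[j]] == "categorical":
                    counts = Counter(donor)
                    top = max(counts.values())
                    out[i, j] = min(v for v, c in counts.items() if c == top)
                elif self.weights == "distance":
                    w = 1.0 / (d[order] + 1e-12)
                    out[i, j] = float(np.average(donor, weights=w))
                else:
                    out[i, j] = float(donor.mean())
        return pd.DataFrame(out, index=X.index, columns=self.columns_)


def encode_clinical(
    clinical: pd.DataFrame, feature_types: dict[str, str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Integer-code categorical columns, then one-hot expand those with more
    than two categories.  Returns the numeric table and per-column types of
    the expanded layout (indicator columns are tagged categorical)."""
    out = {}
    types_out = {}
    for col in clinical.columns:
        s = clinical[col]
        if feature_types.get(col, "continuous") == "continuous":
            out[col] = pd.to_numeric(s, errors="coerce")
            types_out[col] = "continuous"
            continue
        cats = sorted(s.dropna().unique(), key=str)
        codes = s.map({c: i for i, c in enumerate(cats)})
        if len(cats) <= 2:
            out[col] = codes.astype(float)
            types_out[col] = "categorical"
        else:
            for i, c in enumerate(cats):
                name = f"{col}={c}"
                col_vals = (codes == i).astype(float)
                col_vals[s.isna()] = np.nan
                out[name] = col_vals
                types_out[name] = "categorical"
    return pd.DataFrame(out, index=clinical.index), types_out


# ---------------------------------------------------------------------------
# split / balance / scale / targets
# ---------------------------------------------------------------------------

def split_stratified(
    labels: pd.Series,
    fractions: tuple[float, float, float] = (0.56, 0.14, 0.30),
    seed: int = 0,
) -> pd.Series:
    """Assign train/validation/test with class stratification.

    Realised as a stratified (train+val)/test split followed by a
    stratified train/val split, so with the default fractions the test
    share is 30% and the validation share 14% (20% of the remaining 70%).
    """
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    counts = labels.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"classes with <3 samples cannot be stratified: {list(small.index)}")
    idx = np.asarray(labels.index)
    trainval, test = train_test_split(
        idx, test_size=f_test, stratify=labels.values, random_state=seed
    )
    rel_val = f_val / (f_train + f_val)
    train, val = train_test_split(
        trainval, test_size=rel_val, stratify=labels.loc[trainval].values,
        random_state=seed + 1,
    )
    split = pd.Series(index=labels.index, dtype=object)
    split.loc[train] = "train"
    split.loc[val] = "validation"
    split.loc[test] = "test"
    return split


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling on one concatenated feature matrix.

    Every class is brought up to the majority count; each synthetic row is
    a convex combination ``x + u * (neighbour - x)``, ``u ~ U(0, 1)``, of a
    minority row and one of its ``k_neighbors`` nearest same-class
    neighbours.  Classes with too few members shrink ``k`` with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    counts = Counter(y.tolist())
    target = max(counts.values())
    out_X, out_y = [X], [y]
    for cls in sorted(counts, key=str):
        need = target - counts[cls]
        if need == 0:
            continue
        rows = X[y == cls]
        k = k_neighbors
        if len(rows) <= k:
            k = max(1, len(rows) - 1)
            warnings.warn(
                f"class {cls!r} has {len(rows)} rows; SMOTE k reduced to {k}",
                stacklevel=2,
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(rows)
        _, neigh = nn.kneighbors(rows)
        base = rng.integers(0, len(rows), size=need)
        pick = rng.integers(1, k + 1, size=need)  # skip self at position 0
        u = rng.uniform(0.0, 1.0, size=need)
        partners = rows[neigh[base, pick]]
        synth = rows[base] + u[:, None] * (partners - rows[base])
        out_X.append(synth)
        out_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(out_X), np.concatenate(out_y)


def minmax_scale(
    X_train: np.ndarray, apply_to: list[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray], MinMaxScaler]:
    """Fit per-feature min-max on training rows; transform the rest
    unclipped (validation/test may leave [0, 1]).  Constant features map
    to 0."""
    scaler = MinMaxScaler(clip=False)
    Xt = scaler.fit_transform(X_train)
    others = [scaler.transform(b) for b in apply_to]
    return Xt, others, scaler


def one_hot_labels(labels) -> np.ndarray:
    """CN/MCI/AD (or codes 0/1/2) -> n x 3 indicator matrix, columns in
    (CN, MCI, AD) order."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        codes = arr.astype(int)
        if codes.min() < 0 or codes.max() > 2:
            raise ValueError("integer labels must be in {0, 1, 2}")
    else:
        unknown = set(arr.tolist()) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        codes = np.array([CLASS_CODES[v] for v in arr])
    out = np.zeros((len(codes), 3))
    out[np.arange(len(codes)), codes] = 1.0
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def preprocess_cohort(
    dataset: CohortDataset,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.56, 0.14, 0.30),
    max_missing: float = 0.60,
    impute_k: int = 5,
    smote_k: int = 5,
    apply_smote: bool = True,
) -> ProcessedCohort:
    """Run the full chain and return model-ready tensors.

    Order: split assignment -> clinical categorical encoding -> sparse-
    feature drop (missingness on training rows) -> kNN imputation (fitted
    on train) -> block concatenation -> SMOTE on the training block ->
    min-max scaling (fitted on the balanced training block).
    """
    split = split_stratified(dataset.labels, fractions=fractions, seed=seed)
    train_ids = split.index[split == "train"]
    val_ids = split.index[split == "validation"]
    test_ids = split.index[split == "test"]

    clin_num, clin_types = encode_clinical(dataset.clinical, dataset.clinical_types)
    clin_kept, dropped = drop_sparse_features(clin_num, train_ids, max_missing=max_missing)
    kept_types = {c: clin_types[c] for c in clin_kept.columns}
    imputer = KNNImputerMixed(n_neighbors=impute_k, feature_types=kept_types)
    imputer.fit(clin_kept.loc[train_ids])
    clin_imp = pd.concat(
        [imputer.transform(clin_kept.loc[ids]) for ids in (train_ids, val_ids, test_ids)]
    ).loc[clin_kept.index]

    snp_names = [f"snp:{g}" for g in dataset.genotype.columns]
    expr_names = [f"expr:{g}" for g in dataset.expression.columns]
    clin_names = [f"clin:{c}" for c in clin_imp.columns]
    feature_names = snp_names + expr_names + clin_names
    n_s, n_e, n_c = len(snp_names), len(expr_names), len(clin_names)
    slices = {
        "snp": slice(0, n_s),
        "expression": slice(n_s, n_s + n_e),
        "clinical": slice(n_s + n_e, n_s + n_e + n_c),
    }
    modality = np.array(["snp"] * n_s + ["expression"] * n_e + ["clinical"] * n_c)

    def block(ids):
        return np.concatenate(
            [
                dataset.genotype.loc[ids].to_numpy(float),
                dataset.expression.loc[ids].to_numpy(float),
                clin_imp.loc[ids].to_numpy(float),
            ],
            axis=1,
        )

    codes = dataset.labels.map(CLASS_CODES)
    X_train, y_train = block(train_ids), codes.loc[train_ids].to_numpy()
    X_val, y_val = block(val_ids), codes.loc[val_ids].to_numpy()
    X_test, y_test = block(test_ids), codes.loc[test_ids].to_numpy()

    if apply_smote:
        X_train, y_train = smote_balance(X_train, y_train, k_neighbors=smote_k, seed=seed + 2)

    X_train, (X_val, X_test), scaler = minmax_scale(X_train, [X_val, X_test])

    fitted = {
        "seed": seed,
        "fractions": list(fractions),
        "dropped_clinical": dropped,
        "split": {sid: s for sid, s in split.items()},
        "scaler_min": scaler.data_min_.tolist(),
        "scaler_max": scaler.data_max_.tolist(),
        "smote": bool(apply_smote),
        "pipeline_order": [
            "split", "encode_clinical", "drop_sparse", "knn_impute",
            "concatenate", "smote", "minmax_scale",
        ],
    }
    return ProcessedCohort(
        X_train=X_train, y_train=y_train,
        X_val=X_val, y_val=y_val,
        X_test=X_test, y_test=y_test,
        feature_names=feature_names, modality=modality, slices=slices,
        fitted_params=fitted,
    )
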