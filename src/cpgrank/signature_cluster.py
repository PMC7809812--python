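"""Z-scoring, hierarchical clustering, PCA and signature re-application.

Signature heatmaps in methylation studies are drawn on per-probe Z-scores
(each probe centered and scaled across samples) and samples are grouped by
agglomerative clustering with Euclidean distance and complete linkage —
the defaults of the standard R heatmap/`hclust` stack. This module
reproduces that convention, exposes the k-cut and per-cluster composition,
and adds a nearest-centroid classifier so a fixed signature can be applied
quantitatively to new (e.g. follow-up) samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from cpgrank.core_io import BetaMatrix, ValidationError


@dataclass
class Signature:
    """An ordered panel of K probes with their per-group mean betas.

    ``table`` columns: probe_id (index), direction (+1 if more methylated
    in group 1), mean_group1, mean_group2, combined_rank. Row order is the
    selection order (ascending combined rank).
    """

    table: pd.DataFrame
    group_names: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        required = {"direction", "mean_group1", "mean_group2", "combined_rank"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"signature table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValidationError("signature probes must be unique")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_stats(
        cls, top: pd.DataFrame, group_names: tuple[str, str] = ("group1", "group2")
    ) -> "Signature":
        """Build from a ``select_top_k`` output (keeps its row order)."""
        table = pd.DataFrame(
            {
                "direction": np.sign(top["diff"]).astype(int),
                "mean_group1": top["mean_g1"],
                "mean_group2": top["mean_g2"],
                "combined_rank": top["combined_rank"],
            },
            index=top.index,
        )
        return cls(table, group_names)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "group1", self.group_names[0])
        out.insert(1, "group2", self.group_names[1])
        out.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Signature":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        names = ("group1", "group2")
        if {"group1", "group2"} <= set(df.columns):
            names = (str(df["group1"].iloc[0]), str(df["group2"].iloc[0]))
            df = df.drop(columns=["group1", "group2"])
        return cls(df, names)


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples.

    ``merges`` is the (n−1)×4 scipy linkage matrix; ``sample_ids`` the leaf
    identifiers in input order; ``leaf_order`` the dendrogram left-to-right
    ordering.
    """

    merges: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def zscore_rows(m: BetaMatrix) -> pd.DataFrame:
    """Standardize each probe across samples (mean 0, sd 1, n−1 denominator).

    Constant rows become all-zero with a warning; rows with fewer than two
    non-missing values are dropped and reported via the warning as well.
    """
    df = m.values
    n_ok = df.notna().sum(axis=1)
    too_few = n_ok < 2
    if too_few.any():
        warnings.warn(
            f"{int(too_few.sum())} probe(s) with <2 values excluded from Z-scoring",
            stacklevel=2,
        )
    df = df.loc[~too_few]
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    # exact range test: df.std() on a constant row returns ~1e-17, not 0
    constant = (df.max(axis=1) - df.min(axis=1)) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant probe(s) Z-scored to all zeros",
            stacklevel=2,
        )
    sd[constant] = np.nan
    z = df.sub(mean, axis=0).div(sd, axis=0)
    z.loc[constant] = 0.0
    return z


def hierarchical_cluster(
    z: pd.DataFrame | BetaMatrix, method: str = "complete", metric: str = "euclidean"
) -> ClusterResult:
    """Cluster samples (columns) of a Z-scored matrix.

    Complete linkage on Euclidean distances by default. Missing values are
    not allowed here: drop or impute upstream. Deterministic given column
    order (scipy's tie handling is order-stable).
    """
    df = z.values if isinstance(z, BetaMatrix) else z
    if df.shape[1] < 2:
        raise ValidationError("need >=2 samples to cluster")
    if df.isna().any().any():
        df = df.dropna()
    x = df.to_numpy().T
    merges = linkage(x, method=method, metric=metric)
    order = [df.columns[i] for i in leaves_list(merges)]
    return ClusterResult(merges=merges, sample_ids=list(df.columns), leaf_order=order)


def cut_clusters(tree: ClusterResult, k: int) -> pd.Series:
    """Labels (1..k) from cutting the dendrogram into k groups."""
    n = len(tree.sample_ids)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    labels = fcluster(tree.merges, t=k, criterion="maxclust")
    return pd.Series(labels, index=tree.sample_ids, name="cluster")


def cluster_purity(labels: pd.Series, classes: pd.Series) -> pd.DataFrame:
    """Per-cluster class composition with a purity flag.

    Returns one row per cluster: size, the count of each class present,
    and ``pure`` True when a single class accounts for all members (samples
    with missing class are ignored for purity).
    """
    aligned = pd.DataFrame({"cluster": labels, "klass": classes.reindex(labels.index)})
    rows = []
    for cl, sub in aligned.groupby("cluster"):
        counts = sub["klass"].dropna().value_counts().to_dict()
        rows.append(
            {
                "cluster": cl,
                "size": len(sub),
                "composition": counts,
                "pure": len(counts) == 1,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def apply_signature(
    sig: Signature,
    m_new: BetaMatrix,
    m_reference: BetaMatrix | None = None,
    min_coverage: float = 0.5,
) -> tuple[pd.DataFrame, ClusterResult, pd.DataFrame]:
    """Apply a fixed signature to new samples.

    Restricts to the signature probes (at least ``min_coverage`` of them
    must be present in ``m_new``), Z-scores jointly with the reference
    cohort when given (Z-scores are cohort-relative, so new samples must be
    standardized against the same pool they are compared to), re-clusters,
    and assigns each new sample to the nearer of the two signature
    centroids by Euclidean distance on raw beta values.

    Returns ``(subset_z, tree, assignment)`` where ``assignment`` has one
    row per new sample: predicted class, distances to both centroids and
    the relative margin ``|d1 − d2| / (d1 + d2)`` (near zero when neither
    centroid fits better — the signature is uninformative for that sample).
    """
    present = sig.probe_ids.intersection(m_new.probe_ids)
    coverage = len(present) / len(sig)
    if coverage < min_coverage:
        raise ValidationError(
            f"only {coverage:.0%} of signature probes present (need >= {min_coverage:.0%})"
        )
    sub_new = m_new.values.loc[present]

    if m_reference is not None:
        ref_probes = present.intersection(m_reference.probe_ids)
        sub_new = sub_new.loc[ref_probes]
        joint = pd.concat(
            [
                m_reference.values.loc[ref_probes],
                sub_new.drop(
                    columns=[c for c in sub_new.columns if c in m_reference.sample_ids]
                ),
            ],
            axis=1,
        )
    else:
        joint = sub_new
    z = zscore_rows(BetaMatrix(joint))
    tree = hierarchical_cluster(z)

    cent1 = sig.table.loc[z.index.intersection(sig.probe_ids), "mean_group1"]
    cent2 = sig.table.loc[z.index.intersection(sig.probe_ids), "mean_group2"]
    rows = []
    for s in m_new.sample_ids:
        v = m_new.values.loc[cent1.index, s]
        ok = v.notna()
        d1 = float(np.sqrt(((v[ok] - cent1[ok]) ** 2).sum()))
        d2 = float(np.sqrt(((v[ok] - cent2[ok]) ** 2).sum()))
        margin = abs(d1 - d2) / (d1 + d2) if (d1 + d2) > 0 else 0.0
        rows.append(
            {
                "sample_id": s,
                "predicted": sig.group_names[0] if d1 <= d2 else sig.group_names[1],
                "dist_group1": d1,
                "dist_group2": d2,
                "margin": margin,
            }
        )
    assignment = pd.DataFrame(rows).set_index("sample_id")
    return z, tree, assignment


def pca_embed(m: BetaMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """First principal components of the samples.

    Probes are mean-centered (no scaling) and components come from the SVD
    of the centered matrix. Returns per-sample coordinates and the
    explained-variance fractions.
    """
    if m.shape[1] < 3:
        raise ValidationError("need >=3 samples for PCA")
    df = m.values.dropna()
    x = df.to_numpy().T  # samples × probes
    x = x - x.mean(axis=0)
    if np.allclose(x, 0):
        raise ValidationError("degenerate (constant) matrix: PCA undefined")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        u[:, :k] * s[:k],
        index=df.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return coords, frac[:k]


def global_methylation_change(m: BetaMatrix, sheet) -> pd.DataFrame:
    """Per-subject mean beta change diagnosis → follow-up.

    For each subject with both timepoints, the mean over shared non-missing
    probes of (follow-up − diagnosis); negative values indicate global
    demethylation. Subjects missing a timepoint are skipped and reported in
    the ``skipped`` attribute of the returned frame.
    """
    table = sheet.table
    rows = []
    skipped = []
    for subject, sub in table[table["subject_id"] != "reference"].groupby("subject_id"):
        dx = sub.loc[sub["timepoint"] == "diagnosis", "sample_id"]
        fu = sub.loc[sub["timepoint"] == "followup", "sample_id"]
        if len(dx) != 1 or len(fu) != 1:
            skipped.append(subject)
            continue
        a = m.values[dx.iloc[0]]
        b = m.values[fu.iloc[0]]
        ok = a.notna() & b.notna()
        rows.append(
            {
                "subject_id": subject,
                "treatment": sub["treatment"].iloc[0],
                "mean_change": float((b[ok] - a[ok]).mean()),
                "n_probes": int(ok.sum()),
            }
        )
    out = pd.DataFrame(rows, columns=["subject_id", "treatment", "mean_change", "n_probes"])
    out.attrs["skipped"] = skipped
    return out


def pairwise_sample_distances(z: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance matrix between sample columns (convenience)."""
    from scipy.spatial.distance import squareform

    d = squareform(pdist(z.dropna().to_numpy().T))
    return pd.DataFrame(d, index=z.columns, columns=z.columns)
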