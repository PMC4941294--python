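"""Per-dataset differential expression and the training/validation signature.

Each cohort is tested feature-by-feature (tumor vs normal on log2 values)
with either a Welch t-test or an empirical-Bayes variance-moderated
t-test, p-values are Benjamini-Hochberg adjusted within the cohort, and a
feature enters the cross-dataset signature only when it is significant,
with a consistent direction, in every training AND every validation
cohort.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotate import strip_version
from .types import ExpressionDataset, TranscriptRecord

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "feature", "mean_tumor", "mean_normal", "log2fc", "t", "df", "p", "p_adj", "direction",
]


# ---------------------------------------------------------------------------
# tests


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t with Satterthwaite degrees of freedom.

    Degenerate zero-variance inputs are resolved by the limit: equal
    means give (t=0, p=1); unequal means give an infinite statistic and
    p=0 rather than a division error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    denom2 = vx / x.size + vy / y.size
    if denom2 == 0.0:
        if diff == 0.0:
            return 0.0, float(x.size + y.size - 2), 1.0
        return float(np.sign(diff) * np.inf), float(x.size + y.size - 2), 0.0
    t = diff / np.sqrt(denom2)
    df = denom2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x - dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from per-feature variances.

    Method of moments on z = log s^2: if s^2 ~ s0^2 * F(df, d0) then
    E[z] = log s0^2 + psi(df/2) - log(df/2) + log(d0/2) - psi(d0/2) and
    Var[z] = psi'(df/2) + psi'(d0/2).  When the observed spread of z is
    no larger than the sampling component, d0 is +inf (all features share
    one variance) and s0^2 is the corresponding pooled value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        # no excess spread beyond sampling noise: one shared variance
        return np.inf, float(s2[ok].mean())
    d0 = 2.0 * _trigamma_inverse(evar)
    if np.isinf(d0):
        return np.inf, float(s2[ok].mean())
    s0_2 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def moderated_t_test(
    values: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes variance-moderated t-tests, feature-wise.

    Per-feature pooled variances s_g^2 (df = n1 + n2 - 2) are shrunk
    toward a prior: s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g), with
    (d0, s0^2) estimated by moments across features.  The statistic uses
    s~_g^2 and is referred to a t distribution with d0 + d_g degrees of
    freedom.  d0=0 recovers the ordinary pooled-variance t per feature;
    d0=inf gives a common-variance t shared by all features.
    """
    mat = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    labels = np.asarray(labels)
    classes = ("tumor", "normal") if "tumor" in labels else tuple(pd.unique(labels))[:2]
    m1 = labels == classes[0]
    m2 = labels == classes[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least 2 samples")
    if mat.shape[0] < 10:
        raise ValueError("moderated test needs >=10 features to estimate the variance prior")
    x1, x2 = mat[:, m1], mat[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    dg = n1 + n2 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / dg
    if d0 is None:
        d0, s0_2 = fit_f_dist(s2, dg)
    elif s0_2 is None:
        s0_2 = float(np.mean(s2))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    # total df cannot exceed the pooled residual df of all features
    df_total = min(df_total, float(mat.shape[0] * dg))
    diff = mean1 - mean2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no difference, no variance
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "mean_tumor": mean1,
            "mean_normal": mean2,
            "log2fc": diff,
            "t": t,
            "df": df_total,
            "p": p,
        },
        index=values.index if isinstance(values, pd.DataFrame) else None,
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_adj(i) = min_{j >= i} (m * p_(j) / j) clipped at 1, returned in the
    original order.
    """
    p = np.asarray(pvals, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def dataset_de(
    dataset: ExpressionDataset, method: str = "moderated", alpha: float = 0.01
) -> pd.DataFrame:
    """Per-feature DE table for one cohort with BH-adjusted p-values.

    The ``significant`` column applies the strict threshold
    p_adj < alpha.
    """
    if method not in ("welch", "moderated"):
        raise ValueError(f"unknown method {method!r}")
    labels = dataset.labels.to_numpy()
    if method == "moderated":
        res = moderated_t_test(dataset.values, labels)
    else:
        tum = dataset.class_values("tumor")
        nor = dataset.class_values("normal")
        rows = [welch_t_test(tum[i], nor[i]) for i in range(tum.shape[0])]
        t, df, p = map(np.array, zip(*rows))
        res = pd.DataFrame(
            {
                "mean_tumor": tum.mean(axis=1),
                "mean_normal": nor.mean(axis=1),
                "log2fc": tum.mean(axis=1) - nor.mean(axis=1),
                "t": t,
                "df": df,
                "p": p,
            },
            index=dataset.values.index,
        )
    res = res.reset_index(names="feature")
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["direction"] = np.where(res["log2fc"] >= 0, "up", "down")
    res["significant"] = res["p_adj"] < alpha
    return res


# ---------------------------------------------------------------------------
# training/validation intersection


def train_validate_signature(
    results_by_dataset: Mapping[str, pd.DataFrame],
    roles: Mapping[str, str],
    alpha: float = 0.01,
    require_direction: bool = True,
    min_support: int | None = None,
) -> pd.DataFrame:
    """Features significant in every training AND every validation cohort.

    The default scheme requires p_adj < alpha in all cohorts with a
    consistent fold-change sign; ``min_support`` relaxes this to "at
    least min_support cohorts" (direction consistency, if required, is
    then over the supporting cohorts).  The result is sorted by combined
    evidence (sum of log10 p_adj over all cohorts, ascending) with ties
    broken by feature id, and carries per-cohort p_adj/log2fc columns.
    """
    ids = list(results_by_dataset)
    if not any(roles[d] == "train" for d in ids) or not any(
        roles[d] == "validation" for d in ids
    ):
        raise ValueError("need at least one training and one validation dataset")
    common = set(results_by_dataset[ids[0]]["feature"])
    union: set = set()
    for d in ids:
        feats = set(results_by_dataset[d]["feature"])
        common &= feats
        union |= feats
    n_dropped = len(union - common)
    if n_dropped:
        logger.warning(
            "%d features absent from at least one dataset were excluded", n_dropped
        )
    frames = {
        d: results_by_dataset[d].set_index("feature").loc[sorted(common)] for d in ids
    }
    feats = sorted(common)
    padj = np.column_stack([frames[d]["p_adj"].to_numpy() for d in ids])
    lfc = np.column_stack([frames[d]["log2fc"].to_numpy() for d in ids])
    sig = padj < alpha
    if min_support is None:
        keep = sig.all(axis=1)
        if require_direction:
            keep &= (np.sign(lfc) == np.sign(lfc[:, [0]])).all(axis=1)
        n_support = sig.sum(axis=1)
    else:
        n_support = sig.sum(axis=1)
        keep = n_support >= min_support
        if require_direction:
            up = (sig & (lfc > 0)).sum(axis=1)
            down = (sig & (lfc < 0)).sum(axis=1)
            keep &= (up == n_support) | (down == n_support)
    score = np.log10(np.clip(padj, 1e-300, 1.0)).sum(axis=1)
    out = pd.DataFrame(
        {
            "feature": feats,
            "direction": np.where(lfc.mean(axis=1) >= 0, "up", "down"),
            "n_support": n_support,
            "score": score,
        }
    )
    for d in ids:
        out[f"p_adj_{d}"] = padj[:, ids.index(d)]
        out[f"log2fc_{d}"] = lfc[:, ids.index(d)]
    out = out[keep]
    out = out.sort_values(["score", "feature"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_features_dropped"] = n_dropped
    return out


def top_k(signature: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """First k signature entries by combined evidence (ties by feature id)."""
    if k > len(signature):
        logger.warning("k=%d exceeds signature size %d; returning all", k, len(signature))
        k = len(signature)
    ordered = signature.sort_values(["score", "feature"], kind="mergesort")
    return ordered.head(k).reset_index(drop=True)


def annotate_signature(
    signature: pd.DataFrame, annotation: pd.DataFrame, collapse: bool = True
) -> pd.DataFrame:
    """Map probeset features to lncRNA accessions via the annotation table.

    With ``collapse`` (default), multiple probe sets for one accession
    keep only the best-scoring (smallest combined evidence) entry.
    """
    ann = annotation[["probeset_id", "accession", "gene_symbol"]].drop_duplicates()
    merged = signature.merge(
        ann, left_on="feature", right_on="probeset_id", how="inner"
    ).drop(columns="probeset_id")
    if collapse and not merged.empty:
        merged = (
            merged.sort_values(["score", "feature"], kind="mergesort")
            .groupby("accession", sort=False)
            .head(1)
        )
    return merged.sort_values(["score", "feature"], kind="mergesort").reset_index(drop=True)


def intersect_signature(
    signature: pd.DataFrame, external_ids: Sequence[str]
) -> pd.DataFrame:
    """Signature entries whose accession or gene symbol is in an external list.

    Ids are normalized (uppercase, accession version stripped) before
    comparison, mirroring how published candidate lists are matched.
    """
    if len(external_ids) == 0:
        logger.warning("empty external id list; intersection is empty")
        return signature.iloc[0:0]
    norm = {strip_version(str(e)).upper() for e in external_ids}

    def hit(row) -> bool:
        keys = {strip_version(str(row.get("feature", ""))).upper()}
        for col in ("accession", "gene_symbol"):
            if col in row.index:
                keys.add(strip_version(str(row[col])).upper())
        return bool(keys & norm)

    mask = signature.apply(hit, axis=1) if not signature.empty else pd.Series(dtype=bool)
    return signature[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# clustering and tallies


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "one_minus_pearson",
    linkage: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of the matrix rows.

    Returns the scipy linkage matrix and the deterministic leaf order
    (labels).  Correlation distance (1 - Pearson r) requires non-constant
    rows; offenders are named in the error.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    X = matrix.to_numpy(dtype=float)
    if distance == "one_minus_pearson":
        sd = X.std(axis=1)
        if (sd == 0).any():
            bad = list(matrix.index[sd == 0])
            raise ValueError(f"constant rows have undefined correlation: {bad}")
        D = 1.0 - np.corrcoef(X)
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
        condensed = squareform(D, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(X)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    Z = hierarchy.linkage(condensed, method=linkage)
    order = [matrix.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


def cut_clusters(Z: np.ndarray, labels: Sequence[str], k: int) -> pd.Series:
    """Partition the linkage tree into k clusters."""
    assign = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(assign, index=list(labels), name="cluster")


def tally_by_chromosome(
    signature: pd.DataFrame, transcripts: Sequence[TranscriptRecord]
) -> pd.DataFrame:
    """Up/down counts of signature lncRNAs per chromosome.

    Entries whose accession has no located transcript are tallied under
    ``unlocated``; totals across rows equal the signature size.
    """
    loc = {strip_version(t.accession): t.chrom for t in transcripts}
    rows: dict[str, list[int]] = {}
    for _, entry in signature.iterrows():
        acc = strip_version(str(entry.get("accession", entry["feature"])))
        chrom = loc.get(acc, "unlocated")
        rows.setdefault(chrom, [0, 0])
        rows[chrom][0 if entry["direction"] == "up" else 1] += 1
    out = pd.DataFrame(
        [(c, u, d) for c, (u, d) in rows.items()], columns=["chrom", "n_up", "n_down"]
    )
    return out.sort_values("chrom", kind="mergesort").reset_index(drop=True)


def tally_by_biotype(
    signature: pd.DataFrame, transcripts: Sequence[TranscriptRecord]
) -> pd.DataFrame:
    """Signature counts per lncRNA biotype (antisense, lincRNA, ...)."""
    bio = {strip_version(t.accession): t.biotype for t in transcripts}
    counts: dict[str, int] = {}
    for _, entry in signature.iterrows():
        acc = strip_version(str(entry.get("accession", entry["feature"])))
        b = bio.get(acc, "unknown")
        counts[b] = counts.get(b, 0) + 1
    out = pd.DataFrame(sorted(counts.items()), columns=["biotype", "n"])
    return out
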