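"""Signature characterization: survival, coexpression, GSEA, enrichment.

Survival analysis dichotomizes patients at the median expression of the
target lncRNA and compares the groups by Kaplan-Meier curves, a two-group
log-rank test, and a univariate Cox proportional-hazards fit (Newton-
Raphson on the Breslow partial likelihood).  Functional characterization
ranks protein-coding genes by Pearson correlation with the target (or by
signal-to-noise between expression groups) and scores gene sets with the
weighted Kolmogorov-Smirnov enrichment statistic and a permutation null.
Gene Ontology-style enrichment of a query list is an upper-tail
hypergeometric test per set with BH adjustment.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust, welch_t_test
from .types import CoxFit, ExpressionDataset, GseaResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# survival


def median_dichotomize(expression: Sequence[float]) -> np.ndarray:
    """Split samples into high/low at the median; ties go to low.

    Guarantees |high| <= |low|.  All-identical input admits no split and
    is rejected.
    """
    x = np.asarray(expression, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples to dichotomize")
    med = np.median(x)
    if (x == x[0]).all():
        raise ValueError("all expression values identical; no median split possible")
    return np.where(x > med, "high", "low")


def kaplan_meier(time: Sequence[float], event: Sequence[int]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with the at-risk count,
    number of events, and the survival probability just after that time.
    S(0) = 1; censored observations only shrink the risk set.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty cohort")
    if (t <= 0).any():
        raise ValueError("survival times must be strictly positive")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n = t.size
    i = 0
    while i < n:
        ti = t[i]
        d = int(e[(t == ti)].sum())
        at_risk = int(n - i)
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append((ti, at_risk, d, s))
        i += int((t == ti).sum())
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def logrank_test(
    time: Sequence[float], event: Sequence[int], group: Sequence[str]
) -> tuple[float, float]:
    """Two-group log-rank test.

    Sums observed-minus-expected events in group 1 over distinct event
    times with the hypergeometric variance; the statistic is referred to
    chi-square with 1 df.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    groups = np.unique(g)
    if groups.size != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {list(groups)}")
    if e.sum() == 0:
        raise ValueError("no events observed")
    g1 = g == groups[0]
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(e[(t == ti)].sum())
        d1 = int(e[(t == ti) & g1].sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def cox_univariate(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence[int] | Sequence[str],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Univariate Cox PH fit for a binary covariate, Breslow ties.

    Newton-Raphson maximization of the partial likelihood; the Wald 95%
    interval is exp(beta +/- 1.96 SE).  Monotone likelihood (complete
    separation) caps |beta| and reports converged=False.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    if g.dtype.kind in "UO":  # 'high'/'low' labels -> indicator for 'high'
        x = (g == "high").astype(float)
    else:
        x = g.astype(float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("covariate must be binary (0/1 or low/high)")
    order = np.argsort(t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        raise ValueError("no events observed")
    # per distinct event time: observed sum of x over events, and risk-set masks
    d_k = np.array([e[t == ti].sum() for ti in event_times], dtype=float)
    sx_k = np.array([x[(t == ti) & (e == 1)].sum() for ti in event_times])
    risk_n1 = np.array([x[t >= ti].sum() for ti in event_times])  # group-1 at risk
    risk_n0 = np.array([(t >= ti).sum() for ti in event_times]) - risk_n1

    beta = 0.0
    converged = False
    it = 0
    cap = 15.0
    for it in range(1, max_iter + 1):
        r1 = risk_n1 * np.exp(beta)
        s0 = risk_n0 + r1
        mu = r1 / s0
        U = float(np.sum(sx_k - d_k * mu))
        I = float(np.sum(d_k * mu * (1 - mu)))
        if I <= 0:
            break
        step = U / I
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > cap:  # monotone likelihood
            beta = float(np.sign(beta) * cap)
            break
        if abs(step) < tol:
            converged = True
            break
    r1 = risk_n1 * np.exp(beta)
    mu = r1 / (risk_n0 + r1)
    I = float(np.sum(d_k * mu * (1 - mu)))
    se = float(1.0 / np.sqrt(I)) if I > 0 else np.inf
    if not converged:
        logger.warning("Cox fit did not converge (monotone likelihood or max_iter)")
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxFit(
        beta=float(beta),
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(p),
        n_events=int(e.sum()),
        converged=converged,
        iterations=it,
    )


def survival_report(cohort: pd.DataFrame) -> dict:
    """Median split on expression, then KM, log-rank and Cox in one pass.

    ``cohort`` needs columns sample/time/event/expression; a ``group``
    column is derived if absent.
    """
    df = cohort.copy()
    if "group" not in df.columns:
        df["group"] = median_dichotomize(df["expression"].to_numpy())
    chi2, p_lr = logrank_test(df["time"], df["event"], df["group"])
    fit = cox_univariate(df["time"], df["event"], df["group"])
    return {"cohort": df, "logrank_chi2": chi2, "logrank_p": p_lr, "cox": fit}


# ---------------------------------------------------------------------------
# rankings


def correlation_ranking(
    dataset: ExpressionDataset,
    target_feature: str,
    candidate_features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genes ranked by Pearson correlation with the target feature.

    Constant rows get score 0 and a ``constant`` flag instead of an
    undefined correlation.  The target itself is excluded.  Ties are
    broken by gene id for a strict deterministic order.
    """
    if target_feature not in dataset.values.index:
        raise KeyError(f"target feature {target_feature!r} absent from dataset")
    if dataset.values.shape[1] < 4:
        raise ValueError("need at least 4 samples for correlation ranking")
    target = dataset.values.loc[target_feature].to_numpy(dtype=float)
    feats = (
        [f for f in candidate_features if f != target_feature]
        if candidate_features is not None
        else [f for f in dataset.values.index if f != target_feature]
    )
    X = dataset.values.loc[feats].to_numpy(dtype=float)
    tc = target - target.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (tc**2).sum())
    constant = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ tc) / denom
    r = np.where(constant, 0.0, r)
    out = pd.DataFrame({"gene": feats, "score": r, "constant": constant})
    return out.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


def signal_to_noise_ranking(
    values: pd.DataFrame, labels: Sequence[str], positive_class: str = "high"
) -> pd.DataFrame:
    """GSEA's default per-gene metric: (mu_pos - mu_neg) / (sd_pos + sd_neg).

    Standard deviations are floored at 0.2*|mean| (and at 0.2 absolute
    when the mean is 0), the classic implementation convention that
    guards near-constant genes.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if positive_class not in classes or classes.size != 2:
        raise ValueError(f"need 2 classes including {positive_class!r}, got {list(classes)}")
    pos = labels == positive_class
    if pos.sum() < 3 or (~pos).sum() < 3:
        raise ValueError("each class needs at least 3 samples for signal-to-noise")
    X = values.to_numpy(dtype=float)
    mu_p, mu_n = X[:, pos].mean(axis=1), X[:, ~pos].mean(axis=1)
    sd_p, sd_n = X[:, pos].std(axis=1, ddof=1), X[:, ~pos].std(axis=1, ddof=1)

    def floor(sd, mu):
        f = 0.2 * np.abs(mu)
        f = np.where(f == 0, 0.2, f)
        return np.maximum(sd, f)

    s2n = (mu_p - mu_n) / (floor(sd_p, mu_p) + floor(sd_n, mu_n))
    out = pd.DataFrame({"gene": values.index, "score": s2n})
    return out.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# GSEA


def gsea_enrichment_score(
    ranked: pd.DataFrame, gene_set: Sequence[str], set_name: str = "", p_weight: float = 1.0
) -> GseaResult:
    """Weighted-KS enrichment score of a gene set in a ranked list.

    Walking down the list, a hit increments the running sum by
    |score|^p_weight normalized by the total hit weight; a miss
    decrements by 1/(N - N_hits).  ES is the extremum of largest
    magnitude; the leading edge contains the hits at or before (positive
    ES) or at and after (negative ES) the extremum.  By construction the
    running sum returns to 0 at the end of the list.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    in_set = np.isin(genes, np.asarray(list(gene_set)))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {set_name!r} has no overlap with the ranked list")
    N = genes.size
    w = np.abs(scores) ** p_weight
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores exactly 0: fall back to unweighted steps
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total
    if N > n_hits:
        steps = steps - (~in_set) / (N - n_hits)
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], in_set[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], in_set[i_ext:]) if h]
    return GseaResult(set_name=set_name, es=es, running_sum=running, leading_edge=leading)


def gsea_permutation_test(
    values: pd.DataFrame | None,
    labels: Sequence[str] | None,
    gene_set: Sequence[str],
    set_name: str = "",
    n_perm: int = 1000,
    scheme: str = "phenotype",
    seed: int = 0,
    p_weight: float = 1.0,
    positive_class: str = "tumor",
    ranked: pd.DataFrame | None = None,
) -> GseaResult:
    """Permutation p-value and NES for one gene set.

    ``phenotype`` permutes sample labels and re-ranks by signal-to-noise
    each time; ``gene_set`` keeps the observed ranking and scores random
    gene sets of equal size.  Following the classic sign-stratified
    convention, p_perm = (1 + #{|ES*| >= |ES|, same sign}) /
    (1 + #{same-sign ES*}), which is null-uniform; NES =
    ES / mean(|same-sign ES*|).
    """
    rng = np.random.default_rng(seed)
    if scheme not in ("phenotype", "gene_set"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "phenotype":
        if values is None or labels is None:
            raise ValueError("phenotype permutation needs the expression matrix and labels")
        labels = np.asarray(labels)
        if np.unique(labels).size < 2:
            raise ValueError("cannot permute a single-class label vector")
        ranked = signal_to_noise_ranking(values, labels, positive_class)
    elif ranked is None:
        raise ValueError("gene_set permutation needs a precomputed ranking")
    obs = gsea_enrichment_score(ranked, gene_set, set_name, p_weight)
    es_perm = np.empty(n_perm)
    if scheme == "phenotype":
        for b in range(n_perm):
            perm = rng.permutation(labels)
            rk = signal_to_noise_ranking(values, perm, positive_class)
            es_perm[b] = gsea_enrichment_score(rk, gene_set, set_name, p_weight).es
    else:
        genes = ranked["gene"].to_numpy()
        size = int(np.isin(genes, np.asarray(list(gene_set))).sum())
        for b in range(n_perm):
            rnd = rng.choice(genes, size=size, replace=False)
            es_perm[b] = gsea_enrichment_score(ranked, rnd, set_name, p_weight).es
    same_sign = es_perm * np.sign(obs.es) > 0 if obs.es != 0 else np.ones(n_perm, bool)
    extreme = np.abs(es_perm) >= abs(obs.es)
    p_perm = (1.0 + int((same_sign & extreme).sum())) / (1.0 + int(same_sign.sum()))
    denom = np.abs(es_perm[same_sign]).mean() if same_sign.any() else np.nan
    nes = obs.es / denom if denom and np.isfinite(denom) else np.nan
    return GseaResult(
        set_name=set_name,
        es=obs.es,
        running_sum=obs.running_sum,
        leading_edge=obs.leading_edge,
        nes=float(nes),
        p_perm=float(p_perm),
        n_perm=n_perm,
    )


def gsea_report(
    values: pd.DataFrame,
    labels: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    scheme: str = "phenotype",
    seed: int = 0,
    p_weight: float = 1.0,
    positive_class: str = "tumor",
) -> pd.DataFrame:
    """Score every gene set; BH-adjust the permutation p-values across sets."""
    rows = []
    ranked = (
        signal_to_noise_ranking(values, np.asarray(labels), positive_class)
        if scheme == "gene_set"
        else None
    )
    for i, (name, members) in enumerate(gene_sets.items()):
        res = gsea_permutation_test(
            values,
            labels,
            members,
            ranked=ranked,
            set_name=name,
            n_perm=n_perm,
            scheme=scheme,
            seed=seed + i,
            p_weight=p_weight,
            positive_class=positive_class,
        )
        rows.append(
            {
                "set_name": name,
                "size": len(members),
                "es": res.es,
                "nes": res.nes,
                "p_perm": res.p_perm,
                "leading_edge_size": len(res.leading_edge),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_perm"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# hypergeometric set enrichment (GO-style stand-in)


def hypergeometric_enrichment(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    With N universe genes, K in the set, n in the query, and k in the
    overlap, p = P[X >= k] for X ~ Hypergeom(N, K, n), BH-adjusted
    across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(uni), len(query)
    rows = []
    for name, members in gene_sets.items():
        m = set(members) & uni
        K = len(m)
        k = len(m & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# nearest TSS


def distance_to_nearest_tss(lnc_bed: pd.DataFrame, tss_bed: pd.DataFrame) -> pd.DataFrame:
    """Signed distance from each lncRNA's TSS to the nearest coding TSS.

    Both inputs are BED6 frames (0-based half-open; TSS = start on '+',
    end-1 on '-').  The sign is relative to the coding gene's strand:
    negative when the lncRNA TSS lies upstream of the coding TSS,
    positive downstream.  A lncRNA TSS inside a coding gene's interval
    has distance 0.  Chromosomes with no coding TSS yield NaN and a flag.
    """

    def tss_of(row) -> int:
        return int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1

    by_chrom: dict[str, list[tuple[int, str, int, int]]] = {}
    for _, row in tss_bed.iterrows():
        by_chrom.setdefault(row["chrom"], []).append(
            (tss_of(row), row["strand"], int(row["start"]), int(row["end"]))
        )
    rows = []
    for _, row in lnc_bed.iterrows():
        ltss = tss_of(row)
        cands = by_chrom.get(row["chrom"])
        if not cands:
            rows.append({"name": row["name"], "distance": np.nan, "no_tss_on_chrom": True})
            continue
        best = None
        for ctss, cstrand, cstart, cend in cands:
            if cstart <= ltss < cend:
                d = 0
            else:
                d = ltss - ctss if cstrand == "+" else ctss - ltss
            key = (abs(d), d)
            if best is None or key < best[0]:
                best = (key, d)
        rows.append({"name": row["name"], "distance": best[1], "no_tss_on_chrom": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# utility formulas


def ddct_fold_change(
    ct_target_case: float, ct_ref_case: float, ct_target_ctrl: float, ct_ref_ctrl: float
) -> float:
    """Relative qPCR quantification, 2**(-ddCt)."""
    vals = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def xenograft_volume(length_mm: float, width_mm: float) -> float:
    """Tumor volume estimate: length x width^2 x 0.5 (mm^3)."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("dimensions must be nonnegative")
    return float(length_mm * width_mm**2 * 0.5)


def group_comparison(values: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """Two groups: Welch t-test; more: classical one-way ANOVA F."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    uniq = pd.unique(g)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    parts = [v[g == u] for u in uniq]
    if any(p.size < 2 for p in parts):
        raise ValueError("every group needs at least 2 values")
    if uniq.size == 2:
        t, _df, p = welch_t_test(parts[0], parts[1])
        return t, p
    f, p = stats.f_oneway(*parts)
    return float(f), float(p)
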