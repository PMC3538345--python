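"""Batch-matched differential expression with empirical-Bayes moderation.

Each knockdown is contrasted against the GFP controls of its own batch, so
any additive per-(gene, batch) effect cancels exactly. Residual variance is
pooled over every replicate group in the model (one group per experiment
plus one control group per batch), giving singlicate knockdowns degrees of
freedom from the quadruplicate controls. Per-gene variances are then shrunk
toward a common prior by a method-of-moments fit of the scaled-F
distribution of sample variances, and moderated t statistics computed on
the augmented degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

VARIANCE_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# normalisation


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of per-rank means.

    After normalisation the sorted value vector of every column is the
    across-column mean of sorted values. Ties within a column receive the
    mean of the reference values over their rank range.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    x = matrix.to_numpy(float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        assigned = np.empty(len(order))
        assigned[order] = reference
        # tied input values receive the mean reference over their rank range
        _, inverse = np.unique(x[:, j], return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# linear-model contrasts


def fit_batch_contrasts(
    compendium: pd.DataFrame, sheet: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Per-(experiment, gene) contrasts against in-batch GFP controls.

    Returns ``(contrasts, s2, df)`` where ``contrasts`` is a long table with
    columns (experiment_id, batch, gene is implicit in the wide companion)
    -- concretely: a DataFrame with one row per (experiment, gene) carrying
    ``logfc`` and the contrast variance scale ``1/n_treated + 1/n_control``;
    ``s2`` is the per-gene residual variance pooled over all replicate
    groups and batches, and ``df`` the total residual degrees of freedom.
    """
    sheet = sheet.set_index("sample_id", drop=False)
    x = compendium.to_numpy(float)
    genes = compendium.index

    ss = np.zeros(len(genes))
    total_df = 0
    group_means: dict[str, np.ndarray] = {}
    group_sizes: dict[str, int] = {}
    control_means: dict[str, np.ndarray] = {}
    control_sizes: dict[str, int] = {}

    for batch, bsheet in sheet.groupby("batch"):
        ctrl_ids = bsheet.loc[bsheet["is_control"], "sample_id"]
        if len(ctrl_ids) < 1:
            raise ValueError(f"batch {batch!r} has no control samples")
        n_groups = 0
        for exp_id, grp in bsheet.groupby("experiment_id"):
            cols = [compendium.columns.get_loc(s) for s in grp["sample_id"]]
            sub = x[:, cols]
            mean = sub.mean(axis=1)
            ss += ((sub - mean[:, None]) ** 2).sum(axis=1)
            n_groups += 1
            if grp["is_control"].iloc[0]:
                control_means[batch] = mean
                control_sizes[batch] = len(cols)
            else:
                group_means[exp_id] = mean
                group_sizes[exp_id] = len(cols)
        n_batch = len(bsheet)
        if n_batch - n_groups < 1 and len(ctrl_ids) < 2:
            raise ValueError(
                f"batch {batch!r}: no residual degrees of freedom "
                "(need >=2 controls or replicated treatments)"
            )
        total_df += n_batch - n_groups
    if total_df < 1:
        raise ValueError("model has no residual degrees of freedom")

    s2 = pd.Series(ss / total_df, index=genes, name="s2")

    batch_of = sheet.drop_duplicates("experiment_id").set_index("experiment_id")["batch"]
    frames = []
    for exp_id, mean in group_means.items():
        batch = batch_of[exp_id]
        logfc = mean - control_means[batch]
        scale = 1.0 / group_sizes[exp_id] + 1.0 / control_sizes[batch]
        frames.append(pd.DataFrame({
            "experiment_id": exp_id,
            "gene": genes,
            "logfc": logfc,
            "scale": scale,
        }))
    contrasts = pd.concat(frames, ignore_index=True)
    return contrasts, s2, float(total_df)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation


@dataclass
class ModeratedVariance:
    """Hyperparameters and posterior variances of the shrinkage model.

    ``d0`` is the prior degrees of freedom (``inf`` means complete
    shrinkage to the prior variance ``s0_sq``); ``s2_post`` are the per-gene
    posterior variances and ``df_total`` the augmented degrees of freedom
    used by the moderated t.
    """

    d0: float
    s0_sq: float
    s2_post: pd.Series
    df: float
    fallback: bool = False

    @property
    def df_total(self) -> float:
        return self.d0 + self.df if np.isfinite(self.d0) else np.inf


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2: pd.Series, df: float) -> ModeratedVariance:
    """Method-of-moments fit of ``s2 ~ s0_sq * F(df, d0)`` across genes.

    Follows the classic empirical-Bayes recipe: on the log scale the sample
    variances have known digamma/trigamma moments given the hyperparameters,
    which yields closed-form estimates up to one trigamma inversion. When
    the excess dispersion of log variances is non-positive the prior
    degrees of freedom are infinite (complete shrinkage). If every variance
    is (numerically) zero, an ordinary floor variance is used and flagged.
    """
    s2v = s2.to_numpy(float)
    positive = s2v > VARIANCE_FLOOR
    if positive.sum() < 2:
        s2_post = pd.Series(np.full(len(s2), VARIANCE_FLOOR), index=s2.index)
        return ModeratedVariance(d0=0.0, s0_sq=VARIANCE_FLOOR,
                                 s2_post=s2_post, df=df, fallback=True)
    if positive.sum() < 50:
        warnings.warn("fewer than 50 positive variances; hyperparameters unstable")

    z = np.log(s2v[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))

    if np.isfinite(d0):
        s2_post_v = (d0 * s0_sq + df * s2v) / (d0 + df)
    else:
        s2_post_v = np.full(len(s2v), s0_sq)
    return ModeratedVariance(d0=float(d0), s0_sq=s0_sq,
                             s2_post=pd.Series(s2_post_v, index=s2.index),
                             df=df)


def moderated_t(
    logfc: np.ndarray, scale: np.ndarray, mv: ModeratedVariance,
    genes: pd.Index | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p values.

    ``scale`` is the contrast variance multiplier (1/n_t + 1/n_c); the
    standard error is ``sqrt(s2_post * scale)``. p values come from the t
    distribution on ``d0 + df`` degrees of freedom (normal when d0 = inf).
    """
    s2_post = mv.s2_post.to_numpy(float) if genes is None \
        else mv.s2_post.loc[genes].to_numpy(float)
    se = np.sqrt(np.maximum(s2_post, VARIANCE_FLOOR) * np.asarray(scale, float))
    t = np.asarray(logfc, float) / se
    if np.isfinite(mv.df_total):
        p = 2.0 * stats.t.sf(np.abs(t), mv.df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    return t, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# result assembly


@dataclass
class SignificantSet:
    """Signed significant-gene set of one experiment."""

    experiment_id: str
    entries: dict            # gene -> +1 / -1
    lfc_threshold: float
    adj_p_threshold: float

    def genes(self) -> set:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def run_de(compendium: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Full DE pass: contrasts, moderation, per-experiment BH adjustment.

    Returns a long DataFrame with one row per (experiment, gene):
    experiment_id, gene, logfc, t, p, adj_p.
    """
    contrasts, s2, df = fit_batch_contrasts(compendium, sheet)
    mv = moderate_variances(s2, df)
    out = []
    for exp_id, grp in contrasts.groupby("experiment_id", sort=False):
        t, p = moderated_t(grp["logfc"].to_numpy(), grp["scale"].to_numpy(),
                           mv, genes=pd.Index(grp["gene"]))
        adj = bh_adjust(p)
        out.append(pd.DataFrame({
            "experiment_id": exp_id,
            "gene": grp["gene"].to_numpy(),
            "logfc": grp["logfc"].to_numpy(),
            "t": t,
            "p": p,
            "adj_p": adj,
        }))
    return pd.concat(out, ignore_index=True)


def significant_set(
    de: pd.DataFrame, experiment_id: str,
    lfc_threshold: float, adj_p_threshold: float,
) -> SignificantSet:
    """Genes with |logfc| strictly above and adj_p strictly below threshold."""
    sub = de[de["experiment_id"] == experiment_id]
    hit = sub[(sub["logfc"].abs() > lfc_threshold)
              & (sub["adj_p"] < adj_p_threshold)]
    entries = {g: int(np.sign(l)) for g, l in zip(hit["gene"], hit["logfc"])}
    return SignificantSet(experiment_id, entries, lfc_threshold, adj_p_threshold)


def all_significant_sets(
    de: pd.DataFrame, lfc_threshold: float, adj_p_threshold: float,
) -> dict[str, SignificantSet]:
    return {
        e: significant_set(de, e, lfc_threshold, adj_p_threshold)
        for e in de["experiment_id"].unique()
    }


def self_knockdown_rank(
    de: pd.DataFrame, experiment_id: str, target_gene: str,
    top_fraction: float = 0.01,
) -> dict | None:
    """Rank of the intended target among genes ordered by ascending logfc.

    Returns None when the target is absent from the matrix (the platform
    did not carry it). ``flag`` is true when the target sits within the top
    ``top_fraction`` of down-regulated genes.
    """
    sub = de[de["experiment_id"] == experiment_id]
    if target_gene not in set(sub["gene"]):
        return None
    order = sub.sort_values("logfc", kind="stable").reset_index(drop=True)
    rank = int(order.index[order["gene"] == target_gene][0]) + 1
    percentile = rank / len(order)
    return {"rank": rank, "percentile": percentile,
            "flag": percentile <= top_fraction}


def shortlist_genes(
    sig_sets: dict[str, SignificantSet], min_experiments: int,
) -> list[str]:
    """Genes significant (any direction) in at least ``min_experiments``."""
    counts: dict[str, int] = {}
    for ss in sig_sets.values():
        for g in ss.entries:
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= min_experiments)


def logfc_matrix(de: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Wide gene x experiment logFC matrix from the long DE table."""
    wide = de.pivot(index="gene", columns="experiment_id", values="logfc")
    if genes is not None:
        wide = wide.loc[list(genes)]
    return wide
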