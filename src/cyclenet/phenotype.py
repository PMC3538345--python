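"""Expression-phenotype correlation under a batch-restricted permutation
null, and the transcription / cell-cycle uncoupling analysis.

The correlation step ranks every gene's logFC profile against each FACS
phenotype (Spearman). Significance is calibrated by permuting the phenotype
records among experiments *within each transfection batch* (the whole
record moves as a unit, preserving cross-phenotype structure), and the
passing cutoff is chosen so that fewer than one gene per phenotype is
expected to pass by chance -- a family-level criterion implemented through
the pooled permutation distribution.

The uncoupling analysis summarises each knockdown by the Manhattan norm of
its logFC profile over the clustering shortlist and relates it to the
G1-fraction shift; knockdowns with a top-decile G1 shift but a small
significant set are flagged as transcriptionally uncoupled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .diffexpr import SignificantSet

G1_RESTRICTED_PHENOTYPES = ("g1_frac", "g1_size", "g2_size")
PHENOTYPE_COLUMNS = ("g1_frac", "s_frac", "g2_frac", "g1_size", "g2_size")


def delta_g1(pheno: pd.DataFrame) -> pd.Series:
    """Per-experiment G1-fraction change versus in-batch control mean."""
    ctrl = pheno[pheno["is_control"]].groupby("batch")["g1_frac"].mean()
    exp = pheno[~pheno["is_control"]]
    base = exp["batch"].map(ctrl)
    if base.isna().any():
        missing = sorted(exp.loc[base.isna(), "batch"].unique())
        raise ValueError(f"batches without control phenotype records: {missing}")
    return pd.Series((exp["g1_frac"] - base).to_numpy(),
                     index=exp["experiment_id"].to_numpy())


def spearman_phenotype_correlation(
    logfc: pd.DataFrame, phenotype: pd.Series, experiments=None,
    min_experiments: int = 5,
) -> pd.Series:
    """Spearman rho of each gene's logFC profile against one phenotype.

    ``experiments`` optionally restricts the columns (e.g. to knockdowns
    with increased G1); fewer than ``min_experiments`` remaining is an
    error. Constant vectors yield NaN.
    """
    if experiments is not None:
        experiments = [e for e in experiments if e in logfc.columns]
        logfc = logfc[experiments]
        phenotype = phenotype.loc[experiments]
    else:
        phenotype = phenotype.loc[logfc.columns]
    if logfc.shape[1] < min_experiments:
        raise ValueError(
            f"only {logfc.shape[1]} experiments after restriction "
            f"(need >= {min_experiments})"
        )
    ranks = _rank_rows(logfc.to_numpy(float))
    y = _rank_rows(phenotype.to_numpy(float)[None, :])[0]
    rho = _pearson_rows(ranks, y)
    return pd.Series(rho, index=logfc.index, name="rho")


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1, method="average")


def _pearson_rows(xr: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of rank matrices (NaN when degenerate)."""
    xc = xr - xr.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (xc @ yc) / denom
    rho[denom == 0] = np.nan
    return rho


@dataclass
class CorrelationResult:
    phenotype: str
    rho: pd.Series               # observed rho per gene
    empirical_p: pd.Series       # per-gene add-one permutation p
    familywise_p: pd.Series      # p against the max-|rho| null
    cutoff_rho: float            # pass iff |rho| > cutoff_rho
    passed: pd.Series
    n_experiments: int
    n_permutations: int
    null_mean_passing: float = float("nan")  # mean permuted genes above cutoff

    def hits(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "gene": self.rho.index,
            "phenotype": self.phenotype,
            "rho": self.rho.to_numpy(),
            "empirical_p": self.empirical_p.to_numpy(),
            "familywise_p": self.familywise_p.to_numpy(),
            "passed": self.passed.to_numpy(),
        })
        return out


def batch_permutation_cutoff(
    logfc: pd.DataFrame,
    phenotype: pd.Series,
    batches: pd.Series,
    n_permutations: int,
    seed: int,
    phenotype_name: str = "phenotype",
    min_experiments: int = 5,
) -> CorrelationResult:
    """Permutation-calibrated correlation significance for one phenotype.

    Phenotype values are shuffled among experiments within each batch;
    batches of size 1 stay fixed (with a warning upstream). The passing
    cutoff is the B-th largest pooled permutation |rho| (B = number of
    permutations): above it the expected number of passing genes per
    permutation is below one. Per-gene empirical p values use add-one
    smoothing; family-wise p values compare against the per-permutation
    max |rho|.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    experiments = list(logfc.columns)
    if len(experiments) < min_experiments:
        raise ValueError("too few experiments for correlation analysis")
    phenotype = phenotype.loc[experiments]
    batches = batches.loc[experiments]

    ranks = _rank_rows(logfc.to_numpy(float))
    y = phenotype.to_numpy(float)
    rho_obs = _pearson_rows(ranks, _rank_rows(y[None, :])[0])
    rho_obs = pd.Series(rho_obs, index=logfc.index)

    rng = np.random.default_rng(seed)
    batch_groups = [np.flatnonzero(batches.to_numpy() == b)
                    for b in pd.unique(batches)]
    n_genes = len(logfc.index)
    abs_obs = np.abs(rho_obs.to_numpy())
    exceed = np.zeros(n_genes)          # per-gene count of |rho_perm| >= |rho_obs|
    fw_exceed = np.zeros(n_genes)       # count of max-|rho_perm| >= |rho_obs|
    pooled = np.empty((n_permutations, n_genes))
    for b in range(n_permutations):
        perm = np.arange(len(y))
        for idx in batch_groups:
            if len(idx) > 1:
                perm[idx] = idx[rng.permutation(len(idx))]
        y_perm = y[perm]
        rho_perm = np.abs(_pearson_rows(ranks, _rank_rows(y_perm[None, :])[0]))
        rho_perm = np.nan_to_num(rho_perm)
        pooled[b] = rho_perm
        exceed += rho_perm >= abs_obs
        fw_exceed += rho_perm.max() >= abs_obs

    empirical_p = pd.Series((1.0 + exceed) / (n_permutations + 1.0),
                            index=logfc.index)
    familywise_p = pd.Series((1.0 + fw_exceed) / (n_permutations + 1.0),
                             index=logfc.index)
    flat = np.sort(pooled.ravel())
    # mean passing genes per permutation < 1  <=>  fewer than B pooled
    # permutation values at or above the cutoff
    cutoff = float(flat[-n_permutations])
    passed = pd.Series(np.abs(rho_obs.to_numpy()) > cutoff, index=logfc.index)
    null_mean = float((pooled > cutoff).sum() / n_permutations)
    return CorrelationResult(
        phenotype=phenotype_name, rho=rho_obs, empirical_p=empirical_p,
        familywise_p=familywise_p, cutoff_rho=cutoff, passed=passed,
        n_experiments=len(experiments), n_permutations=n_permutations,
        null_mean_passing=null_mean,
    )


def correlate_phenotypes(
    logfc: pd.DataFrame,
    pheno: pd.DataFrame,
    config: AnalysisConfig,
    seed: int | None = None,
    phenotypes=PHENOTYPE_COLUMNS,
) -> dict[str, CorrelationResult]:
    """Run the permutation-calibrated correlation for every phenotype.

    For the G1-fraction and cell-size phenotypes, only experiments whose G1
    fraction increased versus their batch controls are analysed (a G1
    decrease commonly reflects death or polyploidy); the restriction is
    applied before permuting so each batch's phenotype multiset within the
    analysed subset is preserved exactly.
    """
    if seed is None:
        seed = config.rng_seed
    dg1 = delta_g1(pheno)
    exp_rows = pheno[~pheno["is_control"]].set_index("experiment_id")
    results = {}
    for i, name in enumerate(phenotypes):
        if name in G1_RESTRICTED_PHENOTYPES:
            keep = [e for e in logfc.columns if dg1.get(e, 0.0) > 0]
        else:
            keep = list(logfc.columns)
        sub = logfc[keep]
        results[name] = batch_permutation_cutoff(
            sub, exp_rows.loc[keep, name], exp_rows.loc[keep, "batch"],
            config.n_permutations, seed + i, phenotype_name=name,
        )
    return results


# ---------------------------------------------------------------------------
# uncoupling analysis


@dataclass
class UncouplingResult:
    records: pd.DataFrame        # per experiment
    pearson_r: float
    g1_threshold: float

    def flagged(self) -> list[str]:
        return self.records.loc[self.records["uncoupled_flag"],
                                "experiment_id"].tolist()


def uncoupling_metrics(
    de: pd.DataFrame,
    sig_sets: dict[str, SignificantSet],
    pheno: pd.DataFrame,
    shortlist: list[str],
    config: AnalysisConfig,
) -> UncouplingResult:
    """Total transcriptional effect versus G1 shift for every knockdown.

    ``total_effect`` is the Manhattan norm of the experiment's logFC profile
    restricted to the clustering shortlist (the GFP control profile is zero
    by construction of the contrasts). An experiment is flagged uncoupled
    when its G1 shift reaches the top decile of positive shifts while its
    overlap-regime significant set stays at or below the configured cap.
    """
    if not shortlist:
        raise ValueError("empty shortlist")
    short = set(shortlist)
    sub = de[de["gene"].isin(short)]
    total = sub.groupby("experiment_id")["logfc"].apply(lambda v: float(np.abs(v).sum()))
    dg1 = delta_g1(pheno)
    experiments = [e for e in total.index if e in dg1.index]
    records = pd.DataFrame({
        "experiment_id": experiments,
        "total_effect": [total[e] for e in experiments],
        "delta_g1": [dg1[e] for e in experiments],
        "n_significant": [len(sig_sets[e]) for e in experiments],
    })
    positive = records.loc[records["delta_g1"] > 0, "delta_g1"]
    g1_threshold = float(positive.quantile(0.9)) if len(positive) else np.inf
    records["uncoupled_flag"] = (
        (records["delta_g1"] >= g1_threshold)
        & (records["n_significant"] <= config.uncoupled_max_sig_genes)
    )
    r = float(stats.pearsonr(records["delta_g1"], records["total_effect"])[0]) \
        if len(records) > 2 else np.nan
    return UncouplingResult(records=records, pearson_r=r,
                            g1_threshold=g1_threshold)


def set_sharing_fraction(set_a: SignificantSet, set_b: SignificantSet) -> float:
    """Fraction of A's significant genes also significant in B."""
    a, b = set_a.genes(), set_b.genes()
    if not a:
        raise ValueError("set A is empty")
    return len(a & b) / len(a)
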