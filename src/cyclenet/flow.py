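"""Per-cell quantification of unphosphorylated Cdk1 versus cell size.

The chain is: normalise the two antibody channels to unit median over the
gated population, gate G2 cells on DNA content (around twice the G1 peak
mode), form the per-cell unphosphorylated signal as normalised total minus
normalised phospho, bin the G2 cells by FSC-A, and compare every bin's
per-cell values against a designated centre bin with two-sample
Kolmogorov-Smirnov tests. Because both channels are rescaled by their own
medians, the whole chain is invariant to multiplying any raw channel by a
positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .config import AnalysisConfig


def normalize_channels(
    events: pd.DataFrame, method: str = "median",
) -> tuple[pd.DataFrame, dict]:
    """Add ``ch_total_norm`` / ``ch_phospho_norm`` columns.

    Default is unit-median scaling (robust to the long right tails of
    antibody channels); ``method="zscore"`` standardises instead. The
    normalisation constants are returned for logging.
    """
    if len(events) < 100:
        raise ValueError("need >= 100 events for stable normalisation")
    out = events.copy()
    constants = {}
    for ch in ("ch_total", "ch_phospho"):
        x = events[ch].to_numpy(float)
        if method == "median":
            m = float(np.median(x))
            if m <= 0:
                raise ValueError(f"{ch}: non-positive median, cannot scale")
            out[ch + "_norm"] = x / m
            constants[ch] = {"median": m}
        elif method == "zscore":
            mu, sd = float(x.mean()), float(x.std())
            if sd <= 0:
                raise ValueError(f"{ch}: zero spread, cannot standardise")
            out[ch + "_norm"] = (x - mu) / sd
            constants[ch] = {"mean": mu, "sd": sd}
        else:
            raise ValueError(f"unknown normalisation method {method!r}")
    return out, constants


def find_g1_peak(dna: np.ndarray, n_bins: int = 128) -> float:
    """Mode of the G1 peak of a bimodal DNA-content distribution.

    Histogram between the 1st and 99th percentiles, light smoothing, then
    peak detection. The lowest prominent peak is taken as G1; a second peak
    near twice its position must exist, otherwise the distribution is not
    recognisably bimodal and gating should be done manually.
    """
    dna = np.asarray(dna, float)
    lo, hi = np.percentile(dna, [1, 99])
    hist, edges = np.histogram(dna, bins=n_bins, range=(lo, hi))
    smooth = ndimage.gaussian_filter1d(hist.astype(float), sigma=2.0)
    peaks, props = signal.find_peaks(smooth, prominence=0.05 * smooth.max())
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(peaks) < 2:
        raise ValueError(
            "DNA distribution not bimodal; supply manual G2 gate bounds"
        )
    g1 = centers[peaks[0]]
    doubled = centers[peaks] / g1
    if not ((doubled > 1.6) & (doubled < 2.4)).any():
        raise ValueError(
            "no G2 peak near twice the G1 mode; supply manual gate bounds"
        )
    return float(g1)


def gate_g2(
    events: pd.DataFrame,
    config: AnalysisConfig | None = None,
    manual_bounds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Select G2 cells by DNA content.

    The gate is ``dna in [lo * m, hi * m]`` where ``m`` is the detected G1
    peak mode and (lo, hi) come from ``config.g2_gate``; ``manual_bounds``
    overrides the automatic gate entirely.
    """
    config = config or AnalysisConfig()
    dna = events["dna"].to_numpy(float)
    if manual_bounds is not None:
        lo, hi = manual_bounds
    else:
        m = find_g1_peak(dna)
        lo, hi = config.g2_gate[0] * m, config.g2_gate[1] * m
    mask = (dna >= lo) & (dna <= hi)
    return events[mask].copy(), (float(lo), float(hi))


def unphospho_per_cell(events: pd.DataFrame) -> pd.Series:
    """Normalised total minus normalised phospho signal, per cell.

    Negative values are retained: clipping would bias the small-cell bins
    toward zero.
    """
    for col in ("ch_total_norm", "ch_phospho_norm"):
        if col not in events.columns:
            raise ValueError("run normalize_channels first")
    return events["ch_total_norm"] - events["ch_phospho_norm"]


def bin_by_size(
    events: pd.DataFrame, n_bins: int, scheme: str = "quantile",
) -> pd.Series:
    """Assign each cell to an FSC-A size bin (1-based, ordered by size).

    ``quantile`` (default) gives near-equal cell counts per bin;
    ``equal_width`` uses equal FSC-A ranges between the 1st and 99th
    percentiles (cells outside are clipped into the edge bins). Boundaries
    are half-open with the rightmost bin closed.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    fsc = events["fsc_a"].to_numpy(float)
    if len(fsc) < n_bins:
        raise ValueError("fewer cells than bins")
    if scheme == "quantile":
        edges = np.quantile(fsc, np.linspace(0, 1, n_bins + 1))
    elif scheme == "equal_width":
        lo, hi = np.percentile(fsc, [1, 99])
        edges = np.linspace(lo, hi, n_bins + 1)
        fsc = np.clip(fsc, lo, hi)
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    idx = np.searchsorted(edges, fsc, side="right")
    idx = np.clip(idx, 1, n_bins)
    return pd.Series(idx, index=events.index, name="size_bin")


@dataclass
class G2BinProfile:
    """Summary of one size bin: mean unphospho signal, SE, KS versus centre."""

    bin_index: int
    fsc_lo: float
    fsc_hi: float
    n: int
    mean_u: float
    se: float
    ks_p: float
    significant: bool
    stable: bool


def bin_summary_and_ks(
    u: pd.Series, bins: pd.Series, fsc: pd.Series,
    center_bin: int, ks_alpha: float = 0.01, min_cells: int = 20,
) -> pd.DataFrame:
    """Per-bin mean/SE of the unphospho signal and KS tests versus the
    centre bin.

    The centre bin's own p is 1 by definition. The exact two-sample KS
    distribution is used when both bins hold fewer than 50 cells, the
    asymptotic one otherwise. Bins below ``min_cells`` are flagged
    unstable; empty bins produce NA rows with a warning.
    """
    n_bins = int(bins.max())
    center_u = u[bins == center_bin].to_numpy(float)
    if len(center_u) == 0:
        raise ValueError(f"centre bin {center_bin} is empty")
    rows = []
    for b in range(1, n_bins + 1):
        ub = u[bins == b].to_numpy(float)
        fb = fsc[bins == b].to_numpy(float)
        if len(ub) == 0:
            warnings.warn(f"size bin {b} is empty")
            rows.append(G2BinProfile(b, np.nan, np.nan, 0, np.nan, np.nan,
                                     np.nan, False, False))
            continue
        if b == center_bin:
            p = 1.0
        else:
            method = "exact" if (len(ub) < 50 and len(center_u) < 50) else "asymp"
            p = float(stats.ks_2samp(ub, center_u, method=method).pvalue)
        rows.append(G2BinProfile(
            bin_index=b,
            fsc_lo=float(fb.min()),
            fsc_hi=float(fb.max()),
            n=len(ub),
            mean_u=float(ub.mean()),
            se=float(ub.std(ddof=1) / np.sqrt(len(ub))) if len(ub) > 1 else np.nan,
            ks_p=p,
            significant=bool(p < ks_alpha) and b != center_bin,
            stable=len(ub) >= min_cells,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


def run_flow(
    events: pd.DataFrame, config: AnalysisConfig | None = None,
    scheme: str = "quantile",
    manual_bounds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full chain: normalise, gate G2, subtract, bin, summarise with KS.

    Returns the per-bin profile table and a provenance dict (normalisation
    constants and gate bounds).
    """
    config = config or AnalysisConfig()
    gated, gate = gate_g2(events, config, manual_bounds=manual_bounds)
    # channel medians are taken over the gated population
    g2, constants = normalize_channels(gated)
    u = unphospho_per_cell(g2)
    bins = bin_by_size(g2, config.n_size_bins, scheme=scheme)
    profile = bin_summary_and_ks(
        u, bins, g2["fsc_a"], config.center_bin,
        ks_alpha=config.ks_alpha, min_cells=config.min_cells_per_bin,
    )
    return profile, {"normalisation": constants, "g2_gate": gate}
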