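"""Run configuration for the compendium analysis.

Every printed constant of the analysis lives here with its default, so that
no stage hard-codes a threshold: the 0.5-log2 clustering shortlist regime,
the 0.3-log2 overlap regime, the BH-adjusted P cutoff, the five-experiment
recurrence rule, the network degree-pruning rule, the COSA scale factor,
the TSS window, and the flow-cytometry binning layout.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Declarative configuration shared by all pipeline stages.

    Parameters
    ----------
    lfc_threshold_cluster : float
        Absolute log2 fold-change threshold (strict ``>``) for the
        clustering shortlist regime. Default 0.5.
    lfc_threshold_overlap : float
        Absolute log2 fold-change threshold (strict ``>``) for the
        per-experiment significant sets used in the overlap network and
        the uncoupling analysis. Default 0.3.
    adj_p_threshold : float
        Benjamini-Hochberg adjusted P threshold (strict ``<``), shared by
        both regimes and by the ChIP peak-significance rule. Default 0.01.
    min_experiments : int
        A gene enters the shortlist / overlap universe when significant in
        at least this many experiments. Default 5.
    min_sig_genes_percent_overlap : int
        Minimum significant-set size for an experiment to enter the
        percent-overlap clustering. Default 50.
    min_node_degree : int
        Nodes with fewer adjacent edges are (iteratively) pruned from the
        overlap network. Default 5.
    cosa_lambda : float
        Scale factor of the attribute-weighted (COSA-style) clustering.
        Default 0.6.
    tss_window : int
        Half-width in bp of the symmetric window around a TSS used to call
        direct ChIP targets: ``[TSS - w, TSS + w)``. Default 2000.
    n_size_bins : int
        Number of cell-size (FSC-A) bins for the G2 flow analysis.
        Default 12 (the 8-bin layout is the S2-style alternative).
    center_bin : int
        1-based index of the reference bin for the per-bin KS tests.
        Default 7 (4 for the 8-bin layout).
    ks_alpha : float
        Significance level for the per-bin KS tests. Default 0.01.
    n_permutations : int
        Number of batch-restricted phenotype permutations. Default 1000.
    uncoupled_max_sig_genes : int
        An experiment can only be flagged as transcriptionally uncoupled
        when its significant set (overlap regime) is at most this large.
        Default 100.
    g2_gate : tuple of float
        G2 DNA-content gate as multiples of the G1 peak mode.
    min_cells_per_bin : int
        Below this count a flow bin is flagged unstable.
    rng_seed : int
        Seed for every stochastic stage.
    """

    lfc_threshold_cluster: float = 0.5
    lfc_threshold_overlap: float = 0.3
    adj_p_threshold: float = 0.01
    min_experiments: int = 5
    min_sig_genes_percent_overlap: int = 50
    min_node_degree: int = 5
    cosa_lambda: float = 0.6
    tss_window: int = 2000
    n_size_bins: int = 12
    center_bin: int = 7
    ks_alpha: float = 0.01
    n_permutations: int = 1000
    uncoupled_max_sig_genes: int = 100
    g2_gate: tuple = (1.8, 2.2)
    min_cells_per_bin: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.lfc_threshold_cluster <= 0 or self.lfc_threshold_overlap <= 0:
            raise ValueError("log fold-change thresholds must be > 0")
        for name in ("adj_p_threshold", "ks_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.min_experiments < 1:
            raise ValueError("min_experiments must be >= 1")
        if self.tss_window <= 0:
            raise ValueError("tss_window must be > 0")
        if not 1 <= self.center_bin <= self.n_size_bins:
            raise ValueError(
                f"center_bin {self.center_bin} outside 1..{self.n_size_bins}"
            )
        if self.cosa_lambda <= 0:
            raise ValueError("cosa_lambda must be > 0")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        lo, hi = self.g2_gate
        if not 1.0 < lo < hi:
            raise ValueError("g2_gate must satisfy 1 < lo < hi")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["g2_gate"] = list(self.g2_gate)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "g2_gate" in d:
            d = dict(d, g2_gate=tuple(d["g2_gate"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
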