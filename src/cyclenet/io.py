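"""Readers and writers for every external format the pipeline touches.

Expression matrices and sample sheets are plain TSV; genomic peak intervals
are BED4+/BED5 (0-based, half-open); per-cell flow events are CSV; networks
are exchanged as GraphML. All numeric round trips are lossless: floats are
written with full shortest-repr precision.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

CONTROL_TARGET = "NONE"

SAMPLE_SHEET_COLUMNS = ["sample_id", "batch", "target_gene", "is_control"]
FLOW_COLUMNS = ["event_id", "dna", "fsc_a", "ch_total", "ch_phospho"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample log2 expression matrix from TSV.

    First column holds gene ids, the header row sample ids. Duplicated ids,
    missing cells and non-numeric body cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated gene ids: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicated sample ids: {dup}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in expression matrix: {exc}") from exc
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise FormatError(f"missing values in columns {bad}")
    return df


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# sample sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    sheet = sheet.copy()
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    sheet["batch"] = sheet["batch"].astype(str)
    sheet["is_control"] = sheet["is_control"].astype(bool)
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicated sample ids: {dup}")
    for batch, grp in sheet.groupby("batch"):
        if not grp["is_control"].any():
            raise FormatError(f"batch {batch!r} has no control sample")
    bad = sheet[~sheet["is_control"] & (
        sheet["target_gene"].isna() | (sheet["target_gene"] == CONTROL_TARGET)
    )]
    if len(bad):
        raise FormatError(
            f"non-control samples without target gene: {bad['sample_id'].tolist()}"
        )
    sheet.loc[sheet["is_control"], "target_gene"] = CONTROL_TARGET
    if "experiment_id" not in sheet.columns:
        # replicates of the same knockdown share an experiment id
        sheet["experiment_id"] = np.where(
            sheet["is_control"],
            "GFP_" + sheet["batch"],
            "kd_" + sheet["target_gene"].astype(str),
        )
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if "is_control" in sheet.columns:
        sheet["is_control"] = sheet["is_control"].astype(str).str.lower().isin(
            {"1", "true", "yes"}
        )
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    out = sheet.copy()
    out["is_control"] = out["is_control"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def align(matrix: pd.DataFrame, sheet: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join matrix columns with sample-sheet rows, failing loudly on mismatch."""
    mat_ids = set(matrix.columns)
    sheet_ids = set(sheet["sample_id"])
    only_mat = sorted(mat_ids - sheet_ids)
    only_sheet = sorted(sheet_ids - mat_ids)
    if only_mat or only_sheet:
        raise FormatError(
            "sample ids do not match between matrix and sheet; "
            f"matrix-only: {only_mat[:10]}, sheet-only: {only_sheet[:10]}"
        )
    sheet = sheet.set_index("sample_id", drop=False).loc[list(matrix.columns)]
    return matrix, sheet.reset_index(drop=True)


# ---------------------------------------------------------------------------
# genomic intervals


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """Read BED4+/BED5 peak intervals (0-based half-open).

    Column five, when present, is interpreted as the peak's significance
    (P value) and retained; otherwise P defaults to 0 (always significant).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: malformed coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"line {lineno}: start {start} >= end {end} (half-open BED)"
                )
            name = parts[3] if len(parts) > 3 else f"peak{lineno}"
            if len(parts) > 4:
                try:
                    p = float(parts[4])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: malformed score field") from exc
            else:
                p = 0.0
            rows.append((chrom, start, end, name, p))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "p"])


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a gene -> (chrom, position, strand) TSS table (0-based positions)."""
    tss = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "pos"}
    missing = required - set(tss.columns)
    if missing:
        raise FormatError(f"TSS table missing columns: {sorted(missing)}")
    if "strand" not in tss.columns:
        tss["strand"] = "+"
    tss["pos"] = tss["pos"].astype(int)
    if tss["gene"].duplicated().any():
        raise FormatError("duplicated gene ids in TSS table")
    return tss


# ---------------------------------------------------------------------------
# phenotypes and flow events


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t")
    required = {"experiment_id", "batch", "g1_frac", "s_frac", "g2_frac",
                "g1_size", "g2_size"}
    missing = required - set(pheno.columns)
    if missing:
        raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
    fracs = pheno[["g1_frac", "s_frac", "g2_frac"]].to_numpy(float)
    if (fracs < 0).any() or (fracs > 1).any():
        raise FormatError("phase fractions outside [0, 1]")
    if np.abs(fracs.sum(axis=1) - 1.0).max() > 0.01:
        raise FormatError("phase fractions do not sum to 1 (tolerance 0.01)")
    if (pheno[["g1_size", "g2_size"]].to_numpy(float) <= 0).any():
        raise FormatError("cell sizes must be positive")
    return pheno


def write_phenotype_table(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_flow_events(path: str | Path) -> pd.DataFrame:
    """Read a per-cell flow event table from CSV.

    Expected columns: event_id, dna, fsc_a, ch_total, ch_phospho.
    """
    events = pd.read_csv(path)
    missing = [c for c in FLOW_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"flow event table missing columns: {missing}")
    body = events[["dna", "fsc_a", "ch_total", "ch_phospho"]].to_numpy(float)
    if not np.isfinite(body).all():
        raise FormatError("non-finite values in flow event table")
    if (events["dna"].to_numpy(float) <= 0).any():
        raise FormatError("DNA-content signal must be positive")
    return events


def write_flow_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network exchange (GraphML)


def write_network_graphml(net, path: str | Path) -> None:
    """Serialise an :class:`~cyclenet.overlap.OverlapNetwork` as GraphML.

    Node attributes: degree, n_significant_genes. Edge attributes: sign,
    weight, observed, expected, tie. Only pruned networks are exported.
    """
    if not net.pruned:
        raise ValueError("refusing to export an unpruned overlap network")
    g = nx.Graph()
    g.graph["universe_size"] = int(net.universe_size)
    for node, attrs in net.graph.nodes(data=True):
        g.add_node(
            node,
            degree=int(net.graph.degree[node]),
            n_significant_genes=int(attrs.get("n_significant_genes", 0)),
        )
    for a, b, attrs in net.graph.edges(data=True):
        g.add_edge(
            a, b,
            sign=int(attrs["sign"]),
            weight=float(attrs["weight"]),
            observed=int(attrs["observed"]),
            expected=float(attrs["expected"]),
            tie=bool(attrs.get("tie", False)),
        )
    nx.write_graphml(g, path)


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_edge_list(net, path: str | Path) -> None:
    rows = [
        (a, b, attrs["sign"], attrs["observed"], attrs["expected"], attrs["weight"])
        for a, b, attrs in net.graph.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["experiment_a", "experiment_b", "sign", "observed",
                       "expected", "weight"]
    ).to_csv(path, sep="\t", index=False)
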