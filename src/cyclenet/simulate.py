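"""Synthetic multi-batch RNAi knockdown compendium with recorded ground truth.

The generator emulates the statistical structure the analysis assumes:

* several transfection batches, each with four GFP control samples and a
  mix of quadruplicate (module-class) and singlicate (generic) knockdowns;
* strong self-knockdown of every intended target (default -2 log2);
* a proteasome-like module whose members are mutually up-regulated when any
  one of them is knocked down;
* a ribosome-biogenesis module driven in opposite directions by two
  perturbation classes (translation-initiation knockdowns push it up, Myc-
  like knockdowns push it down) -- the feedback-circuit motif;
* a shared signed "arrest program" of cell-cycle genes regulated by every
  coupled generic knockdown, with a strong and a weak phenotype class;
* additive per-(gene, batch) offsets and iid Gaussian noise on the log2
  scale;
* FACS phenotypes coupled to the planted transcriptional magnitude, plus a
  set of deliberately uncoupled knockdowns (strong G1 shift, smaller cells,
  no planted non-self expression effect);
* per-cell flow events in which the unphosphorylated-Cdk1 amount rises
  super-linearly with cell size through a saturating surface-to-volume
  phosphorylation model.

Everything planted is recorded in :class:`SimTruth` so downstream recovery
tests can compare against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTROL_TARGET, validate_sample_sheet

# experiment class labels
CLASS_PROTEASOME = "proteasome"
CLASS_EIF = "eif"
CLASS_MYC = "myc"
CLASS_GENERIC_STRONG = "generic_strong"
CLASS_GENERIC_WEAK = "generic_weak"
CLASS_UNCOUPLED = "uncoupled"

MODULE_CLASSES = (CLASS_PROTEASOME, CLASS_EIF, CLASS_MYC)


@dataclass
class SimParams:
    """Generator settings.

    The defaults define the reference study conditions: 2000 genes, 6
    batches, 12 experiments per batch (72 experiments total), four GFP
    controls per batch, self effect -2 log2, module effect +/-1 log2,
    noise sd 0.3 log2. Module-class knockdowns (proteasome / eIF / Myc)
    are quadruplicate, all others singlicate.

    ``phenotype_alpha`` converts the Manhattan norm of a planted profile to
    a G1-fraction increase; ``phenotype_noise_sd`` is the FACS measurement
    noise on phase fractions. :meth:`fig5b_regime` returns a copy with the
    larger biological scatter under which the expression-phenotype
    correlation sits near r = 0.5.
    """

    n_genes: int = 2000
    n_batches: int = 6
    experiments_per_batch: int = 12
    n_controls_per_batch: int = 4
    module_class_replicates: int = 4

    # planted structure
    n_module_genes: int = 40         # per coexpression module
    n_program_genes: int = 350       # shared arrest program (signed, up-heavy)
    program_up_fraction: float = 0.9
    n_proteasome_kd: int = 6
    n_eif_kd: int = 4
    n_myc_kd: int = 4
    n_uncoupled: int = 4

    self_effect: float = -2.0
    module_effect: float = 1.0
    program_amp_low: float = 0.6     # per-gene arrest-program amplitude range
    program_amp_high: float = 1.6
    proteasome_program_scale: float = 0.8
    weak_gamma: float = 0.4
    strong_gamma: float = 1.0

    # noise model
    noise_sd: float = 0.3
    batch_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    # phenotype link
    phenotype_coupling: float = 1.0  # 0 -> null (no expression-phenotype link)
    phenotype_alpha: float = 3.4e-4
    phenotype_noise_sd: float = 0.01         # biological scatter, experiments
    control_phenotype_noise_sd: float = 0.01  # measurement noise, GFP controls
    size_noise_sd: float = 0.01
    uncoupled_delta_g1: float = 0.2
    uncoupled_size_drop: float = -0.10
    baseline_g1: float = 0.5
    baseline_s: float = 0.2
    baseline_g2: float = 0.3
    baseline_g1_size: float = 100.0
    baseline_g2_size: float = 130.0

    # optional directly phenotype-linked genes (for correlation power tests)
    n_correlated_genes: int = 0
    correlated_rho: float = 0.9

    # flow phosphorylation model
    flow_k_surface: float = 3.0
    flow_k_nuclear: float = 0.5
    flow_size_midpoint: float | None = None  # None -> median G2 FSC-A

    def __post_init__(self) -> None:
        n_experiments = self.n_batches * self.experiments_per_batch
        n_special = (self.n_proteasome_kd + self.n_eif_kd + self.n_myc_kd
                     + self.n_uncoupled)
        if n_experiments < n_special:
            raise ValueError("not enough experiments for the planted classes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.self_effect >= 0:
            raise ValueError("self_effect must be negative (knockdown)")
        n_planted = 2 * self.n_module_genes + self.n_program_genes
        if self.n_genes < max(10 * 4, n_planted + n_experiments):
            raise ValueError("n_genes too small for the planted structure")
        if not 0.0 < self.program_up_fraction < 1.0:
            raise ValueError("program_up_fraction must lie in (0, 1)")

    def fig5b_regime(self) -> "SimParams":
        """Copy with the biological phenotype scatter of the r~0.5 regime."""
        import dataclasses
        return dataclasses.replace(self, phenotype_noise_sd=0.075)

    def null_regime(self) -> "SimParams":
        """Copy with no expression-phenotype link and no uncoupled set."""
        import dataclasses
        return dataclasses.replace(self, phenotype_coupling=0.0, n_uncoupled=0)


@dataclass
class SimTruth:
    """Ground-truth record of everything the generator planted."""

    module_assignments: dict            # gene -> module id
    module_effects: dict                # module id -> {experiment class: effect}
    planted_effects: pd.DataFrame       # genes x experiments, log2
    self_effect: float
    noise_sd: float
    batch_offsets: pd.DataFrame         # genes x batches, log2
    experiment_classes: dict            # experiment id -> class label
    uncoupled_experiments: set
    phenotype_links: dict               # experiment id -> (delta_g1, delta_size)
    correlated_genes: list
    flow_model_params: dict
    params: SimParams

    def planted_significant_set(self, experiment_id: str, lfc_threshold: float) -> dict:
        """Signed planted set {gene: +/-1} above a |log2| threshold."""
        col = self.planted_effects[experiment_id]
        hit = col[col.abs() > lfc_threshold]
        return {g: int(np.sign(v)) for g, v in hit.items()}

    def module_labels(self, genes) -> pd.Series:
        return pd.Series({g: self.module_assignments.get(g, "none") for g in genes})


# ---------------------------------------------------------------------------


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _build_roster(params: SimParams) -> pd.DataFrame:
    """Assign targets, classes, gammas and replication to every experiment."""
    genes = _gene_ids(params.n_genes)
    nm, npr = params.n_module_genes, params.n_program_genes
    n_up = int(round(npr * params.program_up_fraction))
    proteasome = genes[:nm]
    ribosome = genes[nm:2 * nm]
    program_up = genes[2 * nm:2 * nm + n_up]
    program_down = genes[2 * nm + n_up:2 * nm + npr]
    cursor = 2 * nm + npr

    def take(k):
        nonlocal cursor
        out = genes[cursor:cursor + k]
        cursor += k
        return out

    rows = []
    for t in proteasome[: params.n_proteasome_kd]:
        rows.append((t, CLASS_PROTEASOME, params.strong_gamma))
    for t in take(params.n_eif_kd):
        rows.append((t, CLASS_EIF, params.strong_gamma))
    for t in take(params.n_myc_kd):
        rows.append((t, CLASS_MYC, params.strong_gamma))
    for t in take(params.n_uncoupled):
        rows.append((t, CLASS_UNCOUPLED, 0.0))
    n_generic = params.n_batches * params.experiments_per_batch - len(rows)
    generic_targets = take(n_generic)
    for i, t in enumerate(generic_targets):
        if i % 2 == 0:
            rows.append((t, CLASS_GENERIC_STRONG, params.strong_gamma))
        else:
            rows.append((t, CLASS_GENERIC_WEAK, params.weak_gamma))

    roster = pd.DataFrame(rows, columns=["target", "class", "gamma"])
    roster["experiment_id"] = "kd_" + roster["target"]
    # deal classes round-robin across batches so every batch mixes classes
    roster["batch"] = [
        f"b{i % params.n_batches + 1}" for i in range(len(roster))
    ]
    roster["replicates"] = np.where(
        roster["class"].isin(MODULE_CLASSES), params.module_class_replicates, 1
    )
    roster.attrs["modules"] = {
        "proteasome": proteasome,
        "ribosome": ribosome,
        "program_up": program_up,
        "program_down": program_down,
    }
    return roster


def _planted_profile(roster_row, modules, params: SimParams, gene_index,
                     program_amplitudes: dict) -> np.ndarray:
    """Planted log2 effect vector for one experiment.

    The arrest program is a fixed signed response: gene g moves by
    ``direction(g) * amplitude(g) * gamma(experiment)`` whenever a coupled
    generic or proteasome knockdown is applied (proteasome knockdowns drive
    the program at a reduced scale on top of the mutual module
    up-regulation).
    """
    eff = np.zeros(len(gene_index))
    loc = {g: i for i, g in enumerate(gene_index)}
    cls = roster_row["class"]
    target = roster_row["target"]
    gamma = roster_row["gamma"]

    def add(genes, value):
        for g in genes:
            eff[loc[g]] += value

    def add_program(scale):
        for g in modules["program_up"]:
            eff[loc[g]] += program_amplitudes[g] * scale
        for g in modules["program_down"]:
            eff[loc[g]] -= program_amplitudes[g] * scale

    if cls == CLASS_PROTEASOME:
        add([g for g in modules["proteasome"] if g != target], params.module_effect)
        add_program(params.proteasome_program_scale)
    elif cls == CLASS_EIF:
        add(modules["ribosome"], params.module_effect)
    elif cls == CLASS_MYC:
        add(modules["ribosome"], -params.module_effect)
    elif cls in (CLASS_GENERIC_STRONG, CLASS_GENERIC_WEAK):
        add_program(gamma)
    # uncoupled: self effect only
    eff[loc[target]] = params.self_effect
    return eff


def generate_compendium(
    params: SimParams | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (expression matrix, sample sheet, truth record).

    The matrix is gene x sample log2 intensities::

        x[g, s] = baseline[g] + batch_offset[g, b(s)] + effect[g, e(s)] + noise

    so batch-matched contrasts recover the planted effects exactly in the
    zero-noise limit regardless of batch offsets.
    """
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    genes = _gene_ids(params.n_genes)
    roster = _build_roster(params)
    modules = roster.attrs["modules"]

    # sample sheet: per batch, 4 GFP controls then the treated samples
    rows = []
    for batch, grp in roster.groupby("batch", sort=True):
        for r in range(params.n_controls_per_batch):
            rows.append((f"GFP_{batch}_r{r + 1}", batch, CONTROL_TARGET, True,
                         f"GFP_{batch}"))
        for _, exp in grp.iterrows():
            for r in range(int(exp["replicates"])):
                rows.append((f"{exp['experiment_id']}_r{r + 1}", batch,
                             exp["target"], False, exp["experiment_id"]))
    sheet = pd.DataFrame(
        rows, columns=["sample_id", "batch", "target_gene", "is_control",
                       "experiment_id"]
    )
    sheet = validate_sample_sheet(sheet)

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, params.n_genes)
    batches = sorted(sheet["batch"].unique())
    offsets = rng.normal(0.0, params.batch_sd, (params.n_genes, len(batches)))
    batch_offsets = pd.DataFrame(offsets, index=genes, columns=batches)

    program_genes = modules["program_up"] + modules["program_down"]
    program_amplitudes = dict(zip(
        program_genes,
        rng.uniform(params.program_amp_low, params.program_amp_high,
                    len(program_genes)),
    ))
    effects = pd.DataFrame(
        {row["experiment_id"]: _planted_profile(row, modules, params, genes,
                                                program_amplitudes)
         for _, row in roster.iterrows()},
        index=genes,
    )

    matrix = np.empty((params.n_genes, len(sheet)))
    for j, (_, s) in enumerate(sheet.iterrows()):
        col = baseline + batch_offsets[s["batch"]].to_numpy()
        if not s["is_control"]:
            col = col + effects[s["experiment_id"]].to_numpy()
        matrix[:, j] = col
    if params.noise_sd > 0:
        matrix += rng.normal(0.0, params.noise_sd, matrix.shape)
    compendium = pd.DataFrame(matrix, index=genes, columns=sheet["sample_id"])

    module_assignments = {
        g: name for name, members in modules.items() for g in members
    }
    mean_amp = 0.5 * (params.program_amp_low + params.program_amp_high)
    module_effects = {
        "proteasome": {CLASS_PROTEASOME: params.module_effect},
        "ribosome": {CLASS_EIF: params.module_effect,
                     CLASS_MYC: -params.module_effect},
        # per-gene amplitudes vary; exact planted values live in planted_effects
        "program_up": {CLASS_GENERIC_STRONG: mean_amp,
                       CLASS_GENERIC_WEAK: mean_amp * params.weak_gamma,
                       CLASS_PROTEASOME: mean_amp * params.proteasome_program_scale},
        "program_down": {CLASS_GENERIC_STRONG: -mean_amp,
                         CLASS_GENERIC_WEAK: -mean_amp * params.weak_gamma,
                         CLASS_PROTEASOME: -mean_amp * params.proteasome_program_scale},
    }
    classes = dict(zip(roster["experiment_id"], roster["class"]))
    uncoupled = {e for e, c in classes.items() if c == CLASS_UNCOUPLED}

    # phenotype links: planted (delta_g1, delta_size) per experiment
    links = {}
    for _, row in roster.iterrows():
        e = row["experiment_id"]
        if row["class"] == CLASS_UNCOUPLED:
            links[e] = (params.uncoupled_delta_g1, params.uncoupled_size_drop)
        else:
            manhattan = float(np.abs(effects[e]).sum())
            links[e] = (params.phenotype_coupling * params.phenotype_alpha
                        * manhattan, 0.0)

    truth = SimTruth(
        module_assignments=module_assignments,
        module_effects=module_effects,
        planted_effects=effects,
        self_effect=params.self_effect,
        noise_sd=params.noise_sd,
        batch_offsets=batch_offsets,
        experiment_classes=classes,
        uncoupled_experiments=uncoupled,
        phenotype_links=links,
        correlated_genes=[],
        flow_model_params={
            "k_surface": params.flow_k_surface,
            "k_nuclear": params.flow_k_nuclear,
            "size_midpoint": params.flow_size_midpoint,
        },
        params=params,
    )
    return compendium, sheet, truth


def generate_phenotypes(
    sheet: pd.DataFrame, truth: SimTruth, seed: int = 0
) -> pd.DataFrame:
    """Per-experiment FACS phenotype summaries, plus batch-control baselines.

    Coupled experiments receive a G1-fraction increase proportional to the
    Manhattan norm of their planted profile; uncoupled experiments receive a
    fixed large G1 increase and a cell-size reduction. The (G1, S, G2)
    fractions always form a probability vector: mass removed from G1's
    complement is taken from S and G2 proportionally.
    """
    params = truth.params
    rng = np.random.default_rng(seed)
    rows = []
    groups = sheet.drop_duplicates("experiment_id")[
        ["experiment_id", "batch", "is_control"]
    ]
    for _, grp in groups.iterrows():
        e = grp["experiment_id"]
        if grp["is_control"]:
            dg1, dsize = 0.0, 0.0
            dg1 = dg1 + rng.normal(0.0, params.control_phenotype_noise_sd)
        else:
            dg1, dsize = truth.phenotype_links[e]
            dg1 = dg1 + rng.normal(0.0, params.phenotype_noise_sd)
        dg1 = float(np.clip(dg1, -params.baseline_g1 + 0.01,
                            1.0 - params.baseline_g1 - 0.01))
        g1 = params.baseline_g1 + dg1
        rest = 1.0 - g1
        base_rest = params.baseline_s + params.baseline_g2
        s = params.baseline_s * rest / base_rest
        g2 = params.baseline_g2 * rest / base_rest
        size_factor = (1.0 + dsize) * (1.0 + rng.normal(0.0, params.size_noise_sd))
        rows.append((
            e, grp["batch"], bool(grp["is_control"]), g1, s, g2,
            params.baseline_g1_size * size_factor,
            params.baseline_g2_size * size_factor,
        ))
    return pd.DataFrame(
        rows, columns=["experiment_id", "batch", "is_control", "g1_frac",
                       "s_frac", "g2_frac", "g1_size", "g2_size"]
    )


def plant_correlated_genes(
    compendium: pd.DataFrame,
    sheet: pd.DataFrame,
    pheno: pd.DataFrame,
    truth: SimTruth,
    n_genes: int,
    target_rho: float,
    seed: int = 0,
) -> list[str]:
    """Overwrite the last ``n_genes`` gene rows with expression directly
    linked to the G1 phenotype, at approximately the requested correlation.

    Used by permutation-power analyses; the modified genes are recorded in
    ``truth.correlated_genes``.
    """
    if not 0 < target_rho < 1:
        raise ValueError("target_rho must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    pheno_exp = pheno[~pheno["is_control"]].set_index("experiment_id")
    g1 = pheno_exp["g1_frac"]
    signal = (g1 - g1.mean()) / (g1.std() + 1e-12)
    noise_sd = math.sqrt(1.0 / target_rho**2 - 1.0)
    chosen = list(compendium.index[-n_genes:])
    exp_of_sample = dict(zip(sheet["sample_id"], sheet["experiment_id"]))
    is_ctrl = dict(zip(sheet["sample_id"], sheet["is_control"]))
    for gene in chosen:
        vals = []
        gene_noise = rng.normal(0.0, noise_sd, len(signal))
        per_exp = dict(zip(signal.index, signal.to_numpy() + gene_noise))
        for s in compendium.columns:
            if is_ctrl[s]:
                vals.append(0.0)
            else:
                vals.append(per_exp[exp_of_sample[s]])
        compendium.loc[gene] = truth.params.baseline_mean + np.asarray(vals)
    truth.correlated_genes = chosen
    return chosen


# ---------------------------------------------------------------------------
# per-cell flow events


def phospho_fraction(size: np.ndarray, k_surface: float, k_nuclear: float,
                     midpoint: float) -> np.ndarray:
    """Fraction of Cdk1 phosphorylated as a saturating function of cell size.

    The inhibitory-kinase activity reaching soluble Cdk1 scales with the
    surface-to-volume ratio, ``(size / midpoint) ** (-1/3)`` for the
    membrane-bound component plus a nuclear component; the phosphorylated
    fraction is ``a / (1 + a)``. As ``k_surface -> inf`` the fraction tends
    to 1 for every size; it is strictly decreasing in size for
    ``k_surface > 0``.
    """
    size = np.asarray(size, float)
    if (size <= 0).any():
        raise ValueError("cell sizes must be positive")
    activity = k_surface * (size / midpoint) ** (-1.0 / 3.0) + k_nuclear
    return activity / (1.0 + activity)


def generate_flow_events(
    n_cells: int = 20000,
    params: SimParams | None = None,
    seed: int = 0,
    measurement_cv: float = 0.05,
    dna_cv: float = 0.03,
    size_coupled: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate per-cell flow events (dna, fsc_a, ch_total, ch_phospho).

    Phases are drawn G1/S/G2 with DNA content 1x / interpolated / 2x the G1
    baseline times measurement noise; FSC-A is lognormal with larger G2
    cells; total Cdk1 is proportional to cell size; the phosphorylated
    fraction follows :func:`phospho_fraction`. With ``size_coupled=False``
    both antibody channels are drawn independently of cell size (the
    size-independent null used for type-I calibration of the bin tests).

    Returns the event table and the true per-cell phase labels.
    """
    params = params or SimParams()
    if n_cells < 10:
        raise ValueError("n_cells too small for stable summaries")
    rng = np.random.default_rng(seed)
    phase = rng.choice(["G1", "S", "G2"], size=n_cells,
                       p=[params.baseline_g1, params.baseline_s, params.baseline_g2])

    dna_base = np.where(phase == "G1", 100.0,
                        np.where(phase == "G2", 200.0,
                                 rng.uniform(100.0, 200.0, n_cells)))
    dna = dna_base * (1.0 + rng.normal(0.0, dna_cv, n_cells)) if dna_cv > 0 else dna_base

    size_scale = np.where(phase == "G1", 1.0, np.where(phase == "S", 1.15, 1.3))
    fsc = 100.0 * size_scale * np.exp(rng.normal(0.0, 0.25, n_cells))

    mid = params.flow_size_midpoint
    if mid is None:
        mid = float(np.median(fsc[phase == "G2"]))

    def noisy(x):
        return x * (1.0 + rng.normal(0.0, measurement_cv, n_cells)) \
            if measurement_cv > 0 else x

    if size_coupled:
        total = 0.05 * fsc
        frac = phospho_fraction(fsc, params.flow_k_surface,
                                params.flow_k_nuclear, mid)
    else:
        total = np.full(n_cells, 0.05 * mid)
        frac = np.full(n_cells, phospho_fraction(
            np.array([mid]), params.flow_k_surface, params.flow_k_nuclear, mid
        )[0])
    ch_total = noisy(total)
    ch_phospho = noisy(frac * total)

    events = pd.DataFrame({
        "event_id": np.arange(n_cells),
        "dna": dna,
        "fsc_a": fsc,
        "ch_total": ch_total,
        "ch_phospho": ch_phospho,
    })
    return events, pd.Series(phase, name="phase")
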