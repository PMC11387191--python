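"""Synthetic sort-seq experiments with known ground truth.

The generator emulates the full measurement chain of a pooled readthrough
assay so that every downstream stage of the pipeline can be tested
against known parameters:

1. a library of 147-nt stop-anchored contexts (stop at offset 72,
   balanced across TAA/TAG/TGA) plus a no-nonsense control variant,
2. per-variant true readthrough fractions from a sequence-feature
   logistic model (inverse-logit of a linear predictor over the same
   design matrix the models module fits),
3. per-replicate variant-level perturbation on the logit scale,
4. per-cell log-normal mCherry fluorescence around a variant mean
   proportional to true readthrough, Poisson cell counts per variant,
5. gate assignment by log10-fluorescence boundaries, with gate
   percentages and mean fluorescences recomputed from the simulated
   cells, and
6. multinomial sequencing reads per gate proportional to within-gate
   variant cell counts.

Defaults reflect the study conditions of a genome-scale screen: ~272
cells per variant, two biological replicates and a handful of mCherry
gates spanning the fluorescence range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignBuilder, ModelSpec
from .features import STOP_CODONS, VariantContext, features_table
from .sortseq import GateMetadata

CONTROL_ID = "control"
CONTEXT_LENGTH = 147
STOP_OFFSET = 72

# sense codons used for the control variant's "stop" position
_SENSE_CODON = "CAG"


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic sort-seq experiment.

    Defaults: 272 cells/variant matches the scale of the real screens
    (~1.6 million sorted cells for ~5,800 variants); four gates,
    log-spaced across the expected fluorescence range, within the three
    to five used per drug experiment; sequencing depth, cell noise and
    replicate noise are not reported for the original experiments and
    are set to values typical of this assay class (see docs/methods.md).
    """

    n_variants: int = 2000
    drugs: tuple[str, ...] = ("drugA",)
    truth_coefficients: dict[str, dict[str, float]] | None = None
    mean_cells_per_variant: float = 272.0
    gate_boundaries: tuple[float, ...] = (2.0, 2.75, 3.5)  # log10 units
    reads_per_gate: int = 500_000
    cell_noise_sd: float = 0.2  # s.d. of per-cell log10 fluorescence
    replicate_noise_sd: float = 0.1  # s.d. of per-replicate logit shift
    n_replicates: int = 2
    control_fluorescence: float = 1e4  # mean mCherry of the control
    spec: ModelSpec = field(default_factory=ModelSpec.drug_f4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.mean_cells_per_variant <= 0:
            raise ValueError("mean_cells_per_variant must be positive")
        bounds = np.asarray(self.gate_boundaries, float)
        if not np.all(np.diff(bounds) > 0):
            raise ValueError("gate boundaries must strictly increase")
        if self.cell_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("noise s.d. must be >= 0")
        if self.reads_per_gate < 0:
            raise ValueError("reads_per_gate must be >= 0")

    @property
    def n_gates(self) -> int:
        return len(self.gate_boundaries) + 1


@dataclass
class SyntheticTruth:
    """Latent state of a simulation.

    ``rtp`` is a variants x conditions table of true readthrough percent
    (the control row is exactly 100); ``replicate_fluorescence`` maps
    (condition, replicate) to the realized per-variant mean fluorescence
    used for cell sampling.
    """

    contexts: list[VariantContext]
    rtp: pd.DataFrame
    replicate_fluorescence: dict[tuple[str, int], pd.Series] = field(
        default_factory=dict
    )

    @property
    def variant_ids(self) -> pd.Index:
        return self.rtp.index


def simulate_library(
    n_variants: int, seed: int = 0, rng: np.random.Generator | None = None
) -> list[VariantContext]:
    """Random 147-nt contexts with a balanced stop at offset 72, plus a
    no-nonsense control appended last."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    nts = np.array(list("ACGT"))
    contexts = []
    for i in range(n_variants):
        seq = rng.choice(nts, size=CONTEXT_LENGTH)
        stop = STOP_CODONS[i % 3]
        seq[STOP_OFFSET : STOP_OFFSET + 3] = list(stop)
        contexts.append(
            VariantContext(f"v{i:05d}", "".join(seq), STOP_OFFSET)
        )
    seq = rng.choice(nts, size=CONTEXT_LENGTH)
    seq[STOP_OFFSET : STOP_OFFSET + 3] = list(_SENSE_CODON)
    contexts.append(
        VariantContext(CONTROL_ID, "".join(seq), STOP_OFFSET, is_control=True)
    )
    return contexts


def default_truth_coefficients(
    contexts: list[VariantContext],
    drugs: tuple[str, ...],
    spec: ModelSpec | None = None,
    seed: int = 0,
    intercept: float = -3.0,
    effect_sd: float = 0.25,
) -> dict[str, dict[str, float]]:
    """Seeded per-drug coefficient tables over the model design columns.

    The intercept of -3 puts the median true readthrough at a few
    percent with a long upper tail, the readthrough regime observed for
    effective drugs; per-column effects are N(0, effect_sd^2) draws.
    """
    spec = spec or ModelSpec.drug_f4()
    feats = features_table(contexts, include_controls=False)
    builder = DesignBuilder(spec).fit(feats)
    rng = np.random.default_rng(seed)
    coefficients = {}
    for drug in drugs:
        values = rng.normal(0.0, effect_sd, size=len(builder.columns_) - 1)
        table = {"Intercept": intercept}
        table.update(dict(zip(builder.columns_[1:], values)))
        coefficients[drug] = table
    return coefficients


def true_readthrough(
    contexts: list[VariantContext],
    truth_coefficients: dict[str, dict[str, float]],
    spec: ModelSpec | None = None,
) -> SyntheticTruth:
    """True readthrough percentages implied by coefficient tables.

    For each condition, ``p = inverse-logit(X beta)`` over the design
    matrix of the non-control contexts and ``RTp = 100 p``; the control
    variant is fixed at exactly 100. Raises if a coefficient table does
    not cover every design column its contexts produce.
    """
    spec = spec or ModelSpec.drug_f4()
    feats = features_table(contexts, include_controls=False)
    builder = DesignBuilder(spec).fit(feats)
    X = builder.transform(feats)
    columns = {}
    for condition, table in truth_coefficients.items():
        missing = [c for c in X.columns if c not in table]
        if missing:
            raise KeyError(
                f"truth coefficients for {condition!r} missing level(s) "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        beta = np.array([table[c] for c in X.columns])
        eta = X.to_numpy() @ beta
        columns[condition] = 100.0 / (1.0 + np.exp(-eta))
    rtp = pd.DataFrame(columns, index=feats.index)
    control_rows = pd.DataFrame(
        100.0,
        index=[c.variant_id for c in contexts if c.is_control],
        columns=rtp.columns,
    )
    rtp = pd.concat([rtp, control_rows])
    return SyntheticTruth(contexts=contexts, rtp=rtp)


def _gate_table(
    boundaries: np.ndarray, pc: np.ndarray, fv: np.ndarray
) -> pd.DataFrame:
    lower = np.concatenate([[-np.inf], boundaries])
    upper = np.concatenate([boundaries, [np.inf]])
    return pd.DataFrame(
        {
            "gate_id": [f"gate{j + 1}" for j in range(len(pc))],
            "pc": pc,
            "fv": fv,
            "lower_bound": lower,
            "upper_bound": upper,
        }
    )


def simulate_sortseq(
    truth: SyntheticTruth,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator | None = None,
) -> list[tuple[pd.DataFrame, GateMetadata]]:
    """Simulate binned read counts for one condition, per replicate.

    Returns ``[(counts, gates), ...]`` with one entry per replicate;
    ``counts`` is a variants x gates read-count table and ``gates`` the
    recomputed gate metadata (pc and fv from the simulated cells). Gates
    that receive no cells are emitted with pc = 0 and fv = NaN; the
    estimator drops them downstream.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rtp = truth.rtp[condition]
    variant_ids = truth.variant_ids
    is_control = np.array(
        [vid == CONTROL_ID or vid.startswith("control") for vid in variant_ids]
    )
    p = np.clip(rtp.to_numpy(float) / 100.0, 1e-12, 1 - 1e-12)
    boundaries = np.asarray(config.gate_boundaries, float)
    n_gates = config.n_gates
    out = []
    for rep in range(config.n_replicates):
        logit = np.log(p / (1 - p))
        noise = rng.normal(0.0, config.replicate_noise_sd, size=len(p))
        noise[is_control] = 0.0
        p_rep = 1.0 / (1.0 + np.exp(-(logit + noise)))
        p_rep[is_control] = 1.0
        mean_f = config.control_fluorescence * p_rep
        truth.replicate_fluorescence[(condition, rep)] = pd.Series(
            mean_f, index=variant_ids
        )
        cells = rng.poisson(config.mean_cells_per_variant, size=len(p))
        owner = np.repeat(np.arange(len(p)), cells)
        log_f = rng.normal(
            np.log10(np.repeat(mean_f, cells)), config.cell_noise_sd
        )
        gate_of = np.digitize(log_f, boundaries)
        gate_counts = np.bincount(gate_of, minlength=n_gates)
        total = gate_counts.sum()
        pc = 100.0 * gate_counts / total if total else np.zeros(n_gates)
        fluor = 10.0**log_f
        fv = np.full(n_gates, np.nan)
        for j in range(n_gates):
            in_gate = gate_of == j
            if in_gate.any():
                fv[j] = fluor[in_gate].mean()
        # per-gate multinomial reads over within-gate variant cell counts
        cell_matrix = np.zeros((len(p), n_gates), dtype=np.int64)
        np.add.at(cell_matrix, (owner, gate_of), 1)
        reads = np.zeros_like(cell_matrix)
        for j in range(n_gates):
            col_total = cell_matrix[:, j].sum()
            if col_total == 0 or config.reads_per_gate == 0:
                continue
            reads[:, j] = rng.multinomial(
                config.reads_per_gate, cell_matrix[:, j] / col_total
            )
        counts = pd.DataFrame(
            reads,
            index=variant_ids,
            columns=[f"gate{j + 1}" for j in range(n_gates)],
        )
        counts.index.name = "variant_id"
        out.append((counts, GateMetadata(_gate_table(boundaries, pc, fv))))
    return out


@dataclass
class SyntheticExperiment:
    """Everything a synthetic run produces."""

    config: SimulationConfig
    contexts: list[VariantContext]
    features: pd.DataFrame
    truth: SyntheticTruth
    sortseq: dict[str, list[tuple[pd.DataFrame, GateMetadata]]]


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Run the full generator: library, truth and per-condition sort-seq."""
    rng = np.random.default_rng(config.seed)
    contexts = simulate_library(config.n_variants, rng=rng)
    coefficients = config.truth_coefficients
    if coefficients is None:
        coefficients = default_truth_coefficients(
            contexts, config.drugs, spec=config.spec, seed=config.seed
        )
    truth = true_readthrough(contexts, coefficients, spec=config.spec)
    sortseq = {
        condition: simulate_sortseq(truth, config, condition, rng=rng)
        for condition in config.drugs
    }
    feats = features_table(contexts, include_controls=False)
    return SyntheticExperiment(
        config=replace(config, truth_coefficients=coefficients),
        contexts=contexts,
        features=feats,
        truth=truth,
        sortseq=sortseq,
    )
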