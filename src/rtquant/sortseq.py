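"""Readthrough quantification from binned sort-seq read counts.

Cells carrying a reporter variant are FACS-sorted into fluorescence gates
and each gate is sequenced. A gate *j* is characterised by the percentage
of the sorted population it contains (``pc_j``) and its mean mCherry
fluorescence (``fv_j``). With ``r_vj`` reads of variant *v* in gate *j*
and ``R_j`` total reads in the gate, the variant's normalized mCherry
score is the ``pc``-weighted convex combination of gate fluorescences::

    score_v = sum_j (r_vj / R_j) * pc_j * fv_j  /  sum_j (r_vj / R_j) * pc_j

Dividing by the score of the untreated no-nonsense control variant (which
represents 100% of wild-type expression) gives the readthrough percentage

    RTp_v = 100 * score_v / score_control .

The module also covers the ancillary steps of the pipeline: the >= 10
read confidence filter, LOESS recalibration of non-linearly related
replicates, replicate merging with the between-replicate s.d. as the
error measure, and readthrough quantification from individual
(non-pooled) flow-cytometry measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

_PC_SUM_TOL = 1e-6


@dataclass
class GateMetadata:
    """Ordered FACS gate description.

    ``table`` holds one row per gate with columns ``gate_id``, ``pc``
    (percent of the sorted population, 0-100), ``fv`` (mean mCherry
    fluorescence, arbitrary units > 0) and optionally ``lower_bound`` /
    ``upper_bound`` (log10 fluorescence gate limits).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gate_id", "pc", "fv"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"gate table missing columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        pc = self.table["pc"].to_numpy(float)
        if (pc < 0).any():
            raise ValueError("gate pc must be non-negative")
        if pc.sum() > 100 + _PC_SUM_TOL:
            raise ValueError(f"gate pc sum {pc.sum():.6f} exceeds 100")
        fv = self.table["fv"].to_numpy(float)
        occupied = pc > 0
        if not np.all(np.diff(fv[occupied & np.isfinite(fv)]) > 0):
            raise ValueError("gate fv must strictly increase with gate order")

    @property
    def gate_ids(self) -> list[str]:
        return list(self.table["gate_id"].astype(str))

    @property
    def pc(self) -> np.ndarray:
        return self.table["pc"].to_numpy(float)

    @property
    def fv(self) -> np.ndarray:
        return self.table["fv"].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GateMetadata":
        return cls(pd.read_csv(path, sep="\t"))


def _score_matrix(
    reads: np.ndarray, totals: np.ndarray, pc: np.ndarray, fv: np.ndarray
) -> np.ndarray:
    """Vectorized score over a variants x gates read matrix."""
    usable = (totals > 0) & (pc > 0) & np.isfinite(fv)
    if not usable.any():
        raise ValueError("no usable gates (all totals or pc are zero)")
    if not usable.all():
        dropped = int((~usable).sum())
        logger.info("dropping %d empty gate(s) from estimation", dropped)
    r = reads[:, usable].astype(float)
    weights = r / totals[usable] * pc[usable]
    denom = weights.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = weights @ fv[usable] / denom
    scores[denom == 0] = np.nan
    return scores


def variant_mcherry(reads, gates: GateMetadata, totals) -> float:
    """Normalized mCherry score for a single variant.

    Parameters
    ----------
    reads : array-like
        Reads of the variant per gate, ordered as in ``gates``.
    gates : GateMetadata
    totals : array-like
        Total reads per gate (``R_j``), same order.
    """
    reads = np.asarray(reads, float)
    totals = np.asarray(totals, float)
    if reads.sum() <= 0:
        raise ValueError("undefined mCherry score: variant has zero reads")
    if (totals <= 0).any():
        raise ValueError("all gate totals R_j must be positive")
    score = _score_matrix(reads[None, :], totals, gates.pc, gates.fv)[0]
    return float(score)


def mcherry_scores(counts: pd.DataFrame, gates: GateMetadata) -> pd.Series:
    """Scores for a whole read-count table (variants x gates).

    Gates whose read total or ``pc`` is zero are dropped from both the
    numerator and denominator for all variants; variants without any
    reads in the usable gates get NaN.
    """
    counts = counts[gates.gate_ids]
    reads = counts.to_numpy(float)
    totals = reads.sum(axis=0)
    scores = _score_matrix(reads, totals, gates.pc, gates.fv)
    return pd.Series(scores, index=counts.index, name="mcherry_score")


def normalize_to_control(
    scores: pd.Series, control_score_untreated: float
) -> pd.Series:
    """Readthrough percent: 100 x score / untreated-control score."""
    if not np.isfinite(control_score_untreated):
        raise ValueError("control score is not finite")
    if control_score_untreated <= 0:
        raise ValueError("control score must be positive")
    rtp = 100.0 * scores / control_score_untreated
    return rtp.rename("rtp")


def quantify(
    counts: pd.DataFrame,
    gates: GateMetadata,
    control_id: str,
    min_reads: int = 10,
    control_score: float | None = None,
) -> pd.DataFrame:
    """Full count-table -> readthrough-table conversion.

    Returns a table indexed by variant_id with columns ``mcherry_score``,
    ``rtp`` and ``total_reads``. When ``control_score`` is given (the
    untreated condition's control) it is used for normalization;
    otherwise the control variant must be present in ``counts``.
    """
    scores = mcherry_scores(counts, gates)
    if control_score is None:
        if control_id not in scores.index:
            raise KeyError(f"control variant {control_id!r} missing")
        control_score = float(scores.loc[control_id])
    table = pd.DataFrame(
        {
            "mcherry_score": scores,
            "rtp": normalize_to_control(scores, control_score),
            "total_reads": counts[gates.gate_ids].sum(axis=1).astype(int),
        }
    )
    table = table.dropna(subset=["mcherry_score"])
    return filter_high_confidence(table, min_reads=min_reads)


def filter_high_confidence(
    table: pd.DataFrame, min_reads: int = 10
) -> pd.DataFrame:
    """Retain variants with >= ``min_reads`` total reads."""
    kept = table[table["total_reads"] >= min_reads]
    removed = len(table) - len(kept)
    if removed:
        logger.info(
            "filter_high_confidence: removed %d/%d variants with <%d reads",
            removed,
            len(table),
            min_reads,
        )
    return kept


def loess_recalibrate(
    rep1: pd.Series, rep2: pd.Series, span: float = 0.75
) -> pd.Series:
    """Calibrate replicate 2 onto replicate 1's scale.

    A LOESS curve of rep1 as a function of rep2 is fitted on shared
    variants and made monotone by isotonic regression; rep2 values are
    then mapped through the calibration curve. After calibration the
    rep1-vs-rep2 relation is linear (identity up to noise) and the
    Pearson correlation between replicates is non-decreasing for
    monotone distortions such as the sigmoidal relation caused by
    cytometer voltage differences.
    """
    shared = rep1.index.intersection(rep2.index)
    shared_vals = pd.DataFrame(
        {"r1": rep1.loc[shared], "r2": rep2.loc[shared]}
    ).dropna()
    if len(shared_vals) < 50:
        raise ValueError(
            f"only {len(shared_vals)} shared variants; >= 50 required"
        )
    fitted = lowess(
        shared_vals["r1"].to_numpy(),
        shared_vals["r2"].to_numpy(),
        frac=span,
        return_sorted=False,
    )
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(shared_vals["r2"].to_numpy(), fitted)
    calibrated = pd.Series(
        iso.predict(rep2.to_numpy(float)), index=rep2.index, name=rep2.name
    )
    return calibrated


def merge_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-replicate readthrough tables.

    Returns per variant the mean ``rtp`` over the replicates in which it
    was measured, the between-replicate standard deviation (the error
    measure of the assay; 0 for single-replicate variants, which are
    flagged via ``n_reps``) and the summed read support.
    """
    if not tables:
        raise ValueError("no replicate tables given")
    rtp = pd.concat(
        [t["rtp"].rename(i) for i, t in enumerate(tables)], axis=1
    )
    reads = pd.concat(
        [t["total_reads"].rename(i) for i, t in enumerate(tables)], axis=1
    )
    n_reps = rtp.notna().sum(axis=1)
    merged = pd.DataFrame(
        {
            "rtp_mean": rtp.mean(axis=1),
            "rtp_sd": rtp.std(axis=1, ddof=1).fillna(0.0),
            "total_reads": reads.sum(axis=1).astype(int),
            "n_reps": n_reps.astype(int),
        }
    )
    single = int((n_reps == 1).sum())
    if single:
        logger.info("merge_replicates: %d variant(s) single-replicate", single)
    return merged[n_reps > 0]


def replicate_correlation(rep1: pd.Series, rep2: pd.Series) -> float:
    """Pearson correlation of shared-variant readthrough values."""
    shared = rep1.index.intersection(rep2.index)
    pair = pd.DataFrame(
        {"r1": rep1.loc[shared], "r2": rep2.loc[shared]}
    ).dropna()
    return float(pearsonr(pair["r1"], pair["r2"])[0])


def individual_readthrough(
    cell_events: pd.DataFrame,
    egfp_gate: tuple[float, float],
    mcherry_threshold: float,
    control_value: float,
) -> float:
    """Readthrough percent from individual flow-cytometry events.

    Readthrough is the fraction of EGFP+ cells that are also mCherry+,
    multiplied by the mean mCherry intensity of the mCherry+ population
    and normalized to the no-nonsense control:

        RTp = 100 * (n_mCherry+ / n_EGFP+) * mean_mCherry+ / control_value

    ``cell_events`` needs columns ``egfp`` and ``mcherry``; ``egfp_gate``
    is the (low, high) EGFP window retaining correctly expressing cells.
    """
    if control_value <= 0:
        raise ValueError("control_value must be positive")
    low, high = egfp_gate
    egfp_pos = cell_events[
        (cell_events["egfp"] >= low) & (cell_events["egfp"] <= high)
    ]
    if len(egfp_pos) == 0:
        raise ValueError("no EGFP+ cells in the gate")
    mcherry_pos = egfp_pos[egfp_pos["mcherry"] >= mcherry_threshold]
    if len(mcherry_pos) == 0:
        return 0.0
    frac = len(mcherry_pos) / len(egfp_pos)
    mean_intensity = float(mcherry_pos["mcherry"].mean())
    return 100.0 * frac * mean_intensity / control_value
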