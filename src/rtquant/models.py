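"""Sequence-context readthrough models.

The central object is :class:`ReadthroughModel`, a fractional-response
logistic regression of readthrough percentage on local sequence context,
organised like a statsmodels model: construct it from data, call
``fit()`` and work with the returned :class:`ReadthroughResults`.

The response is the readthrough fraction ``p = RTp / 100`` clipped to
``[1e-4, 1 - 1e-4]`` (readthrough percentages are continuous, can exceed
100 after control normalization and can dip below 0 after noise, so the
model is a quasi-likelihood binomial GLM with logit link rather than a
Bernoulli classifier). Predictions are returned on the percent scale.

Model evaluation follows the repeated random-split protocol: ``r^2`` is
the squared Pearson correlation of observed vs predicted readthrough over
pooled held-out predictions of seeded 90/10 splits (disjoint test sets
whenever ``n_rounds * test_fraction <= 1``). Term importance is the drop
in cross-validated r^2 when a term is removed, normalized to the full
model; coefficient uncertainty comes from the spread of per-fold
coefficient vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    HessianInversionWarning,
    PerfectSeparationWarning,
)

from .design import DesignBuilder, ModelSpec

logger = logging.getLogger(__name__)

#: clipping bound for the fraction response
CLIP = 1e-4


def _clip_fraction(rtp: np.ndarray) -> np.ndarray:
    p = np.asarray(rtp, float) / 100.0
    # negative measured readthrough (normalization noise) clips to 0 first
    return np.clip(p, CLIP, 1.0 - CLIP)


class ConvergenceError(RuntimeError):
    pass


def pooled_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation (the model-performance metric)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.std() == 0 or predicted.std() == 0:
        return 0.0
    return float(stats.pearsonr(observed, predicted)[0] ** 2)


class ReadthroughModel:
    """Fractional logistic regression of readthrough on sequence context.

    Parameters
    ----------
    rtp : Series or array
        Readthrough percentages (response).
    features : DataFrame
        Sequence features aligned with ``rtp`` (one row per variant; a
        ``drug`` column is required by the pan-drug spec).
    spec : ModelSpec, optional
        Defaults to the four-term single-drug formulation
        (``ModelSpec.drug_f4()``).
    condition : str, optional
        Label stored in the fit metadata (e.g. the drug name).
    """

    def __init__(self, rtp, features: pd.DataFrame, spec=None, condition=None):
        self.spec = spec or ModelSpec.drug_f4()
        if isinstance(rtp, pd.Series):
            features = features.loc[rtp.index]
        self.rtp = np.asarray(rtp, float)
        if len(self.rtp) != len(features):
            raise ValueError("rtp and features length mismatch")
        self.features = features.copy()
        self.condition = condition

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, spec=None, rtp_col: str = "rtp",
        condition=None,
    ) -> "ReadthroughModel":
        """Build from a joined readthrough + features table."""
        return cls(
            data[rtp_col].to_numpy(float),
            data.drop(columns=[rtp_col]),
            spec=spec,
            condition=condition,
        )

    @property
    def nobs(self) -> int:
        return len(self.rtp)

    def fit(self) -> "ReadthroughResults":
        builder = DesignBuilder(self.spec).fit(self.features)
        X = builder.transform(self.features)
        if X.shape[0] <= X.shape[1]:
            raise ValueError(
                f"n rows ({X.shape[0]}) must exceed number of design "
                f"columns ({X.shape[1]})"
            )
        params = _fit_glm(X, self.rtp)
        return ReadthroughResults(self, builder, params)


def _fit_glm(X: pd.DataFrame, rtp: np.ndarray, maxiter: int = 100) -> pd.Series:
    y = _clip_fraction(rtp)
    glm = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # fractional responses that the model fits exactly trip the
        # perfect-separation heuristic; with y strictly inside (0,1) the
        # IRLS solution is finite and well-defined
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = glm.fit(maxiter=maxiter, tol=1e-8)
        if not getattr(res, "converged", True):
            # IRLS can oscillate on small, noisy designs with sparsely
            # populated level combinations; polish with a gradient step
            trace = getattr(res, "fit_history", {}).get("deviance", [])
            logger.info(
                "IRLS did not converge in %d iterations (%d x %d design); "
                "retrying with L-BFGS",
                maxiter,
                *X.shape,
            )
            # coefficient uncertainty comes from CV folds, not the GLM
            # covariance, so a failed hessian inversion is irrelevant here
            warnings.simplefilter("ignore", HessianInversionWarning)
            res = glm.fit(
                start_params=res.params,
                method="lbfgs",
                maxiter=500,
                disp=False,
            )
            if not _gradient_converged(res):
                raise ConvergenceError(
                    f"GLM did not converge (IRLS {maxiter} iterations, then "
                    f"L-BFGS); design {X.shape[0]} x {X.shape[1]}; last IRLS "
                    f"deviances: {[round(float(d), 6) for d in trace[-5:]]}"
                )
    return pd.Series(res.params, index=X.columns, name="coef")


def _gradient_converged(res) -> bool:
    retvals = getattr(res, "mle_retvals", None)
    if retvals is None:
        return bool(np.isfinite(np.asarray(res.params)).all())
    return bool(retvals.get("converged", False))


@dataclass
class CVResult:
    """Cross-validation output.

    ``predictions`` has one row per held-out (round, variant) pair with
    observed and predicted readthrough; ``coefs`` stacks the per-fold
    coefficient vectors (folds x columns).
    """

    predictions: pd.DataFrame
    fold_r2: np.ndarray
    pooled_r2: float
    coefs: pd.DataFrame
    folds: list[np.ndarray]
    spec: ModelSpec

    def coefficient_stats(self) -> pd.DataFrame:
        return coefficient_stats(self.coefs)


class ReadthroughResults:
    """Fitted readthrough model: coefficients, predictions, diagnostics."""

    def __init__(
        self,
        model: ReadthroughModel,
        builder: DesignBuilder,
        params: pd.Series,
    ):
        self.model = model
        self.builder = builder
        self.params = params

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.features)

    @property
    def rsquared(self) -> float:
        """Training r^2 (squared Pearson of observed vs fitted)."""
        return pooled_r2(self.model.rtp, self.fittedvalues)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predicted readthrough percent, in (0, 100).

        Factor levels unseen at fit time map to the reference level with
        a logged warning (never an error at prediction time).
        """
        X = self.builder.transform(features, allow_unseen=True)
        eta = X.to_numpy() @ self.params.to_numpy()
        return 100.0 * _invlogit(eta)

    def cross_validate(self, n_rounds=10, test_fraction=0.10, seed=None):
        return cross_validate(
            self.model, n_rounds=n_rounds, test_fraction=test_fraction,
            seed=seed,
        )

    def ablation(self, n_rounds=10, test_fraction=0.10, seed=None):
        return ablation(
            self.model, n_rounds=n_rounds, test_fraction=test_fraction,
            seed=seed,
        )

    def summary(self) -> str:
        """Plain-text model summary with term-grouped coefficients."""
        lines = [
            "Readthrough fractional-logit model",
            "=" * 50,
            f"formula:      {self.model.spec.formula_kind}",
            f"condition:    {self.model.condition or '-'}",
            f"n variants:   {self.model.nobs}",
            f"n columns:    {len(self.params)}",
            f"training r2:  {self.rsquared:.4f}",
            "-" * 50,
            f"{'term':<14}{'coefficient':<32}{'value':>10}",
        ]
        for name, value in self.params.items():
            term = self.builder.term_of_column(name)
            lines.append(f"{term:<14}{name:<32}{value:>10.4f}")
        return "\n".join(lines)


def _invlogit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-eta))


def _make_folds(
    index: pd.Index,
    n_rounds: int,
    test_fraction: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Seeded test-set index lists: disjoint chunks of one permutation
    when rounds x fraction <= 1, otherwise independent random draws.

    Positions are permuted in the sorted order of the row labels, so fold
    membership (and everything downstream, e.g. ablation drops) does not
    depend on the physical row order of the data.
    """
    n = len(index)
    canonical = np.argsort(np.asarray(index, dtype=str), kind="stable")
    size = max(1, int(round(n * test_fraction)))
    if n_rounds * test_fraction <= 1.0 + 1e-9:
        perm = canonical[rng.permutation(n)]
        return [perm[i * size : (i + 1) * size] for i in range(n_rounds)]
    return [
        canonical[rng.choice(n, size=size, replace=False)]
        for _ in range(n_rounds)
    ]


def cross_validate(
    model: ReadthroughModel,
    n_rounds: int = 10,
    test_fraction: float = 0.10,
    seed: int | None = None,
    folds: list[np.ndarray] | None = None,
    spec: ModelSpec | None = None,
) -> CVResult:
    """Repeated random-split cross-validation.

    Fits the model on each training split, predicts the held-out split
    and reports per-fold and pooled (squared-Pearson) r^2 plus the
    per-fold coefficient vectors. ``folds`` allows sharing splits across
    models (used by ablation and the position scan).
    """
    spec = spec or model.spec
    rng = np.random.default_rng(seed)
    n = model.nobs
    if folds is None:
        folds = _make_folds(
            model.features.index, n_rounds, test_fraction, rng
        )
    builder = DesignBuilder(spec).fit(model.features)
    X_all = builder.transform(model.features).to_numpy()
    columns = builder.columns_
    rows, fold_r2, coef_rows, kept_folds = [], [], [], []
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(n, bool)
        train_mask[test_idx] = False
        observed = model.rtp[test_idx]
        if len(np.unique(observed)) < 2:
            logger.info("fold %d skipped: <2 distinct observed values", k)
            continue
        X_train = pd.DataFrame(X_all[train_mask], columns=columns)
        params = _fit_glm(X_train, model.rtp[train_mask])
        predicted = 100.0 * _invlogit(
            X_all[test_idx] @ params.to_numpy()
        )
        rows.append(
            pd.DataFrame(
                {
                    "fold": k,
                    "variant": model.features.index[test_idx],
                    "observed": observed,
                    "predicted": predicted,
                }
            )
        )
        fold_r2.append(pooled_r2(observed, predicted))
        coef_rows.append(params)
        kept_folds.append(test_idx)
    if not rows:
        raise ValueError(
            "every fold was skipped (constant held-out response); "
            "cross-validation is undefined"
        )
    predictions = pd.concat(rows, ignore_index=True)
    return CVResult(
        predictions=predictions,
        fold_r2=np.array(fold_r2),
        pooled_r2=pooled_r2(
            predictions["observed"], predictions["predicted"]
        ),
        coefs=pd.DataFrame(coef_rows).reset_index(drop=True),
        folds=kept_folds,
        spec=spec,
    )


def ablation(
    model: ReadthroughModel,
    n_rounds: int = 10,
    test_fraction: float = 0.10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Normalized r^2 drop when each named term is removed.

    The full model and every reduced model are cross-validated on the
    same folds; the reported drop is ``1 - r2_removed / r2_full``.
    """
    if len(model.spec.terms) < 2:
        raise ValueError("ablation needs a spec with >= 2 terms")
    rng = np.random.default_rng(seed)
    folds = _make_folds(
        model.features.index, n_rounds, test_fraction, rng
    )
    full = cross_validate(model, folds=folds)
    if full.pooled_r2 == 0:
        raise ZeroDivisionError("full-model r^2 is 0; drop undefined")
    records = []
    for term in model.spec.term_names:
        reduced_spec = model.spec.drop_term(term)
        reduced = cross_validate(model, folds=folds, spec=reduced_spec)
        records.append(
            {
                "term": term,
                "r2_full": full.pooled_r2,
                "r2_removed": reduced.pooled_r2,
                "normalized_drop": 1.0 - reduced.pooled_r2 / full.pooled_r2,
            }
        )
    return pd.DataFrame(records).set_index("term")


def added_position_scan(
    rtp,
    features: pd.DataFrame,
    positions: tuple[int, ...] = tuple(range(1, 9)),
    n_rounds: int = 20,
    test_fraction: float = 0.10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Contribution of downstream positions +1..+8, added one at a time.

    Every model keeps the stop type and the upstream 1-3 nt factorial;
    downstream positions are added cumulatively (+1..+3 with their mutual
    interactions, +4..+8 as main effects). Each model is compared to the
    previous one with a one-sided paired t test over the per-round r^2
    values; p values are Benjamini-Hochberg adjusted across positions.
    """
    from .design import DOWN_123, UP_123, Term, factorial_term, main_term

    base_terms = (main_term("stop_type"), factorial_term("up_123", UP_123))
    rng = np.random.default_rng(seed)
    folds = _make_folds(features.index, n_rounds, test_fraction, rng)

    def spec_for(max_pos: int) -> ModelSpec:
        terms = list(base_terms)
        if max_pos >= 1:
            k = min(max_pos, 3)
            terms.append(
                factorial_term(f"down_1{''.join(map(str, range(2, k + 1)))}",
                               DOWN_123[:k])
            )
        for extra in range(4, max_pos + 1):
            terms.append(main_term(f"down_{extra}"))
        return ModelSpec("drug_f5_extended", tuple(terms), max(max_pos, 3))

    previous = cross_validate(
        ReadthroughModel(rtp, features, spec=spec_for(0)), folds=folds
    )
    records = []
    for pos in positions:
        current = cross_validate(
            ReadthroughModel(rtp, features, spec=spec_for(pos)), folds=folds
        )
        tstat, pval = _paired_onesided_t(current.fold_r2, previous.fold_r2)
        records.append(
            {
                "position": pos,
                "mean_r2": float(current.fold_r2.mean()),
                "pooled_r2": current.pooled_r2,
                "delta_mean_r2": float(
                    (current.fold_r2 - previous.fold_r2).mean()
                ),
                "t": float(tstat),
                "p": float(pval),
            }
        )
        previous = current
    table = pd.DataFrame(records).set_index("position")
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def _paired_onesided_t(
    current: np.ndarray, previous: np.ndarray
) -> tuple[float, float]:
    """One-sided paired t test of r^2 gain (current > previous).

    Two identical per-round r^2 vectors leave the test statistic
    undefined (zero variance of differences); that boundary is reported
    as non-significant (t = 0, p = 1).
    """
    tstat, pval = stats.ttest_rel(current, previous, alternative="greater")
    if np.isnan(pval):
        return 0.0, 1.0
    return float(tstat), float(pval)


def coefficient_stats(coefs: pd.DataFrame) -> pd.DataFrame:
    """Per-coefficient summary over cross-validation folds.

    Mean, s.d., 95% CI (t distribution, df = folds - 1), two-sided
    one-sample t test against 0 and Benjamini-Hochberg adjusted p values
    across all coefficients of the model. Coefficients with zero
    between-fold variance are flagged degenerate (p reported as the
    smallest positive float when the mean is nonzero).
    """
    k = len(coefs)
    if k < 3:
        raise ValueError("need >= 3 folds for coefficient statistics")
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.975, df=k - 1)
    sem = sd / np.sqrt(k)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = mean / sem
    pval = 2.0 * stats.t.sf(np.abs(tval), df=k - 1)
    pval = pd.Series(pval, index=mean.index)
    pval[degenerate & (mean != 0)] = np.finfo(float).tiny
    pval[degenerate & (mean == 0)] = 1.0
    tval = tval.replace([np.inf, -np.inf], np.nan)
    out = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "ci95_low": mean - tcrit * sem,
            "ci95_high": mean + tcrit * sem,
            "t": tval,
            "p": pval,
            "degenerate": degenerate,
        }
    )
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def explainable_variance(
    rep1: pd.Series, rep2: pd.Series, model_r2: float
) -> tuple[float, float]:
    """Maximum achievable r^2 and the fraction of it a model explains.

    The ceiling is the squared Pearson correlation between replicate
    readthrough vectors; ``fraction = model_r2 / max_r2``.
    """
    shared = rep1.index.intersection(rep2.index)
    if len(shared) < 100:
        raise ValueError(f"only {len(shared)} shared variants; >= 100 needed")
    r = stats.pearsonr(rep1.loc[shared], rep2.loc[shared])[0]
    max_r2 = float(r**2)
    return max_r2, model_r2 / max_r2


def multistop_correlation(
    table: pd.DataFrame,
    position_col: str = "position",
    stop_col: str = "stop_type",
    rtp_col: str = "rtp",
    min_positions: int = 3,
) -> pd.DataFrame:
    """Concordance of readthrough between stop types at shared positions.

    ``table`` holds per-variant readthrough with a genomic position key
    and the stop type; rows are matched on position for each stop-type
    pair and the Pearson r plus ratio of medians is reported. Pairs with
    fewer than ``min_positions`` shared positions are omitted (logged).
    """
    stop_types = sorted(table[stop_col].unique())
    wide = table.pivot_table(
        index=position_col, columns=stop_col, values=rtp_col
    )
    records = []
    for i, a in enumerate(stop_types):
        for b in stop_types[i + 1 :]:
            pair = wide[[a, b]].dropna()
            if len(pair) < min_positions:
                logger.info(
                    "multistop pair %s/%s omitted: %d shared positions",
                    a, b, len(pair),
                )
                continue
            records.append(
                {
                    "stop_a": a,
                    "stop_b": b,
                    "n_positions": len(pair),
                    "pearson_r": float(stats.pearsonr(pair[a], pair[b])[0]),
                    "median_ratio": float(
                        pair[a].median() / pair[b].median()
                    ),
                }
            )
    return pd.DataFrame(records)
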