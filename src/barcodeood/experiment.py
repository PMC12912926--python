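"""Replicated evaluation grids and the determinant regressions.

The driver mirrors the study design: per genus dataset, sweep database size
{Sufficient, Small} x noise {0.0, 0.02} x fragment length {650, 300, 150} x
method, with replicated 70/30 splits. Each replicate prepares the windowed
data, trains a CNN or indexes a distance reference on the clean training
split, injects per-base Bernoulli noise into test material only, calibrates class-wise 95%
thresholds on the held-out ID samples, and measures baseline accuracy,
FNR@95% on OOD samples, FPR on ID samples and the zero-distance perfect
bounds of the noiseless windowed split.

Downstream analyses: dummy-coded OLS of performance on the design factors,
LASSO selection of population-genetic determinants across genera (lambda by
10-fold cross-validation with the 1-SE rule), and the accuracy-FNR
correlation with a permutation p-value.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import pearsonr
from sklearn.linear_model import Lasso, LassoCV
from statsmodels.stats.multitest import multipletests

from ._seeds import child_seed, rng_for
from . import cnn as cnn_mod
from . import distances as dist_mod
from . import ood as ood_mod
from . import seqprep
from .dataset import GenusDataset, SplitDataset

__all__ = [
    "Condition",
    "ExperimentResult",
    "DEFAULT_WINDOWS",
    "CNN_METHODS",
    "DISTANCE_METHODS",
    "ALL_METHODS",
    "run_replicate",
    "run_grid",
    "condition_effects",
    "lasso_determinants",
    "correlate_accuracy_fnr",
]

DEFAULT_WINDOWS = {650: (0, 650), 300: (350, 650), 150: (350, 500)}
CNN_METHODS = ("cnn_msp", "cnn_energy", "cnn_maha", "cnn_vote")
DISTANCE_METHODS = ("dist_k2p", "dist_identity")
ALL_METHODS = CNN_METHODS + DISTANCE_METHODS
_METRIC_OF = {"dist_k2p": "k2p", "dist_identity": "identity"}


@dataclass(frozen=True)
class Condition:
    """One cell of the evaluation grid."""

    db_size: str = "Sufficient"
    noise: float = 0.0
    length: int = 650
    method: str = "dist_k2p"
    replicate: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.db_size not in ("Sufficient", "Small"):
            raise ValueError("db_size must be 'Sufficient' or 'Small'")
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ExperimentResult:
    """Per-replicate metrics for one condition."""

    dataset: str
    db_size: str
    noise: float
    length: int
    method: str
    replicate: int
    accuracy: float
    fnr_at_95: float
    fpr_on_id: float
    accuracy_upper: float
    fnr_lower: float
    n_train: int
    n_test: int
    n_ood: int
    runtime: float

    def as_dict(self) -> dict:
        return asdict(self)


class _StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _prepare_split(
    dataset: GenusDataset,
    db_size: str,
    length: int,
    replicate: int,
    seed: int,
    windows: Mapping[int, tuple[int, int]],
) -> SplitDataset:
    start, end = windows[length]
    win = seqprep.extract_window(dataset, start, end)
    stage_seed = int(child_seed(seed, db_size, length, replicate).generate_state(1)[0] % (2**31))
    if db_size == "Small":
        win = seqprep.make_small(win, seed=stage_seed)
    return seqprep.train_test_split_id(win, train_frac=0.7, seed=stage_seed)


def _noisy(records, noise: float, seed: int, mode: str):
    if noise == 0.0 or not records:
        return list(records)
    ds = GenusDataset(records, validate=False)
    return seqprep.inject_noise(ds, rate=noise, seed=seed, mode=mode).records


def _evaluate_bundle(
    dataset_name: str,
    split: SplitDataset,
    db_size: str,
    length: int,
    replicate: int,
    noise_levels: Sequence[float],
    methods: Sequence[str],
    seed: int,
    q: float = 0.95,
    cnn_kwargs: Mapping | None = None,
    noise_mode: str = "bernoulli",
) -> list[ExperimentResult]:
    """Evaluate all requested methods/noise levels on one prepared split.

    The CNN is trained once per bundle (noise touches only test material, so
    training is shared across noise levels and across the CNN score types).
    """
    cnn_kwargs = dict(cnn_kwargs or {})
    bounds = dist_mod.perfect_bounds(split)
    truth_id = np.array([r.species for r in split.test_id])
    results: list[ExperimentResult] = []

    cnn_methods = [m for m in methods if m in CNN_METHODS]
    dist_methods = [m for m in methods if m in DISTANCE_METHODS]

    model = maha_fit = None
    if cnn_methods:
        t0 = time.perf_counter()
        spec = cnn_mod.CnnSpec(
            n_classes=len(split.classes),
            input_length=split.alignment_length,
            **{k: v for k, v in cnn_kwargs.items() if k in (
                "conv_channels", "kernel_size", "conv_dropout", "fc_dropout", "fc_hidden"
            )},
        )
        train_seed = int(
            child_seed(seed, "cnn", db_size, length, replicate).generate_state(1)[0]
            % (2**31)
        )
        model = cnn_mod.build_model(spec, split.classes, seed=train_seed)
        train_kwargs = {
            k: v for k, v in cnn_kwargs.items()
            if k in ("epochs", "batch_size", "lr", "patience", "min_delta")
        }
        try:
            cnn_mod.train(model, split.train_id, **train_kwargs)
        except Exception as exc:  # noqa: BLE001
            raise _StageError("cnn-train", exc) from exc
        maha_fit = ood_mod.fit_mahalanobis(
            model.penultimate_features(split.train_id),
            [r.species for r in split.train_id],
        )
        cnn_train_time = time.perf_counter() - t0

    for noise in noise_levels:
        noise_seed = int(
            child_seed(seed, "noise", db_size, length, replicate, str(noise))
            .generate_state(1)[0] % (2**31)
        )
        test_noisy = _noisy(split.test_id, noise, noise_seed, noise_mode)
        ood_noisy = _noisy(split.ood, noise, noise_seed + 1, noise_mode)

        if cnn_methods:
            t0 = time.perf_counter()
            id_table = ood_mod.score_table(model, test_noisy, maha_fit)
            ood_table = ood_mod.score_table(model, ood_noisy, maha_fit) if ood_noisy else None
            acc = cnn_mod.accuracy(id_table["predicted_class"].to_numpy(), truth_id)
            thresholds = ood_mod.calibrate_thresholds(id_table, q=q)
            id_flags = {
                m: ood_mod.detect(id_table, thresholds[m]) for m in ood_mod.METHODS
            }
            ood_flags = {
                m: (ood_mod.detect(ood_table, thresholds[m]) if ood_table is not None else None)
                for m in ood_mod.METHODS
            }
            id_flags["vote"] = ood_mod.majority_vote(*id_flags.values())
            ood_flags["vote"] = (
                ood_mod.majority_vote(
                    ood_flags["msp"], ood_flags["energy"], ood_flags["mahalanobis"]
                )
                if ood_table is not None
                else None
            )
            name_of = {
                "cnn_msp": "msp", "cnn_energy": "energy",
                "cnn_maha": "mahalanobis", "cnn_vote": "vote",
            }
            elapsed = time.perf_counter() - t0
            for method in cnn_methods:
                key = name_of[method]
                fnr = (
                    ood_mod.fnr_at_95(ood_flags[key]) if ood_flags[key] is not None
                    else float("nan")
                )
                results.append(ExperimentResult(
                    dataset=dataset_name, db_size=db_size, noise=noise,
                    length=length, method=method, replicate=replicate,
                    accuracy=acc, fnr_at_95=fnr,
                    fpr_on_id=ood_mod.fpr_on_id(id_flags[key]),
                    accuracy_upper=bounds.accuracy_upper,
                    fnr_lower=bounds.fnr_lower,
                    n_train=len(split.train_id), n_test=len(split.test_id),
                    n_ood=len(split.ood),
                    runtime=cnn_train_time + elapsed,
                ))

        for method in dist_methods:
            t0 = time.perf_counter()
            metric = _METRIC_OF[method]
            # each query-by-reference matrix is computed once and reused for
            # 1NN assignment and for the best-close-match flags
            dist_test = dist_mod.pairwise_distances(test_noisy, split.train_id, metric)
            labels, nn_dist, _ = dist_mod._nn_from_matrix(dist_test, split.train_id)
            acc = cnn_mod.accuracy(labels, truth_id)
            thr = dist_mod.query_calibrated_thresholds(
                test_noisy, split.train_id, metric=metric, q=q
            )
            # a test sample is rejected when its NN distance exceeds the NN
            # species' cutoff, mirroring the score-based detectors
            id_ood_flags = nn_dist > np.array([thr[l] for l in labels])
            if ood_noisy:
                dist_ood = dist_mod.pairwise_distances(
                    ood_noisy, split.train_id, metric
                )
                ood_labels, ood_nn, _ = dist_mod._nn_from_matrix(
                    dist_ood, split.train_id
                )
                ood_is_ood = ood_nn > np.array([thr[l] for l in ood_labels])
                fnr = ood_mod.fnr_at_95(ood_is_ood)
            else:
                fnr = float("nan")
            results.append(ExperimentResult(
                dataset=dataset_name, db_size=db_size, noise=noise,
                length=length, method=method, replicate=replicate,
                accuracy=acc, fnr_at_95=fnr,
                fpr_on_id=ood_mod.fpr_on_id(id_ood_flags),
                accuracy_upper=bounds.accuracy_upper,
                fnr_lower=bounds.fnr_lower,
                n_train=len(split.train_id), n_test=len(split.test_id),
                n_ood=len(split.ood),
                runtime=time.perf_counter() - t0,
            ))
    return results


def run_replicate(
    dataset: GenusDataset,
    condition: Condition,
    windows: Mapping[int, tuple[int, int]] | None = None,
    q: float = 0.95,
    cnn_kwargs: Mapping | None = None,
    dataset_name: str = "dataset",
    noise_mode: str = "bernoulli",
) -> ExperimentResult:
    """Run one condition end to end on one dataset; fully seed-deterministic."""
    windows = dict(windows or DEFAULT_WINDOWS)
    split = _prepare_split(
        dataset, condition.db_size, condition.length, condition.replicate,
        condition.seed, windows,
    )
    rows = _evaluate_bundle(
        dataset_name, split, condition.db_size, condition.length,
        condition.replicate, [condition.noise], [condition.method],
        condition.seed, q=q, cnn_kwargs=cnn_kwargs, noise_mode=noise_mode,
    )
    return rows[0]


def run_grid(
    datasets: Mapping[str, GenusDataset],
    db_sizes: Sequence[str] = ("Sufficient", "Small"),
    noises: Sequence[float] = (0.0, 0.02),
    lengths: Sequence[int] = (650, 300, 150),
    methods: Sequence[str] = ALL_METHODS,
    replicates: int = 20,
    seed: int = 0,
    windows: Mapping[int, tuple[int, int]] | None = None,
    q: float = 0.95,
    cnn_kwargs: Mapping | None = None,
    existing: pd.DataFrame | None = None,
    popgen: bool = True,
    noise_mode: str = "bernoulli",
) -> pd.DataFrame:
    """Full factorial sweep; returns one tidy row per (condition, replicate).

    Training is shared across noise levels and CNN score types within a
    (dataset, db_size, length, replicate) cell. Cells already present in
    ``existing`` are skipped, making long sweeps resumable.
    """
    if not datasets:
        raise ValueError("no datasets given")
    windows = dict(windows or DEFAULT_WINDOWS)
    done = set()
    rows: list[dict] = []
    if existing is not None and len(existing):
        rows = existing.to_dict("records")
        done = {
            (r["dataset"], r["db_size"], r["noise"], r["length"], r["method"], r["replicate"])
            for r in rows
        }
    popgen_cache: dict[tuple[str, int], dict[str, float]] = {}
    for name, dataset in datasets.items():
        for length in lengths:
            if popgen:
                start, end = windows[length]
                win = seqprep.extract_window(dataset, start, end)
                popgen_cache[(name, length)] = dist_mod.popgen_metrics(win).as_dict()
            for db_size in db_sizes:
                for rep in range(1, replicates + 1):
                    todo_methods = [
                        m for m in methods
                        if any(
                            (name, db_size, n, length, m, rep) not in done
                            for n in noises
                        )
                    ]
                    if not todo_methods:
                        continue
                    split = _prepare_split(dataset, db_size, length, rep, seed, windows)
                    for res in _evaluate_bundle(
                        name, split, db_size, length, rep, list(noises),
                        todo_methods, seed, q=q, cnn_kwargs=cnn_kwargs,
                        noise_mode=noise_mode,
                    ):
                        key = (name, db_size, res.noise, length, res.method, rep)
                        if key in done:
                            continue
                        row = res.as_dict()
                        if popgen:
                            row.update(popgen_cache[(name, length)])
                        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

_FACTOR_TERMS = {
    "length": "C(length, Treatment(reference=650))",
    "db_size": "C(db_size, Treatment(reference='Sufficient'))",
    "noise": "C(noise, Treatment(reference=0.0))",
    "method": "C(method, Treatment(reference='dist_k2p'))",
}


def condition_effects(
    results: pd.DataFrame,
    response: str = "accuracy",
    factors: Sequence[str] = ("length", "db_size", "noise", "method"),
) -> pd.DataFrame:
    """OLS of a performance metric on dummy-coded design factors.

    Reference levels: 650 bp, Sufficient, no noise, dist_k2p. Returns the
    coefficient table with raw two-sided p-values and a Holm-adjusted column.
    """
    for factor in factors:
        levels = results[factor].nunique()
        if levels < 2:
            raise ValueError(
                f"factor {factor!r} has a single level; drop it from `factors`"
            )
    terms = [_FACTOR_TERMS[f] for f in factors]
    data = results.dropna(subset=[response])
    fit = smf.ols(f"{response} ~ " + " + ".join(terms), data=data).fit()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "std_err": fit.bse,
            "p_value": fit.pvalues,
        }
    )
    table["p_holm"] = multipletests(table["p_value"].to_numpy(), method="holm")[1]
    return table


DETERMINANTS = (
    "n_classes", "dw_avg", "dbt_avg", "dbt_min", "completeness",
    "samples_per_species",
)


def lasso_determinants(
    summaries: pd.DataFrame,
    response: str = "accuracy",
    predictors: Sequence[str] = DETERMINANTS,
    cv: int = 10,
    seed: int = 0,
    rule: str = "1se",
) -> pd.DataFrame:
    """LASSO variable selection of per-genus performance determinants.

    Predictors are standardized; the penalty is chosen by ``cv``-fold
    cross-validation with the 1-SE rule (largest lambda whose mean CV error
    is within one standard error of the minimum) or, with ``rule="min"``,
    at the CV-error minimum (denser solutions; useful when few genera make
    the 1-SE band very wide). Coefficients are reported on the original
    predictor scale; dropped variables carry a zero coefficient and
    ``selected=False``.
    """
    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    if summaries.shape[0] < 8:
        raise ValueError("need at least 8 genus summaries for the LASSO")
    x = summaries.loc[:, list(predictors)].to_numpy(dtype=float)
    y = summaries[response].to_numpy(dtype=float)
    mu, sigma = x.mean(axis=0), x.std(axis=0)
    if np.any(sigma == 0):
        constant = [p for p, s in zip(predictors, sigma) if s == 0]
        raise ValueError(f"constant predictors: {constant}")
    xs = (x - mu) / sigma
    cv_fit = LassoCV(cv=cv, random_state=seed, alphas=100, max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv_fit.fit(xs, y)
    if rule == "min":
        alpha = float(cv_fit.alpha_)
    else:
        mse_mean = cv_fit.mse_path_.mean(axis=1)
        mse_se = cv_fit.mse_path_.std(axis=1, ddof=1) / np.sqrt(
            cv_fit.mse_path_.shape[1]
        )
        i_min = int(mse_mean.argmin())
        limit = mse_mean[i_min] + mse_se[i_min]
        candidates = np.where(mse_mean <= limit)[0]
        alphas = cv_fit.alphas_
        alpha = (
            float(alphas[candidates].max())
            if candidates.size
            else float(cv_fit.alpha_)
        )
    fit = Lasso(alpha=alpha, max_iter=50_000).fit(xs, y)
    coef_std = fit.coef_
    coef_orig = coef_std / sigma
    return pd.DataFrame(
        {
            "variable": list(predictors),
            "coef": coef_orig,
            "coef_standardized": coef_std,
            "selected": coef_std != 0.0,
        }
    ).set_index("variable")


def correlate_accuracy_fnr(
    results: pd.DataFrame,
    group: str = "dataset",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson r between per-dataset mean accuracy and mean FNR@95%.

    The p-value is a two-sided permutation test (seeded). Returns
    (nan, nan) when either summary is constant across datasets.
    """
    grouped = results.groupby(group)[["accuracy", "fnr_at_95"]].mean().dropna()
    acc = grouped["accuracy"].to_numpy()
    fnr = grouped["fnr_at_95"].to_numpy()
    if acc.size < 3 or np.allclose(acc, acc[0]) or np.allclose(fnr, fnr[0]):
        return float("nan"), float("nan")
    r = pearsonr(acc, fnr).statistic
    rng = rng_for(seed, "perm")
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(fnr)
        if abs(np.corrcoef(acc, perm)[0, 1]) >= abs(r) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return float(r), float(p)
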