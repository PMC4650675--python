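"""Resampling robustness comparison of PLSDA model variants.

The experiment re-draws the stratified 2:1 train/test split many times and,
on every replicate, evaluates up to three variants at a fixed latent-variable
count (26 in the study):

* ``baseline`` — PLSDA on all spectral features;
* ``scheme1``  — PLSDA on one fixed, pre-selected GA feature subset reused
  across all replicates;
* ``scheme2``  — PLSDA on a fresh GA-selected subset per replicate.

Each variant records calibration, internal-validation (LOO or k-fold) and
external-validation accuracy.  Summaries are medians with bootstrap
percentile confidence intervals of the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SpectraSet, stratified_split
from .ga import Chromosome, GAConfig, _stratified_fold_accuracy, run_ga
from .plsda import loo_cv, overall_accuracy, test_confusion, train_confusion

SCHEMES = ("baseline", "scheme1", "scheme2")

#: Reduced GA configuration used by desk-scale scheme-2 runs.
DESK_GA = dict(population_size=20, max_generations=10)


@dataclass
class ResampleResult:
    """Per-replicate accuracy records of the comparison experiment."""

    records: pd.DataFrame  # columns: replicate, scheme, calibration, loo, external
    n_replicates: int
    n_components: int
    seed: int

    def __post_init__(self) -> None:
        pct = self.records[["calibration", "loo", "external"]].to_numpy()
        if pct.size and not ((pct >= 0) & (pct <= 100)).all():
            raise ValueError("accuracy records outside [0, 100]")


def _evaluate(
    train: SpectraSet,
    test: SpectraSet,
    n_components: int,
    subset: Chromosome | None,
    cv_folds: int | None,
) -> dict[str, float]:
    feats = None if subset is None else subset.features
    cal = overall_accuracy(train_confusion(train, n_components, feats))
    if cv_folds is None:
        loo = overall_accuracy(loo_cv(train, n_components, feats))
    else:
        sub = train if feats is None else train.select_features(feats)
        loo = 100.0 * _stratified_fold_accuracy(sub, n_components, cv_folds)
    ext = overall_accuracy(test_confusion(train, test, n_components, feats))
    return {"calibration": cal, "loo": loo, "external": ext}


def run_comparison(
    spectra: SpectraSet,
    schemes: tuple[str, ...] = SCHEMES,
    n_replicates: int = 50,
    fixed_subset: Chromosome | None = None,
    ga_config: GAConfig | None = None,
    n_components: int = 26,
    seed: int = 0,
    cv_folds: int | None = None,
) -> ResampleResult:
    """Run the resampling experiment.

    Parameters
    ----------
    schemes : subset of ``("baseline", "scheme1", "scheme2")``
    fixed_subset : required when ``scheme1`` is requested; the same subset
        is used on every replicate (asserted).
    ga_config : GA settings for ``scheme2``; defaults to the reduced desk
        configuration (population 20, 10 generations) at ``n_components``.
    cv_folds : replace the exact LOO internal validation by stratified
        k-fold (also forwarded to the scheme-2 GA fitness) for large runs.
    seed : master seed; per-replicate split and GA seeds are spawned from
        it deterministically.
    """
    schemes = tuple(schemes)
    unknown = set(schemes) - set(SCHEMES)
    if unknown:
        raise ValueError(f"unknown scheme(s) {sorted(unknown)}; choose from {SCHEMES}")
    if "scheme1" in schemes and fixed_subset is None:
        raise ValueError("scheme1 requires a fixed_subset")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if ga_config is None:
        ga_config = GAConfig(n_components=n_components, cv_folds=cv_folds, **DESK_GA)

    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for r, ss in enumerate(child_seeds):
        split_seed, ga_seed = (int(s) % (2**31) for s in ss.generate_state(2))
        train, test = stratified_split(spectra, seed=split_seed)
        for scheme in schemes:
            if scheme == "baseline":
                subset = None
            elif scheme == "scheme1":
                subset = fixed_subset
            else:
                cfg = GAConfig(**{**ga_config.__dict__, "seed": ga_seed})
                subset = run_ga(train, cfg).best_subset
            rec = _evaluate(train, test, n_components, subset, cv_folds)
            rec.update(replicate=r, scheme=scheme,
                       n_features=spectra.n_features if subset is None else subset.size)
            rows.append(rec)
    records = pd.DataFrame(rows)
    return ResampleResult(records, n_replicates, n_components, seed)


def summarize(
    result: ResampleResult, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Median accuracy per scheme and metric with a 95% bootstrap CI.

    The interval is a percentile bootstrap of the *median* (the statistic
    reported by the study), not of the replicate distribution.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for scheme, grp in result.records.groupby("scheme", sort=False):
        for metric in ("calibration", "loo", "external"):
            x = grp[metric].to_numpy()
            boot = np.median(
                rng.choice(x, size=(n_boot, x.size), replace=True), axis=1
            )
            rows.append(
                {
                    "scheme": scheme,
                    "metric": metric,
                    "median": float(np.median(x)),
                    "ci_low": float(np.percentile(boot, 2.5)),
                    "ci_high": float(np.percentile(boot, 97.5)),
                }
            )
    return pd.DataFrame(rows)
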