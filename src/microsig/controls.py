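"""Label-permutation negative controls.

A control run reassigns each sample's label to a *different* sample (a
uniformly random non-identity permutation), destroying any true association
between attributes and classes while preserving the label multiset. The full
classifier ensemble is then evaluated on each randomized dataset; if learning
on the real data were genuine, the randomized grand mean must sit near the
chance level. Chance is defined as the empirical majority-class frequency
(0.5 for balanced two-class line labels, ~1/3 for balanced three-class
abundance labels), which stays meaningful for imbalanced discretizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from microsig import signature as sig
from microsig._seeds import child_seed
from microsig.containers import InputError
from microsig.exprlink import merge_rare_classes

log = logging.getLogger(__name__)


@dataclass
class ControlResult:
    n_randomizations: int
    per_run: list = field(default_factory=list)  # average accuracy per randomization
    grand_mean: float = float("nan")
    chance_level: float = float("nan")
    gap: float = float("nan")
    mc_se: float = float("nan")  # Monte-Carlo standard error of the grand mean


def permute_dataset(labels, seed: int):
    """Reassign labels by a random non-identity permutation of the samples.

    Returns ``(permuted_labels, permutation)`` where ``permutation[i]`` is the
    index whose label sample ``i`` received. Features are never touched.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise InputError("need at least 3 samples to permute")
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n)
        if not np.array_equal(perm, np.arange(n)):
            break
    permuted = y[perm]
    if isinstance(labels, pd.Series):
        permuted = pd.Series(permuted, index=labels.index, name=labels.name)
    return permuted, perm


def chance_level(labels) -> float:
    """Empirical majority-class frequency: the accuracy of always guessing it."""
    y = pd.Series(np.asarray(labels))
    return float(y.value_counts(normalize=True).max())


def run_control(
    X,
    labels,
    n_randomizations: int = 10,
    config: sig.MLConfig | None = None,
    seed: int = 0,
    merge_strat: bool = False,
) -> ControlResult:
    """Evaluate the ensemble on ``n_randomizations`` label-permuted datasets.

    ``seed`` is the *main analysis* seed: the control derives its own seed
    stream from it and never evaluates with the main seed itself (enforced
    here and logged), so control runs cannot silently reuse the analysis
    splits. ``merge_strat`` enables rare-class merging for fold construction
    (stage-2 abundance targets).
    """
    if n_randomizations < 1:
        raise InputError("n_randomizations must be >= 1")
    config = config or sig.MLConfig()
    base = child_seed(seed, "negative_control")
    if base == seed:  # astronomically unlikely; keep the guarantee absolute
        base += 1
    log.info("negative control: main seed %d -> control seed %d", seed, base)

    y = pd.Series(np.asarray(labels))
    per_run = []
    for i in range(n_randomizations):
        run_seed = child_seed(base, f"run{i}")
        permuted, _ = permute_dataset(y, run_seed)
        strat = merge_rare_classes(permuted, 2).to_numpy() if merge_strat else None
        res = sig.evaluate_ensemble(X, permuted.to_numpy(), config, run_seed, strat=strat)
        per_run.append(res.average_accuracy)

    grand = float(np.mean(per_run))
    chance = chance_level(y)
    se = float(np.std(per_run, ddof=1) / np.sqrt(len(per_run))) if len(per_run) > 1 else float("nan")
    return ControlResult(
        n_randomizations=n_randomizations,
        per_run=per_run,
        grand_mean=grand,
        chance_level=chance,
        gap=grand - chance,
        mc_se=se,
    )
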