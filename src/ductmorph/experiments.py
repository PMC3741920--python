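"""Reference phantom experiments.

Glue for the package's standard study design: generate a graded phantom
cohort, measure the per-image feature table on ground-truth objects, and
evaluate feature-set classifiers under the SVM protocol.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify
from .phantom import PhantomConfig, generate_cohort, grade_configs
from .pipeline import FeatureParams, features_from_truth

__all__ = ["cohort_feature_table", "evaluate_case"]


def cohort_feature_table(
    n_per_class: int = 80,
    seed: int = 0,
    configs: dict[str, PhantomConfig] | None = None,
    vary: bool = True,
    params: FeatureParams | None = None,
) -> pd.DataFrame:
    """Feature table of a labelled phantom cohort (truth-object measurement).

    Uses the per-grade reference conditions of :func:`grade_configs` unless
    ``configs`` overrides them; one row per image, with a ``label`` column.
    """
    params = params or FeatureParams()
    cohort = generate_cohort(
        n_per_class, configs or grade_configs(), seed=seed, vary=vary
    )
    rows = []
    for label, image, truth, _cfg in cohort:
        row = features_from_truth(image, truth, params)
        row["label"] = label
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_case(
    table: pd.DataFrame,
    case: str,
    set_symbol: str = "PDF",
    seed: int = 0,
    proto: classify.SvmProtocol | None = None,
    shuffle_labels: bool = False,
) -> classify.EvalResult:
    """Bootstrap SVM evaluation of one feature set on one diagnostic case.

    ``shuffle_labels=True`` permutes the class labels (seeded) — the
    chance-level control.
    """
    expt = classify.assemble_case(table, case, seed=seed)
    if shuffle_labels:
        rng = np.random.default_rng(seed + 1)
        expt["y"] = rng.permutation(expt["y"].to_numpy())
    datasets = classify.build_feature_sets(expt)
    proto = proto or classify.SvmProtocol(seed=seed)
    return classify.train_eval_bootstrap(datasets[set_symbol], proto)
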