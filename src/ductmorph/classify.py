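"""Feature-set composition, SVM bootstrap evaluation, ROC and ANOVA/LSD.

The evaluation protocol: for a labelled per-image feature table, build the
13 feature-set datasets, and for each run repeated stratified 60:40
train/test splits; on every training split an RBF soft-margin SVM is tuned
by 10-fold cross-validated grid search over C in {10^-1, 10^-0.5, ..., 10^4}
and gamma in {2^-5, 2^-4.5, ..., 2^0}, refit, and scored on the held-out
split.  Confusion counts, SN/SP/PPV/NPV/ACC and ROC/AUC are averaged over
the repetitions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classical import FEATURE_NAMES

__all__ = [
    "FeatureSetSpec",
    "FEATURE_SETS",
    "LabeledDataset",
    "SvmProtocol",
    "EvalResult",
    "AnovaResult",
    "build_feature_sets",
    "assemble_case",
    "confusion_metrics",
    "train_eval_bootstrap",
    "roc_auc",
    "anova_lsd",
]

_CLF = [f"Lumen_{n}" for n in FEATURE_NAMES]
_PLF = ["RMSAA", "TSAV", "AtypiaRatio", "#AtypiaRegions"]
_CEF = [f"EN_{n}" for n in FEATURE_NAMES]
_PEF = ["CytoplasmLength", "CytoplasmLength_SD"]
_CNF = [f"NEN_{n}" for n in FEATURE_NAMES]


@dataclass(frozen=True)
class FeatureSetSpec:
    symbol: str
    features: tuple[str, ...]

    @property
    def dimension(self) -> int:
        return len(self.features)


FEATURE_SETS: dict[str, FeatureSetSpec] = {
    sym: FeatureSetSpec(sym, tuple(feats))
    for sym, feats in {
        "CNF": _CNF,
        "CLF": _CLF,
        "PLF": _PLF,
        "ALF": _CLF + _PLF,
        "CEF": _CEF,
        "PEF": _PEF,
        "AEF": _CEF + _PEF,
        "CDF": _CLF + _CEF,
        "PDF": _PLF + _PEF,
        "ADF": _CLF + _CEF + _PLF + _PEF,
        "CTF": _CLF + _CEF + _CNF,
        "PTF": _PLF + _PEF + _CNF,
        "ATF": _CLF + _CEF + _PLF + _PEF + _CNF,
    }.items()
}


@dataclass
class LabeledDataset:
    X: np.ndarray
    y: np.ndarray          # in {-1, +1}
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X and y are inconsistent")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be -1 / +1")

    def __len__(self) -> int:
        return len(self.y)


def build_feature_sets(
    feature_table: pd.DataFrame, label_column: str = "y"
) -> dict[str, LabeledDataset]:
    """Slice a per-image feature table into the 13 feature-set datasets."""
    if label_column not in feature_table:
        raise KeyError(f"missing label column '{label_column}'")
    y = feature_table[label_column].to_numpy()
    out = {}
    for sym, spec in FEATURE_SETS.items():
        missing = [f for f in spec.features if f not in feature_table]
        if missing:
            raise KeyError(f"feature set {sym}: missing column '{missing[0]}'")
        out[sym] = LabeledDataset(
            feature_table[list(spec.features)].to_numpy(), y, spec.features
        )
    return out


def assemble_case(
    table: pd.DataFrame,
    case: str,
    seed: int = 0,
    label_column: str = "label",
) -> pd.DataFrame:
    """Build a binary experiment table from a 3-class feature table.

    ``normal-vs-pdac``: normal ducts are the negative class; the positive
    class is a stratified half-sample of the two carcinoma grades, balanced
    to the normal count.  ``g1-vs-g2``: grade 1 negative, grade 2 positive.
    Adds the numeric column ``y``.
    """
    rng = np.random.default_rng(seed)
    lab = table[label_column]
    if case == "normal-vs-pdac":
        neg = table[lab == "normal"]
        per_grade = len(neg) // 2
        parts = []
        for g in ("grade1", "grade2"):
            sub = table[lab == g]
            take = min(per_grade, len(sub))
            parts.append(sub.iloc[rng.permutation(len(sub))[:take]])
        pos = pd.concat(parts)
        out = pd.concat([neg.assign(y=-1), pos.assign(y=1)])
    elif case == "g1-vs-g2":
        out = pd.concat(
            [
                table[lab == "grade1"].assign(y=-1),
                table[lab == "grade2"].assign(y=1),
            ]
        )
    else:
        raise ValueError(f"unknown case '{case}'")
    return out.reset_index(drop=True)


def confusion_metrics(TP: float, FP: float, FN: float, TN: float) -> dict:
    """SN, SP, PPV, NPV and ACC in percent; None where a denominator is 0."""
    if min(TP, FP, FN, TN) < 0:
        raise ValueError("counts must be non-negative")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "SN": ratio(TP, TP + FN),
        "SP": ratio(TN, TN + FP),
        "PPV": ratio(TP, TP + FP),
        "NPV": ratio(TN, TN + FN),
        "ACC": ratio(TP + TN, TP + TN + FP + FN),
    }


@dataclass
class SvmProtocol:
    """The printed SVM evaluation protocol."""

    C_grid: tuple[float, ...] = tuple(10.0 ** (np.arange(-2, 9) / 2.0))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** (np.arange(-10, 1) / 2.0))
    cv_folds: int = 10
    train_fraction: float = 0.6
    reps: int = 10
    seed: int = 0
    standardize: bool = True
    resample: str = "split"  # "split" (repeated 60/40) | "bootstrap"


@dataclass
class EvalResult:
    per_rep: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    mean_roc: tuple[np.ndarray, np.ndarray]  # (fpr grid, averaged tpr)
    chosen_params: list[tuple[float, float]]


def _grid_search(X, y, proto: SvmProtocol, rng_seed: int) -> tuple[float, float]:
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    skf = StratifiedKFold(
        n_splits=proto.cv_folds, shuffle=True, random_state=rng_seed
    )
    folds = list(skf.split(X, y))
    best = (-np.inf, None, None)
    for C in sorted(proto.C_grid):
        for gamma in sorted(proto.gamma_grid):
            acc = np.mean(
                [
                    SVC(C=C, gamma=gamma, kernel="rbf")
                    .fit(X[tr], y[tr])
                    .score(X[te], y[te])
                    for tr, te in folds
                ]
            )
            if acc > best[0]:  # strict: ties keep smallest C, then gamma
                best = (acc, C, gamma)
    return best[1], best[2]


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC points and trapezoidal AUC from decision scores."""
    from sklearn.metrics import roc_curve

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    return (fpr, tpr), float(np.trapezoid(tpr, fpr))


def train_eval_bootstrap(D: LabeledDataset, proto: SvmProtocol) -> EvalResult:
    """Repeated stratified 60:40 evaluation of the grid-tuned RBF SVM."""
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if len(np.unique(D.y)) < 2:
        raise ValueError("training needs both classes")
    rng = np.random.default_rng(proto.seed)
    rows, params = [], []
    fpr_grid = np.linspace(0, 1, 101)
    tprs = []
    for rep in range(proto.reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        tr_idx, te_idx = _stratified_split(D.y, proto, rep_seed)
        Xtr, ytr = D.X[tr_idx], D.y[tr_idx]
        Xte, yte = D.X[te_idx], D.y[te_idx]
        if proto.standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        C, gamma = _grid_search(Xtr, ytr, proto, rep_seed)
        clf = SVC(C=C, gamma=gamma, kernel="rbf").fit(Xtr, ytr)
        pred = clf.predict(Xte)
        scores = clf.decision_function(Xte)
        TP = int(np.sum((pred == 1) & (yte == 1)))
        TN = int(np.sum((pred == -1) & (yte == -1)))
        FP = int(np.sum((pred == 1) & (yte == -1)))
        FN = int(np.sum((pred == -1) & (yte == 1)))
        row = {"TN": TN, "FP": FP, "FN": FN, "TP": TP}
        row.update(confusion_metrics(TP, FP, FN, TN))
        (fpr, tpr), auc = roc_auc(scores, yte)
        row["AUC"] = auc
        rows.append(row)
        params.append((C, gamma))
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    per_rep = pd.DataFrame(rows)
    return EvalResult(
        per_rep=per_rep,
        mean=per_rep.mean(),
        sd=per_rep.std(ddof=1),
        mean_roc=(fpr_grid, np.mean(tprs, axis=0)),
        chosen_params=params,
    )


def _stratified_split(y, proto: SvmProtocol, seed: int):
    rng = np.random.default_rng(seed)
    tr, te = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if proto.resample == "bootstrap":
            n_tr = int(round(proto.train_fraction * len(idx)))
            tr.extend(rng.choice(idx, size=n_tr, replace=True))
            te.extend(np.setdiff1d(idx, tr))
        else:
            perm = rng.permutation(idx)
            n_tr = int(round(proto.train_fraction * len(idx)))
            tr.extend(perm[:n_tr])
            te.extend(perm[n_tr:])
    return np.array(sorted(tr)), np.array(sorted(te))


@dataclass
class AnovaResult:
    table: pd.DataFrame          # per feature: F, df, reject, LSD, pair diffs
    alpha: float
    group_names: tuple[str, ...]
    group_stats: pd.DataFrame = field(default=None)


def anova_lsd(
    features: pd.DataFrame,
    groups: np.ndarray,
    alpha: float = 0.01,
    ci_level: float = 0.95,
) -> AnovaResult:
    """One-way ANOVA per feature with Fisher-LSD post-hoc pairwise tests.

    For features whose F statistic exceeds the critical value at ``alpha``,
    LSD = t_{1-alpha/2, df_W} * sqrt(MS_W * (1/n_a + 1/n_b)) and a pair of
    group means differs when |mean_a - mean_b| > LSD.
    """
    groups = np.asarray(groups)
    names = tuple(sorted(pd.unique(groups)))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    k = len(names)
    rows, stat_rows = [], []
    for col in features.columns:
        samples = [features[col][groups == g].to_numpy(dtype=float) for g in names]
        ns = np.array([len(s) for s in samples])
        if (ns < 2).any():
            raise ValueError("need at least 2 samples per group")
        means = np.array([s.mean() for s in samples])
        N = ns.sum()
        grand = np.concatenate(samples).mean()
        ssb = float(np.sum(ns * (means - grand) ** 2))
        ssw = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
        df_b, df_w = k - 1, N - k
        msw = ssw / df_w
        F = 0.0 if ssw == 0 and ssb == 0 else (
            np.inf if msw == 0 else (ssb / df_b) / msw
        )
        f_crit = stats.f.ppf(1 - alpha, df_b, df_w)
        reject = bool(F > f_crit)
        t_crit = stats.t.ppf(1 - alpha / 2, df_w)
        t_ci = stats.t.ppf(0.5 + ci_level / 2, df_w)
        row = {"feature": col, "F": F, "df_between": df_b, "df_within": df_w,
               "reject": reject}
        for i, gi in enumerate(names):
            stat_rows.append(
                {"feature": col, "group": gi, "mean": means[i],
                 "ci_half_width": t_ci * np.sqrt(msw / ns[i])}
            )
        for i in range(k):
            for j in range(i + 1, k):
                pair = f"{names[i]}|{names[j]}"
                if reject:
                    lsd = t_crit * np.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
                    diff = abs(means[i] - means[j])
                    row[f"diff {pair}"] = diff
                    row[f"LSD {pair}"] = lsd
                    row[f"sig {pair}"] = bool(diff > lsd)
                else:
                    row[f"diff {pair}"] = np.nan
                    row[f"LSD {pair}"] = np.nan
                    row[f"sig {pair}"] = False
        rows.append(row)
    return AnovaResult(
        table=pd.DataFrame(rows).set_index("feature"),
        alpha=alpha,
        group_names=names,
        group_stats=pd.DataFrame(stat_rows),
    )
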