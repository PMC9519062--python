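"""Derived environmental variables and linear discriminant characterisation.

Derived quantities follow standard limnological conventions: dissolved
inorganic nitrogen is the sum of nitrate, nitrite and ammonium; dissolved
organic N and P are obtained by difference from the measured totals; the
light extinction coefficient is estimated from Secchi depth as
``k = 1.7 / z_sd`` and relative irradiance at depth z as ``exp(-k z)``.

The cluster environments are characterised (not predicted) by Fisher linear
discriminant analysis on all declared variables — no variable selection —
with every variable except pH and the stoichiometric ratios log-transformed
to reduce skewness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

logger = logging.getLogger(__name__)

EXTINCTION_FACTOR = 1.7  # k = 1.7 / Secchi depth

#: columns that must be present before derivation, with the derived outputs
REQUIRED_FOR = {
    "DIN": ("NO3", "NO2", "NH4"),
    "DON": ("TN", "NO3", "NO2", "NH4"),
    "DOP": ("TDP", "SRP"),
    "C_P_ratio": ("PC", "PP"),
    "N_P_ratio": ("PN", "PP"),
    "k_ext": ("z_sd",),
    "I_rel": ("z_sd", "depth_m"),
}

#: raw columns that are concentrations and must be non-negative
CONCENTRATION_COLS = (
    "O2", "Chla", "NO3", "NO2", "NH4", "TN", "TDP", "SRP",
    "DRSi", "SO4", "DOC", "CO2", "PC", "PN", "PP",
)

RATIO_SUFFIX = "_ratio"
LOG_EXEMPT = ("pH",)


@dataclass
class LdaResult:
    """Fisher discriminant axes for the cluster environments.

    ``axes`` holds unit-norm per-variable weight vectors (variables x axes);
    ``sample_scores`` are the projections of the (transformed, centered)
    samples; ``var_significant`` flags variables whose one-way ANOVA across
    clusters is significant, as reported alongside the discriminant fit.
    """

    axes: np.ndarray
    sample_scores: np.ndarray
    class_means: np.ndarray
    eigenvalues: np.ndarray
    variables: list[str]
    classes: np.ndarray
    var_significant: np.ndarray
    var_p: np.ndarray


def derive_env(raw: pd.DataFrame, derived: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Add derived variables (DIN, DON, DOP, C:P, N:P, k_ext, I_rel).

    ``derived=None`` computes every quantity whose inputs are all present,
    silently skipping the rest; passing an explicit tuple raises a named
    error for any missing input column.
    """
    df = raw.copy()
    for col in CONCENTRATION_COLS:
        if col in df.columns and (df[col] < 0).any():
            raise ValueError(f"negative concentration in column {col!r}")
    if "z_sd" in df.columns and (df["z_sd"] <= 0).any():
        raise ValueError("z_sd must be positive")

    targets = REQUIRED_FOR if derived is None else {d: REQUIRED_FOR[d] for d in derived}
    for name, needs in targets.items():
        missing = sorted(set(needs) - set(df.columns))
        if missing:
            if derived is None:
                continue
            raise KeyError(f"deriving {name} requires missing column(s) {missing}")
        if name == "DIN":
            df["DIN"] = df["NO3"] + df["NO2"] + df["NH4"]
        elif name == "DON":
            df["DON"] = df["TN"] - (df["NO3"] + df["NO2"] + df["NH4"])
        elif name == "DOP":
            df["DOP"] = df["TDP"] - df["SRP"]
        elif name == "C_P_ratio":
            df["C_P_ratio"] = df["PC"] / df["PP"]
        elif name == "N_P_ratio":
            df["N_P_ratio"] = df["PN"] / df["PP"]
        elif name == "k_ext":
            df["k_ext"] = EXTINCTION_FACTOR / df["z_sd"]
        elif name == "I_rel":
            df["I_rel"] = np.exp(-(EXTINCTION_FACTOR / df["z_sd"]) * df["depth_m"])
    return df


def _default_variables(env: pd.DataFrame) -> list[str]:
    return [
        c for c in env.columns
        if c not in ("sample_id", "date", "depth_m", "ice_cover", "truth_label")
        and np.issubdtype(env[c].dtype, np.number)
    ]


def _log_transform(
    X: np.ndarray, names: list[str], deltas: dict[str, float] | None = None
) -> tuple[np.ndarray, dict[str, float]]:
    """log(x + delta) for each non-exempt variable, delta = half the smallest
    positive observed value (admits zeros); pH and *_ratio columns pass
    through untouched.  Pass precomputed ``deltas`` to transform held-out
    data consistently with a training fit."""
    out = X.astype(float).copy()
    used: dict[str, float] = {}
    for j, name in enumerate(names):
        if name in LOG_EXEMPT or name.endswith(RATIO_SUFFIX):
            continue
        col = out[:, j]
        if deltas is None:
            positive = col[col > 0]
            delta = 0.5 * positive.min() if positive.size else 1.0
        else:
            delta = deltas[name]
        used[name] = delta
        out[:, j] = np.log(col + delta)
    return out, used


def lda_clusters(
    env: pd.DataFrame,
    clusters: np.ndarray,
    log_transform: bool = True,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> LdaResult:
    """Fisher LDA of the environmental conditions against cluster labels.

    Solves the generalized eigenproblem of between-class vs pooled
    within-class scatter; a singular within-class scatter is ridge-
    regularised with a logged epsilon.  All declared variables enter — the
    aim is characterisation of the clusters' environments, so overfitting is
    accepted by design.
    """
    clusters = np.asarray(clusters)
    if variables is None:
        variables = _default_variables(env)
    X = env[variables].to_numpy(dtype=float)
    if X.shape[0] != clusters.size:
        raise ValueError("env rows and cluster labels are misaligned")
    classes = np.unique(clusters)
    if classes.size < 2:
        raise ValueError("LDA needs at least two clusters")
    if log_transform:
        X, _ = _log_transform(X, variables)

    grand = X.mean(axis=0)
    p = X.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[clusters == c]
        mu = Xc.mean(axis=0)
        d = Xc - mu
        Sw += d.T @ d
        m = (mu - grand)[:, None]
        Sb += Xc.shape[0] * (m @ m.T)

    eps = 0.0
    base = np.trace(Sw) / p if np.trace(Sw) > 0 else 1.0
    for attempt in range(12):
        try:
            evals, evecs = linalg.eigh(Sb, Sw + eps * np.eye(p))
            break
        except linalg.LinAlgError:
            eps = base * 10.0 ** (-8 + attempt)
            logger.info("within-class scatter singular; ridge eps=%.3g", eps)
    else:  # pragma: no cover - last resort
        raise linalg.LinAlgError("within-class scatter could not be regularised")

    order = np.argsort(evals)[::-1]
    n_axes = min(classes.size - 1, p)
    evals = evals[order][:n_axes]
    W = evecs[:, order][:, :n_axes]
    W = W / np.linalg.norm(W, axis=0)
    for a in range(n_axes):  # sign determinism
        i = int(np.argmax(np.abs(W[:, a])))
        if W[i, a] < 0:
            W[:, a] *= -1.0

    scores = (X - grand) @ W
    class_means = np.vstack([scores[clusters == c].mean(axis=0) for c in classes])

    var_p = np.array(
        [stats.f_oneway(*(X[clusters == c, j] for c in classes)).pvalue for j in range(p)]
    )
    var_p = np.nan_to_num(var_p, nan=1.0)
    return LdaResult(
        axes=W,
        sample_scores=scores,
        class_means=class_means,
        eigenvalues=evals,
        variables=list(variables),
        classes=classes,
        var_significant=var_p < alpha,
        var_p=var_p,
    )


def _predict(scores_train, labels_train, scores_test, classes):
    means = np.vstack([scores_train[labels_train == c].mean(axis=0) for c in classes])
    d = ((scores_test[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    return classes[d.argmin(axis=1)]


def loo_accuracy(
    env: pd.DataFrame,
    clusters: np.ndarray,
    log_transform: bool = True,
    variables: list[str] | None = None,
) -> float:
    """Leave-one-out reclassification accuracy: refit the LDA without each
    sample and classify it by the nearest class centroid in discriminant
    space.  Log-transform offsets are taken from the training fold."""
    clusters = np.asarray(clusters)
    if variables is None:
        variables = _default_variables(env)
    Xall = env[variables].to_numpy(dtype=float)
    n = Xall.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(clusters[mask]).size < 2:
            continue
        Xtr, Xte = Xall[mask], Xall[i : i + 1]
        if log_transform:
            Xtr, deltas = _log_transform(Xtr, variables)
            Xte, _ = _log_transform(Xte, variables, deltas=deltas)
        train = pd.DataFrame(Xtr, columns=variables)
        res = lda_clusters(train, clusters[mask], log_transform=False,
                           variables=variables)
        grand = Xtr.mean(axis=0)
        score = (Xte - grand) @ res.axes
        pred = _predict(res.sample_scores, clusters[mask], score, res.classes)
        correct += int(pred[0] == clusters[i])
    return correct / n
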