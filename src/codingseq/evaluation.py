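"""Cross-validated comparison of classifiers and sequence representations.

Performance is the percentage of correctly classified ORFs in the held-out
fold of a 10-fold cross-validation, together with sensitivity (ability to
identify Positives) and specificity (ability to identify Negatives).  To
compare the two methods (IMM, CPPLS) and three representations (dna, codon,
protein) across species in one analysis, fold-averaged performances are
arcsine-square-root transformed, z = arcsin(sqrt(y/100)), and fed to a
balanced mixed-effect ANOVA

    z_ijk = mu + alpha_i + beta_j + (alpha beta)_ij + s_k + e_ijk

with fixed method and representation effects, their interaction, a random
species effect s_k ~ N(0, sigma_s^2) and residual e_ijk ~ N(0, sigma_e^2).
Pairwise mean comparisons use Tukey's studentized-range test; variance
comparisons between two performance samples use a two-sided F-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alphabets import ALPHABETS, DEFAULT_ORDERS, LabeledOrf, feature_matrix
from . import cppls as cppls_mod
from . import imm as imm_mod
from .dataset import split_folds

__all__ = [
    "PerformanceRecord",
    "AnovaResult",
    "run_cv",
    "score_densities",
    "transform_performance",
    "mixed_anova",
    "tukey_hsd",
    "variance_f_test",
]

log = logging.getLogger(__name__)

PERFORMANCE_COLUMNS = [
    "species", "method", "representation", "fold",
    "percent_correct", "sensitivity", "specificity",
]


@dataclass
class PerformanceRecord:
    species: str
    method: str
    representation: str
    fold: int
    percent_correct: float
    sensitivity: float
    specificity: float


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    correct = y_true == y_pred
    pos, neg = y_true == 1, y_true == -1
    pct = 100.0 * correct.mean()
    sens = 100.0 * correct[pos].mean() if pos.any() else np.nan
    spec = 100.0 * correct[neg].mean() if neg.any() else np.nan
    return pct, sens, spec


def run_cv(
    data: list[LabeledOrf],
    method: str,
    representation: str,
    folds: int = 10,
    seed: int = 0,
    K: int | None = None,
    species: str | None = None,
    A_max: int = cppls_mod.DEFAULT_A_MAX,
    gamma_grid: np.ndarray | None = None,
    collect_scores: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """K-fold cross-validated performance of one method x representation.

    Each fold trains on the remaining folds and is scored on percent
    correct, sensitivity and specificity.  ``collect_scores`` additionally
    returns the held-out decision scores (IMM: Positive minus Negative
    log-probability; CPPLS: fitted value) for density diagnostics.
    """
    if method not in ("imm", "cppls"):
        raise ValueError(f"unknown method {method!r}")
    alphabet = ALPHABETS[representation]
    if K is None:
        K = DEFAULT_ORDERS[representation]
    if species is None:
        species = data[0].species_id if data else "?"
    labels = np.array([o.label for o in data])
    assignment = split_folds(data, folds=folds, seed=seed)
    records = []
    scored = []
    for fold in range(folds):
        test_mask = assignment == fold
        train = [o for o, m in zip(data, test_mask) if not m]
        test = [o for o, m in zip(data, test_mask) if m]
        y_test = labels[test_mask]
        if method == "imm":
            model = imm_mod.fit_imm(
                [o for o in train if o.label == 1],
                [o for o in train if o.label == -1],
                alphabet, K,
            )
            sc = np.array(
                [np.subtract(*imm_mod.score(model, o)) for o in test]
            )
            y_pred = np.where(sc > 0, 1, -1)
        else:
            fm_train = feature_matrix(train, alphabet, K)
            fm_test = feature_matrix(test, alphabet, K)
            y_train = np.array([o.label for o in train], dtype=float)
            model = cppls_mod.fit(
                fm_train.values, y_train, A_max=A_max,
                gamma_grid=gamma_grid, seed=seed,
            )
            sc = cppls_mod.predict_score(model, fm_test.values)
            y_pred = np.where(sc > 0, 1, -1)
        pct, sens, spec = _metrics(y_test, y_pred)
        records.append(
            PerformanceRecord(species, method, representation, fold, pct, sens, spec)
        )
        if collect_scores:
            for o, s, yt in zip(test, sc, y_test):
                scored.append({"orf_id": o.orf_id, "fold": fold,
                               "score": float(s), "label": int(yt)})
    table = pd.DataFrame([r.__dict__ for r in records])[PERFORMANCE_COLUMNS]
    if collect_scores:
        return table, pd.DataFrame(scored)
    return table


def score_densities(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-class score samples and the overlap of their kernel densities.

    The overlap coefficient is the shared area under the two Gaussian kernel
    density estimates (1 for identical samples, 0 for disjoint supports);
    large overlap means the classifier's scores barely separate the classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg, _kde_overlap(pos, neg)


def _kde_overlap(a: np.ndarray, b: np.ndarray, grid_size: int = 2048) -> float:
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    sd_a, sd_b = np.std(a), np.std(b)
    if sd_a == 0 or sd_b == 0:
        # degenerate (constant) sample: treat as a point mass
        return 0.0 if not np.array_equal(np.unique(a), np.unique(b)) else 1.0
    kde_a, kde_b = stats.gaussian_kde(a), stats.gaussian_kde(b)
    lo = min(a.min(), b.min()) - 3 * max(sd_a, sd_b)
    hi = max(a.max(), b.max()) + 3 * max(sd_a, sd_b)
    grid = np.linspace(lo, hi, grid_size)
    da, db = kde_a(grid), kde_b(grid)
    return float(np.trapezoid(np.minimum(da, db), grid))


def transform_performance(y: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing arcsine transform z = arcsin(sqrt(y/100)).

    Maps percentages in [0, 100] to radians in [0, pi/2]; the binomial
    sampling variance of z is approximately constant across performance
    levels, which the ANOVA assumes.
    """
    arr = np.asarray(y, dtype=float)
    if (arr < 0).any() or (arr > 100).any():
        raise ValueError("performance must lie in [0, 100]")
    z = np.arcsin(np.sqrt(arr / 100.0))
    return float(z) if np.ndim(y) == 0 else z


@dataclass
class AnovaResult:
    """Balanced mixed-effect ANOVA table plus variance components."""

    table: pd.DataFrame  # rows Method, Sequence, Method:Sequence, Species, Residual
    sigma_species: float
    sigma_residual: float
    n_species: int

    def __str__(self) -> str:
        return self.table.to_string()


def mixed_anova(cells: pd.DataFrame, value: str = "z") -> AnovaResult:
    """Balanced mixed-effect ANOVA of transformed performance.

    ``cells`` holds exactly one value per (method, representation, species)
    cell of a complete 2 x 3 x S design.  Classical balanced-design sums of
    squares are computed from marginal means; every F statistic (including
    the random species term) is taken against the residual mean square, and
    the variance components follow from the method of moments:
    sigma_e^2 = MS_residual, sigma_s^2 = max(0, (MS_species - MS_residual)/6).
    """
    required = {"method", "representation", "species", value}
    if not required <= set(cells.columns):
        raise ValueError(f"cells must have columns {sorted(required)}")
    methods = sorted(cells["method"].unique())
    reps = sorted(cells["representation"].unique())
    species = sorted(cells["species"].unique())
    I, J, S = len(methods), len(reps), len(species)
    if I != 2 or J != 3:
        raise ValueError("design must have 2 methods and 3 representations")
    if S < 2:
        raise ValueError("at least 2 species required")
    counts = cells.groupby(["method", "representation", "species"])[value].count()
    if len(counts) != I * J * S or (counts != 1).any():
        raise ValueError("design must be complete and balanced with one value per cell")

    z = cells.set_index(["method", "representation", "species"])[value]
    arr = np.empty((I, J, S))
    for i, m in enumerate(methods):
        for j, r in enumerate(reps):
            for k, s in enumerate(species):
                arr[i, j, k] = z.loc[(m, r, s)]

    grand = arr.mean()
    m_i = arr.mean(axis=(1, 2))
    m_j = arr.mean(axis=(0, 2))
    m_k = arr.mean(axis=(0, 1))
    m_ij = arr.mean(axis=2)

    ss_method = J * S * ((m_i - grand) ** 2).sum()
    ss_seq = I * S * ((m_j - grand) ** 2).sum()
    ss_int = S * ((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2).sum()
    ss_species = I * J * ((m_k - grand) ** 2).sum()
    ss_total = ((arr - grand) ** 2).sum()
    ss_resid = ss_total - ss_method - ss_seq - ss_int - ss_species

    df_method, df_seq, df_int = I - 1, J - 1, (I - 1) * (J - 1)
    df_species = S - 1
    df_resid = (I * J * S - 1) - df_method - df_seq - df_int - df_species
    ms_resid = ss_resid / df_resid

    rows = []
    for name, ss, df in [
        ("Method", ss_method, df_method),
        ("Sequence", ss_seq, df_seq),
        ("Method:Sequence", ss_int, df_int),
        ("Species", ss_species, df_species),
    ]:
        ms = ss / df
        F = ms / ms_resid if ms_resid > 0 else np.nan
        p = float(stats.f.sf(F, df, df_resid)) if np.isfinite(F) else np.nan
        rows.append(
            {"term": name, "sum_sq": ss, "df": df, "mean_sq": ms, "F": F, "p": p}
        )
    rows.append(
        {"term": "Residual", "sum_sq": ss_resid, "df": df_resid,
         "mean_sq": ms_resid, "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows).set_index("term")
    ms_species = ss_species / df_species
    sigma_s2 = max(0.0, (ms_species - ms_resid) / (I * J))
    return AnovaResult(
        table=table,
        sigma_species=float(np.sqrt(sigma_s2)),
        sigma_residual=float(np.sqrt(ms_resid)),
        n_species=S,
    )


def tukey_hsd(
    means: dict[str, float],
    ms_residual: float,
    df_residual: int,
    n_per_group: int,
) -> pd.DataFrame:
    """Tukey studentized-range comparisons of balanced factor-level means.

    q = |mean_a - mean_b| / sqrt(MS_residual / n); the adjusted p-value is
    the survival function of the studentized range with k groups and the
    residual degrees of freedom.
    """
    if df_residual < 1:
        raise ValueError("df_residual must be >= 1")
    if ms_residual <= 0:
        raise ValueError("MS_residual must be positive")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    k = len(means)
    if k < 2:
        raise ValueError("need at least two groups")
    se = np.sqrt(ms_residual / n_per_group)
    names = sorted(means)
    rows = []
    for a_idx, a in enumerate(names):
        for b in names[a_idx + 1 :]:
            diff = means[a] - means[b]
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_residual))
            rows.append({"group_a": a, "group_b": b, "diff": diff,
                         "q": q, "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)


def variance_f_test(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided F-test for equality of two variances.

    F = var_a / var_b with (n_a - 1, n_b - 1) degrees of freedom; swapping
    the samples inverts F and leaves p unchanged.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator sample")
    F = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.sf(F, dfa, dfb), stats.f.cdf(F, dfa, dfb))
    return float(F), float(min(1.0, p))
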