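"""Statistical comparison battery for bruise indices.

Four families of tests compare the pipeline's outputs the way fruit-
quality studies do:

* one-way MANOVA (Wilks' lambda, Rao's F approximation) on tissue
  spectra, all bands as variables — are healthy and bruised spectra
  separable as multivariate observations?
* Kruskal-Wallis with Dunn-type joint-rank multiple comparisons and a
  compact letter display — do treatments differ in a bruise index whose
  distribution is not normal?
* ordinary least-squares regression with R^2 and RMSE — does the image
  index agree with human slice grading?
* one-way ANOVA on per-replicate bruised-fruit counts — do two calling
  methods disagree in how many fruit they flag?

All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "LetterDisplay",
    "manova_spectra",
    "kruskal_wallis",
    "kw_multcomp",
    "linreg_index_vs_human",
    "anova_counts",
]

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    df: tuple[float, ...]
    pvalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.pvalue < ALPHA


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: groups sharing a letter do not differ."""

    letters: dict[str, str]

    def __post_init__(self) -> None:
        if any(not v for v in self.letters.values()):
            raise ValueError("every group needs at least one letter")


def manova_spectra(groups: list[np.ndarray]) -> TestResult:
    """One-way MANOVA on spectra matrices via Wilks' lambda.

    ``groups`` holds one (n_i x p) matrix per group; all bands are
    response variables.  Wilks' lambda = det(W) / det(W + B) with W the
    pooled within-group and B the between-group scatter; the p-value
    uses Rao's F approximation.  Requires total n - #groups > p so the
    within scatter is full rank — with 141 bands and too few pixels,
    subsample bands rather than regularize silently.
    """
    if len(groups) < 2:
        raise ValueError("MANOVA needs at least two groups")
    mats = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    p = mats[0].shape[1]
    if any(m.shape[1] != p for m in mats):
        raise ValueError("all groups must have the same number of variables")
    ns = np.array([m.shape[0] for m in mats])
    n, g = int(ns.sum()), len(mats)
    if n - g <= p:
        raise ValueError(
            f"within-group df (n - g = {n - g}) must exceed {p} variables; "
            "subsample bands or pool more pixels"
        )
    grand = np.vstack(mats).mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for m in mats:
        mu = m.mean(axis=0)
        c = m - mu
        W += c.T @ c
        d = (mu - grand)[:, None]
        B += m.shape[0] * (d @ d.T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("within-group scatter is singular; reduce variables")
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation for one-way Wilks' lambda
    dh = g - 1
    t = np.sqrt((p**2 * dh**2 - 4) / (p**2 + dh**2 - 5)) if p**2 + dh**2 - 5 > 0 else 1.0
    df1 = p * dh
    df2 = (n - g - (p - dh + 1) / 2.0) * t - (p * dh - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(sps.f.sf(F, df1, df2)) if lam < 1.0 else 1.0
    return TestResult("manova_wilks", lam, (float(df1), float(df2)), pval)


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H on joint ranks with tie correction."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one observation")
    if np.ptp(np.concatenate(arrays)) == 0:
        raise ValueError("all observations identical; H is undefined")
    H, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(H), (float(len(arrays) - 1),), float(p))


def _dunn_pvalues(arrays: list[np.ndarray]) -> np.ndarray:
    """Bonferroni-adjusted two-sided Dunn z-test p-values, pairwise."""
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    k = len(arrays)
    m = k * (k - 1) // 2
    pmat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)  # Bonferroni
        pmat[i, j] = pmat[j, i] = p
    return pmat


def kw_multcomp(
    groups: dict[str, np.ndarray] | list[np.ndarray], alpha: float = ALPHA
) -> LetterDisplay:
    """Dunn-type joint-rank pairwise comparisons -> compact letter display.

    Pairwise two-sided z-tests on mean joint ranks, Bonferroni-adjusted;
    letters are assembled by insertion over the non-significance graph,
    smallest group mean first, so monotone treatments read a, b, c, ...
    """
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        names = [str(i) for i in range(len(groups))]
        arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups for multiple comparisons")
    pmat = _dunn_pvalues(arrays)
    order = np.argsort([a.mean() for a in arrays])  # smallest mean first
    # letter groups = maximal sets of mutually non-different treatments,
    # built by insertion: try to add each treatment to existing letters
    letter_sets: list[set[int]] = []
    for idx in order:
        placed = False
        for s in letter_sets:
            if all(pmat[idx, j] >= alpha for j in s):
                s.add(int(idx))
                placed = True
        if not placed:
            letter_sets.append({int(idx)})
    # drop letter sets fully contained in another (absorbed by insertion)
    letter_sets = [
        s for s in letter_sets if not any(s < t for t in letter_sets if s is not t)
    ]
    letters = {name: "" for name in names}
    for letter, s in zip(string.ascii_lowercase, letter_sets):
        for idx in s:
            letters[names[idx]] += letter
    letters = {k: "".join(sorted(v)) for k, v in letters.items()}
    return LetterDisplay(letters)


def linreg_index_vs_human(
    x: np.ndarray, y: np.ndarray
) -> dict[str, float]:
    """OLS of bruise ratio (y) on human assessment (x).

    Returns slope, intercept, R^2 = 1 - SS_res/SS_tot and
    RMSE = sqrt(SS_res / n).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 points for regression")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    pred = res.slope * x + res.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": r2,
        "rmse": float(np.sqrt(ss_res / x.size)),
        "pvalue": float(res.pvalue),
    }


def anova_counts(counts_a: np.ndarray, counts_b: np.ndarray) -> TestResult:
    """One-way ANOVA comparing per-replicate bruised counts of two methods."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per method")
    df = (1.0, float(a.size + b.size - 2))
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            log.info("anova_counts: all counts identical; F = 0, p = 1")
            return TestResult("anova_counts", 0.0, df, 1.0)
        return TestResult("anova_counts", float("inf"), df, 0.0)
    F, p = sps.f_oneway(a, b)
    return TestResult("anova_counts", float(F), df, float(p))
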