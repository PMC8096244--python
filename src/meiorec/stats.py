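"""Tract-length summaries and the nonparametric tests of the study.

Pooled hDNA tract lengths are compared between genotypes with a two-sided
Mann–Whitney U test (exact enumeration for small untied samples, normal
approximation with tie and continuity corrections otherwise), short-tract
proportions with Fisher's exact test, and mass-spectrometry interactor
candidates are filtered with the fold-change / BH-adjusted p / peptide-count
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

EXACT_MAX_N = 8  # per-arm size up to which the exact U distribution is used


@dataclass(frozen=True)
class LengthSample:
    """Pooled tract lengths (bp) for one genotype and event-class filter."""

    genotype: str
    lengths: np.ndarray
    event_class: str = "all"  # all | CO | NCO
    n_meioses: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "lengths", arr)
        if self.n_meioses < 1:
            raise ParameterError("n_meioses must be >= 1")
        if arr.size and (arr <= 0).any():
            raise ParameterError("tract lengths must be positive")


@dataclass(frozen=True)
class Contingency2x2:
    """A 2x2 count table [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ParameterError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class MSRecord:
    """One protein from a label-free pulldown quantification."""

    protein: str
    fold_change: float
    adj_p: float
    peptides: int

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ParameterError("fold change must be positive")
        if not 0.0 <= self.adj_p <= 1.0:
            raise ParameterError("adjusted p-value must lie in [0, 1]")
        if self.peptides < 0:
            raise ParameterError("peptide count must be non-negative")


def summarize_lengths(sample: LengthSample) -> dict:
    """n, mean and median tract length in kb (rounded copies to 0.1 kb)."""
    if sample.lengths.size == 0:
        raise ParameterError("cannot summarize an empty length sample")
    mean_kb = float(np.mean(sample.lengths)) / 1000.0
    median_kb = float(np.median(sample.lengths)) / 1000.0
    return {
        "genotype": sample.genotype,
        "class": sample.event_class,
        "n": int(sample.lengths.size),
        "mean_kb": mean_kb,
        "median_kb": median_kb,
        "mean_kb_rounded": round(mean_kb, 1),
        "median_kb_rounded": round(median_kb, 1),
    }


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of the first sample, p).

    ``method='auto'`` uses the exact U distribution when both samples have at
    most 8 observations and there are no ties across the pooled data, and the
    normal approximation with tie and continuity corrections otherwise; the
    two branches can be forced with ``'exact'`` / ``'asymptotic'``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        use_exact = x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties
    elif method == "exact":
        use_exact = True
    elif method == "asymptotic":
        use_exact = False
    else:
        raise ParameterError(f"unknown method {method!r}")
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table: Contingency2x2) -> float:
    """Two-sided Fisher's exact p (sum of hypergeometric outcome
    probabilities no larger than the observed one).

    Degenerate margins (an empty row or column) give p = 1.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_filter(
    records: list[MSRecord],
    min_fold: float = 2.0,
    max_adj_p: float = 0.05,
    min_peptides: int = 3,
) -> list[MSRecord]:
    """Significantly enriched proteins from a tagged-vs-untagged pulldown.

    Keeps a protein iff fold change >= ``min_fold``, BH-adjusted p <
    ``max_adj_p`` and at least ``min_peptides`` distinct peptides.
    """
    return [
        r
        for r in records
        if r.fold_change >= min_fold and r.adj_p < max_adj_p and r.peptides >= min_peptides
    ]


def short_tract_fraction(
    sample: LengthSample, cutoff_bp: float = 300.0
) -> tuple[int, int, float]:
    """(k, n, k/n) of tracts strictly shorter than the cutoff."""
    if sample.lengths.size == 0:
        raise ParameterError("cannot compute a fraction of an empty sample")
    k = int((sample.lengths < cutoff_bp).sum())
    n = int(sample.lengths.size)
    return k, n, k / n


def short_tract_test(
    sample_a: LengthSample, sample_b: LengthSample, cutoff_bp: float = 300.0
) -> dict:
    """Compare short-tract proportions of two samples by Fisher's exact test."""
    ka, na, fa = short_tract_fraction(sample_a, cutoff_bp)
    kb, nb, fb = short_tract_fraction(sample_b, cutoff_bp)
    p = fisher_exact(Contingency2x2(ka, na - ka, kb, nb - kb))
    return {
        "frac_a": fa,
        "frac_b": fb,
        "pct_a": round(100 * fa),
        "pct_b": round(100 * fb),
        "p": p,
    }


def compare_samples(samples: list[LengthSample]) -> pd.DataFrame:
    """All pairwise Mann–Whitney comparisons of pooled length samples."""
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            a, b = samples[i], samples[j]
            u, p = mann_whitney_u(a.lengths, b.lengths)
            rows.append(
                {
                    "comparison": f"{a.genotype}[{a.event_class}] vs {b.genotype}[{b.event_class}]",
                    "n_a": a.lengths.size,
                    "n_b": b.lengths.size,
                    "U": u,
                    "p": p,
                }
            )
    return pd.DataFrame(rows, columns=["comparison", "n_a", "n_b", "U", "p"])
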