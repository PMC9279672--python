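"""Interregional Pearson correlation matrices and their group comparisons.

Functional connectivity is defined here as the Pearson product-moment
correlation, across subjects, between the c-Fos-positive cell counts of two
brain regions:

    r = S_xy / (S_x S_y)

with the population (1/n) form of covariance and standard deviation — the
1/n factors cancel, so r is identical under the sample convention. Each
pairwise correlation is tested against r = 0 with

    t = r * sqrt(n - 2) / sqrt(1 - r**2),   df = n - 2,

two-sided p from the Student t distribution. Group-level differences in
connectivity are assessed with Mann-Whitney U tests on correlation vectors
(the matrix upper triangle, or one region's row), Bonferroni-corrected where
per-region tests multiply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AtlasMismatchError",
    "CountTable",
    "CorrelationMatrix",
    "EdgeTest",
    "pearson_matrix",
    "edge_significance",
    "edge_table",
    "compare_all_correlations",
    "compare_region_correlations",
    "per_region_count_comparison",
    "plot_correlation_heatmap",
]


class AtlasMismatchError(ValueError):
    """Two inputs cover different region sets or orders."""


@dataclass
class CountTable:
    """Subjects x regions matrix of c-Fos-positive cell counts.

    ``values`` is a DataFrame indexed by subject id with one column per
    region, in atlas order. Counts are non-negative with no missing entries.
    """

    values: pd.DataFrame
    group: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("count table contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("count table contains negative values")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate region labels in count table")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.values.index)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def mean_counts(self) -> pd.Series:
        return self.values.mean(axis=0)

    # CSV contract: subject_id, group, then one column per region.

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.group)
        out.index.name = "subject_id"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path)
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise ValueError(f"{path}: count table CSV must have a {col!r} column")
        groups = df["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"{path}: expected one group per file, found {list(groups)}")
        values = df.drop(columns=["group"]).set_index("subject_id")
        bad = values.columns[~values.dtypes.map(pd.api.types.is_numeric_dtype)]
        if len(bad):
            raise ValueError(f"{path}: non-numeric region columns {list(bad)}")
        return cls(values=values, group=str(groups[0]))


@dataclass
class CorrelationMatrix:
    """Region x region Pearson matrix with the sample size that produced it.

    ``n`` is the number of rows (observations) of the source count table.
    Regions with zero variance have undefined correlations: their rows and
    columns are NaN and they are listed in ``undefined_regions``.
    """

    r: pd.DataFrame
    n: int
    group: str = ""
    undefined_regions: tuple[str, ...] = ()

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.r.columns)

    def offdiag_values(self, triangles: str = "upper") -> np.ndarray:
        """Off-diagonal correlations, each unordered pair once by default.

        ``triangles='both'`` returns every ordered pair (each r twice), an
        alternative reading of "entire correlation coefficients".
        Undefined (NaN) entries are dropped.
        """
        m = self.r.to_numpy()
        if triangles == "upper":
            vals = m[np.triu_indices_from(m, k=1)]
        elif triangles == "both":
            iu = np.triu_indices_from(m, k=1)
            vals = np.concatenate([m[iu], m.T[iu]])
        else:
            raise ValueError("triangles must be 'upper' or 'both'")
        return vals[~np.isnan(vals)]

    def region_values(self, region: str) -> np.ndarray:
        """Correlations of one region with every other region (length R-1)."""
        row = self.r.loc[region].drop(labels=[region]).to_numpy()
        return row[~np.isnan(row)]

    def to_csv(self, path: str | Path) -> None:
        self.r.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, n: int, group: str = "") -> "CorrelationMatrix":
        r = pd.read_csv(path, index_col=0)
        undef = tuple(c for c in r.columns if r[c].isna().all())
        return cls(r=r, n=n, group=group, undefined_regions=undef)


@dataclass(frozen=True)
class EdgeTest:
    """Significance test of one pairwise correlation against r = 0."""

    pair: tuple[str, str]
    r: float
    t: float
    df: int
    p: float


def pearson_matrix(table: CountTable) -> CorrelationMatrix:
    """All-pairs Pearson correlation matrix of a count table.

    Requires at least 3 subjects. Zero-variance regions (a region where every
    subject has the same count) are flagged as undefined rather than imputed:
    their entries are NaN and downstream edge testing skips them.
    """
    if table.n_subjects < 3:
        raise ValueError(
            f"need >= 3 subjects for correlations, got {table.n_subjects}"
        )
    x = table.values.to_numpy(dtype=float)
    sd = x.std(axis=0)
    undefined = tuple(np.asarray(table.regions)[sd == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(x, rowvar=False)
    m = np.asarray(m, dtype=float)
    m[sd == 0, :] = np.nan
    m[:, sd == 0] = np.nan
    np.clip(m, -1.0, 1.0, out=m)
    np.fill_diagonal(m, np.where(sd > 0, 1.0, np.nan))
    r = pd.DataFrame(m, index=table.regions, columns=table.regions)
    return CorrelationMatrix(
        r=r, n=table.n_subjects, group=table.group, undefined_regions=undefined
    )


def edge_significance(r: float, n: int, pair: tuple[str, str] = ("", "")) -> EdgeTest:
    """Two-sided t test of a single correlation coefficient against zero.

    |r| = 1 (e.g. a duplicated region) gets p = 0 by convention, matching the
    limit of the t statistic.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 for the correlation t test, got n={n}")
    if not -1.0 <= r <= 1.0 or math.isnan(r):
        raise ValueError(f"correlation must be in [-1, 1], got {r}")
    df = n - 2
    if abs(r) >= 1.0 - 1e-12:
        t = math.copysign(math.inf, r)
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return EdgeTest(pair=pair, r=float(r), t=t, df=df, p=min(p, 1.0))


def edge_table(corr: CorrelationMatrix) -> pd.DataFrame:
    """Long-format table of (region_i, region_j, r, t, df, p) per unordered pair.

    Pairs involving undefined (zero-variance) regions are excluded.
    """
    rows = []
    regions = corr.regions
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            rv = corr.r.loc[a, b]
            if np.isnan(rv):
                continue
            et = edge_significance(float(rv), corr.n, pair=(a, b))
            rows.append(
                {"region_i": a, "region_j": b, "r": et.r, "t": et.t, "df": et.df, "p": et.p}
            )
    return pd.DataFrame(rows, columns=["region_i", "region_j", "r", "t", "df", "p"])


def _require_same_atlas(a_regions: Sequence[str], b_regions: Sequence[str]) -> None:
    if tuple(a_regions) != tuple(b_regions):
        raise AtlasMismatchError(
            f"region sets differ: {list(a_regions)} vs {list(b_regions)}"
        )


def compare_all_correlations(
    a: CorrelationMatrix, b: CorrelationMatrix, triangles: str = "upper"
) -> tuple[float, float]:
    """Mann-Whitney U on the two groups' full correlation distributions.

    Compares the vectors of off-diagonal correlations (190 values per group
    for 20 regions, each unordered pair once). Two-sided, normal approximation
    with tie correction. Returns (U, p).
    """
    _require_same_atlas(a.regions, b.regions)
    va = a.offdiag_values(triangles)
    vb = b.offdiag_values(triangles)
    if np.array_equal(np.sort(va), np.sort(vb)):
        # identical samples: U at its null mean, no evidence of a shift
        return float(len(va) * len(vb) / 2.0), 1.0
    u, p = stats.mannwhitneyu(va, vb, alternative="two-sided", method="asymptotic")
    return float(u), float(p)


def compare_region_correlations(
    a: CorrelationMatrix, b: CorrelationMatrix
) -> pd.DataFrame:
    """Per-region Mann-Whitney U with Bonferroni correction over regions.

    For each region, its vector of correlations with all other regions
    (length R-1) is compared between groups; adjusted p = min(1, raw p * R).
    """
    _require_same_atlas(a.regions, b.regions)
    regions = a.regions
    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    n_regions = len(regions)
    rows = []
    for region in regions:
        va = a.region_values(region)
        vb = b.region_values(region)
        if len(va) == 0 or len(vb) == 0:
            u, p = float("nan"), float("nan")
        elif np.array_equal(np.sort(va), np.sort(vb)):
            u, p = float(len(va) * len(vb) / 2.0), 1.0
        else:
            u, p = stats.mannwhitneyu(va, vb, alternative="two-sided", method="asymptotic")
        rows.append(
            {
                "region": region,
                "U": float(u),
                "p_raw": float(p),
                "p_bonferroni": min(1.0, float(p) * n_regions) if not math.isnan(p) else p,
            }
        )
    return pd.DataFrame(rows)


def per_region_count_comparison(
    a: CountTable, b: CountTable, welch: bool = False
) -> pd.DataFrame:
    """Per-region two-sample t comparison of counts, Bonferroni over regions.

    Fold change is mean(b)/mean(a); undefined (NaN) and flagged when a
    region's mean in ``a`` is zero. A simple per-region stand-in for a
    genotype-by-region repeated-measures analysis.
    """
    _require_same_atlas(a.regions, b.regions)
    n_regions = len(a.regions)
    rows = []
    for region in a.regions:
        xa = a.values[region].to_numpy(dtype=float)
        xb = b.values[region].to_numpy(dtype=float)
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            t, p = (0.0, 1.0) if xa.mean() == xb.mean() else (float("inf"), 0.0)
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
        mean_a = xa.mean()
        fold = xb.mean() / mean_a if mean_a > 0 else float("nan")
        rows.append(
            {
                "region": region,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": min(1.0, float(p) * n_regions),
                "fold_change": fold,
                "fold_change_undefined": mean_a == 0,
            }
        )
    return pd.DataFrame(rows)


def plot_correlation_heatmap(corr: CorrelationMatrix, path: str | Path) -> None:
    """Optional figure: render the correlation matrix as a heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.regions)), corr.regions, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr.regions)), corr.regions, fontsize=7)
    ax.set_title(f"{corr.group} interregional correlation (n={corr.n})")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
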