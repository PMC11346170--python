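"""Nonparametric statistical layer: Spearman correlograms, Mann-Whitney
comparisons, and the grading-score stratifications.

Conventions follow common clinical-ophthalmology reporting: tie-corrected
(average-rank) Spearman rho with a t approximation for n > 10 and an exact
permutation p for tiny n; two-sided Mann-Whitney U with midrank ties, exact
for small untied samples; raw p values masked at alpha = 0.05 by default
(an optional Benjamini-Hochberg adjustment is available but off by default,
mirroring how such cohorts are usually reported).  Missing values are
handled by pairwise-complete deletion with per-cell n reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

#: variable order used for correlogram serialisation
DEFAULT_CORRELOGRAM_VARS = (
    "age",
    "osdi_symptoms",
    "osdi_vision",
    "osdi_triggers",
    "osdi_total",
    "oxford",
    "schirmer_mm",
    "tbut_s",
    "ic_sub",
    "nd_sub",
    "nm_sub",
    "tivcm",
    "hla_dr_auf",
)


@dataclass(frozen=True)
class CorrelogramResult:
    variables: tuple[str, ...]
    rho: np.ndarray
    p: np.ndarray
    mask: np.ndarray       # True where p < alpha
    n_pairs: np.ndarray
    alpha: float

    def to_frames(self) -> dict[str, pd.DataFrame]:
        v = list(self.variables)
        return {
            "rho": pd.DataFrame(self.rho, index=v, columns=v),
            "p": pd.DataFrame(self.p, index=v, columns=v),
            "mask": pd.DataFrame(self.mask, index=v, columns=v),
            "n_pairs": pd.DataFrame(self.n_pairs, index=v, columns=v),
        }

    def write_tsv(self, out_dir: str | Path, prefix: str = "correlogram") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in self.to_frames().items():
            path = out_dir / f"{prefix}_{name}.tsv"
            frame.to_csv(path, sep="\t")
            paths.append(path)
        return paths


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Average-rank Spearman rho (Pearson on midranks)."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _spearman_p_t(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def _spearman_p_exact(x: np.ndarray, y: np.ndarray, chunk: int = 200_000) -> float:
    """Two-sided permutation p by full enumeration of the n! rank pairings."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    n = len(rx)
    rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum())
    count = total = 0
    perms = itertools.permutations(ry)
    while True:
        block = np.array(list(itertools.islice(perms, chunk)))
        if block.size == 0:
            break
        bc = block - block.mean(axis=1, keepdims=True)
        bden = np.sqrt((bc**2).sum(axis=1))
        rhos = (bc @ rx_c) / (bden * denom)
        count += int(np.sum(np.abs(rhos) >= rho_obs - 1e-12))
        total += block.shape[0]
    return count / total


def spearman_pair(x, y) -> tuple[float, float, int]:
    """(rho, p, n) for one pairwise-complete variable pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return float("nan"), float("nan"), n
    rho = _spearman_rho(x, y)
    if np.isnan(rho):
        return rho, float("nan"), n
    p = _spearman_p_exact(x, y) if n <= 10 else _spearman_p_t(rho, n)
    return rho, p, n


def spearman_matrix(
    table: pd.DataFrame,
    variables: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> CorrelogramResult:
    """Spearman rho/p matrices with a significance mask.

    ``adjust="bh"`` applies a Benjamini-Hochberg correction across the
    upper-triangle p values before masking (off by default).
    """
    if variables is None:
        variables = tuple(v for v in DEFAULT_CORRELOGRAM_VARS if v in table.columns)
    k = len(variables)
    data = table.loc[:, list(variables)].to_numpy(dtype=float)
    rho = np.eye(k)
    p = np.zeros((k, k))
    n_pairs = np.full((k, k), data.shape[0], dtype=int)

    no_missing = not np.isnan(data).any()
    if no_missing and data.shape[0] > 10:
        # fast path: rank once, Pearson on the rank matrix, t approximation
        ranks = sps.rankdata(data, axis=0)
        sd = ranks.std(axis=0)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(ranks.T)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
        np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
        rho = r
        n = data.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * sps.t.sf(np.abs(t), n - 2)
        p[np.isnan(rho)] = np.nan
        np.fill_diagonal(p, 0.0)
    else:
        for i in range(k):
            for j in range(i + 1, k):
                r_ij, p_ij, n_ij = spearman_pair(data[:, i], data[:, j])
                rho[i, j] = rho[j, i] = r_ij
                p[i, j] = p[j, i] = p_ij
                n_pairs[i, j] = n_pairs[j, i] = n_ij

    if adjust == "bh":
        iu = np.triu_indices(k, 1)
        raw = p[iu]
        ok = ~np.isnan(raw)
        if ok.any():
            from statsmodels.stats.multitest import multipletests

            adj = raw.copy()
            adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
            p[iu] = adj
            p[(iu[1], iu[0])] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    with np.errstate(invalid="ignore"):
        mask = p < alpha
    mask &= ~np.isnan(p)
    np.fill_diagonal(mask, False)
    return CorrelogramResult(
        variables=tuple(variables), rho=rho, p=p, mask=mask, n_pairs=n_pairs, alpha=alpha
    )


def mann_whitney(a, b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-sided Mann-Whitney U; exact for small untied samples.

    Exact enumeration applies when n1+n2 <= 12 with no cross-group ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else float("nan"),
        sem_b=float(b.std(ddof=1) / np.sqrt(len(b))) if len(b) > 1 else float("nan"),
    )


def stratify_icsc(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Low (IC-0..IC-2) vs high (IC-3) inflammatory-cell subscore strata."""
    if "ic_sub" not in table.columns:
        raise ValueError("records are not scored: missing 'ic_sub'")
    low = table[table["ic_sub"].isin([0, 1, 2])]
    high = table[table["ic_sub"] == 3]
    return low, high


def compare_hla_by_icsc(table: pd.DataFrame) -> GroupComparison | None:
    """HLA-DR in low vs high ICsc strata; None when a stratum is empty."""
    low, high = stratify_icsc(table)
    if len(low) == 0 or len(high) == 0:
        return None
    return mann_whitney(
        low["hla_dr_auf"], high["hla_dr_auf"], label_a="ICsc low", label_b="ICsc high"
    )


def stratify_extreme_tivcm(
    table: pd.DataFrame, low_max: int = 2, high_min: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extreme total-score groups: total <= low_max vs total >= high_min."""
    if low_max >= high_min:
        raise ValueError(f"low_max ({low_max}) must be < high_min ({high_min})")
    if "tivcm" not in table.columns:
        raise ValueError("records are not scored: missing 'tivcm'")
    return table[table["tivcm"] <= low_max], table[table["tivcm"] >= high_min]


def within_group_correlations(
    group: pd.DataFrame,
    variables: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> tuple[CorrelogramResult, pd.DataFrame]:
    """Correlogram restricted to one stratum plus its significant-edge list."""
    if len(group) < 3:
        raise ValueError(f"group too small for correlation ({len(group)} records)")
    result = spearman_matrix(group, variables, alpha)
    rows = []
    k = len(result.variables)
    for i in range(k):
        for j in range(i + 1, k):
            if result.mask[i, j]:
                rows.append(
                    {
                        "var_a": result.variables[i],
                        "var_b": result.variables[j],
                        "rho": result.rho[i, j],
                        "p": result.p[i, j],
                        "sign": "+" if result.rho[i, j] > 0 else "-",
                    }
                )
    edges = pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p", "sign"])
    return result, edges


def plot_correlogram(result: CorrelogramResult, path: str | Path) -> Path:
    """Correlogram figure: red positive, blue negative, blank nonsignificant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(result.variables)
    shown = np.where(result.mask, result.rho, np.nan)
    fig, ax = plt.subplots(figsize=(0.6 * k + 2, 0.6 * k + 2))
    im = ax.imshow(shown, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(k), result.variables, rotation=90)
    ax.set_yticks(range(k), result.variables)
    for i in range(k):
        for j in range(k):
            if i != j and result.mask[i, j]:
                ax.text(
                    j, i, f"{result.rho[i, j]:.2f}", ha="center", va="center", fontsize=7
                )
    fig.colorbar(im, ax=ax, label="Spearman rho (significant only)")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
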