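"""mtDNA summary statistics: diversity panel, Tajima's D and AMOVA PhiST.

Distances between haplotypes are plain Hamming counts over the alignment
(number of differing sites).  PhiST follows the two-level AMOVA variance
partition on squared molecular distances (among- vs within-population
components); estimates may be slightly negative by sampling noise and are
reported unclamped.

Statistics that are undefined on a given sample (Tajima's D with no
segregating sites; PhiST with zero total variance) are returned as NaN; the
reference-table layer imputes them to 0 alongside an indicator column so the
random forest can exploit the missingness pattern.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coalsim import Alignment


class SumstatsError(ValueError):
    pass


def hamming_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances between rows of a (n x sites) matrix."""
    n = matrix.shape[0]
    if matrix.shape[1] == 0:
        return np.zeros((n, n))
    diff = matrix[:, None, :] != matrix[None, :, :]
    return diff.sum(axis=2).astype(float)


def _tajimas_d(n: int, S: int, pi_total: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences; NaN when undefined (S == 0 or n < 2)."""
    if n < 2 or S == 0:
        return float("nan")
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_total - S / a1) / np.sqrt(var))


def _stats_from_matrix(matrix: np.ndarray, length: int) -> dict[str, float]:
    """Diversity panel for one set of sequences given as a variant matrix."""
    n = matrix.shape[0]
    if n < 2:
        raise SumstatsError("need >= 2 sequences for diversity statistics")
    poly = (matrix != matrix[0]).any(axis=0)
    S = int(poly.sum())
    sub = matrix[:, poly]
    d = hamming_matrix(sub)
    iu = np.triu_indices(n, k=1)
    Pi = float(d[iu].mean()) if len(iu[0]) else 0.0
    _, counts = np.unique(sub, axis=0, return_counts=True)
    K = int(len(counts))
    p = counts / n
    H = float(n / (n - 1) * (1.0 - np.sum(p**2)))
    return {
        "S": float(S),
        "K": float(K),
        "H": H,
        "pi": Pi / length,
        "Pi": Pi,
        "D": _tajimas_d(n, S, Pi),
    }


def within_population_stats(aln: Alignment, population: str) -> dict[str, float]:
    """S, K (haplotypes), H, pi (per site), Pi and Tajima's D for one
    population."""
    idx = aln.sample_indices(population)
    if len(idx) == 0:
        raise SumstatsError(f"population {population!r} absent from alignment")
    if len(idx) < 2:
        raise SumstatsError(
            f"population {population!r} has {len(idx)} sequence(s); need >= 2"
        )
    return _stats_from_matrix(aln.variant_matrix[idx], aln.length)


def _amova_components(
    d: np.ndarray, groups: Sequence[np.ndarray]
) -> tuple[float, float]:
    """(sigma2_among, sigma2_within) from the two-level AMOVA partition.

    Hamming counts are used directly as the squared molecular distances, as
    in the standard haplotype-level AMOVA.
    """
    all_idx = np.concatenate(groups)
    N = len(all_idx)
    P = len(groups)
    sub = d[np.ix_(all_idx, all_idx)]
    iu = np.triu_indices(N, k=1)
    ssd_total = float(sub[iu].sum()) / N
    ssd_within = 0.0
    for g in groups:
        if len(g) < 2:
            continue
        dg = d[np.ix_(g, g)]
        gi = np.triu_indices(len(g), k=1)
        ssd_within += float(dg[gi].sum()) / len(g)
    ssd_among = ssd_total - ssd_within
    df_among = P - 1
    df_within = N - P
    if df_within <= 0:
        return float("nan"), float("nan")
    sigma_w = ssd_within / df_within
    sizes = np.array([len(g) for g in groups], dtype=float)
    n_eff = (N - np.sum(sizes**2) / N) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_eff
    return float(sigma_a), float(sigma_w)


def _amova_phist(d: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    sigma_a, sigma_w = _amova_components(d, groups)
    denom = sigma_a + sigma_w
    if not np.isfinite(denom) or denom == 0:
        return float("nan")
    return sigma_a / denom


def phi_st_components(
    aln: Alignment, pop_a: str, pop_b: str
) -> tuple[float, float]:
    """The raw AMOVA variance components (sigma2_among, sigma2_within).

    Useful for combining estimates across datasets: the among component is
    exactly unbiased (zero-mean under panmixia), whereas the PhiST ratio
    carries a small negative finite-sample bias.
    """
    ia = aln.sample_indices(pop_a)
    ib = aln.sample_indices(pop_b)
    if len(ia) < 2 or len(ib) < 2:
        raise SumstatsError("need >= 2 sequences in each population for PhiST")
    d = hamming_matrix(aln.variant_matrix)
    return _amova_components(d, [ia, ib])


def phi_st(
    aln: Alignment, pop_a: str, pop_b: str, clamp: bool = False
) -> float:
    """AMOVA-based PhiST between two populations (NaN if total variance 0).

    Sampling noise can produce slightly negative estimates; they are
    reported unclamped unless ``clamp=True`` truncates them at 0.
    """
    ia = aln.sample_indices(pop_a)
    ib = aln.sample_indices(pop_b)
    if len(ia) < 2 or len(ib) < 2:
        raise SumstatsError("need >= 2 sequences in each population for PhiST")
    d = hamming_matrix(aln.variant_matrix)
    val = _amova_phist(d, [ia, ib])
    if clamp and np.isfinite(val):
        val = max(val, 0.0)
    return val


def summary_layout(populations: Sequence[str]) -> list[str]:
    """The fixed, documented ordering of the summary vector.

    Per population: S, K, H, pi, Pi, D; per pair (in roster order):
    PhiST and mean between-population distance (dxy); then pooled totals.
    """
    cols: list[str] = []
    for p in populations:
        cols += [f"{s}_{p}" for s in ("S", "K", "H", "pi", "Pi", "D")]
    for a, b in itertools.combinations(populations, 2):
        cols.append(f"PhiST_{a}_{b}")
    for a, b in itertools.combinations(populations, 2):
        cols.append(f"dxy_{a}_{b}")
    cols += [f"{s}_all" for s in ("S", "K", "H", "pi", "Pi", "D")]
    return cols


def summarize(
    aln: Alignment, populations: Sequence[str] | None = None
) -> pd.Series:
    """The full summary vector for one dataset, in the documented order.

    ``populations`` fixes the roster order; by default the order of first
    appearance in the alignment is used.  Undefined entries are NaN.
    """
    pops = list(populations) if populations is not None else list(aln.population_names)
    idx = {p: aln.sample_indices(p) for p in pops}
    for p, ind in idx.items():
        if len(ind) == 0:
            raise SumstatsError(f"population {p!r} absent from alignment")
    out: dict[str, float] = {}
    for p in pops:
        if len(idx[p]) < 2:  # null policy: diversity undefined on one sequence
            for k in ("S", "K", "H", "pi", "Pi", "D"):
                out[f"{k}_{p}"] = float("nan")
            continue
        st = _stats_from_matrix(aln.variant_matrix[idx[p]], aln.length)
        for k, val in st.items():
            out[f"{k}_{p}"] = val
    d = hamming_matrix(aln.variant_matrix)
    for a, b in itertools.combinations(pops, 2):
        if len(idx[a]) < 2 or len(idx[b]) < 2:
            out[f"PhiST_{a}_{b}"] = float("nan")
        else:
            out[f"PhiST_{a}_{b}"] = _amova_phist(d, [idx[a], idx[b]])
    for a, b in itertools.combinations(pops, 2):
        out[f"dxy_{a}_{b}"] = float(d[np.ix_(idx[a], idx[b])].mean())
    pooled = _stats_from_matrix(aln.variant_matrix, aln.length)
    for k, val in pooled.items():
        out[f"{k}_all"] = val
    layout = summary_layout(pops)
    return pd.Series([out[c] for c in layout], index=layout, dtype=float)


#: summary columns that may legitimately be undefined (NaN)
def nullable_columns(layout: Sequence[str]) -> list[str]:
    return [c for c in layout if c.startswith(("D_", "PhiST_"))]


def impute_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Impute NaN summary entries to 0 and append 0/1 ``*_def`` indicators.

    Indicators are added for every nullable column so the table layout is
    identical across runs regardless of which rows were undefined.
    """
    out = table.copy()
    for col in nullable_columns(list(table.columns)):
        defined = out[col].notna().astype(float)
        out[col] = out[col].fillna(0.0)
        out[f"{col}_def"] = defined
    # any remaining NaN (e.g. single-sequence populations in non-default
    # designs) is filled without a dedicated flag to keep the layout fixed
    stat_cols = [c for c in out.columns if not c.endswith("_def")]
    out[stat_cols] = out[stat_cols].fillna(0.0)
    return out
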