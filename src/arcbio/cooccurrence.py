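"""Probabilistic pairwise species co-occurrence: exact hypergeometric null built
from first principles (log-gamma arithmetic), pair classification, and regional
class-frequency series with trends."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from arcbio._stats import ols_trend, pearson_r
from arcbio.synthetic_data.grid import Grid

POSITIVE = "positive"
NEGATIVE = "negative"
RANDOM = "random"
CLASSES = (POSITIVE, NEGATIVE, RANDOM)


@dataclass(frozen=True)
class PairCooccurrence:
    sp1: str
    sp2: str
    N: int
    N1: int
    N2: int
    Q_obs: int
    expected: float
    p_lt: float
    p_gt: float
    classification: str


@dataclass
class SiteSpeciesMatrix:
    region_id: int
    period: str
    sites: np.ndarray  # flat cell indices into the grid
    species: list[str]
    M: np.ndarray  # (n_sites, n_species) binary incidence

    @property
    def n_sites(self) -> int:
        return int(self.M.shape[0])

    def occupancy(self) -> np.ndarray:
        return self.M.sum(axis=0)


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def cooccurrence_pmf(N: int, N1: int, N2: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of the number of co-occupied sites j when two species with
    N1 and N2 occupied sites are placed independently among N sites:

        P(Q = j) = C(N1, j) C(N - N1, N2 - j) / C(N, N2)

    over the feasible range max(0, N1+N2-N) <= j <= min(N1, N2).
    Returns (j values, probabilities); computed in log space.
    """
    if not (0 <= N1 <= N and 0 <= N2 <= N):
        raise ValueError("need 0 <= N1, N2 <= N")
    j = np.arange(max(0, N1 + N2 - N), min(N1, N2) + 1)
    logp = _log_comb(N1, j) + _log_comb(N - N1, N2 - j) - _log_comb(N, N2)
    return j, np.clip(np.exp(logp), 0.0, 1.0)


def pair_test(N: int, N1: int, N2: int, Q_obs: int, alpha: float = 0.05,
              sp1: str = "sp1", sp2: str = "sp2") -> PairCooccurrence:
    """Classify one species pair against the independence null.

    p_lt = P(Q <= Q_obs), p_gt = P(Q >= Q_obs). Positive when p_gt < alpha,
    negative when p_lt < alpha, random otherwise.
    """
    j, pmf = cooccurrence_pmf(N, N1, N2)
    if not (j[0] <= Q_obs <= j[-1]):
        raise ValueError(
            f"Q_obs={Q_obs} outside combinatorial bounds [{j[0]}, {j[-1]}] for N={N}, N1={N1}, N2={N2}"
        )
    p_lt = float(np.clip(pmf[j <= Q_obs].sum(), 0.0, 1.0))
    p_gt = float(np.clip(pmf[j >= Q_obs].sum(), 0.0, 1.0))
    if p_gt < alpha:
        cls = POSITIVE
    elif p_lt < alpha:
        cls = NEGATIVE
    else:
        cls = RANDOM
    expected = N1 * N2 / N if N else float("nan")
    return PairCooccurrence(sp1, sp2, int(N), int(N1), int(N2), int(Q_obs), float(expected), p_lt, p_gt, cls)


def build_matrix(
    binaries: dict[str, np.ndarray], grid: Grid, region: int, period: str = ""
) -> SiteSpeciesMatrix:
    """Site x species incidence over one region's ocean cells.

    Species never present in the region are kept as all-zero columns (they are
    excluded later from pair enumeration, not from the matrix).
    """
    cells = grid.region_id == int(region)
    if not cells.any():
        raise ValueError(f"region {region} has no cells")
    sites = np.nonzero(cells.reshape(-1))[0]
    species = list(binaries)
    M = np.column_stack([np.asarray(binaries[s], dtype=bool).reshape(-1)[sites] for s in species])
    return SiteSpeciesMatrix(int(region), str(period), sites, species, M.astype(np.int8))


def region_cooccurrence(
    matrix: SiteSpeciesMatrix, alpha: float = 0.05, min_expected: float = 1.0
) -> tuple[list[PairCooccurrence], dict[str, int], list[tuple[str, str]]]:
    """Test all unordered pairs of species with non-empty columns.

    Pairs with expected co-occurrence below ``min_expected`` are flagged
    unanalyzable and excluded from the class counts (returned separately).
    Returns (pair results, class counts, unanalyzable pairs).
    """
    occ = matrix.occupancy()
    N = matrix.n_sites
    nonempty = [i for i, s in enumerate(matrix.species) if occ[i] > 0]
    results: list[PairCooccurrence] = []
    unanalyzable: list[tuple[str, str]] = []
    counts = {c: 0 for c in CLASSES}
    M = matrix.M.astype(bool)
    for ii, i in enumerate(nonempty):
        for k in nonempty[ii + 1:]:
            n1, n2 = int(occ[i]), int(occ[k])
            expected = n1 * n2 / N
            sp1, sp2 = matrix.species[i], matrix.species[k]
            if expected < min_expected:
                unanalyzable.append((sp1, sp2))
                continue
            q = int((M[:, i] & M[:, k]).sum())
            res = pair_test(N, n1, n2, q, alpha=alpha, sp1=sp1, sp2=sp2)
            results.append(res)
            counts[res.classification] += 1
    return results, counts, unanalyzable


def pair_results_table(results: list[PairCooccurrence], region: int, period: str) -> pd.DataFrame:
    rows = [
        {
            "region": region,
            "period": period,
            "sp1": r.sp1,
            "sp2": r.sp2,
            "N": r.N,
            "N1": r.N1,
            "N2": r.N2,
            "Q_obs": r.Q_obs,
            "expected": r.expected,
            "p_lt": r.p_lt,
            "p_gt": r.p_gt,
            "class": r.classification,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["region", "period", "sp1", "sp2", "N", "N1", "N2", "Q_obs", "expected", "p_lt", "p_gt", "class"],
    )


def cooccurrence_trend(
    series: pd.DataFrame, richness_series: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per region and class: OLS trend of annual class counts, plus Pearson r
    against the regional mean SR series when supplied.

    ``series`` columns: region, year, positive, negative, random.
    ``richness_series`` columns: region, year, SR.
    """
    if series["year"].nunique() < 3:
        raise ValueError("need >= 3 periods for a trend")
    rows = []
    for region, g in series.groupby("region"):
        g = g.sort_values("year")
        sr = None
        if richness_series is not None:
            sr_g = richness_series[richness_series["region"] == region].sort_values("year")
            sr = sr_g.set_index("year")["SR"].reindex(g["year"]).to_numpy()
        for cls in CLASSES:
            tr = ols_trend(g["year"], g[cls])
            row = {
                "region": region,
                "class": cls,
                "slope_per_year": tr.slope,
                "p": tr.p_value,
                "adj_R2": tr.adj_r_squared,
            }
            if sr is not None:
                r, rp = pearson_r(g[cls].to_numpy(), sr)
                row["pearson_r_SR"] = r
                row["pearson_p_SR"] = rp
            rows.append(row)
    return pd.DataFrame(rows)
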