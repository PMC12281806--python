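"""Geographic structure: site ancestry means, clines, leave-one-out, Mantel.

Isolation by distance is assessed by correlating the pairwise genetic
distance matrix (Fst) with great-circle geographic distances (Haversine) via
a Mantel permutation test. Ancestry clines are ordinary least-squares fits of
per-site mean ancestry proportions against latitude or longitude, with a
leave-one-out re-fit to expose sites that single-handedly drive (or destroy)
a significant slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0


@dataclass
class ClineFit:
    ancestry: str
    axis: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_sites: int


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    n: int
    alternative: str


def site_mean_ancestry(
    q: np.ndarray,
    site_labels,
    ancestry_labels: list[str],
    min_n: int = 1,
) -> pd.DataFrame:
    """Unweighted per-site mean ancestry vectors; small sites are dropped.

    Returns a DataFrame indexed by site with one column per ancestry plus
    'n'. Sites with fewer than ``min_n`` individuals are excluded.
    """
    q = np.asarray(q, dtype=float)
    df = pd.DataFrame(q, columns=ancestry_labels)
    df["site"] = np.asarray(site_labels)
    counts = df.groupby("site").size()
    means = df.groupby("site").mean()
    means["n"] = counts
    kept = means[means["n"] >= min_n]
    return kept


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance between decimal-degree coordinates, in km."""
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude outside [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return 2 * radius_km * np.arcsin(np.sqrt(h))


def geographic_distance_matrix(site_table: pd.DataFrame) -> np.ndarray:
    lat = site_table["latitude"].to_numpy(dtype=float)
    lon = site_table["longitude"].to_numpy(dtype=float)
    n = len(lat)
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = haversine_km(lat[i], lon[i], lat, lon)
    np.fill_diagonal(D, 0.0)
    return D


def _check_distance_matrix(D: np.ndarray, name: str) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return D


def mantel_test(
    D1,
    D2,
    n_perm: int = 9999,
    seed=None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel matrix-correlation test by joint row/column permutation of D2.

    r is the Pearson correlation of the upper-triangle entries. The one-sided
    'greater' p-value is (1 + #{r_perm >= r_obs}) / (n_perm + 1); 'two-sided'
    compares |r_perm| with |r_obs|. Deterministic given ``seed``.
    """
    D1 = _check_distance_matrix(D1, "D1")
    D2 = _check_distance_matrix(D2, "D2")
    if D1.shape != D2.shape:
        raise ValueError("matrices must have the same dimension")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = D1[iu]
    if np.nanstd(x) == 0 or np.nanstd(D2[iu]) == 0:
        raise ValueError("constant distance matrix: correlation undefined")

    def corr(perm):
        y = D2[np.ix_(perm, perm)][iu]
        ok = ~(np.isnan(x) | np.isnan(y))
        return float(np.corrcoef(x[ok], y[ok])[0, 1])

    identity = np.arange(n)
    r_obs = corr(identity)

    # small matrices: the full permutation group fits inside n_perm, so
    # enumerate it exactly instead of sampling
    import itertools
    import math

    exhaustive = math.factorial(n) - 1 <= n_perm
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n))
                 if tuple(p) != tuple(identity)]
    else:
        rng = np.random.default_rng(seed)
        perms = (rng.permutation(n) for _ in range(n_perm))

    count = 0
    n_used = 0
    for perm in perms:
        n_used += 1
        r_p = corr(perm)
        if alternative == "greater":
            count += r_p >= r_obs - 1e-12
        else:
            count += abs(r_p) >= abs(r_obs) - 1e-12
    p = (1 + count) / (n_used + 1)
    return MantelResult(r=r_obs, p_value=p, n_perm=n_used, n=n,
                        alternative=alternative)


def fit_cline(
    values,
    coords,
    axis: str,
    ancestry: str = "",
) -> ClineFit:
    """OLS of per-site mean ancestry on one coordinate axis.

    p is the two-sided t-test on the slope with n-2 degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(coords, dtype=float)
    if len(x) != len(y):
        raise ValueError("values and coordinates must align")
    if len(x) < 3:
        raise ValueError("need at least 3 sites to fit a cline")
    if np.std(x) == 0:
        raise ValueError("zero variance in the coordinate axis")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.std(y) > 0 else 0.0
    p = float(res.pvalue) if np.std(y) > 0 else 1.0
    return ClineFit(
        ancestry=ancestry,
        axis=axis,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=p,
        n_sites=len(x),
    )


def leave_one_out_clines(
    site_means: pd.DataFrame,
    site_table: pd.DataFrame,
    ancestry: str,
    axis: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Refit the cline dropping one site at a time; flag significance flips.

    ``site_means`` is the output of :func:`site_mean_ancestry` (indexed by
    site); ``site_table`` carries latitude/longitude per site; ``axis`` is
    'latitude' or 'longitude'. The returned table lists, per dropped site,
    the refit p-value next to the full-model p-value and a flag: 'flips'
    where removal crosses alpha in either direction, 'undefined' where only
    3 sites remain, otherwise 'stable'.
    """
    if axis not in ("latitude", "longitude"):
        raise ValueError("axis must be 'latitude' or 'longitude'")
    merged = site_means.merge(
        site_table.set_index("site")[["latitude", "longitude"]],
        left_index=True,
        right_index=True,
        how="inner",
    )
    if len(merged) < 4:
        raise ValueError("need at least 4 sites for leave-one-out")
    full = fit_cline(merged[ancestry], merged[axis], axis, ancestry)
    rows = []
    for site in merged.index:
        rest = merged.drop(index=site)
        fit = fit_cline(rest[ancestry], rest[axis], axis, ancestry)
        if len(rest) == 3:
            flag = "undefined"
        elif (full.p_value < alpha) != (fit.p_value < alpha):
            flag = "flips"
        else:
            flag = "stable"
        rows.append(
            {
                "dropped_site": site,
                "ancestry": ancestry,
                "axis": axis,
                "p_without": fit.p_value,
                "p_full": full.p_value,
                "slope_without": fit.slope,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def combine_asian_components(
    q_table: pd.DataFrame, component_labels: list[str], merged_label: str = "Asian"
) -> pd.DataFrame:
    """Sum named ancestry columns into one merged component (simplex kept)."""
    missing = [c for c in component_labels if c not in q_table.columns]
    if missing:
        raise ValueError(f"labels absent from table: {missing}")
    out = q_table.copy()
    merged = out[list(component_labels)].sum(axis=1)
    out = out.drop(columns=list(component_labels))
    out[merged_label] = merged
    return out
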