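"""Resource selection for resting sites: home range, availability, RSF,
selection ratios, and Boyce-style k-fold cross-validation.

The home range is the 90% contour of a kernel utilization distribution
estimated from active-phase fixes (Gaussian product kernel, normal-reference
bandwidth per axis, 50 m grid).  For each used resting site, random points
are drawn uniformly within the home range as available sites; a binomial
GLMM of used-vs-available with vegetation x distance interactions is the
RSF.  Selection ratios rescale the fitted use/availability density ratio so
1 means neutrality.  Model skill is the average Spearman correlation between
RSF-score bin rank and the area-adjusted frequency of held-out used points
(5 folds, 10 bins, 20 replicates).
"""

from __future__ import annotations

import gc
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import box
from shapely.ops import unary_union

from . import glmm

log = logging.getLogger("boarrest")

AVAILABLE_PER_USED = 1000
RSF_TERMS = ["veg", "d_road", "d_village", "veg:d_road", "veg:d_village"]


# ---------------------------------------------------------------------------
# Home range
# ---------------------------------------------------------------------------

@dataclass
class HomeRange:
    """90% utilization-distribution contour as a union of grid cells."""

    animal_id: str
    polygon: object               # shapely (Multi)Polygon
    bandwidth: tuple              # (hx, hy) meters
    cell_m: float
    _gx: np.ndarray = field(repr=False, default=None)
    _gy: np.ndarray = field(repr=False, default=None)
    _mask: np.ndarray = field(repr=False, default=None)

    @property
    def area_m2(self) -> float:
        return float(self.polygon.area)

    def contains_points(self, x, y):
        """Vectorized membership via the grid mask."""
        ix = np.floor((np.asarray(x) - self._gx[0]) / self.cell_m).astype(int)
        iy = np.floor((np.asarray(y) - self._gy[0]) / self.cell_m).astype(int)
        ok = (ix >= 0) & (ix < self._mask.shape[0]) & (iy >= 0) & (iy < self._mask.shape[1])
        out = np.zeros(np.shape(x), dtype=bool)
        out[ok] = self._mask[ix[ok], iy[ok]]
        return out


def home_range_90kde(x, y, animal_id="", mass: float = 0.90,
                     cell_m: float = 50.0, min_fixes: int = 50) -> HomeRange:
    """Kernel home range: grid cells holding the top 90% of estimated mass.

    Gaussian product kernel with the per-axis normal-reference bandwidth
    ``h = sigma * n^(-1/6)`` (the 2-D Scott rule).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < min_fixes:
        raise ValueError(f"too few fixes for a home range ({n} < {min_fixes})")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate fix distribution (zero variance)")
    hx, hy = sx * n ** (-1 / 6), sy * n ** (-1 / 6)

    pad = 3.5
    gx = np.arange(x.min() - pad * hx, x.max() + pad * hx + cell_m, cell_m)
    gy = np.arange(y.min() - pad * hy, y.max() + pad * hy + cell_m, cell_m)
    cx, cy = gx[:-1] + cell_m / 2, gy[:-1] + cell_m / 2
    kx = np.exp(-0.5 * ((cx[None, :] - x[:, None]) / hx) ** 2) / hx
    ky = np.exp(-0.5 * ((cy[None, :] - y[:, None]) / hy) ** 2) / hy
    dens = (kx.T @ ky) / (2 * np.pi * n)                      # (Gx, Gy)

    cellmass = dens * cell_m ** 2
    order = np.argsort(cellmass, axis=None)[::-1]
    csum = np.cumsum(cellmass.ravel()[order])
    k = int(np.searchsorted(csum, mass * cellmass.sum())) + 1
    mask = np.zeros(dens.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(dens.shape)

    boxes = [box(gx[i], gy[j], gx[i] + cell_m, gy[j] + cell_m)
             for i, j in zip(*np.nonzero(mask))]
    return HomeRange(animal_id, unary_union(boxes), (hx, hy), cell_m,
                     _gx=gx, _gy=gy, _mask=mask)


def sample_available(home_range: HomeRange, n: int, rng) -> np.ndarray:
    """Uniform points within the home range (n, 2).

    Cells of the 90% mask are equal-area, so sampling a cell uniformly and a
    point uniformly within it is exactly uniform over the polygon.
    """
    ii, jj = np.nonzero(home_range._mask)
    if len(ii) == 0:
        raise ValueError("degenerate home range")
    pick = rng.integers(0, len(ii), n)
    u = rng.uniform(0, home_range.cell_m, (n, 2))
    x = home_range._gx[ii[pick]] + u[:, 0]
    y = home_range._gy[jj[pick]] + u[:, 1]
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# RSF dataset and fit
# ---------------------------------------------------------------------------

def build_rsf_dataset(sites_df: pd.DataFrame, home_ranges: dict, landscape,
                      season2: str, rng, n_per_used: int = AVAILABLE_PER_USED
                      ) -> pd.DataFrame:
    """Used (1) vs available (0) rows for one 2-level season.

    Used rows are the resting sites visited at least once in the season
    (each entering once regardless of visit count); available rows are
    ``n_per_used`` uniform points per used site, pooled within each animal's
    home range.  Distance covariates are in km, standardized downstream.
    """
    col = f"n_visits_{season2}"
    used = sites_df[sites_df[col] > 0]
    frames = []
    for aid, grp in used.groupby("animal_id"):
        hr = home_ranges[aid]
        study_site = (grp["study_site"].iloc[0]
                      if "study_site" in grp.columns else "area0")
        frames.append(pd.DataFrame({
            "used": 1, "animal_id": aid, "site_id": study_site,
            "veg": grp["veg"].astype(int).to_numpy(),
            "d_village": grp["d_village_m"].to_numpy() / 1000.0,
            "d_road": grp["d_road_m"].to_numpy() / 1000.0}))
        n_avail = n_per_used * len(grp)
        pts = sample_available(hr, n_avail, rng)
        cov = landscape.covariates(pts[:, 0], pts[:, 1])
        frames.append(pd.DataFrame({
            "used": 0, "animal_id": aid, "site_id": study_site,
            "veg": np.atleast_1d(cov["veg"]).astype(int),
            "d_village": np.atleast_1d(cov["d_village_m"]) / 1000.0,
            "d_road": np.atleast_1d(cov["d_road_m"]) / 1000.0}))
    return (pd.concat(frames, ignore_index=True)
            if frames else pd.DataFrame())


def standardize(df: pd.DataFrame, cols=("d_village", "d_road")) -> tuple:
    """Z-score distance covariates in place; returns (df, scale dict)."""
    scale = {}
    df = df.copy()
    for c in cols:
        mu, sd = float(df[c].mean()), float(df[c].std())
        sd = sd or 1.0
        df[c] = (df[c] - mu) / sd
        scale[c] = (mu, sd)
    return df, scale


def fit_rsf(dataset: pd.DataFrame, terms=RSF_TERMS) -> glmm.GlmmFit:
    """Binomial use-availability GLMM with nested random intercepts."""
    X, names = glmm.build_design(dataset, terms)
    return glmm.fit_glmm(X, dataset["used"].to_numpy(), "binomial",
                         site=dataset["site_id"].to_numpy(),
                         animal=dataset["animal_id"].to_numpy(),
                         term_names=names)


# ---------------------------------------------------------------------------
# Selection ratios
# ---------------------------------------------------------------------------

def selection_ratio(fit: glmm.GlmmFit, profile_df: pd.DataFrame,
                    n_used: int, n_available: int, terms=RSF_TERMS) -> pd.DataFrame:
    """Selection ratio SR(x) = (n_available / n_used) * exp(eta(x)).

    eta includes the intercept, so SR is the fitted use-density to
    availability-density ratio: SR > 1 selection, < 1 avoidance.  The 95% CI
    comes from the Wald interval on the link scale (delta method).
    """
    if not fit.converged:
        raise ValueError("refusing selection ratios from a non-converged fit")
    X, _ = glmm.build_design(profile_df, terms)
    eta = X @ fit.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
    k = n_available / n_used
    out = profile_df.copy()
    out["sr"] = k * np.exp(eta)
    out["sr_lo"] = k * np.exp(eta - 1.96 * se)
    out["sr_hi"] = k * np.exp(eta + 1.96 * se)
    return out


# ---------------------------------------------------------------------------
# Boyce-style k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvConfig:
    n_folds: int = 5
    n_bins: int = 10
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2 or self.n_bins < 3:
            raise ValueError("need >= 2 folds and >= 3 bins")


def _default_fold_fit(train_df, terms):
    """Fixed-effects logistic fit used to score folds (fast refit)."""
    import statsmodels.api as sm
    X, _ = glmm.build_design(train_df, terms)
    res = sm.GLM(train_df["used"].to_numpy(), X,
                 family=sm.families.Binomial()).fit(maxiter=100)
    beta = np.asarray(res.params)

    def score(df):
        Xs, _ = glmm.build_design(df, terms)
        return Xs @ beta
    return score


def boyce_cv(dataset: pd.DataFrame, cv: CvConfig = None, terms=RSF_TERMS,
             fit_procedure=None, score_override=None) -> dict:
    """Area-adjusted frequency cross-validation.

    Per replicate: used points are split into ``n_folds`` folds; for each
    fold the model is refitted on the remaining data and scores computed for
    the held-out used points and all available points.  Scores are binned
    into ``n_bins`` equal-interval bins over the pooled range; the
    area-adjusted frequency (held-out used fraction / available fraction) is
    rank-correlated with bin order.  Bins without available mass are merged
    with their lower neighbor.  Returns mean and SE of the fold-averaged
    Spearman correlation over replicates.
    """
    cv = cv or CvConfig()
    fit_procedure = fit_procedure or _default_fold_fit
    rng = np.random.default_rng(cv.seed)
    used_idx = np.nonzero(dataset["used"].to_numpy() == 1)[0]
    avail = dataset[dataset["used"] == 0]
    if len(used_idx) < cv.n_folds:
        raise ValueError("fewer used points than folds")

    rep_means = []
    for _ in range(cv.n_reps):
        perm = rng.permutation(used_idx)
        folds = np.array_split(perm, cv.n_folds)
        cors = []
        for f in folds:
            train = dataset.drop(index=dataset.index[f])
            held = dataset.iloc[f]
            if score_override is not None:
                s_held, s_avail = score_override(held), score_override(avail)
            else:
                score = fit_procedure(train, terms)
                s_held, s_avail = score(held), score(avail)
                # break the model<->results reference cycles immediately:
                # on large datasets they otherwise pile up across folds
                del score, train
                gc.collect()
            cors.append(_boyce_corr(np.asarray(s_held), np.asarray(s_avail), cv.n_bins))
        rep_means.append(np.nanmean(cors))
    rep_means = np.asarray(rep_means)
    return {"mean": float(rep_means.mean()),
            "se": float(rep_means.std(ddof=1) / np.sqrt(len(rep_means)))
            if len(rep_means) > 1 else 0.0}


def _boyce_corr(s_used, s_avail, n_bins):
    lo = min(s_used.min(), s_avail.min())
    hi = max(s_used.max(), s_avail.max())
    if hi <= lo:
        return np.nan
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] += 1e-9
    cu = np.histogram(s_used, edges)[0].astype(float)
    ca = np.histogram(s_avail, edges)[0].astype(float)
    # merge available-empty bins downward so the adjusted frequency is defined
    ranks, fu, fa = [], [], []
    for b in range(n_bins):
        if fa and ca[b] == 0:
            fu[-1] += cu[b]
            fa[-1] += ca[b]
            continue
        ranks.append(b)
        fu.append(cu[b])
        fa.append(ca[b])
    fu, fa = np.asarray(fu), np.asarray(fa)
    keep = fa > 0
    if keep.sum() < 3:
        return np.nan
    adj = (fu[keep] / max(fu.sum(), 1)) / (fa[keep] / fa.sum())
    rho = stats.spearmanr(np.asarray(ranks)[keep], adj).statistic
    return rho
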