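"""Environmental characterisation of population sites.

Implements the climate summaries used to search for drivers of adaptive
divergence: the 19 standard bioclimatic variables from monthly temperature
and precipitation, delta-method statistical downscaling of coarse climate
series onto fine-scale reference climatologies, PCA of the site x variable
table into synthetic environmental axes, and pairwise environmental
distances between sites.

Monthly means carry no diurnal range, so bio2 (mean diurnal range) and bio3
(isothermality) are only computed when optional monthly tmin/tmax series are
supplied; otherwise they are returned as NaN rather than invented.
Quarters are three consecutive calendar months with Dec-Jan wraparound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BIOCLIM_NAMES = tuple(f"bio{i}" for i in range(1, 20))


@dataclass
class MonthlyClimate:
    """Monthly mean temperature (degC) and precipitation (mm) for one site, Jan..Dec."""

    site: str
    tmean: np.ndarray
    prec: np.ndarray
    tmin: np.ndarray | None = None
    tmax: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tmean = np.asarray(self.tmean, dtype=float)
        self.prec = np.asarray(self.prec, dtype=float)
        if self.tmean.shape != (12,) or self.prec.shape != (12,):
            raise ValueError("tmean and prec must each have exactly 12 monthly values")
        if not np.isfinite(self.tmean).all() or not np.isfinite(self.prec).all():
            raise ValueError("missing month in climate series")
        if (self.prec < 0).any():
            raise ValueError("precipitation must be >= 0")
        for attr in ("tmin", "tmax"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (12,):
                    raise ValueError(f"{attr} must have 12 monthly values")
                setattr(self, attr, v)


def _quarter_windows(x: np.ndarray) -> np.ndarray:
    """Sums (or means via /3) of all 12 consecutive 3-month windows, wrapping Dec-Jan."""
    ext = np.concatenate([x, x[:2]])
    return np.array([ext[i:i + 3].sum() for i in range(12)])


def bioclim(mc: MonthlyClimate) -> dict[str, float]:
    """The 19 standard bioclimatic variables (bio1..bio19).

    Temperature seasonality (bio4) is the standard deviation of monthly means
    x 100; precipitation seasonality (bio15) is the coefficient of variation
    in percent (computed on monthly precip + 1 to tolerate fully dry months).
    Quarter variables use consecutive 3-month windows with wraparound; ties
    between windows resolve to the earliest window, matching the conventional
    implementation.
    """
    t, p = mc.tmean, mc.prec
    tq = _quarter_windows(t) / 3.0  # mean temperature per quarter
    pq = _quarter_windows(p)  # total precipitation per quarter

    wettest_q = int(np.argmax(pq))
    driest_q = int(np.argmin(pq))
    warmest_q = int(np.argmax(tq))
    coldest_q = int(np.argmin(tq))

    out: dict[str, float] = {}
    out["bio1"] = float(t.mean())
    if mc.tmin is not None and mc.tmax is not None:
        diurnal = mc.tmax - mc.tmin
        out["bio2"] = float(diurnal.mean())
        rng = float(mc.tmax.max() - mc.tmin.min())
        out["bio7"] = rng
        out["bio3"] = float(out["bio2"] / rng * 100.0) if rng > 0 else np.nan
        out["bio5"] = float(mc.tmax.max())
        out["bio6"] = float(mc.tmin.min())
    else:
        out["bio2"] = np.nan
        out["bio3"] = np.nan
        out["bio5"] = float(t.max())
        out["bio6"] = float(t.min())
        out["bio7"] = out["bio5"] - out["bio6"]
    out["bio4"] = float(t.std(ddof=1) * 100.0)
    out["bio8"] = float(tq[wettest_q])
    out["bio9"] = float(tq[driest_q])
    out["bio10"] = float(tq[warmest_q])
    out["bio11"] = float(tq[coldest_q])
    out["bio12"] = float(p.sum())
    out["bio13"] = float(p.max())
    out["bio14"] = float(p.min())
    pp = p + 1.0
    out["bio15"] = float(pp.std(ddof=1) / pp.mean() * 100.0)
    out["bio16"] = float(pq[wettest_q])
    out["bio17"] = float(pq[driest_q])
    out["bio18"] = float(pq[warmest_q])
    out["bio19"] = float(pq[coldest_q])
    return {k: out[k] for k in BIOCLIM_NAMES}


def bioclim_table(climates: list[MonthlyClimate]) -> pd.DataFrame:
    """Bioclim variables for several sites as a site x variable DataFrame."""
    rows = {mc.site: bioclim(mc) for mc in climates}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# delta-method downscaling
# ---------------------------------------------------------------------------

def delta_downscale(coarse_series: np.ndarray, coarse_ref: np.ndarray,
                    fine_ref: np.ndarray, mode: str = "additive") -> np.ndarray:
    """Delta-method statistical downscaling of a monthly series.

    ``coarse_series`` has shape (n_years, 12) or (12,); the climatologies are
    12-vectors aligned by month.  Additive mode (temperature) transfers the
    coarse anomaly onto the fine reference; multiplicative mode
    (precipitation) transfers the coarse ratio and clips at zero.
    """
    cs = np.atleast_2d(np.asarray(coarse_series, dtype=float))
    cr = np.asarray(coarse_ref, dtype=float)
    fr = np.asarray(fine_ref, dtype=float)
    if cs.shape[1] != 12 or cr.shape != (12,) or fr.shape != (12,):
        raise ValueError("monthly series and climatologies must be aligned on 12 months")
    if mode == "additive":
        fine = fr[None, :] + (cs - cr[None, :])
    elif mode == "multiplicative":
        zero = np.flatnonzero(cr == 0)
        if zero.size:
            months = ", ".join(str(m + 1) for m in zero)
            raise ValueError(f"multiplicative downscaling with zero reference in month(s) {months}")
        fine = np.clip(fr[None, :] * cs / cr[None, :], 0.0, None)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return fine[0] if np.ndim(coarse_series) == 1 else fine


# ---------------------------------------------------------------------------
# PCA of the environment table
# ---------------------------------------------------------------------------

@dataclass
class EnvPCA:
    """PCA decomposition of a sites x variables table."""

    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # sites x components
    variance_explained: np.ndarray  # fraction per component, sums to 1


def env_pca(table: pd.DataFrame, scale: bool = True) -> EnvPCA:
    """Principal components of the environment table by SVD.

    Variables are centred and (by default) scaled to unit variance
    (divisor n-1).  Each component's loading vector is flipped so that its
    largest-magnitude loading is positive, which fixes the sign convention.
    """
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 sites and 2 variables")
    if not np.isfinite(x).all():
        raise ValueError("missing values in environment table")
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = [str(table.columns[j]) for j in dead]
            raise ValueError(f"zero-variance variable(s): {names}")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n - 1, p)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    var = s**2 / (n - 1)
    total = var.sum()
    comp = [f"PC{i + 1}" for i in range(k)]
    return EnvPCA(
        loadings=pd.DataFrame(vt.T, index=table.columns, columns=comp),
        scores=pd.DataFrame(scores, index=table.index, columns=comp),
        variance_explained=var / total,
    )


def env_distance(values) -> pd.DataFrame:
    """Pairwise environmental distances between sites.

    A 1-D input (one variable per site) gives absolute differences; a 2-D
    input (e.g. selected PC scores) gives Euclidean distances.  The result is
    symmetric with a zero diagonal.
    """
    if isinstance(values, pd.DataFrame):
        idx, arr = list(values.index), values.to_numpy(dtype=float)
    elif isinstance(values, pd.Series):
        idx, arr = list(values.index), values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        idx = list(range(arr.shape[0]))
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    if arr.ndim == 1:
        d = np.abs(arr[:, None] - arr[None, :])
    else:
        diff = arr[:, None, :] - arr[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    return pd.DataFrame(d, index=idx, columns=idx)
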