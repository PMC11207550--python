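"""PCA screening of absorbance spectra and interface-instability outlier removal.

Raw recording-level spectra (no spectral pre-processing) are decomposed by
column-mean-centred PCA.  Score-versus-temperature regressions per phantom
quantify temperature sensitivity (slope), inter-phantom offsets (intercepts)
and within-phantom fit quality (R^2); score-versus-composition regressions
relate the leading components to the gelatin/Intralipid/water make-up.

Interface-instability events appear as sudden jumps in the score-temperature
relation, most prominently on components 2-4.  They are flagged automatically:
per phantom and component, a robust least-absolute-deviation line of score on
temperature is fitted and points whose residual exceeds ``k_mad`` times the MAD
are flagged.  Manual per-phantom index lists can override or augment the
automatic criterion.  Flagging is non-destructive: the mask is stored and the
original table kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acquisition import SPECTRUM_COLUMNS
from .exceptions import ConfigError, DataFormatError
from .phantoms import PhantomSpec

__all__ = [
    "PCAResult",
    "ScoreRegression",
    "OutlierReport",
    "run_pca",
    "fit_score_regressions",
    "fit_composition_regressions",
    "composition_correlations",
    "detect_outliers",
    "apply_outlier_mask",
    "spectra_matrix",
]

CONSTITUENTS = ("gelatin_pct", "intralipid_pct", "water_pct")


def spectra_matrix(df: pd.DataFrame) -> np.ndarray:
    """Extract the (n, 27) absorbance matrix from an interchange table."""
    return df[SPECTRUM_COLUMNS].to_numpy(dtype=float)


@dataclass(frozen=True)
class PCAResult:
    """Column-mean-centred PCA decomposition.

    loadings: (p, k) orthonormal columns; scores: (n, k) projections of the
    centred data; explained_variance_fraction: per-component share of total
    centred variance; column_means: the (p,) centring vector.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    column_means: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Centred-data reconstruction from the retained components."""
        return self.scores @ self.loadings.T


def run_pca(spectra: np.ndarray, k: int | None = None, center: bool = True) -> PCAResult:
    """PCA by SVD of the (optionally column-mean-centred) spectra matrix.

    ``k`` defaults to min(n - 1, p).  ``k`` greater than the numerical rank of
    the centred matrix raises :class:`ConfigError`.
    """
    x = np.asarray(spectra, dtype=float)
    if x.ndim != 2:
        raise DataFormatError("spectra must be a 2-D matrix")
    n, p = x.shape
    if k is None:
        k = min(n - 1, p)
    if not (1 <= k):
        raise ConfigError("need k >= 1 components")
    if n <= k:
        raise ConfigError(f"need more spectra ({n}) than components ({k})")
    means = x.mean(axis=0) if center else np.zeros(p)
    xc = x - means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        raise ConfigError(f"k={k} exceeds the numerical rank {rank} of the centred data")
    total = float(np.sum(s**2))
    return PCAResult(
        loadings=vt[:k].T,
        scores=u[:, :k] * s[:k],
        explained_variance_fraction=s[:k] ** 2 / total,
        column_means=means,
    )


@dataclass(frozen=True)
class ScoreRegression:
    """OLS of one phantom's scores on its assigned temperatures.

    ``component`` is 1-based (PC 1 = first principal component).  ``skipped``
    marks degenerate fits (constant temperature within the phantom).
    """

    phantom_id: int
    component: int
    slope: float
    intercept: float
    r_squared: float
    skipped: bool = False


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, and squared Pearson correlation of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ConfigError("degenerate regressor (constant x)")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    syy = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if syy == 0 else float(np.clip(sxy**2 / (sxx * syy), 0.0, 1.0))
    return float(slope), float(intercept), r2


def fit_score_regressions(
    pca: PCAResult,
    temperatures: np.ndarray,
    phantom_ids: np.ndarray,
) -> tuple[list[ScoreRegression], pd.DataFrame]:
    """Per-phantom, per-component OLS of score on assigned temperature.

    Also returns a per-component intercept-dispersion table with both the plain
    variance of the phantom intercepts and variance / |mean intercept| (the two
    candidate "relative variance" readings; neither is canonical).
    """
    temps = np.asarray(temperatures, float)
    pids = np.asarray(phantom_ids)
    fits: list[ScoreRegression] = []
    rows = []
    for j in range(pca.n_components):
        intercepts = []
        for pid in np.unique(pids):
            sel = pids == pid
            if sel.sum() < 3:
                raise ConfigError(f"phantom {pid}: need >= 3 points for regression")
            y = pca.scores[sel, j]
            x = temps[sel]
            if np.ptp(x) == 0:
                fits.append(ScoreRegression(int(pid), j + 1, np.nan, np.nan, np.nan, skipped=True))
                continue
            slope, intercept, r2 = _ols(x, y)
            fits.append(ScoreRegression(int(pid), j + 1, slope, intercept, r2))
            intercepts.append(intercept)
        intercepts = np.asarray(intercepts)
        var = float(np.var(intercepts)) if intercepts.size else np.nan
        mean = float(np.mean(intercepts)) if intercepts.size else np.nan
        rows.append(
            {
                "component": j + 1,
                "intercept_variance": var,
                "intercept_variance_over_abs_mean": var / abs(mean) if mean else np.inf,
            }
        )
    return fits, pd.DataFrame(rows)


def fit_composition_regressions(
    pca: PCAResult,
    phantom_ids: np.ndarray,
    phantoms: Sequence[PhantomSpec],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS of scores on each constituent's weight-percent.

    Every spectrum inherits its phantom's composition.  Returns the
    per-component, per-constituent fit table and the pairwise squared Pearson
    correlation among the constituents over the phantom design.
    """
    if len(phantoms) < 3:
        raise ConfigError("need >= 3 phantoms for composition regressions")
    comp = {p.phantom_id: p for p in phantoms}
    pids = np.asarray(phantom_ids)
    rows = []
    for j in range(pca.n_components):
        for name in CONSTITUENTS:
            x = np.array([getattr(comp[int(pid)], name) for pid in pids], float)
            if np.ptp(x) == 0:
                rows.append({"component": j + 1, "constituent": name,
                             "slope": np.nan, "r_squared": np.nan, "skipped": True})
                continue
            slope, _, r2 = _ols(x, pca.scores[:, j])
            rows.append({"component": j + 1, "constituent": name,
                         "slope": slope, "r_squared": r2, "skipped": False})
    return pd.DataFrame(rows), composition_correlations(phantoms)


def composition_correlations(phantoms: Sequence[PhantomSpec]) -> pd.DataFrame:
    """Pairwise squared Pearson correlation of constituent weight-percents."""
    vals = {name: np.array([getattr(p, name) for p in phantoms], float) for name in CONSTITUENTS}
    out = pd.DataFrame(index=list(CONSTITUENTS), columns=list(CONSTITUENTS), dtype=float)
    for a in CONSTITUENTS:
        for b in CONSTITUENTS:
            r = np.corrcoef(vals[a], vals[b])[0, 1]
            out.loc[a, b] = r**2
    return out


@dataclass
class OutlierReport:
    """Flagged recordings per phantom (positional indices within the phantom's
    time-ordered 0..n-1 sequence) plus the criterion parameters used."""

    flagged: dict[int, list[int]] = field(default_factory=dict)
    criterion: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict[int, int]:
        return {pid: len(ix) for pid, ix in self.flagged.items()}

    @property
    def total(self) -> int:
        return sum(len(ix) for ix in self.flagged.values())

    def to_dict(self) -> dict:
        return {
            "flagged": {str(k): sorted(v) for k, v in self.flagged.items()},
            "criterion": self.criterion,
            "counts": {str(k): v for k, v in self.counts.items()},
        }


def _lad_line(x: np.ndarray, y: np.ndarray, n_iter: int = 20) -> tuple[float, float]:
    """Least-absolute-deviation line by iteratively reweighted least squares."""
    w = np.ones_like(x)
    slope = intercept = 0.0
    for _ in range(n_iter):
        sw = w.sum()
        xm = np.sum(w * x) / sw
        ym = np.sum(w * y) / sw
        sxx = np.sum(w * (x - xm) ** 2)
        if sxx == 0:
            slope, intercept = 0.0, ym
        else:
            slope = np.sum(w * (x - xm) * (y - ym)) / sxx
            intercept = ym - slope * xm
        r = y - (slope * x + intercept)
        w = 1.0 / np.maximum(np.abs(r), 1e-12)
    return float(slope), float(intercept)


def detect_outliers(
    pca: PCAResult,
    temperatures: np.ndarray,
    phantom_ids: np.ndarray,
    components: Sequence[int] = (2, 3, 4),
    k_mad: float = 5.0,
    manual: Mapping[int, Sequence[int]] | None = None,
    detect: bool = True,
    min_scale: float = 1e-5,
) -> OutlierReport:
    """Flag interface-instability recordings from score-temperature residuals.

    For each phantom and each listed component (1-based), residuals from a
    robust LAD score-temperature line are compared against ``k_mad`` times
    their median absolute deviation; a recording flagged on any component is an
    outlier.  ``manual`` adds per-phantom positional indices unconditionally;
    ``detect=False`` disables the automatic criterion (manual-only mode).

    ``min_scale`` floors the residual scale (absorbance/score units) so that
    physically negligible structure -- numerical rounding or the sub-mK error
    of interpolated temperature assignment -- is never flagged, whatever its
    shape.  Interface events are orders of magnitude above it.
    """
    for c in components:
        if not (1 <= c <= pca.n_components):
            raise ConfigError(f"component {c} not present in the PCA result")
    temps = np.asarray(temperatures, float)
    pids = np.asarray(phantom_ids)
    flagged: dict[int, set[int]] = {}
    if detect:
        for pid in np.unique(pids):
            sel = np.nonzero(pids == pid)[0]
            bad: set[int] = set()
            for c in components:
                y = pca.scores[sel, c - 1]
                x = temps[sel]
                slope, intercept = _lad_line(x, y)
                resid = y - (slope * x + intercept)
                mad = float(np.median(np.abs(resid - np.median(resid))))
                if mad == 0.0:
                    if np.any(resid != 0):
                        warnings.warn(
                            f"phantom {pid}, PC {c}: zero MAD with nonzero residuals; "
                            "falling back to standard-deviation criterion",
                            stacklevel=2,
                        )
                        scale = float(np.std(resid))
                    else:
                        continue
                else:
                    scale = mad
                scale = max(scale, min_scale)
                bad.update(int(i) for i in np.nonzero(np.abs(resid) > k_mad * scale)[0])
            if bad:
                flagged[int(pid)] = bad
    if manual:
        for pid, idx in manual.items():
            flagged.setdefault(int(pid), set()).update(int(i) for i in idx)
    return OutlierReport(
        flagged={pid: sorted(ix) for pid, ix in flagged.items()},
        criterion={
            "components": list(components),
            "k_mad": k_mad,
            "min_scale": min_scale,
            "detect": detect,
            "manual": {int(k): sorted(int(i) for i in v) for k, v in (manual or {}).items()},
        },
    )


def apply_outlier_mask(
    df: pd.DataFrame, report: OutlierReport
) -> tuple[pd.DataFrame, dict]:
    """Remove flagged recordings from an interchange table.

    Non-destructive: returns a filtered copy plus a retention summary; the
    caller's table is untouched (flags can be persisted separately with the
    report).  Positional indices in the report refer to each phantom's
    time-ordered rows.
    """
    mask = np.zeros(len(df), dtype=bool)
    order = df.sort_values(["phantom_id", "step_index", "recording_index"]).index
    positions = {pid: list(order[df.loc[order, "phantom_id"] == pid]) for pid in df["phantom_id"].unique()}
    for pid, idx in report.flagged.items():
        rows = positions.get(pid, [])
        for i in idx:
            if not (0 <= i < len(rows)):
                raise DataFormatError(
                    f"outlier index {i} out of range for phantom {pid} ({len(rows)} rows)"
                )
            mask[df.index.get_loc(rows[i])] = True
    filtered = df.loc[~mask].reset_index(drop=True)
    removed_per_phantom = {
        int(pid): int(mask[(df["phantom_id"] == pid).to_numpy()].sum())
        for pid in sorted(df["phantom_id"].unique())
    }
    summary = {
        "n_total": int(len(df)),
        "removed_per_phantom": removed_per_phantom,
        "total_removed": int(mask.sum()),
        "total_retained": int((~mask).sum()),
        "retention_percent": round(100.0 * (~mask).sum() / len(df), 1),
    }
    return filtered, summary
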