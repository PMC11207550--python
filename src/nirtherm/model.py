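"""PLS1 temperature calibration models and evaluation strategies.

The central object is :class:`TemperatureCalibration`, built from recording
spectra, assigned temperatures and phantom labels; ``fit()`` returns a
:class:`CalibrationResults` carrying the regression vector, the
cross-validation curve used to pick the number of latent variables, and
metric/summary helpers.

Training spectra are mean-centred with the pooled calibration mean by default,
consistent with the prediction equation

    chat = (A_pred - Abar_cal) . b + cbar_cal

which always subtracts the pooled mean.  Pooled centring leaves the
between-phantom offset and composition directions in the training matrix, so
the latent variables can span them and the regression vector learns to be
insensitive to them -- which is what lets a model generalise to an unseen
phantom.  Per-phantom centring (``centering="per_phantom"``, each phantom's own
mean spectrum subtracted before the decomposition) is also available; it
removes all between-phantom variance from training, which makes the regression
vector blind to offset directions and markedly worsens unseen-phantom bias in
this system (see docs/methods.md).

The number of latent variables h is the only optimised parameter.  It is chosen
by leave-one-phantom-out cross-validation: for h = 1..h_max each calibration
phantom is left out in turn, the model refit (re-centred) on the rest, and the
left-out phantom predicted; PRESS(h) accumulates the squared errors and

    AIC(h) = n ln(PRESS/n) + 2 (h + 1)

is minimised (ties break to the smaller h; the +1 counts the intercept,
matching the n - h - 1 degrees of freedom of the SECV).

Two evaluation strategies are provided: :func:`run_split_strategy` (first three
temperature steps of every phantom calibrate, last two predict) and
:func:`run_lopo_strategy` (each phantom in turn is held out entirely, with
nested cross-validation among the remaining phantoms for h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .acquisition import SPECTRUM_COLUMNS
from .exceptions import ConfigError, DataFormatError, RankError
from .metrics import ModelMetrics, evaluate
from .pls import PLSCore, nipals_pls1

__all__ = [
    "PLSModel",
    "CVCurve",
    "SplitPlan",
    "TemperatureCalibration",
    "CalibrationResults",
    "center_by_phantom",
    "fit_calibration",
    "predict",
    "select_latent_variables",
    "run_split_strategy",
    "run_lopo_strategy",
    "SplitStrategyResult",
    "LOPOResult",
]

Centering = Literal["per_phantom", "pooled"]

#: floor on PRESS/n inside the AIC log, so numerically-zero PRESS curves
#: resolve ties toward the smallest h instead of chasing rounding noise
_PRESS_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Centring and the core model container
# ---------------------------------------------------------------------------

def center_by_phantom(
    spectra: np.ndarray,
    temperatures: np.ndarray,
    phantom_ids: np.ndarray,
    mode: Centering = "pooled",
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray], np.ndarray, float]:
    """Centre spectra and temperatures for PLS training.

    Returns ``(Xc, yc, per_phantom_means, pooled_mean, pooled_temp_mean)``.
    ``per_phantom`` subtracts each phantom's own mean spectrum; ``pooled``
    subtracts the grand mean from every spectrum.  Temperatures are always
    centred by the pooled calibration mean.
    """
    X = np.asarray(spectra, dtype=float)
    y = np.asarray(temperatures, dtype=float)
    pids = np.asarray(phantom_ids)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or y.shape[0] != pids.shape[0]:
        raise DataFormatError("spectra, temperatures and phantom ids must align")
    pooled_mean = X.mean(axis=0)
    pooled_temp = float(y.mean())
    per_phantom: dict[int, np.ndarray] = {}
    Xc = X - pooled_mean
    for pid in np.unique(pids):
        sel = pids == pid
        if sel.sum() < 2:
            raise ConfigError(f"phantom {pid}: need >= 2 spectra to centre")
        per_phantom[int(pid)] = X[sel].mean(axis=0)
        if mode == "per_phantom":
            Xc[sel] = X[sel] - per_phantom[int(pid)]
    if mode not in ("per_phantom", "pooled"):
        raise ConfigError(f"unknown centering mode {mode!r}")
    return Xc, y - pooled_temp, per_phantom, pooled_mean, pooled_temp


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS1 temperature model with its centring metadata."""

    b: np.ndarray
    n_latent: int
    mean_spectrum_cal: np.ndarray
    mean_temperature_cal: float
    per_phantom_means: dict[int, np.ndarray]
    centering_mode: Centering
    training_ids: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "b": self.b.tolist(),
            "n_latent": self.n_latent,
            "mean_spectrum_cal": self.mean_spectrum_cal.tolist(),
            "mean_temperature_cal": self.mean_temperature_cal,
            "per_phantom_means": {str(k): v.tolist() for k, v in self.per_phantom_means.items()},
            "centering_mode": self.centering_mode,
            "training_ids": list(self.training_ids),
        }


def fit_calibration(
    spectra: np.ndarray,
    temperatures: np.ndarray,
    phantom_ids: np.ndarray,
    h: int,
    mode: Centering = "pooled",
) -> PLSModel:
    """Centre the training data and fit an h-component PLS1 model."""
    Xc, yc, per_phantom, pooled_mean, pooled_temp = center_by_phantom(
        spectra, temperatures, phantom_ids, mode
    )
    core = nipals_pls1(Xc, yc, h)
    return PLSModel(
        b=core.b,
        n_latent=h,
        mean_spectrum_cal=pooled_mean,
        mean_temperature_cal=pooled_temp,
        per_phantom_means=per_phantom,
        centering_mode=mode,
        training_ids=tuple(int(p) for p in np.unique(np.asarray(phantom_ids))),
    )


def predict(model: PLSModel, spectra: np.ndarray) -> np.ndarray | float:
    """Predicted temperature(s): (A - Abar_cal) . b + cbar_cal.

    The pooled calibration mean is used regardless of the training centring
    mode, so unseen phantoms need no phantom-specific mean.
    """
    A = np.asarray(spectra, dtype=float)
    scalar = A.ndim == 1
    A = np.atleast_2d(A)
    if A.shape[1] != model.b.shape[0]:
        raise DataFormatError(
            f"spectra have {A.shape[1]} channels, model expects {model.b.shape[0]}"
        )
    chat = (A - model.mean_spectrum_cal) @ model.b + model.mean_temperature_cal
    return float(chat[0]) if scalar else chat


# ---------------------------------------------------------------------------
# Latent-variable selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVCurve:
    """Leave-one-phantom-out cross-validation curve over h = 1..h_max."""

    h_values: np.ndarray
    press: np.ndarray
    secv: np.ndarray
    aic: np.ndarray
    selected_h: int
    predictions: np.ndarray  # (n, len(h_values)) CV predictions per h
    reference: np.ndarray    # (n,) assigned temperatures, fold order
    fold_phantom: np.ndarray  # (n,) held-out phantom per CV prediction

    @property
    def cv_predictions(self) -> np.ndarray:
        """CV predictions at the selected h."""
        return self.predictions[:, self.selected_h - 1]


def aic_press(n: int, press: float, h: int) -> float:
    """AIC for a PRESS-based model comparison: n ln(PRESS/n) + 2(h + 1)."""
    return n * np.log(max(press / n, _PRESS_FLOOR)) + 2.0 * (h + 1)


def _fit_core_upto(Xc: np.ndarray, yc: np.ndarray, h: int) -> PLSCore:
    """Fit up to h components, backing off if the data exhaust rank first."""
    while h >= 1:
        try:
            return nipals_pls1(Xc, yc, h)
        except (RankError, np.linalg.LinAlgError):
            if h == 1:
                raise
            h -= 1
    raise ConfigError("unreachable")


def select_latent_variables(
    spectra: np.ndarray,
    temperatures: np.ndarray,
    phantom_ids: np.ndarray,
    h_max: int = 10,
    mode: Centering = "pooled",
) -> CVCurve:
    """Pick h by leave-one-phantom-out PRESS and AIC over h = 1..h_max."""
    X = np.asarray(spectra, dtype=float)
    y = np.asarray(temperatures, dtype=float)
    pids = np.asarray(phantom_ids)
    unique = np.unique(pids)
    if unique.size < 3:
        raise ConfigError("latent-variable selection needs >= 3 phantoms")

    fold_caps = []
    for pid in unique:
        n_train = int((pids != pid).sum())
        fold_caps.append(min(n_train - 1, X.shape[1]))
    h_cap = min(fold_caps)
    if h_max > h_cap:
        warnings.warn(
            f"h_max={h_max} exceeds the smallest training fold's capacity; "
            f"truncating the curve at h={h_cap}",
            stacklevel=2,
        )
        h_max = h_cap

    preds_blocks, ref_blocks, fold_blocks = [], [], []
    achieved = h_max
    for pid in unique:
        out = pids == pid
        Xc, yc, _, pooled_mean, pooled_temp = center_by_phantom(
            X[~out], y[~out], pids[~out], mode
        )
        core = _fit_core_upto(Xc, yc, h_max)
        achieved = min(achieved, core.n_latent)
        block = np.empty((int(out.sum()), core.n_latent))
        A_out = X[out] - pooled_mean
        for h in range(1, core.n_latent + 1):
            block[:, h - 1] = A_out @ core.regression_vector(h) + pooled_temp
        preds_blocks.append(block)
        ref_blocks.append(y[out])
        fold_blocks.append(pids[out])

    if achieved < h_max:
        warnings.warn(
            f"rank exhausted at h={achieved}; curve truncated", stacklevel=2
        )
    h_values = np.arange(1, achieved + 1)
    predictions = np.vstack([b[:, :achieved] for b in preds_blocks])
    reference = np.concatenate(ref_blocks)
    fold_phantom = np.concatenate(fold_blocks)
    n = reference.size
    press = np.sum((predictions - reference[:, None]) ** 2, axis=0)
    secv = np.sqrt(press / (n - h_values - 1))
    aic = np.array([aic_press(n, press[i], int(h)) for i, h in enumerate(h_values)])
    selected = int(h_values[int(np.argmin(aic))])
    return CVCurve(h_values, press, secv, aic, selected, predictions, reference, fold_phantom)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class TemperatureCalibration:
    """PLS1 temperature calibration model for a set of phantom spectra.

    Parameters
    ----------
    spectra : (n, 27) array
        Recording-level absorbance spectra.
    temperature : (n,) array
        Assigned temperatures in degC.
    phantom_id : (n,) array
        Phantom label per spectrum (the cross-validation grouping).
    centering : {"per_phantom", "pooled"}
        Training-spectra centring mode.
    h_max : int
        Largest number of latent variables scanned during selection.
    """

    def __init__(
        self,
        spectra: np.ndarray,
        temperature: np.ndarray,
        phantom_id: np.ndarray,
        centering: Centering = "pooled",
        h_max: int = 10,
    ) -> None:
        self.spectra = np.asarray(spectra, dtype=float)
        self.temperature = np.asarray(temperature, dtype=float)
        self.phantom_id = np.asarray(phantom_id)
        if not (len(self.spectra) == len(self.temperature) == len(self.phantom_id)):
            raise DataFormatError("spectra, temperature and phantom_id must align")
        self.centering: Centering = centering
        self.h_max = int(h_max)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TemperatureCalibration":
        """Build from an interchange table (a01..a27, assigned_temp_C, phantom_id)."""
        return cls(
            df[SPECTRUM_COLUMNS].to_numpy(dtype=float),
            df["assigned_temp_C"].to_numpy(dtype=float),
            df["phantom_id"].to_numpy(),
            **kwargs,
        )

    @property
    def nobs(self) -> int:
        return len(self.temperature)

    def fit(self, n_latent: int | None = None) -> "CalibrationResults":
        """Fit the model; when ``n_latent`` is None, select it by LOPO AIC."""
        cv_curve = None
        if n_latent is None:
            cv_curve = select_latent_variables(
                self.spectra, self.temperature, self.phantom_id,
                h_max=self.h_max, mode=self.centering,
            )
            n_latent = cv_curve.selected_h
        model = fit_calibration(
            self.spectra, self.temperature, self.phantom_id, n_latent, self.centering
        )
        return CalibrationResults(self, model, cv_curve)


class CalibrationResults:
    """Results of a fitted :class:`TemperatureCalibration`."""

    def __init__(
        self,
        model_spec: TemperatureCalibration,
        model: PLSModel,
        cv_curve: CVCurve | None,
    ) -> None:
        self.model_spec = model_spec
        self.model = model
        self.cv_curve = cv_curve

    # -- parameters -------------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """The PLS regression vector b (degC per absorbance unit)."""
        return self.model.b

    @property
    def n_latent(self) -> int:
        return self.model.n_latent

    @property
    def nobs(self) -> int:
        return self.model_spec.nobs

    # -- prediction and metrics -------------------------------------------
    def predict(self, spectra: np.ndarray) -> np.ndarray | float:
        return predict(self.model, spectra)

    @property
    def secv(self) -> float | None:
        """Cross-validation SECV at the selected h (None without a CV curve)."""
        if self.cv_curve is None:
            return None
        return float(self.cv_curve.secv[self.cv_curve.selected_h - 1])

    def cv_metrics(self) -> ModelMetrics:
        """Metrics of the cross-validated predictions at the selected h."""
        if self.cv_curve is None:
            raise ConfigError("model was fitted with a fixed h; no CV curve available")
        cv = self.cv_curve
        return evaluate(cv.reference, cv.cv_predictions, self.n_latent, secv_value=self.secv)

    def metrics(self, spectra: np.ndarray, reference: np.ndarray) -> ModelMetrics:
        """Prediction-set metrics for external spectra (carries the model SECV)."""
        chat = np.atleast_1d(self.predict(spectra))
        return evaluate(reference, chat, self.n_latent, secv_value=self.secv)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "PLS1 temperature calibration",
            "=" * 46,
            f"observations           {self.nobs}",
            f"phantoms               {list(self.model.training_ids)}",
            f"centering              {self.model.centering_mode}",
            f"latent variables (h)   {self.n_latent}",
        ]
        if self.cv_curve is not None:
            m = self.cv_metrics()
            lines += [
                f"SECV                   {m.secv:.3f} degC",
                f"CV R^2                 {m.r_squared:.3f}",
                f"CV bias                {m.bias:+.3f} degC",
                "",
                "h    PRESS        SECV     AIC",
            ]
            cv = self.cv_curve
            for i, h in enumerate(cv.h_values):
                tag = " *" if h == cv.selected_h else ""
                lines.append(
                    f"{int(h):<4d} {cv.press[i]:<12.4g} {cv.secv[i]:<8.3f} {cv.aic[i]:.2f}{tag}"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<CalibrationResults h={self.n_latent} nobs={self.nobs}>"


# ---------------------------------------------------------------------------
# Evaluation strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Row partition of the retained dataset by temperature-step order."""

    calibration_index: np.ndarray
    prediction_index: np.ndarray

    def __post_init__(self) -> None:
        cal = set(self.calibration_index.tolist())
        pred = set(self.prediction_index.tolist())
        if cal & pred:
            raise ConfigError("calibration and prediction indices overlap")


def _build_split_plan(df: pd.DataFrame, n_cal_steps: int = 3) -> SplitPlan:
    for pid, grp in df.groupby("phantom_id"):
        steps = set(int(s) for s in grp["step_index"].unique())
        if len(steps) < n_cal_steps:
            raise ConfigError(
                f"phantom {pid} has only steps {sorted(steps)}; "
                f"need >= {n_cal_steps} distinct temperature steps"
            )
    cal_mask = (df["step_index"] < n_cal_steps).to_numpy()
    return SplitPlan(
        calibration_index=np.nonzero(cal_mask)[0],
        prediction_index=np.nonzero(~cal_mask)[0],
    )


@dataclass
class SplitStrategyResult:
    """Single model from the calibration/prediction step split."""

    plan: SplitPlan
    results: CalibrationResults
    calibration_metrics: ModelMetrics
    prediction_metrics: ModelMetrics
    predicted_calibration: np.ndarray  # CV predictions (fold order)
    predicted_prediction: np.ndarray

    def summary(self) -> str:
        cm, pm = self.calibration_metrics, self.prediction_metrics
        return "\n".join(
            [
                "Calibration/prediction split strategy",
                "=" * 46,
                f"latent variables (h)   {self.results.n_latent}",
                f"calibration spectra    {cm.n}",
                f"prediction spectra     {pm.n}",
                f"SECV                   {cm.secv:.3f} degC",
                f"SEP                    {pm.sep:.3f} degC",
                f"RSEP                   {pm.rsep:.2f} %",
                f"R^2 (calibration)      {cm.r_squared:.3f}",
                f"R^2 (prediction)       {pm.r_squared:.3f}",
                f"bias (prediction)      {pm.bias:+.3f} degC",
                f"fit slope/intercept    {pm.fit_slope:.3f} / {pm.fit_intercept:+.2f} degC",
            ]
        )


def run_split_strategy(
    df: pd.DataFrame,
    h_max: int = 10,
    centering: Centering = "pooled",
) -> SplitStrategyResult:
    """First three temperature steps calibrate; the last two are predicted.

    h is selected by leave-one-phantom-out AIC on the calibration subset only;
    the final model is refit on the whole calibration subset.
    """
    df = df.reset_index(drop=True)
    plan = _build_split_plan(df)
    cal = df.iloc[plan.calibration_index]
    pred = df.iloc[plan.prediction_index]
    res = TemperatureCalibration.from_dataframe(cal, centering=centering, h_max=h_max).fit()
    cal_metrics = res.cv_metrics()
    pred_spectra = pred[SPECTRUM_COLUMNS].to_numpy(dtype=float)
    pred_ref = pred["assigned_temp_C"].to_numpy(dtype=float)
    pred_metrics = res.metrics(pred_spectra, pred_ref)
    return SplitStrategyResult(
        plan=plan,
        results=res,
        calibration_metrics=cal_metrics,
        prediction_metrics=pred_metrics,
        predicted_calibration=res.cv_curve.cv_predictions,
        predicted_prediction=np.atleast_1d(res.predict(pred_spectra)),
    )


@dataclass
class PhantomHoldout:
    """One leave-one-phantom-out row: model + prediction of the held-out phantom."""

    held_out: int
    results: CalibrationResults
    reference: np.ndarray
    predicted: np.ndarray
    metrics: ModelMetrics
    r2_calibration: float


@dataclass
class LOPOResult:
    """Seven (one per phantom) leave-one-phantom-out models and their report."""

    holdouts: list[PhantomHoldout] = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for h in self.holdouts:
            m = h.metrics
            rows.append(
                {
                    "held_out_phantom": h.held_out,
                    "latent_variables": h.results.n_latent,
                    "secv_C": m.secv,
                    "sep_C": m.sep,
                    "rsep_pct": m.rsep,
                    "r2_calibration": h.r2_calibration,
                    "r2_prediction": m.r_squared,
                    "bias_C": m.bias,
                }
            )
        return pd.DataFrame(rows)

    @property
    def median_sep(self) -> float:
        return float(np.median([h.metrics.sep for h in self.holdouts]))

    def summary(self) -> str:
        t = self.table
        lines = [
            "Leave-one-phantom-out strategy",
            "=" * 72,
            t.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
            ),
            f"median SEP  {self.median_sep:.3f} degC",
        ]
        return "\n".join(lines)


def run_lopo_strategy(
    df: pd.DataFrame,
    h_max: int = 10,
    centering: Centering = "pooled",
) -> LOPOResult:
    """Hold each phantom out entirely; calibrate on the rest and predict it.

    h is chosen per model by nested leave-one-phantom-out AIC among the
    remaining phantoms.  The per-model report mirrors the standard column set:
    latent variables, SECV, SEP, RSEP, R^2 (calibration), R^2 (prediction),
    bias.
    """
    df = df.reset_index(drop=True)
    pids = sorted(int(p) for p in df["phantom_id"].unique())
    if len(pids) < 3:
        raise ConfigError("leave-one-phantom-out needs >= 3 phantoms")
    out = LOPOResult()
    for pid in pids:
        train = df[df["phantom_id"] != pid]
        test = df[df["phantom_id"] == pid]
        res = TemperatureCalibration.from_dataframe(
            train, centering=centering, h_max=h_max
        ).fit()
        ref = test["assigned_temp_C"].to_numpy(dtype=float)
        spectra = test[SPECTRUM_COLUMNS].to_numpy(dtype=float)
        m = res.metrics(spectra, ref)
        out.holdouts.append(
            PhantomHoldout(
                held_out=pid,
                results=res,
                reference=ref,
                predicted=np.atleast_1d(res.predict(spectra)),
                metrics=m,
                r2_calibration=res.cv_metrics().r_squared,
            )
        )
    return out
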