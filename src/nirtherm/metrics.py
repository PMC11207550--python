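"""Figures of merit for temperature calibration models.

SECV = sqrt( sum (c_i - chat_i)^2 / (n - h - 1) )   (cross-validation, with
degrees of freedom for n samples, h latent variables and an intercept)

SEP  = sqrt( sum (c_i - chat_i)^2 / n )             (prediction)

RSEP = 100 * SEP / mean(reference)                  (percent of mean reference
temperature; the normaliser is a package convention, configurable)

bias = mean(predicted - reference); slope/intercept/R^2 come from the OLS of
predicted on reference temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import ConfigError, DataFormatError

__all__ = ["ModelMetrics", "secv", "sep", "rsep", "bias_and_fit", "evaluate"]


@dataclass(frozen=True)
class ModelMetrics:
    """Table-style metric bundle for one model / prediction set."""

    n: int
    h: int
    secv: float | None
    sep: float
    rsep: float
    r_squared: float
    bias: float
    fit_slope: float
    fit_intercept: float

    def to_dict(self) -> dict:
        return asdict(self)


def _residual_arrays(reference, predicted) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(reference, dtype=float)
    chat = np.asarray(predicted, dtype=float)
    if c.shape != chat.shape or c.ndim != 1:
        raise DataFormatError("reference and predicted must be matching 1-D arrays")
    if c.size == 0:
        raise DataFormatError("empty input")
    return c, chat


def secv(reference, predicted, h: int) -> float:
    """Standard error of cross-validation with n - h - 1 degrees of freedom."""
    c, chat = _residual_arrays(reference, predicted)
    n = c.size
    if n <= h + 1:
        raise ConfigError(f"SECV needs n > h + 1 (n={n}, h={h})")
    return float(np.sqrt(np.sum((c - chat) ** 2) / (n - h - 1)))


def sep(reference, predicted) -> float:
    """Standard error of prediction (root mean squared error)."""
    c, chat = _residual_arrays(reference, predicted)
    return float(np.sqrt(np.mean((c - chat) ** 2)))


def rsep(sep_value: float, reference) -> float:
    """Relative SEP: percent of the mean reference temperature."""
    c = np.asarray(reference, dtype=float)
    m = c.mean()
    if m == 0:
        raise ConfigError("RSEP undefined for zero-mean reference temperatures")
    return float(100.0 * sep_value / m)


def bias_and_fit(reference, predicted) -> tuple[float, float, float, float]:
    """(bias, slope, intercept, r_squared) of predicted vs reference.

    bias is the mean signed error (predicted minus reference); slope/intercept
    come from the OLS of predicted on reference, and r_squared is the squared
    Pearson correlation.  A constant reference leaves the fit undefined.
    """
    c, chat = _residual_arrays(reference, predicted)
    if c.size < 3:
        raise ConfigError("need >= 3 points for the predicted-vs-reference fit")
    bias = float(np.mean(chat - c))
    sxx = np.sum((c - c.mean()) ** 2)
    if sxx == 0:
        raise ConfigError("constant reference temperatures: fit undefined")
    sxy = np.sum((c - c.mean()) * (chat - chat.mean()))
    slope = float(sxy / sxx)
    intercept = float(chat.mean() - slope * c.mean())
    syy = np.sum((chat - chat.mean()) ** 2)
    r2 = 0.0 if syy == 0 else float(np.clip(sxy**2 / (sxx * syy), 0.0, 1.0))
    return bias, slope, intercept, r2


def evaluate(reference, predicted, h: int, secv_value: float | None = None) -> ModelMetrics:
    """Bundle all prediction-set metrics for a model with ``h`` latent variables."""
    c, chat = _residual_arrays(reference, predicted)
    sep_value = sep(c, chat)
    bias, slope, intercept, r2 = bias_and_fit(c, chat)
    return ModelMetrics(
        n=int(c.size),
        h=int(h),
        secv=secv_value,
        sep=sep_value,
        rsep=rsep(sep_value, c),
        r_squared=r2,
        bias=bias,
        fit_slope=slope,
        fit_intercept=intercept,
    )
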