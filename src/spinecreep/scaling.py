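"""Per-feature linear scaling of sequence features to [−1, 1].

Every model feature χ (τ_t plus the ten loop parameters) is mapped by

    χⁿ = (χ − χ_m) / χ_d,   χ_m = (χ_max + χ_min)/2,   χ_d = (χ_max − χ_min)/2

so the fitting minimum and maximum land exactly on −1 and +1.  The inverse is
the exact affine inverse.  Values outside the fitted range map outside
[−1, 1] (prediction-time extrapolation) with a warning, not an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .hysteresis import HysteresisParams

__all__ = ["ScalingSpec", "SequenceScaler", "INPUT_FEATURES", "OUTPUT_FEATURES"]

#: Model feature order: environmental input first, then the ten parameters.
INPUT_FEATURES = ("tau_t",) + HysteresisParams.FIELDS
OUTPUT_FEATURES = HysteresisParams.FIELDS


@dataclass(frozen=True)
class ScalingSpec:
    """Frozen per-feature midpoints and half-ranges in a fixed feature order."""

    feature_names: tuple[str, ...]
    chi_m: np.ndarray
    chi_d: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "chi_m": np.asarray(self.chi_m).tolist(),
            "chi_d": np.asarray(self.chi_d).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScalingSpec":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tuple(payload["feature_names"]),
            np.asarray(payload["chi_m"], dtype=float),
            np.asarray(payload["chi_d"], dtype=float),
        )


class SequenceScaler(BaseEstimator, TransformerMixin):
    """Min–max [−1, 1] scaler over per-cycle feature rows.

    ``fit`` expects a 2-D array (n_cycles, n_features) — stack all cycles of
    all sequences — or a 3-D padded batch with a boolean mask.  Constant
    features get a half-range of 1 (identity slope) with a warning.
    """

    def __init__(self, feature_names: tuple[str, ...] = INPUT_FEATURES):
        self.feature_names = feature_names

    def fit(self, X, y=None, mask=None):
        rows = self._rows(X, mask)
        if rows.size == 0:
            raise ValueError("cannot fit a scaler on empty data")
        if not np.all(np.isfinite(rows)):
            raise ValueError("features must be finite")
        if rows.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {rows.shape[1]}"
            )
        lo = rows.min(axis=0)
        hi = rows.max(axis=0)
        chi_d = (hi - lo) / 2.0
        constant = chi_d == 0.0
        if np.any(constant):
            warnings.warn(
                "constant feature(s) "
                f"{[self.feature_names[i] for i in np.flatnonzero(constant)]}; "
                "using half-range 1",
                stacklevel=2,
            )
            chi_d = np.where(constant, 1.0, chi_d)
        self.chi_m_ = (hi + lo) / 2.0
        self.chi_d_ = chi_d
        # fit extrema kept so the transform lands on ±1 exactly, not to 1 ulp
        self.lo_ = np.where(constant, lo - 1.0, lo)
        self.span_ = np.where(constant, 2.0, hi - lo)
        self.spec_ = ScalingSpec(tuple(self.feature_names), self.chi_m_, self.chi_d_)
        return self

    def transform(self, X, warn_extrapolation: bool = True):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        # algebraically (χ − χ_m)/χ_d, arranged so the fit extrema map to ±1
        # exactly in floating point
        out = 2.0 * (X - self.lo_) / self.span_ - 1.0
        if warn_extrapolation and np.any(np.abs(out) > 1.0 + 1e-9):
            warnings.warn("values outside the fitted range map outside [-1, 1]", stacklevel=2)
        return out

    def inverse_transform(self, Xn):
        self._check_fitted()
        return (np.asarray(Xn, dtype=float) + 1.0) / 2.0 * self.span_ + self.lo_

    def subset(self, names) -> "SequenceScaler":
        """Scaler restricted to a subset of the fitted features (e.g. outputs)."""
        self._check_fitted()
        idx = [self.feature_names.index(n) for n in names]
        sub = SequenceScaler(tuple(names))
        sub.chi_m_ = self.chi_m_[idx]
        sub.chi_d_ = self.chi_d_[idx]
        sub.lo_ = self.lo_[idx]
        sub.span_ = self.span_[idx]
        sub.spec_ = ScalingSpec(tuple(names), sub.chi_m_, sub.chi_d_)
        return sub

    @classmethod
    def from_spec(cls, spec: ScalingSpec) -> "SequenceScaler":
        scaler = cls(tuple(spec.feature_names))
        scaler.chi_m_ = np.asarray(spec.chi_m, dtype=float)
        scaler.chi_d_ = np.asarray(spec.chi_d, dtype=float)
        scaler.lo_ = scaler.chi_m_ - scaler.chi_d_
        scaler.span_ = 2.0 * scaler.chi_d_
        scaler.spec_ = spec
        return scaler

    @staticmethod
    def _rows(X, mask):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return X
        if X.ndim == 3:
            if mask is None:
                return X.reshape(-1, X.shape[-1])
            mask = np.asarray(mask, dtype=bool)
            return X[mask]
        raise ValueError("expected a 2-D feature matrix or 3-D padded batch")

    def _check_fitted(self):
        if not hasattr(self, "chi_m_"):
            raise ValueError("SequenceScaler is not fitted")
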