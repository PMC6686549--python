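"""LMS growth-reference tables and the BMI-for-age z-score transform.

The LMS method summarises a growth reference at each age by a Box-Cox
power ``L``, a median ``M`` and a coefficient of variation ``S``.  A
measurement ``x`` maps to

    z = ((x / M)**L - 1) / (L * S)        for L != 0
    z = ln(x / M) / S                     in the L -> 0 limit

Tables are read in the CDC growth-chart CSV dialect (columns ``Sex``,
``Agemos``, ``L``, ``M``, ``S``; sex coded 1 = male, 2 = female).  Ages
between tabulated rows are linearly interpolated in L, M and S.  A smooth
synthetic reference covering 24-72 months ships with the package so that
tests and simulations need no external download; it is *not* the CDC 2000
reference, only shaped like one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AgeRangeError, DomainError, SchemaError

_L_EPS = 1e-8
_SEX_CODES = {"1": "male", "2": "female", "male": "male", "female": "female",
              "m": "male", "f": "female"}


def lms_zscore(x, L, M, S):
    """z-score of measurement ``x`` under LMS parameters.

    Uses the analytic log-limit branch when ``|L| <= 1e-8``; the two
    branches agree to well below 1e-6 at the switch point.  Vectorised
    over all arguments.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("measurement must be positive for LMS z-score")
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        power = (np.power(ratio, L) - 1.0) / (L * S)
        log = np.log(ratio) / S
    z = np.where(np.abs(L) > _L_EPS, power, log)
    return z.item() if z.ndim == 0 else z


def lms_inverse(z, L, M, S):
    """Measurement whose z-score is ``z``: x = M (1 + L S z)^(1/L)."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = 1.0 + L * S * z
        if np.any(base <= 0):
            raise DomainError("z outside the invertible range of the LMS curve")
        power = M * np.power(base, 1.0 / L)
        log = M * np.exp(S * z)
    x = np.where(np.abs(L) > _L_EPS, power, log)
    return x.item() if x.ndim == 0 else x


class LMSTable:
    """Sex- and age-indexed LMS reference with linear interpolation."""

    def __init__(self, frame: pd.DataFrame):
        required = {"sex", "agemos", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"LMS table missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["sex"] = frame["sex"].astype(str).str.strip().str.lower().map(_SEX_CODES)
        if frame["sex"].isna().any():
            raise SchemaError("LMS sex column must code male/female (or 1/2)")
        frame = frame.sort_values(["sex", "agemos"]).reset_index(drop=True)
        if (frame["M"] <= 0).any() or (frame["S"] <= 0).any():
            raise SchemaError("LMS M and S must be positive")
        dup = frame.duplicated(subset=["sex", "agemos"])
        if dup.any():
            raise SchemaError("duplicate (sex, age) rows in LMS table")
        self._by_sex = {
            sex: (grp["agemos"].to_numpy(float),
                  grp["L"].to_numpy(float),
                  grp["M"].to_numpy(float),
                  grp["S"].to_numpy(float))
            for sex, grp in frame.groupby("sex")
        }
        self.frame = frame

    @classmethod
    def from_csv(cls, path) -> "LMSTable":
        raw = pd.read_csv(path)
        cols = {c.lower(): c for c in raw.columns}
        try:
            frame = pd.DataFrame({
                "sex": raw[cols["sex"]],
                "agemos": raw[cols["agemos"]],
                "L": raw[cols["l"]],
                "M": raw[cols["m"]],
                "S": raw[cols["s"]],
            })
        except KeyError as exc:
            raise SchemaError(f"LMS CSV lacks required column {exc}") from exc
        return cls(frame)

    def to_csv(self, path) -> None:
        out = self.frame.rename(columns={"sex": "Sex", "agemos": "Agemos"})
        out["Sex"] = out["Sex"].map({"male": 1, "female": 2})
        out.to_csv(path, index=False)

    def age_range(self, sex: str) -> tuple[float, float]:
        ages = self._arrays(sex)[0]
        return float(ages[0]), float(ages[-1])

    def _arrays(self, sex: str):
        key = _SEX_CODES.get(str(sex).strip().lower())
        if key is None or key not in self._by_sex:
            raise SchemaError(f"unknown sex {sex!r} in LMS lookup")
        return self._by_sex[key]

    def lookup(self, sex: str, age):
        """Interpolated (L, M, S) at ``age`` months; exact rows pass through."""
        ages, L, M, S = self._arrays(sex)
        age_arr = np.asarray(age, dtype=float)
        if np.any(age_arr < ages[0]) or np.any(age_arr > ages[-1]):
            raise AgeRangeError(
                f"age {age} months outside LMS coverage "
                f"[{ages[0]:g}, {ages[-1]:g}] for sex={sex}")
        li = np.interp(age_arr, ages, L)
        mi = np.interp(age_arr, ages, M)
        si = np.interp(age_arr, ages, S)
        if age_arr.ndim == 0:
            return float(li), float(mi), float(si)
        return li, mi, si

    def zscore(self, x, sex: str, age):
        L, M, S = self.lookup(sex, age)
        return lms_zscore(x, L, M, S)

    def inverse(self, z, sex: str, age):
        L, M, S = self.lookup(sex, age)
        return lms_inverse(z, L, M, S)


def synthetic_lms_table(age_min: float = 18.0, age_max: float = 84.0,
                        step: float = 3.0) -> LMSTable:
    """Smooth synthetic BMI-for-age LMS reference for both sexes.

    The median declines from ~16.8 kg/m^2 at 24 months toward ~15.7 at
    72 months with a shallow rebound, the skewness parameter L sits near
    -1.6 and S near 0.08, mimicking the shape of pediatric BMI
    references.  Synthetic stand-in only; do not use for clinical work.
    """
    ages = np.arange(age_min, age_max + 0.5 * step, step, dtype=float)
    rows = []
    for sex, m_off, s_off in (("male", 0.0, 0.0), ("female", -0.15, 0.003)):
        t = ages - 24.0
        M = 16.8 - 0.045 * t + 0.0004 * t ** 2 + m_off
        L = -1.6 + 0.004 * t
        S = 0.078 + 0.0003 * t + s_off
        for a, l_, m_, s_ in zip(ages, L, M, S):
            rows.append({"sex": sex, "agemos": a, "L": l_, "M": m_, "S": s_})
    return LMSTable(pd.DataFrame(rows))
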