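"""Anthropometric scoring and cleaning for SMART-style child records.

Weight-for-height (WHZ) and MUAC-for-age (MUACZ) Z-scores are computed with
the LMS method against a growth reference expressed as Box-Cox power (L),
median (M) and coefficient of variation (S) per sex and key value (height in
cm for WHZ, age in months for MUACZ).  Raw child records are cleaned with
four exclusion criteria, applied in order with first-failure reporting:

(i)   incomplete minimal variable set,
(ii)  age outside 6-59 completed months,
(iii) sub-county location of the cluster unknown,
(iv)  implausible Z-score (|WHZ| > 5 or |MUACZ| > 5).

Global acute malnutrition (GAM) is WHZ < -2 and/or bilateral oedema; severe
acute malnutrition (SAM) is WHZ < -3 and/or bilateral oedema, so SAM implies
GAM.  Stratum-level estimates are unweighted child-level proportions/means
(SMART cluster designs are approximately self-weighting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "MINIMAL_VARIABLES",
    "LMSReference",
    "AnthroResult",
    "age_in_months",
    "lms_zscore",
    "lms_inverse",
    "sd_cutoff",
    "restricted_whz",
    "classify",
    "clean_child",
    "clean_table",
    "stratum_estimates",
    "attrition_summary",
    "eligibility_percentage",
    "mean_observations_per_stratum",
]

#: Calendar-average days per month used to convert ages reported in days.
DAYS_PER_MONTH = 30.4375

#: Minimal variable set a record must have to be analysable (criterion i).
MINIMAL_VARIABLES = (
    "cluster",
    "child_id",
    "age_value",
    "age_unit",
    "sex",
    "weight",
    "height",
    "oedema",
    "muac",
)

# Exclusion codes, in precedence order.
EXCLUSION_NONE = "none"
EXCLUSION_INCOMPLETE = "incomplete"
EXCLUSION_AGE = "age_range"
EXCLUSION_SUBCOUNTY = "unknown_subcounty"
EXCLUSION_IMPLAUSIBLE = "implausible_z"
EXCLUSION_ORDER = (
    EXCLUSION_INCOMPLETE,
    EXCLUSION_AGE,
    EXCLUSION_SUBCOUNTY,
    EXCLUSION_IMPLAUSIBLE,
)

#: MUAC values above this are interpreted as millimetres and divided by 10.
MUAC_MM_THRESHOLD = 30.0


def age_in_months(value: float, unit: str) -> float:
    """Convert a reported age to (real-valued) months.

    Ages in days are converted at ``DAYS_PER_MONTH`` = 30.4375 days/month;
    ages already in months pass through unchanged.
    """
    if unit not in ("months", "days"):
        raise ValueError(f"unknown age unit {unit!r}; expected 'months' or 'days'")
    value = float(value)
    if not value > 0:
        raise ValueError("age must be positive")
    return value if unit == "months" else value / DAYS_PER_MONTH


def lms_zscore(y, L, M, S):
    """LMS Z-score: ``((y/M)**L - 1) / (L*S)`` for L != 0, ``ln(y/M)/S`` at L = 0.

    Accepts scalars or arrays; ``y``, ``M`` and ``S`` must be positive.
    """
    y = np.asarray(y, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(y <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("y, M and S must all be positive")
    logr = np.log(y / M)
    with np.errstate(divide="ignore", invalid="ignore"):
        # expm1 keeps the L != 0 branch stable as L -> 0 and makes the two
        # branches agree in the limit
        z = np.where(
            L == 0,
            logr / S,
            np.expm1(np.where(L == 0, 1.0, L) * logr) / (np.where(L == 0, 1.0, L) * S),
        )
    return float(z) if z.ndim == 0 else z


def lms_inverse(z, L, M, S):
    """Measurement value whose LMS Z-score is ``z`` (inverse of :func:`lms_zscore`)."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    Lsafe = np.where(L == 0, 1.0, L)
    arg = np.maximum(Lsafe * S * z, -1.0 + 1e-15)
    with np.errstate(divide="ignore", invalid="ignore"):
        # log1p/exp form is stable as L -> 0 and matches the L = 0 branch
        y = np.where(L == 0, M * np.exp(S * z), M * np.exp(np.log1p(arg) / Lsafe))
    return float(y) if y.ndim == 0 else y


def sd_cutoff(k, L, M, S):
    """Measurement value at the k-SD line of the reference: ``M*(1 + k*L*S)**(1/L)``."""
    return lms_inverse(k, L, M, S)


def restricted_whz(y, L, M, S):
    """WHZ with the restricted adjustment applied outside +/-3 SD.

    Inside [-3, 3] the raw LMS Z-score is returned.  Beyond 3 SD the score is
    extended linearly in the measurement scale:

    * above:  ``3 + (y - SD3pos) / (SD3pos - SD2pos)``
    * below:  ``-3 + (y - SD3neg) / (SD2neg - SD3neg)``

    where ``SDk`` is the measurement value at the k-SD line.  This mirrors the
    restricted application of the WHO standards used by standard anthropometry
    scoring software; it is applied to WHZ only, never to MUACZ.
    """
    scalar = np.isscalar(y) or (np.ndim(y) == 0)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    L = np.broadcast_to(np.asarray(L, dtype=float), y.shape)
    M = np.broadcast_to(np.asarray(M, dtype=float), y.shape)
    S = np.broadcast_to(np.asarray(S, dtype=float), y.shape)
    z = np.atleast_1d(lms_zscore(y, L, M, S))
    sd3p = sd_cutoff(3, L, M, S)
    sd2p = sd_cutoff(2, L, M, S)
    sd3n = sd_cutoff(-3, L, M, S)
    sd2n = sd_cutoff(-2, L, M, S)
    if np.any(~np.isfinite(sd3p) | ~np.isfinite(sd3n)) or np.any(
        (sd3p - sd2p) <= 0
    ) or np.any((sd2n - sd3n) <= 0):
        raise ValueError("reference row yields non-finite or degenerate SD cutoffs")
    out = np.where(
        z > 3,
        3.0 + (y - sd3p) / (sd3p - sd2p),
        np.where(z < -3, -3.0 + (y - sd3n) / (sd2n - sd3n), z),
    )
    return float(out[0]) if scalar else out


class LMSReference:
    """A growth-standard lookup table of (indicator, sex, key) -> (L, M, S).

    ``indicator`` is ``"wfh"`` (weight-for-height; key = height cm) or
    ``"mfa"`` (MUAC-for-age; key = age months).  Keys must be strictly
    increasing within each (indicator, sex) block; lookups between tabulated
    keys interpolate L, M and S linearly, and keys outside the tabulated
    range raise :class:`OutOfReferenceError` (scalar) or return NaN (array).
    """

    COLUMNS = ("indicator", "sex", "key", "L", "M", "S")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        table = table.loc[:, list(self.COLUMNS)].copy()
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("reference M and S must be positive")
        self._blocks: dict[tuple[str, str], tuple[np.ndarray, ...]] = {}
        for (ind, sex), grp in table.groupby(["indicator", "sex"], sort=True):
            keys = grp["key"].to_numpy(dtype=float)
            order = np.argsort(keys)
            keys = keys[order]
            if np.any(np.diff(keys) <= 0):
                raise ValueError(f"keys not strictly increasing for ({ind}, {sex})")
            self._blocks[(str(ind), str(sex))] = (
                keys,
                grp["L"].to_numpy(dtype=float)[order],
                grp["M"].to_numpy(dtype=float)[order],
                grp["S"].to_numpy(dtype=float)[order],
            )
        self.table = table

    def lookup(self, indicator: str, sex: str, key: float) -> tuple[float, float, float]:
        """Interpolated (L, M, S) at ``key``; raises if outside the table range."""
        L, M, S = self.lookup_many(indicator, sex, np.asarray([key], dtype=float))
        if not np.isfinite(M[0]):
            raise OutOfReferenceError(
                f"key {key} outside reference range for ({indicator}, {sex})"
            )
        return float(L[0]), float(M[0]), float(S[0])

    def lookup_many(self, indicator: str, sex: str, keys) -> tuple[np.ndarray, ...]:
        """Vectorised lookup; out-of-range keys yield NaN in all three outputs."""
        try:
            kk, LL, MM, SS = self._blocks[(indicator, sex)]
        except KeyError:
            raise OutOfReferenceError(f"no reference block for ({indicator}, {sex})")
        keys = np.asarray(keys, dtype=float)
        inside = (keys >= kk[0]) & (keys <= kk[-1])
        L = np.where(inside, np.interp(keys, kk, LL), np.nan)
        M = np.where(inside, np.interp(keys, kk, MM), np.nan)
        S = np.where(inside, np.interp(keys, kk, SS), np.nan)
        return L, M, S

    @classmethod
    def read_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class OutOfReferenceError(KeyError):
    """Requested key falls outside the tabulated reference range."""


def classify(whz: float, oedema: bool) -> tuple[bool, bool]:
    """(GAM, SAM) flags: GAM iff WHZ < -2 or oedema; SAM iff WHZ < -3 or oedema."""
    if not np.isfinite(whz):
        raise ValueError("WHZ must be finite to classify")
    oedema = bool(oedema)
    return (whz < -2) or oedema, (whz < -3) or oedema


@dataclass
class AnthroResult:
    """Scored/cleaned outcome for a single child record."""

    whz: float
    muacz: float
    gam: bool | None
    sam: bool | None
    exclusion: str


def _normalise_muac_cm(muac: np.ndarray) -> np.ndarray:
    """MUAC in cm; values above 30 are interpreted as millimetres."""
    return np.where(muac > MUAC_MM_THRESHOLD, muac / 10.0, muac)


def clean_table(
    children: pd.DataFrame,
    ref: LMSReference,
    known_subcounties: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Score and clean a raw child table.

    Returns a copy of ``children`` with added columns ``age_months``, ``whz``
    (restricted), ``muacz``, ``gam``, ``sam`` and ``exclusion``.  Exclusion
    codes are assigned with precedence i (incomplete) -> ii (age_range) ->
    iii (unknown_subcounty) -> iv (implausible_z); Z-scores are computed
    wherever the inputs allow, before criterion iv is judged.  Records whose
    height or age falls outside the reference range cannot be scored and are
    flagged ``implausible_z``.
    """
    out = children.copy()
    n = len(out)

    complete = np.ones(n, dtype=bool)
    for col in MINIMAL_VARIABLES:
        if col not in out.columns:
            complete[:] = False
            break
        complete &= out[col].notna().to_numpy()

    age_val = pd.to_numeric(out.get("age_value"), errors="coerce").to_numpy(dtype=float)
    unit = out.get("age_unit", pd.Series(["months"] * n)).astype(str).to_numpy()
    age_months = np.where(unit == "days", age_val / DAYS_PER_MONTH, age_val)
    age_ok = (age_months >= 6) & (age_months < 60)
    out["age_months"] = age_months

    sc = out.get("subcounty")
    if sc is None:
        sc_known = np.zeros(n, dtype=bool)
    else:
        sc_known = sc.notna().to_numpy()
        if known_subcounties is not None:
            allowed = set(known_subcounties)
            sc_known &= sc.astype(str).isin(allowed).to_numpy()

    # Z-scores (computed where inputs permit, independent of criteria i-iii)
    weight = pd.to_numeric(out.get("weight"), errors="coerce").to_numpy(dtype=float)
    height = pd.to_numeric(out.get("height"), errors="coerce").to_numpy(dtype=float)
    muac = _normalise_muac_cm(
        pd.to_numeric(out.get("muac"), errors="coerce").to_numpy(dtype=float)
    )
    sex = out.get("sex", pd.Series([""] * n)).astype(str).to_numpy()

    whz = np.full(n, np.nan)
    muacz = np.full(n, np.nan)
    for s in np.unique(sex):
        m = sex == s
        if not m.any() or s not in ("male", "female"):
            continue
        hv = np.where(np.isfinite(height[m]) & (height[m] > 0), height[m], np.nan)
        try:
            Lw, Mw, Sw = ref.lookup_many("wfh", s, hv)
        except OutOfReferenceError:
            Lw = Mw = Sw = np.full(m.sum(), np.nan)
        wv = weight[m]
        okw = np.isfinite(Mw) & np.isfinite(wv) & (wv > 0)
        zw = np.full(m.sum(), np.nan)
        if okw.any():
            zw[okw] = restricted_whz(wv[okw], Lw[okw], Mw[okw], Sw[okw])
        whz[m] = zw

        av = np.where(np.isfinite(age_months[m]), age_months[m], np.nan)
        try:
            La, Ma, Sa = ref.lookup_many("mfa", s, av)
        except OutOfReferenceError:
            La = Ma = Sa = np.full(m.sum(), np.nan)
        mv = muac[m]
        oka = np.isfinite(Ma) & np.isfinite(mv) & (mv > 0)
        za = np.full(m.sum(), np.nan)
        if oka.any():
            za[oka] = lms_zscore(mv[oka], La[oka], Ma[oka], Sa[oka])
        muacz[m] = za

    out["whz"] = whz
    out["muacz"] = muacz

    plausible = np.isfinite(whz) & np.isfinite(muacz) & (np.abs(whz) <= 5) & (
        np.abs(muacz) <= 5
    )

    exclusion = np.full(n, EXCLUSION_NONE, dtype=object)
    exclusion[~plausible] = EXCLUSION_IMPLAUSIBLE
    exclusion[~sc_known] = EXCLUSION_SUBCOUNTY
    exclusion[~age_ok] = EXCLUSION_AGE
    exclusion[~complete] = EXCLUSION_INCOMPLETE
    out["exclusion"] = exclusion

    eligible = exclusion == EXCLUSION_NONE
    oed = out.get("oedema")
    oed_flag = (
        oed.astype(str).str.lower().isin(["yes", "y", "true", "1"]).to_numpy()
        if oed is not None
        else np.zeros(n, dtype=bool)
    )
    gam = np.where(eligible, (whz < -2) | oed_flag, None)
    sam = np.where(eligible, (whz < -3) | oed_flag, None)
    out["gam"] = gam
    out["sam"] = sam
    return out


def clean_child(record: Mapping, ref: LMSReference,
                known_subcounties: Iterable[str] | None = None) -> AnthroResult:
    """Score and clean a single raw record (convenience wrapper)."""
    row = clean_table(pd.DataFrame([dict(record)]), ref, known_subcounties).iloc[0]
    return AnthroResult(
        whz=float(row["whz"]) if pd.notna(row["whz"]) else float("nan"),
        muacz=float(row["muacz"]) if pd.notna(row["muacz"]) else float("nan"),
        gam=None if row["exclusion"] != EXCLUSION_NONE else bool(row["gam"]),
        sam=None if row["exclusion"] != EXCLUSION_NONE else bool(row["sam"]),
        exclusion=str(row["exclusion"]),
    )


def stratum_estimates(clean: pd.DataFrame,
                      by: Sequence[str] = ("stratum_id",)) -> pd.DataFrame:
    """Unweighted stratum-level estimates over eligible children.

    Returns one row per group with ``n``, ``gam_prev``, ``sam_prev``,
    ``mean_whz`` and ``mean_muacz``.  Raises on a group with no eligible
    children only implicitly (such groups are absent from the output).
    """
    elig = clean[clean["exclusion"] == EXCLUSION_NONE]
    if elig.empty:
        raise ValueError("no eligible children to estimate from")
    g = elig.groupby(list(by), sort=True)
    res = pd.DataFrame(
        {
            "n": g.size(),
            "gam_prev": g["gam"].apply(lambda s: float(np.mean(s.astype(bool)))),
            "sam_prev": g["sam"].apply(lambda s: float(np.mean(s.astype(bool)))),
            "mean_whz": g["whz"].mean(),
            "mean_muacz": g["muacz"].mean(),
        }
    ).reset_index()
    return res


def attrition_summary(clean: pd.DataFrame) -> pd.DataFrame:
    """Record counts by exclusion code (one row per code plus the total)."""
    counts = clean["exclusion"].value_counts()
    rows = [
        {"exclusion": code, "n": int(counts.get(code, 0))}
        for code in (EXCLUSION_NONE,) + EXCLUSION_ORDER
    ]
    rows.append({"exclusion": "total", "n": int(len(clean))})
    return pd.DataFrame(rows)


def eligibility_percentage(n_eligible: int, n_total: int) -> float:
    """Percentage of records retained after exclusions, on the 0-100 scale."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_eligible / n_total


def mean_observations_per_stratum(n_eligible: int, n_strata: int) -> float:
    """Mean eligible child observations per survey stratum."""
    if n_strata <= 0:
        raise ValueError("n_strata must be positive")
    return n_eligible / n_strata
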