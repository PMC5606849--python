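"""Allometric growth models and body-size normalization.

In zebrafish, developmental progress tracks standard length (SL, mm) more
closely than age, so comparing groups that differ in body size conflates
genotype effects with growth. Each feature ``y`` is modeled against SL by
the standard power law ``y = a * x^b`` (fit by ordinary least squares on
the log-log scale), and observations are mapped to a reference length
``x*`` by ``y* = y * (x*/x)^b``. Isometric expectations are ``b = 3`` for
volumes and mineral content, ``b = 1`` for thickness and length.

Tissue mineral density is never normalized directly: TMD is converted to
tissue mineral content (TMC = Vol x TMD, a mass of mineral in mgHA), TMC
and Vol are normalized independently with their own exponents, and the
normalized TMD is recovered as normalized TMC / normalized Vol. Only
control (wild-type) phenomes are transformed; mutants are left on their
measured scale, with the mutant group's mean SL as the default reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometry import Phenome

__all__ = [
    "UM3_TO_CM3",
    "ISOMETRIC_EXPONENTS",
    "AllometricModel",
    "derive_tmc",
    "add_tmc_columns",
    "fit_power_law",
    "fit_cohort_models",
    "allometric_normalize",
    "normalize_phenome",
    "coefficient_of_variation",
]

#: Volume unit conversion used when forming TMC (mgHA) from um^3 and mgHA/cm^3.
UM3_TO_CM3 = 1e-12

#: Expected scaling exponents under isometric growth, by outcome suffix.
ISOMETRIC_EXPONENTS = {"Vol": 3.0, "TMC": 3.0, "Th": 1.0, "Le": 1.0, "SA": 2.0}

_ELEMENTS = ("Cent", "Neur", "Haem", "Tot")


@dataclass
class AllometricModel:
    """Power-law fit ``y = a * x^b`` of one feature against standard length.

    ``a`` is the feature value at unit length (feature units), ``b`` the
    dimensionless scaling exponent; ``r2`` is the coefficient of
    determination on the log-log scale over ``n`` fish.
    """

    feature: str
    a: float
    b: float
    r2: float = float("nan")
    n: int = 0
    vertebra: int | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scale coefficient a must be positive")
        if not np.isfinite(self.b):
            raise ValueError("scaling exponent b must be finite")

    @property
    def isometric_b(self) -> float | None:
        suffix = self.feature.split(".")[-1]
        return ISOMETRIC_EXPONENTS.get(suffix)

    def predict(self, x) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.b


def derive_tmc(vol, tmd):
    """Tissue mineral content (mgHA) from volume (um^3) and TMD (mgHA/cm^3)."""
    vol = np.asarray(vol, dtype=float)
    tmd = np.asarray(tmd, dtype=float)
    if np.any(tmd[np.isfinite(tmd)] < 0):
        warnings.warn("negative TMD encountered while forming TMC", stacklevel=2)
    out = vol * UM3_TO_CM3 * tmd
    return out if out.ndim else float(out)


def add_tmc_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a phenome table with per-element TMC columns."""
    out = table.copy()
    for el in _ELEMENTS:
        if f"{el}.Vol" in out.columns and f"{el}.TMD" in out.columns:
            out[f"{el}.TMC"] = derive_tmc(out[f"{el}.Vol"], out[f"{el}.TMD"])
    return out


def fit_power_law(
    x, y, feature: str = "", vertebra: int | None = None
) -> AllometricModel:
    """OLS fit of ``log y = log a + b log x`` over a cohort.

    Noiseless power-law data are recovered to machine precision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise ValueError("allometric fit requires at least 3 fish")
    bad = np.nonzero((x <= 0) | (y <= 0) | ~np.isfinite(x) | ~np.isfinite(y))[0]
    if len(bad):
        raise ValueError(
            f"non-positive or missing values at fish indices {bad.tolist()}"
        )
    lx, ly = np.log(x), np.log(y)
    b, log_a = np.polyfit(lx, ly, 1)
    resid = ly - (log_a + b * lx)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return AllometricModel(
        feature=feature, a=float(np.exp(log_a)), b=float(b), r2=r2, n=len(x),
        vertebra=vertebra,
    )


def fit_cohort_models(
    phenomes: list[Phenome],
    features: tuple[str, ...] | None = None,
    vertebrae: tuple[int, ...] | None = None,
) -> dict[tuple[str, int], AllometricModel]:
    """Fit one power-law model per (feature, vertebra) over a cohort.

    Standard lengths must be set on every phenome. Defaults to all
    Vol/TMC/Th/SA features of each element plus Cent.Le, over the
    vertebrae shared by all fish. TMC columns are derived on the fly.
    Non-fittable series (non-positive values) are skipped with a warning.
    """
    if any(ph.standard_length is None for ph in phenomes):
        raise ValueError("every phenome needs a standard length")
    tables = {ph.fish_id: add_tmc_columns(ph.table) for ph in phenomes}
    x = np.array([ph.standard_length for ph in phenomes], dtype=float)
    if features is None:
        features = tuple(
            f"{el}.{o}" for el in _ELEMENTS for o in ("Vol", "TMC", "Th", "SA")
        ) + ("Cent.Le",)
    if vertebrae is None:
        vertebrae = tuple(
            sorted(set.intersection(*(set(ph.table.index) for ph in phenomes)))
        )
    models: dict[tuple[str, int], AllometricModel] = {}
    for feat in features:
        for v in vertebrae:
            y = np.array([tables[ph.fish_id].loc[v, feat] for ph in phenomes])
            try:
                models[(feat, v)] = fit_power_law(x, y, feature=feat, vertebra=v)
            except ValueError as err:
                warnings.warn(
                    f"skipping {feat} at vertebra {v}: {err}", stacklevel=2
                )
    return models


def allometric_normalize(y, x, x_ref: float, b: float):
    """Map ``y`` measured at length ``x`` to reference length ``x_ref``.

    ``x`` broadcasts against ``y`` (one length per fish).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or x_ref <= 0:
        raise ValueError("standard lengths must be positive")
    y = np.asarray(y, dtype=float)
    out = y * (x_ref / x) ** b
    return out if out.ndim else float(out)


def normalize_phenome(
    phenome: Phenome,
    models: dict[tuple[str, int], AllometricModel],
    x_ref: float,
) -> Phenome:
    """Normalize one phenome to a reference standard length.

    Vol, TMC, Th, SA and Cent.Le are normalized with their own fitted
    exponents. TMD is recomputed from independently normalized TMC and
    Vol (two-step rule). SD-type features are scaled with their parent
    feature's exponent (TMD.sd with the effective TMD exponent
    ``b_TMC - b_Vol``), preserving the parent's relative dispersion.
    Features without a fitted model pass through unmodified with a
    warning.
    """
    if phenome.standard_length is None:
        raise ValueError("phenome needs a standard length")
    x = float(phenome.standard_length)
    table = add_tmc_columns(phenome.table)
    out = table.copy()

    def model_b(feat: str, v: int) -> float | None:
        m = models.get((feat, v))
        return None if m is None else m.b

    missing: set[str] = set()
    for v in table.index:
        for el in _ELEMENTS:
            bs = {}
            for o in ("Vol", "TMC", "Th", "SA"):
                feat = f"{el}.{o}"
                b = model_b(feat, v)
                if b is None:
                    missing.add(feat)
                else:
                    bs[o] = b
                    out.loc[v, feat] = allometric_normalize(
                        table.loc[v, feat], x, x_ref, b
                    )
            # two-step TMD: normalized TMC / normalized Vol, back to mgHA/cm^3
            if "TMC" in bs and "Vol" in bs:
                vol_n = out.loc[v, f"{el}.Vol"]
                tmc_n = out.loc[v, f"{el}.TMC"]
                if vol_n > 0:
                    out.loc[v, f"{el}.TMD"] = tmc_n / (vol_n * UM3_TO_CM3)
                b_tmd = bs["TMC"] - bs["Vol"]
                out.loc[v, f"{el}.TMD.sd"] = allometric_normalize(
                    table.loc[v, f"{el}.TMD.sd"], x, x_ref, b_tmd
                )
            else:
                missing.add(f"{el}.TMD")
            if "Th" in bs:
                out.loc[v, f"{el}.Th.sd"] = allometric_normalize(
                    table.loc[v, f"{el}.Th.sd"], x, x_ref, bs["Th"]
                )
        b_le = model_b("Cent.Le", v)
        if b_le is None:
            missing.add("Cent.Le")
        else:
            out.loc[v, "Cent.Le"] = allometric_normalize(
                table.loc[v, "Cent.Le"], x, x_ref, b_le
            )
    if missing:
        warnings.warn(
            f"no model for {sorted(missing)}: passed through unmodified",
            stacklevel=2,
        )
    out = out.drop(columns=[c for c in out.columns if c.endswith(".TMC")])
    return Phenome(
        fish_id=phenome.fish_id,
        table=out,
        standard_length=x_ref,
        group=phenome.group,
    )


def coefficient_of_variation(values) -> float:
    """Population-SD coefficient of variation, SD / mean."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(values.std() / mean)
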