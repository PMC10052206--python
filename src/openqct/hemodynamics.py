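"""Beat-to-beat hemodynamic parameter derivation from impedance cardiography.

Impedance cardiography (ICG) measures, for every heartbeat, the baseline
thoracic impedance ``Z0`` (ohm), the maximum rate of impedance change
``dZmax`` (ohm/s), the left-ventricular ejection time ``LVET`` (s) and the
R-peak-to-C-point interval ``TRC`` (s).  Together with beat-to-beat blood
pressures these primitives yield the standard derived parameters:

=====  =============================  =======================
SV     VEPT * dZmax * LVET / Z0       stroke volume, mL
CO     SV * HR / 1000                 cardiac output, L/min
HI     dZmax * TRC                    Heather index (see note)
TAC    SV / (SBP - DBP)               total arterial compliance, mL/mmHg
SVR    80 * (MBP - CVP) / CO          systemic vascular resistance,
                                      dyn*s*cm^-5
=====  =============================  =======================

``VEPT`` is the volume of electrically participating tissue (Sramek
convention, ``(0.17 * height_cm)**3 / 4.25`` mL, with an optional
multiplicative correction for the Bernstein weight/sex adjustment).  CVP
(central venous pressure) is not measured by ICG and enters SVR as a
configurable constant, 6 mmHg by default.

The Heather index is conventionally defined as the quotient dZmax/TRC; the
product form is used here by default for fidelity to the device convention
this package targets, and the quotient is available via
``heather_index_form="quotient"``.

The module's end product is :func:`assemble_state_matrix`: an M x N float
array (one row per beat, one column per state-vector variable) plus a
boolean missingness mask, the input to the dependency/complexity engine.
Missingness propagates through derivations: a derived cell is masked iff at
least one of its inputs is masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegeneratePressureError,
    InvalidInputError,
)

#: Canonical CSV columns holding measured (not derived) per-beat quantities.
PRIMITIVE_COLUMNS = ("t", "hr", "sbp", "dbp", "mbp", "lvet", "pep", "z0", "dzmax", "trc")

#: Default state vector {x}: the N = 11 monitored hemodynamic variables.
DEFAULT_VARIABLES = ("hr", "sbp", "dbp", "mbp", "lvet", "pep", "sv", "co", "hi", "tac", "svr")

#: Inputs each derived variable depends on (for mask propagation).
_DERIVED_INPUTS = {
    "sv": ("dzmax", "lvet", "z0"),
    "co": ("dzmax", "lvet", "z0", "hr"),
    "hi": ("dzmax", "trc"),
    "tac": ("dzmax", "lvet", "z0", "sbp", "dbp"),
    "svr": ("dzmax", "lvet", "z0", "hr", "mbp"),
    "pp": ("sbp", "dbp"),
}


@dataclass(frozen=True)
class SubjectAnthropometry:
    """Weight (kg), height (cm) and sex of the monitored subject."""

    weight: float
    height: float
    sex: str = "male"

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise InvalidInputError(f"weight must be positive, got {self.weight}")
        if not self.height > 0:
            raise InvalidInputError(f"height must be positive, got {self.height}")
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass
class StateVectorConfig:
    """Which variables form the state vector {x} and how to derive them.

    Parameters
    ----------
    variables
        Ordered variable names (N >= 2, unique).  ``pp`` (pulse pressure,
        SBP - DBP) may be included; it is intended as a replacement for the
        redundant SBP/DBP pair, not an addition to it.
    cvp_assumed
        Constant central venous pressure (mmHg) used in SVR.
    vept_correction
        Multiplicative correction on the Sramek VEPT (Bernstein
        weight/sex adjustment hook); 1.0 = pure Sramek.
    heather_index_form
        ``"product"`` (dZmax * TRC, device-table convention, default) or
        ``"quotient"`` (dZmax / TRC, the textbook Heather index).
    """

    variables: tuple[str, ...] = DEFAULT_VARIABLES
    cvp_assumed: float = 6.0
    vept_correction: float = 1.0
    heather_index_form: str = "product"

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        if len(self.variables) < 2:
            raise ConfigurationError("state vector needs at least 2 variables")
        if len(set(self.variables)) != len(self.variables):
            raise ConfigurationError("variable names must be unique")
        known = set(DEFAULT_VARIABLES) | {"pp"}
        unknown = [v for v in self.variables if v not in known]
        if unknown:
            raise ConfigurationError(f"unknown state-vector variables: {unknown}")
        if self.heather_index_form not in ("product", "quotient"):
            raise ConfigurationError(
                f"heather_index_form must be 'product' or 'quotient', "
                f"got {self.heather_index_form!r}"
            )

    @property
    def n_variables(self) -> int:
        return len(self.variables)


def compute_vept(anthro: SubjectAnthropometry, correction: float = 1.0) -> float:
    """Volume of electrically participating tissue (mL), Sramek convention.

    VEPT = (0.17 * height_cm)^3 / 4.25, optionally scaled by a correction
    factor (Bernstein's weight/sex adjustment; 1.0 = none).
    """
    if correction <= 0:
        raise InvalidInputError(f"correction factor must be positive, got {correction}")
    return (0.17 * anthro.height) ** 3 / 4.25 * correction


def derive_sv(vept: float, dzmax, lvet, z0):
    """Stroke volume (mL): SV = VEPT * dZmax * LVET / Z0."""
    if np.any(np.asarray(z0) <= 0):
        raise InvalidInputError("Z0 must be positive")
    return vept * dzmax * lvet / z0


def derive_co(sv, hr):
    """Cardiac output (L/min): SV (mL) * HR (bpm) / 1000."""
    if np.any(np.asarray(sv) < 0) or np.any(np.asarray(hr) < 0):
        raise InvalidInputError("SV and HR must be non-negative")
    return sv * hr / 1000.0


def derive_hi(dzmax, trc, form: str = "product"):
    """Heather index: dZmax * TRC (product form) or dZmax / TRC (quotient)."""
    if np.any(np.asarray(trc) <= 0):
        raise InvalidInputError("TRC must be positive")
    if form == "product":
        return dzmax * trc
    if form == "quotient":
        return dzmax / trc
    raise ConfigurationError(f"unknown Heather index form {form!r}")


def derive_tac(sv, sbp, dbp):
    """Total arterial compliance (mL/mmHg): SV / pulse pressure."""
    pp = np.asarray(sbp, dtype=float) - np.asarray(dbp, dtype=float)
    if np.any(pp[~np.isnan(pp)] <= 0):
        raise DegeneratePressureError("SBP must exceed DBP")
    return sv / (sbp - dbp)


def derive_svr(mbp, cvp, co):
    """Systemic vascular resistance (dyn*s*cm^-5): 80 * (MBP - CVP) / CO."""
    if np.any(np.asarray(co)[~np.isnan(np.asarray(co, dtype=float))] <= 0):
        raise InvalidInputError("CO must be positive")
    return 80.0 * (mbp - cvp) / co


def derive_all(frame: pd.DataFrame, anthro: SubjectAnthropometry,
               cfg: StateVectorConfig | None = None) -> pd.DataFrame:
    """Add the derived columns (sv, co, hi, tac, svr, pp) to a beat frame.

    ``frame`` holds the primitive columns (:data:`PRIMITIVE_COLUMNS`); NaN
    cells are gaps and propagate into every derived value that depends on
    them.  Returns a new DataFrame; the input is not modified.
    """
    cfg = cfg or StateVectorConfig()
    _validate_beats(frame)
    out = frame.copy()
    vept = compute_vept(anthro, cfg.vept_correction)
    out["sv"] = derive_sv(vept, out["dzmax"], out["lvet"], _positive(out["z0"], "z0"))
    out["co"] = derive_co(out["sv"], _positive(out["hr"], "hr"))
    out["hi"] = derive_hi(out["dzmax"], _positive(out["trc"], "trc"), cfg.heather_index_form)
    out["pp"] = out["sbp"] - out["dbp"]
    out["tac"] = derive_tac(out["sv"], out["sbp"], out["dbp"])
    out["svr"] = derive_svr(out["mbp"], cfg.cvp_assumed, out["co"])
    return out


def _positive(col: pd.Series, name: str) -> pd.Series:
    vals = col.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise InvalidInputError(f"{name} must be positive on every beat where present")
    return col


def _validate_beats(frame: pd.DataFrame) -> None:
    missing = [c for c in PRIMITIVE_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"beat table lacks required columns: {missing}")
    if len(frame) == 0:
        return
    t = frame["t"].to_numpy(dtype=float)
    if np.any(np.isnan(t)):
        raise InvalidInputError("beat timestamps may not be missing")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("beat timestamps must be strictly increasing")
    sbp = frame["sbp"].to_numpy(dtype=float)
    dbp = frame["dbp"].to_numpy(dtype=float)
    both = ~np.isnan(sbp) & ~np.isnan(dbp)
    if np.any(sbp[both] < dbp[both]):
        raise InvalidInputError("SBP must be >= DBP on every beat where both are present")


def assemble_state_matrix(
    records: pd.DataFrame,
    anthro: SubjectAnthropometry,
    cfg: StateVectorConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the M x N state-vector array consumed by the complexity engine.

    Parameters
    ----------
    records
        Beat table with the primitive columns; NaN marks a gap.  Derived
        columns are recomputed here from primitives (any present are
        overwritten), so Table-consistency holds by construction.
    anthro
        Subject anthropometry for VEPT.
    cfg
        State-vector configuration (variables, CVP, Heather form).

    Returns
    -------
    data : (M, N) float array with NaN in masked cells
    mask : (M, N) bool array, True where the value is missing
    times : (M,) float array of beat timestamps (s)
    """
    cfg = cfg or StateVectorConfig()
    if len(records) == 0:
        n = cfg.n_variables
        return (np.empty((0, n)), np.empty((0, n), dtype=bool), np.empty(0))
    derived = derive_all(records, anthro, cfg)
    data = derived.loc[:, list(cfg.variables)].to_numpy(dtype=float)
    mask = np.isnan(data)
    times = derived["t"].to_numpy(dtype=float)
    return data, mask, times
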