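"""Left-ventricular derived indices from M-mode/B-mode caliper measurements.

Single-diameter (Teichholz) volumes, ejection fraction (EF), fractional
shortening (FS), corrected LV mass, stroke volume, cardiac output and
relative wall thickness (RWT), plus the allometric normalization used for
body-size indexing: 1-D measures (diameters, wall thicknesses) are divided
by BW^(1/3) and 3-D measures (volumes, mass) by BW.

Formulas (lengths in mm, volumes in uL, mass in mg):

    LV vol      = (7.0 / (2.4 + LVID)) * LVID^3
    EF (%)      = 100 * (vol_d - vol_s) / vol_d
    FS (%)      = 100 * (LVID;d - LVID;s) / LVID;d
    LV mass corr= 1.053 * ((LVID;d + LVPW;d + IVS;d)^3 - LVID;d^3) * 0.8
    SV          = vol_d - vol_s
    CO (mL/min) = SV * hr / 1000
    RWT         = (IVS;d + LVPW;d) / LVID;d
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import DomainError, ValidationError

MYOCARDIAL_DENSITY = 1.053   # g/mL, i.e. mg/mm^3
MASS_CORRECTION = 0.8
MIN_BEATS_AVERAGED = 3


@dataclass(frozen=True)
class EchoMeasures:
    """Averaged caliper measurements for one animal at one timepoint.

    ``ivs_d`` is the diastolic interventricular-septum (anterior-wall)
    thickness (alias SWTd), ``lvid_d`` the diastolic internal diameter
    (alias LVEDD), ``lvpw_d`` the diastolic posterior-wall thickness
    (alias PWTd); ``_s`` are the systolic counterparts. Values must already
    be averaged over at least three heartbeats.
    """

    ivs_d: float
    ivs_s: float
    lvid_d: float
    lvid_s: float
    lvpw_d: float
    lvpw_s: float
    hr: float                  # beats/min
    bw: float                  # g
    n_beats_averaged: int = 3

    def __post_init__(self) -> None:
        for name in ("ivs_d", "ivs_s", "lvid_d", "lvid_s", "lvpw_d",
                     "lvpw_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.hr <= 0 or self.bw <= 0:
            raise ValidationError("hr and bw must be > 0")
        if self.n_beats_averaged < MIN_BEATS_AVERAGED:
            raise ValidationError(
                f"n_beats_averaged must be >= {MIN_BEATS_AVERAGED}")
        if self.lvid_s >= self.lvid_d:
            warnings.warn(
                "LVID;s >= LVID;d: non-contracting ventricle", stacklevel=2)

    # field aliases used in the echo literature
    @property
    def swt_d(self) -> float:
        return self.ivs_d

    @property
    def lvedd(self) -> float:
        return self.lvid_d

    @property
    def pwt_d(self) -> float:
        return self.lvpw_d


@dataclass(frozen=True)
class EchoDerived:
    lv_vol_d: float   # uL
    lv_vol_s: float   # uL
    ef: float         # %
    fs: float         # %
    lv_mass_corr: float  # mg
    sv: float         # uL
    co: float         # mL/min
    rwt: float        # dimensionless
    warnings: tuple[str, ...] = field(default=())


def teichholz_volume(lvid_mm: float) -> float:
    """Single-diameter LV volume (uL): (7.0/(2.4 + D)) * D^3."""
    if lvid_mm <= 0:
        raise DomainError("LVID must be > 0")
    return (7.0 / (2.4 + lvid_mm)) * lvid_mm**3


def derive(measures: EchoMeasures) -> EchoDerived:
    """All derived LV indices from one set of averaged calipers.

    A systolic diameter exceeding the diastolic one yields a negative FS
    reported with an attached warning rather than an error, so QC review of
    such beats remains possible.
    """
    m = measures
    vol_d = teichholz_volume(m.lvid_d)
    vol_s = teichholz_volume(m.lvid_s)
    ef = 100.0 * (vol_d - vol_s) / vol_d
    fs = 100.0 * (m.lvid_d - m.lvid_s) / m.lvid_d
    mass = (MYOCARDIAL_DENSITY
            * ((m.lvid_d + m.lvpw_d + m.ivs_d) ** 3 - m.lvid_d**3)
            * MASS_CORRECTION)
    sv = vol_d - vol_s
    co = sv * m.hr / 1000.0
    rwt = (m.ivs_d + m.lvpw_d) / m.lvid_d
    notes: tuple[str, ...] = ()
    if fs < 0:
        notes = ("negative fractional shortening (LVID;s > LVID;d)",)
    return EchoDerived(vol_d, vol_s, ef, fs, mass, sv, co, rwt, notes)


def normalize(obj: EchoMeasures | EchoDerived, bw: float):
    """Allometric normalization by body weight.

    1-D measures are divided by ``bw**(1/3)`` and 3-D measures by ``bw``;
    the dimensionless EF, FS and RWT are unchanged. Heart rate and the
    stored body weight are left untouched on measures.
    """
    if bw <= 0:
        raise DomainError("bw must be > 0")
    if isinstance(obj, EchoMeasures):
        s = bw ** (1.0 / 3.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return replace(obj, ivs_d=obj.ivs_d / s, ivs_s=obj.ivs_s / s,
                           lvid_d=obj.lvid_d / s, lvid_s=obj.lvid_s / s,
                           lvpw_d=obj.lvpw_d / s, lvpw_s=obj.lvpw_s / s)
    if isinstance(obj, EchoDerived):
        return replace(obj, lv_vol_d=obj.lv_vol_d / bw,
                       lv_vol_s=obj.lv_vol_s / bw,
                       lv_mass_corr=obj.lv_mass_corr / bw,
                       sv=obj.sv / bw, co=obj.co / bw)
    raise ValidationError("normalize expects EchoMeasures or EchoDerived")


_MEASURE_COLS = ("ivs_d", "ivs_s", "lvid_d", "lvid_s", "lvpw_d", "lvpw_s",
                 "hr", "bw")


def derive_table(measures: pd.DataFrame, normalized: bool = True
                 ) -> pd.DataFrame:
    """Batch derivation over a caliper table (one row per mouse x timepoint).

    Appends the derived columns and, when ``normalized`` is set, their
    body-weight-indexed variants (suffix ``_n``).
    """
    missing = [c for c in _MEASURE_COLS if c not in measures.columns]
    if missing:
        raise ValidationError(f"missing caliper column(s): {missing}")
    rows = []
    for _, row in measures.iterrows():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = EchoMeasures(**{c: row[c] for c in _MEASURE_COLS},
                             n_beats_averaged=int(row.get("n_beats_averaged",
                                                          3)))
        d = derive(m)
        rec = dict(row) | {
            "lv_vol_d": d.lv_vol_d, "lv_vol_s": d.lv_vol_s, "ef": d.ef,
            "fs": d.fs, "lv_mass_corr": d.lv_mass_corr, "sv": d.sv,
            "co": d.co, "rwt": d.rwt,
            "qc_warnings": "; ".join(d.warnings),
        }
        if normalized:
            s = row["bw"] ** (1.0 / 3.0)
            dn = normalize(d, row["bw"])
            rec |= {f"{c}_n": row[c] / s
                    for c in ("ivs_d", "ivs_s", "lvid_d", "lvid_s",
                              "lvpw_d", "lvpw_s")}
            rec |= {"lv_vol_d_n": dn.lv_vol_d, "lv_vol_s_n": dn.lv_vol_s,
                    "lv_mass_corr_n": dn.lv_mass_corr, "sv_n": dn.sv,
                    "co_n": dn.co}
        rows.append(rec)
    return pd.DataFrame(rows)
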