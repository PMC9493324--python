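"""Functional-property indices for protein-ligand preparations.

Scalar assays commonly reported alongside binding studies of food
proteins: DPPH radical scavenging (antioxidant capacity as fractional
loss of 517 nm absorbance), foaming capacity and stability (foam
volumes on whipping and standing), and the turbidimetric emulsifying
activity / emulsion stability indices.

Each index is a small pure function over a validated record; CSV table
helpers apply an index column-wise and append the computed column.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DPPHMeasurement",
    "FoamRecord",
    "EmulsionRecord",
    "EAIMode",
    "dpph_scavenging",
    "foaming_capacity",
    "foaming_stability",
    "foam_retention",
    "emulsifying_activity_index",
    "emulsion_stability_index",
    "process_dpph_table",
    "process_foam_table",
    "process_emulsion_table",
]


@dataclass(frozen=True)
class DPPHMeasurement:
    """Absorbances at 517 nm: A_C with sample + DPPH, A_0 blank."""

    A_C: float
    A_0: float
    ratio_label: str = ""

    def __post_init__(self) -> None:
        if self.A_0 <= 0:
            raise ValueError("blank absorbance A_0 must be positive")
        if self.A_C < 0:
            raise ValueError("A_C must be non-negative")


@dataclass(frozen=True)
class FoamRecord:
    """Foam volumes (mL): whipped V_a, unwhipped V_b, foam at 0 and t min."""

    V_a: float
    V_b: float
    V_F0: float
    V_Ft: float
    t: float = 20.0  # minutes
    ratio_label: str = ""

    def __post_init__(self) -> None:
        for name in ("V_a", "V_b", "V_F0", "V_Ft"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def foam_grew(self) -> bool:
        """Flag: foam volume increased on standing (V_Ft > V_F0)."""
        return self.V_Ft > self.V_F0


@dataclass(frozen=True)
class EmulsionRecord:
    """Turbidimetric emulsion readings with composition metadata.

    A_0_emul and A_10 are 500 nm absorbances of the diluted emulsion at
    0 and 10 min; C_protein is mg/mL protein, oil_fraction the oil phase
    volume fraction, and dilution the fold-dilution before reading.
    """

    A_0_emul: float
    A_10: float
    C_protein: float  # mg/mL
    oil_fraction: float
    dilution: float = 100.0
    ratio_label: str = ""

    def __post_init__(self) -> None:
        if self.C_protein <= 0:
            raise ValueError("C_protein must be positive")
        if not 0 <= self.oil_fraction < 1:
            raise ValueError("oil_fraction must be in [0, 1)")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")
        if self.A_0_emul < 0 or self.A_10 < 0:
            raise ValueError("absorbances must be non-negative")


class EAIMode(str, enum.Enum):
    """Which emulsifying-activity formula to apply.

    ``pearce_kinsella`` (default) is the standard turbidimetric index
    2 x 2.303 x A0 x dilution / (C x (1 - phi) x 10^4) in m^2/g;
    ``as_printed`` is the absorbance-free variant
    2 x 2.303 / (C x (1 - phi) x 10) kept for fidelity to sources that
    print it in that reduced form.
    """

    PEARCE_KINSELLA = "pearce_kinsella"
    AS_PRINTED = "as_printed"


def dpph_scavenging(m: DPPHMeasurement) -> float:
    """Radical scavenging activity (%) = (1 - A_C/A_0) x 100."""
    return (1.0 - m.A_C / m.A_0) * 100.0


def foaming_capacity(r: FoamRecord) -> float:
    """FC (%) = (V_a - V_b)/V_a x 100, normalised by the whipped volume."""
    if r.V_a == 0:
        raise ValueError("whipped volume V_a must be positive")
    return (r.V_a - r.V_b) / r.V_a * 100.0


def foaming_stability(r: FoamRecord) -> float:
    """FS (%) = (V_F0 - V_Ft)/V_F0 x 100 — the fractional foam volume
    lost on standing (0 = no decay, 100 = full collapse)."""
    if r.V_F0 == 0:
        raise ValueError("initial foam volume V_F0 must be positive")
    return (r.V_F0 - r.V_Ft) / r.V_F0 * 100.0


def foam_retention(r: FoamRecord) -> float:
    """Complementary convention: foam retained (%) = 100 - FS."""
    return 100.0 - foaming_stability(r)


def emulsifying_activity_index(
    r: EmulsionRecord, mode: EAIMode | str = EAIMode.PEARCE_KINSELLA
) -> float:
    """EAI in m^2/g; see :class:`EAIMode` for the two conventions."""
    mode = EAIMode(mode)
    denom = r.C_protein * (1.0 - r.oil_fraction)
    if mode is EAIMode.AS_PRINTED:
        return 2.0 * 2.303 / (denom * 10.0)
    return 2.0 * 2.303 * r.A_0_emul * r.dilution / (denom * 1e4)


def emulsion_stability_index(r: EmulsionRecord) -> float:
    """ESI (%) = A_10/A_0 x 100 — absorbance retained over 10 min."""
    if r.A_0_emul == 0:
        raise ValueError("initial absorbance A_0 must be positive")
    return r.A_10 / r.A_0_emul * 100.0


def process_dpph_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Append ``scavenging_pct`` to a (ratio_label, A_C, A_0) table."""
    out = frame.copy()
    out["scavenging_pct"] = [
        dpph_scavenging(DPPHMeasurement(A_C=row.A_C, A_0=row.A_0, ratio_label=str(row.ratio_label)))
        for row in frame.itertuples()
    ]
    return out


def process_foam_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Append FC, FS and retention columns to a foam table."""
    out = frame.copy()
    fc, fs, kept, grew = [], [], [], []
    for row in frame.itertuples():
        rec = FoamRecord(
            V_a=row.V_a, V_b=row.V_b, V_F0=row.V_F0, V_Ft=row.V_Ft,
            t=getattr(row, "t_min", 20.0), ratio_label=str(row.ratio_label),
        )
        fc.append(foaming_capacity(rec))
        fs.append(foaming_stability(rec))
        kept.append(foam_retention(rec))
        grew.append(rec.foam_grew)
    out["FC_pct"] = fc
    out["FS_pct"] = fs
    out["retention_pct"] = kept
    out["foam_grew_flag"] = grew
    return out


def process_emulsion_table(
    frame: pd.DataFrame, mode: EAIMode | str = EAIMode.PEARCE_KINSELLA
) -> pd.DataFrame:
    """Append EAI and ESI columns to an emulsion table."""
    mode = EAIMode(mode)
    out = frame.copy()
    eai, esi = [], []
    for row in frame.itertuples():
        rec = EmulsionRecord(
            A_0_emul=row.A_0, A_10=row.A_10, C_protein=row.C_mg_per_mL,
            oil_fraction=row.oil_fraction, dilution=getattr(row, "dilution", 100.0),
            ratio_label=str(row.ratio_label),
        )
        eai.append(emulsifying_activity_index(rec, mode))
        esi.append(emulsion_stability_index(rec))
    out["EAI_m2_per_g"] = eai
    out["ESI_pct"] = esi
    out["EAI_mode"] = mode.value
    return out
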