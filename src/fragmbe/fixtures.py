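"""Packaged reference tables and the statistics derived from them.

Four tables of published coupled-cluster benchmark results ship as
immutable in-memory fixtures (values digit-for-digit as printed; SHA-256
checksums are pinned so any edit fails the suite):

* ``table1`` — binding energies of the six water hexamer isomers at three
  PNO-truncation settings vs the canonical reference;
* ``table2`` — mean-field/correlation components of the prism binding
  energy under the various embedding schemes;
* ``table3`` — binding energies of all six isomers for three embedding
  schemes;
* ``table5`` — ligand–residue pair interactions in a protein–ligand model,
  with the deviations of the two embedding schemes.

The ``reproduce_*`` functions recompute every error statistic quoted in the
source's discussion from these printed numbers alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import pandas as pd

from .led import mae, max_abs_dev, round_half_up
from .molsys import ValidationError


@dataclass(frozen=True)
class FixtureTable:
    """One transcribed reference table (kcal/mol), immutable at runtime."""

    name: str
    frame: pd.DataFrame
    provenance: str
    notes: tuple[str, ...] = ()
    printed_stats: dict = field(default_factory=dict)

    def checksum(self) -> str:
        return hashlib.sha256(
            self.frame.to_csv(float_format="%.2f").encode()
        ).hexdigest()


def _table1() -> FixtureTable:
    frame = pd.DataFrame(
        {
            "HF": [-32.32, -32.25, -33.49, -32.79, -34.56, -33.47],
            "pno_1e-6": [-47.74, -47.46, -47.32, -46.81, -46.40, -45.42],
            "pno_1e-7": [-48.26, -47.92, -47.73, -47.21, -46.78, -45.79],
            "pno_6/7": [-48.64, -48.26, -48.04, -47.50, -47.06, -46.06],
            "canonical": [-49.04, -48.73, -48.36, -47.85, -47.28, -46.26],
        },
        index=pd.Index(["prism", "cage", "book", "bag", "cyclic", "boat"], name="isomer"),
    )
    return FixtureTable(
        name="table1",
        frame=frame,
        provenance="transcribed published benchmark: water hexamer binding "
        "energies (kcal/mol), CBS-extrapolated, vs canonical reference",
        printed_stats={"MAE": {"HF": 14.77, "pno_1e-6": 1.06, "pno_1e-7": 0.64, "pno_6/7": 0.33}},
    )


def _table2() -> FixtureTable:
    rows = {
        "DLPNO-CCSD(T)/CBS": (-32.32, -16.32, -48.64),
        "LCC(CBS)-in-HF(CBS)": (-32.32, -16.38, -48.70),
        "two-body DLPNO-CCSD(T)/CBS": (-22.73, -16.69, -39.42),
        "LCC(CBS)-in-HF(aDZ)": (-32.33, -16.70, -49.03),
        "LCC(CBS)-in-HF(DZ)": (-33.55, -16.60, -50.05),
        "LCC(CBS)-in-HF(dSVPD)": (-32.32, -16.54, -48.86),
        "LCC(CBS)-in-EE1(CHELPG/aDZ)": (-27.43, -17.00, -44.43),
        "LCC(CBS)-in-EE1(NPA/aDZ)": (-29.77, -17.05, -46.82),
        "LCC(CBS)-in-EE1(NPA/aDZ*1.16)": (-32.21, -17.10, -49.31),
        "LCC(CBS)-in-EE2(NPA/aDZ*1.16)": (-30.60, -17.07, -47.66),
        "LCC(CBS)-in-EE2(NPA/aDZ*1.25)": (-31.85, -17.09, -48.94),
    }
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["dE_HF", "dE_corr", "dE_total"]
    )
    frame.index.name = "method"
    return FixtureTable(
        name="table2",
        frame=frame,
        provenance="transcribed published benchmark: prism-isomer binding "
        "energy components (kcal/mol) under embedded two-body schemes",
        notes=(
            "prose quotes a two-body correlation truncation error of 0.36 "
            "kcal/mol; the printed values (-16.69 vs -16.32) give 0.37 — "
            "both carried, discrepancy flagged, not resolved",
            "prose quotes a DZ-environment mean-field error of 1.22 kcal/mol; "
            "the printed values (-33.55 vs -32.32) give 1.23 — flagged, not "
            "resolved",
        ),
    )


def _table3() -> FixtureTable:
    frame = pd.DataFrame(
        {
            "LCC(CBS)-in-HF(CBS)": [-48.70, -48.36, -48.07, -47.51, -47.12, -46.10],
            "LCC(CBS)-in-HF(aDZ)": [-49.03, -48.58, -48.27, -47.80, -47.38, -46.41],
            "LCC(CBS)-in-EE1(NPA/aDZ*1.16)": [-49.31, -48.51, -48.72, -47.49, -48.60, -47.33],
        },
        index=pd.Index(["prism", "cage", "book", "bag", "cyclic", "boat"], name="isomer"),
    )
    return FixtureTable(
        name="table3",
        frame=frame,
        provenance="transcribed published benchmark: hexamer binding energies "
        "(kcal/mol) for three embedding schemes",
        printed_stats={
            "MAE": {
                "LCC(CBS)-in-HF(CBS)": 0.05,
                "LCC(CBS)-in-HF(aDZ)": 0.32,
                "LCC(CBS)-in-EE1(NPA/aDZ*1.16)": 0.74,
            },
            "MAE(HF)": {
                "LCC(CBS)-in-HF(CBS)": 0.00,
                "LCC(CBS)-in-HF(aDZ)": 0.12,
                "LCC(CBS)-in-EE1(NPA/aDZ*1.16)": 0.68,
            },
            "MAE(Corr)": {
                "LCC(CBS)-in-HF(CBS)": 0.05,
                "LCC(CBS)-in-HF(aDZ)": 0.19,
                "LCC(CBS)-in-EE1(NPA/aDZ*1.16)": 0.39,
            },
        },
    )


def _table5() -> FixtureTable:
    frame = pd.DataFrame(
        {
            "E_int": [-42.80, -22.94, -70.65, -0.48, -48.43, -19.40, -18.89, -5.90, -65.61],
            "delta_hf_like": [-0.09, -0.05, -0.14, 0.00, -0.10, -0.08, -0.03, -0.05, -0.16],
            "wall_hf_like_h": [4.2, 5.1, 12.0, 4.2, 6.8, 4.5, 4.8, 8.2, 4.2],
            "delta_ee2": [-0.39, -0.01, -1.00, 0.02, -0.39, -0.32, -0.48, -0.44, -0.51],
            "wall_ee2_h": [0.7, 2.3, 5.5, 0.9, 3.4, 2.2, 1.1, 1.3, 3.9],
        },
        index=pd.Index(
            ["H20", "W53", "W143", "R55", "Y185", "Y192", "C187-188", "A103", "M14-L112"],
            name="residue",
        ),
    )
    return FixtureTable(
        name="table5",
        frame=frame,
        provenance="transcribed published benchmark: ligand–residue pair "
        "interactions (kcal/mol) in a nicotinic-receptor model, with "
        "embedded-scheme deviations and per-dimer wall times",
        notes=(
            "prose quotes a maximum mean-field-embedding deviation of 0.14 "
            "kcal/mol; the printed column's maximum magnitude is 0.16 "
            "(M14-L112) — both reported, discrepancy flagged, not resolved",
        ),
    )


_BUILDERS = {"table1": _table1, "table2": _table2, "table3": _table3, "table5": _table5}

#: Pinned SHA-256 checksums of the canonical CSV serialization of each table.
PINNED_CHECKSUMS = {
    "table1": "737b0a42a12b29cb61c4e25438eda407fc4e2a700aac5c51499f7574c57709d6",
    "table2": "f324cb696219bf4fb846b6e6096d67fad3b7c4f62e75fd026f88968f1f25c072",
    "table3": "05fa4544609ad2b5ad692ae2ab41530fdd3f0602e40479fb2e0f9a84ecfbd28e",
    "table5": "80e5b59ac7c66e0bb2599f7a99945d1fa3ed3ab89fa22e723c0790e7878320ba",
}


def load_table(name: str) -> FixtureTable:
    """Load a fixture table by name (``table1 | table2 | table3 | table5``)."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValidationError(f"unknown fixture table {name!r}") from None


def verify_checksums() -> None:
    """Raise if any fixture differs from its pinned checksum."""
    for name, pinned in PINNED_CHECKSUMS.items():
        actual = load_table(name).checksum()
        if actual != pinned:
            raise ValidationError(
                f"fixture {name} checksum mismatch: {actual} != pinned {pinned}"
            )


# ----------------------------------------------------------- reproductions

def reproduce_table1_maes(fixture: FixtureTable | None = None) -> pd.DataFrame:
    """MAE of each approximate column against the canonical column.

    Reported at two decimals (table parity) and one decimal (prose parity),
    half-up rounding applied after averaging.
    """
    t = fixture if fixture is not None else load_table("table1")
    if t.name != "table1":
        raise ValidationError("reproduce_table1_maes needs the table1 fixture")
    ref = t.frame["canonical"]
    rows = {}
    for col in ("HF", "pno_1e-6", "pno_1e-7", "pno_6/7"):
        pairs = list(zip(t.frame[col], ref))
        rows[col] = {
            "mae_two_decimals": mae(pairs, decimals=2),
            "mae_one_decimal": mae(pairs, decimals=1),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def reproduce_component_errors(
    table2: FixtureTable | None = None,
) -> pd.DataFrame:
    """Signed and absolute deviations of each method's mean-field and
    correlation binding-energy components from the supersystem reference."""
    t = table2 if table2 is not None else load_table("table2")
    if t.name != "table2":
        raise ValidationError("reproduce_component_errors needs the table2 fixture")
    ref = t.frame.loc["DLPNO-CCSD(T)/CBS"]
    rows = {}
    for method, row in t.frame.iterrows():
        if method == "DLPNO-CCSD(T)/CBS":
            continue
        rows[method] = {
            "hf_error": round_half_up(row["dE_HF"] - ref["dE_HF"], 2),
            "corr_error": round_half_up(row["dE_corr"] - ref["dE_corr"], 2),
            "total_error": round_half_up(row["dE_total"] - ref["dE_total"], 2),
            "abs_hf_error": round_half_up(abs(row["dE_HF"] - ref["dE_HF"]), 2),
            "abs_corr_error": round_half_up(abs(row["dE_corr"] - ref["dE_corr"]), 2),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def reproduce_table3_maes(
    table3: FixtureTable | None = None, table1: FixtureTable | None = None
) -> pd.DataFrame:
    """Per-scheme MAE of the hexamer binding energies vs the supersystem
    reference column of ``table1`` (total energies only; the printed
    mean-field/correlation MAE rows need per-isomer components not printed)."""
    t3 = table3 if table3 is not None else load_table("table3")
    t1 = table1 if table1 is not None else load_table("table1")
    ref = t1.frame["pno_6/7"]
    out = {
        col: {"mae": mae(zip(t3.frame[col], ref), decimals=2)}
        for col in t3.frame.columns
    }
    return pd.DataFrame.from_dict(out, orient="index")


def reproduce_table5_stats(fixture: FixtureTable | None = None) -> dict:
    """Maximum absolute deviation per embedding scheme, plus the per-residue
    deviation listing."""
    t = fixture if fixture is not None else load_table("table5")
    if t.name != "table5":
        raise ValidationError("reproduce_table5_stats needs the table5 fixture")
    zeros = [0.0] * len(t.frame)
    return {
        "max_abs_dev": {
            "hf_like": max_abs_dev(zip(t.frame["delta_hf_like"], zeros), decimals=2),
            "ee2": max_abs_dev(zip(t.frame["delta_ee2"], zeros), decimals=2),
        },
        "per_residue": t.frame[["delta_hf_like", "delta_ee2"]].copy(),
        "notes": t.notes,
    }
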