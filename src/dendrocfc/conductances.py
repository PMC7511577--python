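"""Membrane conductance-density table.

The table assigns, to each of 21 structural levels (0 = distal axon up to
20 = end of the apical tuft), relative densities for nine active
conductances plus three alternative h-current columns: an exponential
somato-apical gradient (``g_h_exp``), a near-uniform distribution
(``g_h_unif``), and zero (``g_h_0``).  The fast Na column is zero at every
level, so the model is strictly subthreshold.  Relative densities are
converted to mS/cm^2 by a single global ``density_scale`` fixed by the
passive calibration (see ``scripts/calibrate.py``).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = [
    "G_COLUMNS",
    "IH_COLUMNS",
    "load_conductance_table",
    "ih_column_for_mode",
    "ConductanceTableError",
]

G_COLUMNS = [
    "g_NaF",
    "g_NaP",
    "g_KDR",
    "g_KC",
    "g_KA",
    "g_KM",
    "g_K2",
    "g_CaH",
    "g_CaL",
    "g_h_exp",
    "g_h_unif",
    "g_h_0",
]

IH_COLUMNS = {"exp_gradient": "g_h_exp", "uniform": "g_h_unif", "none": "g_h_0"}

#: density column -> kinetics channel name (NaF omitted: zero everywhere)
CHANNEL_FOR_COLUMN = {
    "g_NaP": "NaP",
    "g_KDR": "KDR",
    "g_KC": "KC",
    "g_KA": "KA",
    "g_KM": "KM",
    "g_K2": "K2",
    "g_CaH": "CaH",
    "g_CaL": "CaL",
}

N_LEVELS = 21


class ConductanceTableError(ValueError):
    pass


def ih_column_for_mode(ih_mode: str) -> str:
    try:
        return IH_COLUMNS[ih_mode]
    except KeyError:
        raise ConductanceTableError(
            f"unknown ih_mode {ih_mode!r}; expected one of {sorted(IH_COLUMNS)}"
        ) from None


def load_conductance_table(source=None) -> pd.DataFrame:
    """Load and validate the density table, indexed by level.

    ``source`` may be a path or file-like CSV with a ``level`` column and
    the twelve density columns; by default the packaged table is used.
    """
    if source is None:
        ref = importlib.resources.files("dendrocfc.data") / "conductance_table.csv"
        with ref.open("r") as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(source)

    missing = [c for c in ["level", *G_COLUMNS] if c not in table.columns]
    if missing:
        raise ConductanceTableError(f"missing columns: {missing}")
    extra = [c for c in table.columns if c not in ["level", *G_COLUMNS]]
    if extra:
        raise ConductanceTableError(f"unexpected columns: {extra}")
    table = table.set_index("level").astype(float)

    expected_levels = list(range(N_LEVELS))
    if list(table.index) != expected_levels:
        missing_levels = sorted(set(expected_levels) - set(table.index))
        raise ConductanceTableError(
            f"table must have levels 0..{N_LEVELS - 1} exactly; missing or "
            f"misordered levels: {missing_levels or list(table.index)}"
        )
    if table.isna().any().any():
        col = table.columns[table.isna().any()][0]
        lvl = int(table.index[table[col].isna()][0])
        raise ConductanceTableError(f"missing density at level {lvl}, column {col}")
    if (table < 0).any().any():
        col = table.columns[(table < 0).any()][0]
        lvl = int(table.index[(table[col] < 0)][0])
        raise ConductanceTableError(f"negative density at level {lvl}, column {col}")
    return table
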