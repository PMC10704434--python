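"""Published category-averaged hydration-site reference table.

Category means of the thermodynamic and structural quantities reported for
the 159 hydration sites found in the binding cavities of the eight plant
hormone receptors, together with the pure-water reference row. Energies in
kcal/mol. The rows serve as regression inputs: the derived-column
identities and the En/Fr–F/U labeling rules must reproduce each row from
its own measured columns.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "type", "count", "fo", "Esw", "Eww", "Etot", "Eww_nbr", "Nnbr",
    "fenc", "NswHB", "NwwHB", "fwwHB", "Nww_lostHB", "displaced_frac",
]

_ROWS = [
    ("pure water", None, None, 0.00, -9.53, -9.53, -1.36, 5.26, 0.00, 0.00, 3.33, 0.63, 0.00, None),
    ("A.En.F", 11, 0.40, -2.15, -7.92, -10.1, -1.63, 4.21, 0.20, 0.01, 3.17, 0.75, 0.16, 0.64),
    ("A.En.U", 24, 0.39, -1.97, -7.01, -8.98, -1.72, 3.46, 0.34, 0.01, 2.62, 0.76, 0.71, 0.67),
    ("A.Fr.U", 1, 0.30, 0.16, -5.45, -5.29, -1.10, 4.00, 0.24, 0.07, 2.35, 0.59, 0.98, 0.00),
    ("C.En.F", 11, 0.61, -6.06, -4.56, -10.6, -1.64, 2.64, 0.50, 1.20, 2.00, 0.76, 1.33, 0.36),
    ("C.En.U", 11, 0.65, -4.01, -4.67, -8.68, -1.86, 2.23, 0.57, 0.89, 1.69, 0.75, 1.66, 0.73),
    ("C.Fr.F", 26, 0.64, -9.19, -1.78, -11.0, -0.83, 2.65, 0.50, 1.47, 1.55, 0.58, 1.78, 0.20),
    ("C.Fr.U", 5, 0.53, -7.23, -1.89, -9.12, -0.96, 2.60, 0.51, 1.01, 1.54, 0.64, 1.79, 0.40),
    ("P.En.F", 29, 0.52, -4.64, -5.49, -10.1, -1.69, 2.83, 0.46, 0.95, 2.14, 0.76, 1.19, 0.38),
    ("P.En.U", 28, 0.42, -3.20, -5.58, -8.78, -1.75, 2.70, 0.49, 0.64, 1.99, 0.75, 1.36, 0.50),
    ("P.Fr.F", 8, 0.47, -6.25, -4.22, -10.5, -1.15, 3.14, 0.40, 1.10, 2.00, 0.64, 1.33, 0.38),
    ("P.Fr.U", 5, 0.48, -5.06, -4.13, -9.19, -1.22, 2.82, 0.46, 1.15, 1.72, 0.60, 1.61, 0.60),
    ("Undisplaced", 86, 0.53, -5.52, -4.40, -9.93, -1.37, 2.88, 0.46, 0.97, 1.97, 0.69, 1.36, None),
    ("Displaced", 73, 0.48, -3.86, -5.60, -9.46, -1.65, 2.99, 0.43, 0.60, 2.21, 0.75, 1.13, None),
]


def reference_category_table() -> pd.DataFrame:
    """The category-mean reference table as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def labeled_category_rows() -> pd.DataFrame:
    """Only the composite-labeled category rows (env.ww.tot types)."""
    df = reference_category_table()
    return df[df["type"].str.count(r"\.") == 2].reset_index(drop=True)


def environment_counts() -> dict[str, int]:
    """Site counts per environment class summed over labeled categories."""
    df = labeled_category_rows()
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        env = row["type"].split(".")[0]
        out[env] = out.get(env, 0) + int(row["count"])
    return out
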