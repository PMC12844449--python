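"""Parent-compound definitions and packaged reference datasets.

The reference CSVs transcribe the published metabolite inventories of
5F-ADB-PINACA (indazole core, 21 metabolites) and 5F-ADBICA (indole
core, 28 metabolites): retention time, neutral formula, reported
[M+H]+ m/z, reaction/site assignments and diagnostic product ions.

The neutral formulas stored here are structure-consistent, i.e. derived
from the parent formula plus the reaction deltas.  A handful of rows in
the published tables carry hydrogen-count typos (the 5F-ADB-PINACA
parent row and the 5F-ADBICA dihydroxylation/carboxylation rows); those
are corrected, which is verifiable because only the corrected formulas
reproduce the reported 4-decimal m/z values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .formula import Composition, IonMode, ion_mz, parse_formula

__all__ = ["ParentCompound", "PARENTS", "get_parent", "load_reference_table"]


@dataclass(frozen=True)
class ParentCompound:
    id: str
    scaffold: str  # "indazole-ADB" | "indole-ADB"
    formula: str
    reference_csv: str

    @property
    def composition(self) -> Composition:
        return parse_formula(self.formula)

    @property
    def mz(self) -> float:
        return ion_mz(self.composition, IonMode.PROTONATED)


PARENTS: dict[str, ParentCompound] = {
    "5F-ADB-PINACA": ParentCompound(
        id="5F-ADB-PINACA",
        scaffold="indazole-ADB",
        formula="C19H27FN4O2",
        reference_csv="5f_adb_pinaca_metabolites.csv",
    ),
    "5F-ADBICA": ParentCompound(
        id="5F-ADBICA",
        scaffold="indole-ADB",
        formula="C20H28FN3O2",
        reference_csv="5f_adbica_metabolites.csv",
    ),
}


def get_parent(name: str) -> ParentCompound:
    try:
        return PARENTS[name]
    except KeyError:
        raise KeyError(
            f"unknown parent {name!r}; known parents: {sorted(PARENTS)}"
        ) from None


def load_reference_table(parent: str | ParentCompound) -> pd.DataFrame:
    """Load the packaged metabolite inventory for a parent compound.

    Returns a DataFrame with columns: id, rt_min, formula, mz, reactions
    (list of ``(rule_id, moiety)`` tuples) and product_ions (list of
    floats).  The parent row is included with id ``parent``.
    """
    if isinstance(parent, str):
        parent = get_parent(parent)
    ref = resources.files("phasemet.data").joinpath(parent.reference_csv)
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype={"reactions": "string", "product_ions": "string"})
    df["reactions"] = [
        [tuple(tok.split(":")) for tok in s.split(";")] if pd.notna(s) and s else []
        for s in df["reactions"]
    ]
    df["product_ions"] = [
        [float(tok) for tok in s.split(";")] if pd.notna(s) and s else []
        for s in df["product_ions"]
    ]
    return df
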