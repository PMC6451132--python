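"""Interaction-energy ledger comparisons.

Holds per-component intermolecular interaction energies (kcal/mol) of an
inhibitor bound in the ribosomal E-site, as produced by dispersion-corrected
DFT on reduced pocket models, and compares compounds component-wise.  The
quantum-chemical calculation itself is out of scope: the ledger consumes
published energies.  The packaged table covers the C45 and CL reduced models
(components: the Pro-Val-Phe backbone stretch of protein eL42, the cytosine
C2764, and the two guanines G2793/G2794 of the 25S rRNA, plus the all-
together net row "PVF-Cyto-Gua"); the printed values exclude deformation and
desolvation energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "InteractionEnergyTable",
    "LedgerComparison",
    "load_ledgers",
    "published_ledgers",
    "compare_ledgers",
    "NET_LABEL",
]

NET_LABEL = "PVF-Cyto-Gua"


@dataclass(frozen=True)
class InteractionEnergyTable:
    """Per-component interaction energies for one compound, kcal/mol."""

    compound: str
    components: dict          # component label -> energy
    net: float | None         # all-components-together energy, if tabulated
    net_label: str = NET_LABEL

    def __post_init__(self) -> None:
        for label, e in self.components.items():
            if not (e == e and abs(e) != float("inf")):
                raise ValueError(f"non-finite energy for component {label!r}")

    @property
    def component_sum(self) -> float:
        return sum(self.components.values())

    @property
    def net_or_sum(self) -> float:
        """The tabulated net energy, falling back to the component sum."""
        return self.component_sum if self.net is None else self.net

    @property
    def additivity_gap(self) -> float:
        """net - sum of components: the many-body (non-additive) part."""
        return self.net_or_sum - self.component_sum


@dataclass(frozen=True)
class LedgerComparison:
    compound_a: str
    compound_b: str
    component_differences: dict   # label -> E_a - E_b
    net_difference: float         # signed, net_a - net_b
    additivity_gap_a: float
    additivity_gap_b: float

    @property
    def net_difference_magnitude(self) -> float:
        return abs(self.net_difference)


def compare_ledgers(
    a: InteractionEnergyTable, b: InteractionEnergyTable
) -> LedgerComparison:
    """Component-wise and net comparison of two energy ledgers.

    Differences are signed as a - b; swapping the arguments negates every
    difference.  Raises KeyError when the component sets differ.
    """
    if set(a.components) != set(b.components):
        missing = set(a.components) ^ set(b.components)
        raise KeyError(f"component sets differ: {sorted(missing)}")
    diffs = {k: a.components[k] - b.components[k] for k in a.components}
    return LedgerComparison(
        compound_a=a.compound, compound_b=b.compound,
        component_differences=diffs,
        net_difference=a.net_or_sum - b.net_or_sum,
        additivity_gap_a=a.additivity_gap,
        additivity_gap_b=b.additivity_gap,
    )


def load_ledgers(path: str | Path) -> dict[str, InteractionEnergyTable]:
    """Read a long-format CSV (compound, component, energy_kcal_mol)."""
    df = pd.read_csv(path)
    tables = {}
    for compound, sub in df.groupby("compound", sort=False):
        entries = dict(zip(sub["component"], sub["energy_kcal_mol"].astype(float)))
        net = entries.pop(NET_LABEL, None)
        tables[compound] = InteractionEnergyTable(
            compound=str(compound), components=entries, net=net)
    return tables


def published_ledgers() -> dict[str, InteractionEnergyTable]:
    """The packaged BLYP-D3 interaction-energy table for C45 and CL."""
    ref = resources.files("ribofret") / "data" / "interaction_energies.csv"
    with resources.as_file(ref) as path:
        return load_ledgers(path)
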