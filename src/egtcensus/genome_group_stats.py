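"""Group-level means and relative standard deviations of genome measures.

Summarizes genome length, protein / RNA gene counts and coding fraction per
phylogenetic group and compartment, reporting the arithmetic mean and the
relative standard deviation (RSD, in percent of the mean, with the sample
n−1 estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("Chlorophyta", "Nonvascular", "Ferns", "Gymnosperms", "Angiosperms")
COMPARTMENTS = ("nuclear", "plastid", "mitochondrial")
MEASURES = ("length_bp", "n_proteins", "n_rnas", "coding_fraction")


@dataclass
class GenomeMeasure:
    species: str
    group: str
    compartment: str
    length_bp: int
    n_proteins: int
    n_rnas: int
    coding_fraction: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if min(self.n_proteins, self.n_rnas) < 0 or not 0 <= self.coding_fraction <= 1:
            raise ValueError(f"bad counts for {self.species}")


def rsd(values: list[float]) -> float:
    """Relative standard deviation in percent: 100 × sd(n−1) / mean."""
    if not values:
        raise ValueError("rsd of an empty list")
    mean = float(np.mean(values))
    if mean == 0:
        raise ValueError("rsd undefined for zero mean")
    if len(values) == 1:
        warnings.warn("rsd of a single value reported as 0")
        return 0.0
    return 100.0 * float(np.std(values, ddof=1)) / mean


def group_table(measures: list[GenomeMeasure]) -> pd.DataFrame:
    """Mean and RSD per (group, compartment) cell for every measure.

    Cells with no data are simply absent; nothing is imputed.  Row order is
    fixed by the canonical group/compartment order, so totals are invariant
    under permutation of the input.
    """
    if not measures:
        raise ValueError("no measures given")
    df = pd.DataFrame([m.__dict__ for m in measures])
    rows = []
    for group in GROUPS:
        for compartment in COMPARTMENTS:
            cell = df[(df.group == group) & (df.compartment == compartment)]
            if cell.empty:
                continue
            row: dict[str, object] = {"group": group, "compartment": compartment,
                                      "n_genomes": len(cell)}
            for measure in MEASURES:
                vals = cell[measure].astype(float).tolist()
                row[f"{measure}_mean"] = float(np.mean(vals))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row[f"{measure}_rsd_pct"] = rsd(vals)
            rows.append(row)
    return pd.DataFrame(rows)


def read_measures_tsv(path: str | Path) -> list[GenomeMeasure]:
    df = pd.read_csv(path, sep="\t")
    required = {"species", "group", "compartment", "length_bp", "n_proteins",
                "n_rnas", "coding_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns: {sorted(missing)}")
    return [GenomeMeasure(species=r.species, group=r.group, compartment=r.compartment,
                          length_bp=int(r.length_bp), n_proteins=int(r.n_proteins),
                          n_rnas=int(r.n_rnas), coding_fraction=float(r.coding_fraction))
            for r in df.itertuples()]


def write_group_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# RSD in percent of the mean, sample (n-1) standard deviation\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.4g")
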