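"""Phenotype tables: a thin typed wrapper over pandas with column roles.

A role map assigns each used column to one of: trait (numeric, missing
allowed), fixed factor (categorical), covariate (numeric) or environmental
random factor (categorical).  Rows with missing trait values are retained
here and filtered per trait when a model is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NA_TOKENS = ["NA", "na", ".", ""]


class PhenotypeError(ValueError):
    pass


@dataclass
class PhenotypeTable:
    data: pd.DataFrame
    id_column: str
    traits: list[str]
    fixed: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    random: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise PhenotypeError("column names must be unique")
        if not self.traits:
            raise PhenotypeError("at least one trait column is required")
        for col in [self.id_column, *self.traits, *self.fixed,
                    *self.covariates, *self.random]:
            if col not in self.data.columns:
                raise PhenotypeError(f"role map names absent column {col!r}")
        if self.data[self.id_column].isna().any():
            raise PhenotypeError("every row must carry an individual ID")
        df = self.data.copy()
        df[self.id_column] = df[self.id_column].astype(str)
        for col in self.traits + self.covariates:
            try:
                df[col] = pd.to_numeric(df[col].replace(NA_TOKENS, np.nan))
            except (ValueError, TypeError) as err:
                raise PhenotypeError(f"non-numeric value in column {col!r}: {err}")
        if df[self.covariates].isna().any().any():
            raise PhenotypeError("covariate columns may not contain missing values")
        for col in self.fixed + self.random:
            df[col] = df[col].astype(str)
        self.data = df

    @property
    def individual_ids(self) -> list[str]:
        return self.data[self.id_column].tolist()

    def __len__(self) -> int:
        return len(self.data)


def read_phenotypes(
    path: str | Path,
    id_column: str,
    traits: list[str],
    fixed: list[str] | None = None,
    covariates: list[str] | None = None,
    random: list[str] | None = None,
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a delimited phenotype file with a header row.

    ``sep=None`` sniffs tab/comma/whitespace from the header line.
    """
    path = Path(path)
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return PhenotypeTable(
        df,
        id_column=id_column,
        traits=traits,
        fixed=fixed or [],
        covariates=covariates or [],
        random=random or [],
    )


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, na_rep="NA")
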