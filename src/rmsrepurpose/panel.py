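"""Multi-omics cell-line panel containers and TSV exchange format.

A panel bundles the omics layers measured on one set of cell lines:
log-scale gene expression, gene-level minimum/maximum integer copy
numbers with a per-line average ploidy, and somatic variant records.
Derived binary layers (copy-number calls, mutation matrix) are attached
by the preprocessing step.

On disk a panel is a directory of plain TSV files (rows = cell lines,
columns = gene symbols, first column ``cell_line``), a long-format
variant table, and the drug-response table with drugs as rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["cell_line", "gene", "consequence"]

#: consequence classes that alter the protein product; "silent" does not
NON_SILENT = frozenset({"missense", "nonsense", "frameshift"})


@dataclass
class OmicsPanel:
    """Aligned multi-layer omics matrices sharing one cell-line index.

    Parameters
    ----------
    expression : DataFrame
        Cell-line x gene log-scale expression values.
    cn_min, cn_max : DataFrame
        Gene-level minimum / maximum integer copy numbers. They differ
        only when a breakpoint falls inside the gene.
    ploidy : Series
        Average copy number per cell line (the copy-neutral state).
    variants : DataFrame
        Long-format somatic variant records with columns
        ``cell_line``, ``gene``, ``consequence``.
    cn_binary, mutation : DataFrame, optional
        Derived binary layers filled in by preprocessing.
    """

    expression: pd.DataFrame
    cn_min: pd.DataFrame
    cn_max: pd.DataFrame
    ploidy: pd.Series
    variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=VARIANT_COLUMNS)
    )
    cn_binary: pd.DataFrame | None = None
    mutation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name in ("expression", "cn_min", "cn_max", "cn_binary", "mutation"):
            layer = getattr(self, name)
            if layer is not None:
                layer.index.name = "cell_line"
                layer.columns.name = None
        self.ploidy.index.name = "cell_line"
        cells = self.expression.index
        for name in ("cn_min", "cn_max"):
            layer = getattr(self, name)
            if not layer.index.equals(cells):
                raise ValueError(f"{name} cell-line index differs from expression")
        if not self.ploidy.index.equals(cells):
            raise ValueError("ploidy index differs from expression")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_cell_lines(self) -> int:
        return len(self.expression)

    def layer(self, name: str) -> pd.DataFrame:
        """Return a layer by name, raising if a derived layer is missing."""
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"layer {name!r} has not been computed for this panel")
        return value

    def copy(self) -> "OmicsPanel":
        return OmicsPanel(
            expression=self.expression.copy(),
            cn_min=self.cn_min.copy(),
            cn_max=self.cn_max.copy(),
            ploidy=self.ploidy.copy(),
            variants=self.variants.copy(),
            cn_binary=None if self.cn_binary is None else self.cn_binary.copy(),
            mutation=None if self.mutation is None else self.mutation.copy(),
        )

    # ---------------------------------------------------------------- IO

    def to_dir(self, path: str | Path) -> None:
        """Write the panel as a directory of TSV files."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        _write_matrix(self.expression, path / "expression.tsv")
        _write_matrix(self.cn_min, path / "cn_min.tsv")
        _write_matrix(self.cn_max, path / "cn_max.tsv")
        self.ploidy.rename("ploidy").to_csv(
            path / "ploidy.tsv", sep="\t", index_label="cell_line"
        )
        self.variants.to_csv(path / "variants.tsv", sep="\t", index=False)
        if self.cn_binary is not None:
            _write_matrix(self.cn_binary, path / "cn_binary.tsv")
        if self.mutation is not None:
            _write_matrix(self.mutation, path / "mutation.tsv")

    @classmethod
    def from_dir(cls, path: str | Path) -> "OmicsPanel":
        path = Path(path)
        kwargs = dict(
            expression=_read_matrix(path / "expression.tsv"),
            cn_min=_read_matrix(path / "cn_min.tsv").astype(int),
            cn_max=_read_matrix(path / "cn_max.tsv").astype(int),
            ploidy=pd.read_csv(path / "ploidy.tsv", sep="\t", index_col=0)["ploidy"],
        )
        if (path / "variants.tsv").exists():
            kwargs["variants"] = read_variants(path / "variants.tsv")
        panel = cls(**kwargs)
        if (path / "cn_binary.tsv").exists():
            panel.cn_binary = _read_matrix(path / "cn_binary.tsv").astype(int)
        if (path / "mutation.tsv").exists():
            panel.mutation = _read_matrix(path / "mutation.tsv").astype(int)
        return panel


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index_label="cell_line")


def _read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like variant TSV (cell_line, gene, consequence)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return df[VARIANT_COLUMNS]


# ------------------------------------------------------------ responses


def write_response_table(responses: pd.DataFrame, path: str | Path) -> None:
    """Write a drug x cell-line 0/1/NA response table as TSV."""
    responses.to_csv(path, sep="\t", index_label="drug", na_rep="NA")


def read_response_table(path: str | Path) -> pd.DataFrame:
    """Read a drug x cell-line response table; NA marks unscreened pairs."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    bad = df.stack().dropna().unique()
    if not np.isin(bad, [0, 1]).all():
        raise ValueError("response table entries must be 0, 1 or NA")
    return df.astype(float)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))
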