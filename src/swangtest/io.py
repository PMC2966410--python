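"""Expression-matrix container and tab-delimited readers/writers.

Layout convention: genes as rows, samples as columns; the first column
holds gene identifiers and the header row holds sample identifiers.
Group assignments come from a two-column file (sample <tab> case|control)
or a mapping.  Values are log2 intensities; ``log2_transform`` converts
raw intensities with a pseudo-count offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MatrixFormatError",
    "read_matrix",
    "read_groups",
    "write_matrix",
    "write_results",
]

CASE, CONTROL = "case", "control"


class MatrixFormatError(ValueError):
    """Malformed expression matrix or group specification."""


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with a two-group design."""

    data: pd.DataFrame  # index: gene ids, columns: sample ids
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        # normalize axis names so constructed and file-loaded matrices compare equal
        self.data.index.name = "gene_id"
        self.data.columns.name = None
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixFormatError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            raise MatrixFormatError("duplicate sample ids in header")
        unknown = set(self.groups) - set(self.data.columns)
        if unknown:
            raise MatrixFormatError(
                f"group file names samples absent from the matrix header: {sorted(unknown)}"
            )
        missing = set(self.data.columns) - set(self.groups)
        if missing:
            raise MatrixFormatError(f"samples without a group label: {sorted(missing)}")
        bad = {s: g for s, g in self.groups.items() if g not in (CASE, CONTROL)}
        if bad:
            raise MatrixFormatError(f"group labels must be case/control, got {bad}")
        if not self.case_ids or not self.control_ids:
            raise MatrixFormatError("both case and control groups must be non-empty")
        if self.data.isna().any().any():
            na_genes = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise MatrixFormatError(
                f"missing values are not accepted (genes {na_genes[:5]}); "
                "impute or filter explicitly before loading"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def case_ids(self) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == CONTROL]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def group_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(case, control) value stacks of shape (genes, n) and (genes, m)."""
        return (
            self.data[self.case_ids].to_numpy(float),
            self.data[self.control_ids].to_numpy(float),
        )

    def gene(self, gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        row = self.data.loc[gene_id]
        return row[self.case_ids].to_numpy(float), row[self.control_ids].to_numpy(float)

    def log2_transform(self, offset: float = 1.0) -> "ExpressionMatrix":
        """log2(x + offset) for matrices of raw (linear-scale) intensities."""
        values = self.data.to_numpy(float) + offset
        if (values <= 0).any():
            raise MatrixFormatError(
                f"log2 transform undefined: values <= {-offset} present"
            )
        return ExpressionMatrix(
            pd.DataFrame(np.log2(values), index=self.data.index, columns=self.data.columns),
            dict(self.groups),
        )


def read_groups(path: str | Path) -> dict[str, str]:
    """Two-column tab-delimited file: sample_id <tab> case|control."""
    groups: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise MatrixFormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sample, label = parts[0].strip(), parts[1].strip().lower()
        if sample in groups:
            raise MatrixFormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
        groups[sample] = label
    return groups


def read_matrix(
    path: str | Path,
    groups: str | Path | dict[str, str],
    *,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Parse a tab-delimited genes x samples matrix with a group design.

    The first row is a header of sample ids, the first column gene ids.
    ``transpose=True`` accepts the samples-as-rows layout.
    """
    lines = Path(path).read_text().splitlines()
    rows = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")
    header = rows[0].split("\t")
    width = len(header)
    for lineno, ln in enumerate(rows[1:], start=2):
        if len(ln.split("\t")) != width:
            raise MatrixFormatError(
                f"{path}:{lineno}: ragged row ({len(ln.split(chr(9)))} fields, expected {width})"
            )
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transpose:
        df = df.T
    if isinstance(groups, (str, Path)):
        groups = read_groups(groups)
    return ExpressionMatrix(df, dict(groups))


def _provenance_header(provenance: str | None) -> str:
    return f"# {provenance}\n" if provenance else ""


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    *,
    provenance: str | None = None,
) -> None:
    """Write matrix and an adjacent ``<path>.groups`` design file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        matrix.data.to_csv(fh, sep="\t", index_label="gene_id")
    with open(path.with_suffix(path.suffix + ".groups"), "w") as fh:
        fh.write(_provenance_header(provenance))
        for sample in matrix.sample_ids:
            fh.write(f"{sample}\t{matrix.groups[sample]}\n")


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    *,
    provenance: str | None = None,
) -> None:
    """Tab-delimited result table with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        table.to_csv(fh, sep="\t", index=False)
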