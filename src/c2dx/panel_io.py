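"""Domain types and file I/O for gene panels, expression matrices, and subtype models.

The tool touches three kinds of artifacts:

* NanoString nCounter ``.RCC`` files — sectioned text, one sample per file,
  with a ``<Code_Summary>`` CSV block (CodeClass,Name,Accession,Count).
* Plain tab-delimited gene-by-sample expression matrices (counts or FPKM-UQ).
* JSON files for gene panels (name/role records) and logistic subtype models
  (intercept + per-gene coefficients on the individually normalized scale).

The published 15-signature-gene LUAD-vs-LUSC model ships as a constant via
:func:`published_model`.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "Platform",
    "GenePanel",
    "ExpressionMatrix",
    "SubtypeModel",
    "PanelFormatError",
    "read_rcc",
    "read_rcc_set",
    "read_matrix",
    "write_matrix",
    "read_model",
    "write_model",
    "read_panel",
    "write_panel",
    "published_model",
    "NORMALIZATION_CONTRACT",
]

VALID_LABELS = ("LUAD", "LUSC", "NOS", "UNKNOWN")

#: Marker recorded in every serialized model: predictions are only meaningful on
#: profiles that went through the per-sample (individual) normalization scheme.
NORMALIZATION_CONTRACT = "individual-log2-housekeeping-z"


class PanelFormatError(ValueError):
    """Raised when a panel, matrix, model, or RCC file violates its format."""


class Role(str, enum.Enum):
    """Role of a gene on the diagnostic panel."""

    LUAD = "LUAD"
    LUSC = "LUSC"
    HOUSEKEEPING = "HOUSEKEEPING"


class Platform(str, enum.Enum):
    """Expression measurement platform of a matrix."""

    COUNTS = "COUNTS"  # NanoString reporter code counts
    FPKM_UQ = "FPKM_UQ"  # upper-quartile normalized RNA-Seq


@dataclass(frozen=True)
class GenePanel:
    """An ordered gene panel assigning each gene a diagnostic or housekeeping role.

    Parameters
    ----------
    entries
        Sequence of ``(gene_name, role)`` pairs. Gene names must be unique and
        non-empty; the panel must contain at least one housekeeping gene and at
        least one diagnostic (LUAD- or LUSC-associated) gene.
    """

    entries: tuple[tuple[str, Role], ...]

    def __init__(self, entries: Iterable[tuple[str, Role | str]]):
        normalized = tuple((str(name), Role(role)) for name, role in entries)
        names = [n for n, _ in normalized]
        if any(not n for n in names):
            raise PanelFormatError("panel contains an empty gene name")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelFormatError(f"duplicate gene names in panel: {dupes}")
        roles = [r for _, r in normalized]
        if Role.HOUSEKEEPING not in roles:
            raise PanelFormatError("panel has no housekeeping gene")
        if all(r is Role.HOUSEKEEPING for r in roles):
            raise PanelFormatError("panel has no diagnostic gene")
        object.__setattr__(self, "entries", normalized)

    @property
    def genes(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def diagnostic_genes(self) -> list[str]:
        return [n for n, r in self.entries if r is not Role.HOUSEKEEPING]

    @property
    def housekeeping_genes(self) -> list[str]:
        return [n for n, r in self.entries if r is Role.HOUSEKEEPING]

    def genes_with_role(self, role: Role | str) -> list[str]:
        role = Role(role)
        return [n for n, r in self.entries if r is role]

    def role_of(self, gene: str) -> Role:
        for n, r in self.entries:
            if n == gene:
                return r
        raise KeyError(gene)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ExpressionMatrix:
    """Raw non-negative expression values, genes in rows and samples in columns.

    ``values`` is a pandas DataFrame indexed by gene name with sample ids as
    columns. ``labels``, when present, maps every sample id to one of
    LUAD / LUSC / NOS / UNKNOWN.
    """

    values: pd.DataFrame
    platform: Platform
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        v = self.values
        if v.index.has_duplicates:
            raise PanelFormatError(
                f"duplicate gene names: {sorted(v.index[v.index.duplicated()])}"
            )
        if v.columns.has_duplicates:
            raise PanelFormatError(
                f"duplicate sample ids: {sorted(v.columns[v.columns.duplicated()])}"
            )
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise PanelFormatError("expression values must be finite")
        if np.any(arr < 0):
            bad = v.index[(arr < 0).any(axis=1)][:5].tolist()
            raise PanelFormatError(f"negative expression values (genes {bad})")
        if self.labels is not None:
            self.labels = pd.Series(self.labels).reindex(v.columns)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()].tolist()
                raise PanelFormatError(f"samples without a label: {missing}")
            bad_labels = set(self.labels) - set(VALID_LABELS)
            if bad_labels:
                raise PanelFormatError(f"invalid subtype labels: {sorted(bad_labels)}")

    @property
    def gene_names(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SubtypeModel:
    """Logistic LUAD-vs-LUSC model: intercept plus per-gene coefficients.

    Coefficients apply to individually normalized (per-sample z-scaled)
    expression profiles; positive coefficients favor LUAD, negative LUSC.
    The number of coefficient genes is the model complexity ``m``.
    """

    intercept: float
    coefficients: Mapping[str, float]
    normalization_contract: str = NORMALIZATION_CONTRACT

    def __post_init__(self) -> None:
        coef = dict(self.coefficients)
        if not coef:
            raise PanelFormatError("model has no coefficient genes")
        if not math.isfinite(self.intercept):
            raise PanelFormatError("model intercept must be finite")
        for g, b in coef.items():
            if not g:
                raise PanelFormatError("model contains an empty gene name")
            if not math.isfinite(float(b)):
                raise PanelFormatError(f"non-finite coefficient for gene {g!r}")
        object.__setattr__(self, "intercept", float(self.intercept))
        object.__setattr__(self, "coefficients", {g: float(b) for g, b in coef.items()})

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients)

    @property
    def complexity(self) -> int:
        return len(self.coefficients)


# ---------------------------------------------------------------------------
# NanoString RCC files
# ---------------------------------------------------------------------------

_RCC_GENE_CLASSES = {"Endogenous", "Housekeeping"}


def read_rcc(path: str | Path) -> ExpressionMatrix:
    """Read a single-sample NanoString ``.RCC`` file into a COUNTS matrix.

    Only Endogenous and Housekeeping code classes are retained as genes;
    positive/negative/binding controls are excluded. The sample id is taken
    from the ``ID`` record of the ``<Sample_Attributes>`` section when present,
    otherwise from the file name stem.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    sample_id = path.stem
    in_attrs = in_summary = False
    saw_summary = header_seen = False
    genes: list[str] = []
    counts: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line == "<Sample_Attributes>":
            in_attrs = True
            continue
        if line == "</Sample_Attributes>":
            in_attrs = False
            continue
        if line == "<Code_Summary>":
            in_summary = saw_summary = True
            header_seen = False
            continue
        if line == "</Code_Summary>":
            in_summary = False
            continue
        if in_attrs:
            key, _, value = line.partition(",")
            if key == "ID" and value:
                sample_id = value
        elif in_summary and line:
            fields = line.split(",")
            if not header_seen:
                header_seen = True
                if fields[0] != "CodeClass":
                    raise PanelFormatError(
                        f"{path}: line {lineno}: Code_Summary header must start "
                        f"with CodeClass, got {fields[0]!r}"
                    )
                continue
            if len(fields) < 4:
                raise PanelFormatError(
                    f"{path}: line {lineno}: expected CodeClass,Name,Accession,Count"
                )
            code_class, name = fields[0], fields[1]
            if code_class not in _RCC_GENE_CLASSES:
                continue
            try:
                count = float(fields[3])
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}: line {lineno}: non-numeric count {fields[3]!r}"
                ) from exc
            if count < 0:
                raise PanelFormatError(f"{path}: line {lineno}: negative count")
            genes.append(name)
            counts.append(count)
    if not saw_summary:
        raise PanelFormatError(f"{path}: no <Code_Summary> section")
    values = pd.DataFrame({sample_id: counts}, index=pd.Index(genes, name="gene"))
    return ExpressionMatrix(values=values, platform=Platform.COUNTS)


def read_rcc_set(paths: Sequence[str | Path]) -> ExpressionMatrix:
    """Read several single-sample RCC files and merge them by gene name."""
    singles = [read_rcc(p) for p in paths]
    gene_sets = {tuple(m.gene_names) for m in singles}
    if len(gene_sets) > 1:
        raise PanelFormatError("RCC files do not share an identical gene list")
    values = pd.concat([m.values for m in singles], axis=1)
    return ExpressionMatrix(values=values, platform=Platform.COUNTS)


# ---------------------------------------------------------------------------
# Tab-delimited matrices
# ---------------------------------------------------------------------------


def read_matrix(
    path: str | Path,
    platform: Platform | str,
    labels: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (first column gene names, header
    row sample ids). Lines starting with ``#`` are treated as comments."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise PanelFormatError(f"{path}: duplicate gene names: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise PanelFormatError(f"{path}: non-numeric expression value: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, platform=Platform(platform), labels=labels)


def write_matrix(
    matrix: ExpressionMatrix, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a matrix as tab-delimited text, optionally with ``#`` header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df = matrix.values.copy()
        df.index.name = "gene"
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Model and panel JSON
# ---------------------------------------------------------------------------

_MODEL_FIELDS = {"intercept", "coefficients", "normalization_contract", "provenance"}


def write_model(model: SubtypeModel, path: str | Path, provenance: dict | None = None) -> None:
    payload: dict = {
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
        "normalization_contract": model.normalization_contract,
    }
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path: str | Path) -> SubtypeModel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PanelFormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise PanelFormatError(f"{path}: model file must hold a JSON object")
    unknown = set(payload) - _MODEL_FIELDS
    if unknown:
        raise PanelFormatError(f"{path}: unknown model fields: {sorted(unknown)}")
    if "intercept" not in payload:
        raise PanelFormatError(f"{path}: model file missing 'intercept'")
    if "coefficients" not in payload:
        raise PanelFormatError(f"{path}: model file missing 'coefficients'")
    return SubtypeModel(
        intercept=payload["intercept"],
        coefficients=payload["coefficients"],
        normalization_contract=payload.get(
            "normalization_contract", NORMALIZATION_CONTRACT
        ),
    )


def write_panel(panel: GenePanel, path: str | Path) -> None:
    payload = {"genes": [{"name": n, "role": r.value} for n, r in panel.entries]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_panel(path: str | Path) -> GenePanel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PanelFormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "genes" not in payload:
        raise PanelFormatError(f"{path}: panel file must hold a JSON object with 'genes'")
    try:
        entries = [(g["name"], Role(g["role"])) for g in payload["genes"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise PanelFormatError(f"{path}: malformed panel entry: {exc}") from exc
    return GenePanel(entries)


# ---------------------------------------------------------------------------
# The published model
# ---------------------------------------------------------------------------

# 15-signature-gene logistic model: negative coefficients are LUSC-related
# markers (TP63, keratins, ...), positive ones LUAD-related (NKX2-1/TTF-1,
# MUC1, ...). Gene symbols kept exactly as published (GPR116 is alias-prone
# and deliberately not remapped). Coefficients are on the individually
# normalized scale.
_PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "TP63": -0.58872,
    "KRT14": -0.39198,
    "ANXA8L2": -0.27091,
    "KRT5": -0.25936,
    "SERPINB13": -0.10086,
    "SNAI2": -0.048,
    "KRT6A": -0.0221,
    "PKP1": -0.00488,
    "SPINK1": 0.00302,
    "CD55": 0.00562,
    "NKX2-1": 0.02709,
    "MUC1": 0.13468,
    "GPR116": 0.13792,
    "PNMA2": 0.15816,
    "TMC5": 0.31305,
}
_PUBLISHED_INTERCEPT = 0.27297


def published_model() -> SubtypeModel:
    """Return the published 15-signature-gene LUAD-vs-LUSC subtyping model."""
    return SubtypeModel(
        intercept=_PUBLISHED_INTERCEPT, coefficients=dict(_PUBLISHED_COEFFICIENTS)
    )
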