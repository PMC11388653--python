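"""Reading and writing the LH2 expression-matrix dialect, result tables and run configs.

The LH2 dialect is delimited text with genes as rows and samples as columns:
a header row of sample identifiers, one row per gene (gene id followed by
intensities), and a final row of class-label tokens (``ADCA`` for
adenocarcinoma, ``MPM`` for mesothelioma).  Gene order is preserved exactly
as read because the downstream window partitioning depends on it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, InputError, LabelError, ParseError

logger = logging.getLogger("mgx")

ADENO = "Adeno"
MESO = "Meso"
LABEL_TOKENS = {"ADCA": ADENO, "MPM": MESO, ADENO: ADENO, MESO: MESO}
_WRITE_TOKENS = {ADENO: "ADCA", MESO: "MPM"}

#: Table-5 metric column order used by every results table.
METRIC_COLUMNS = ("acc", "f1", "mcc", "er", "ji", "csi", "gmean", "kappa")


@dataclass
class ExpressionMatrix:
    """A genes x samples intensity matrix with per-sample class labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise InputError("expression matrix must be 2-D with at least one gene")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise InputError("gene_ids length does not match the matrix")
        if len(self.sample_ids) != n_samples or len(self.labels) != n_samples:
            raise InputError("sample_ids/labels length does not match the matrix")
        bad = sorted({l for l in self.labels if l not in (ADENO, MESO)})
        if bad:
            raise LabelError(f"unknown class labels: {bad}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == label)


@dataclass
class RunConfig:
    """One pipeline run: DR method, optional wrapper selection, classifier, CV setup.

    Classifier and optimizer hyperparameters default to the tuned values the
    study conditions prescribe; any field can be overridden from YAML.
    """

    dr_method: str = "DFA"             # HT | DFA | LSLR
    fsel_method: str = "none"          # none | EHO | CS
    classifier: str = "SVM_linear"     # BLDC | NBC | RFC | DTC | SVM_linear | SVM_poly | SVM_rbf
    target_dim: int = 1253
    folds: int = 10
    seed: int = 42
    # regression targets for MSE monitoring / optimizer fitness
    t_meso: float = 0.1
    t_adeno: float = 0.95
    # optimizer budgets (desk scale; paper scale = population 1253, 1000 iterations)
    population: int = 50
    iterations: int = 200
    paper_scale: bool = False
    eho_alpha: float = 0.65
    eho_beta: float = 0.68
    cs_alpha: float = 1.0
    cs_beta: float = 1.0
    cs_abandon_fraction: float = 0.4
    levy_mu: float = 1.3
    levy_sigma: float = 1.0
    selection_threshold: float = 0.5
    fsel_global_mode: bool = False     # True reproduces selection outside the CV loop
    # classifier hyperparameters
    bldc_prior: float = 0.5
    bldc_ridge: float = 1e-3
    nbc_smoothing: float = 0.01
    nbc_prior_meso: float = 0.2
    rf_n_trees: int = 100
    rf_max_depth: int = 10
    rf_bootstrap_fraction: float = 0.25
    rf_bootstrap_absolute: int | None = None
    rf_class_weight: float = 0.4
    dt_max_depth: int = 10
    dt_class_weight: float = 0.45
    svm_linear_c: float = 0.85
    svm_linear_class_weight: float = 0.4
    svm_poly_c: float = 0.76
    svm_poly_gamma: float = 10.0
    svm_poly_degree: int = 3
    svm_poly_class_weight: float = 0.5
    svm_rbf_c: float = 1.0
    svm_rbf_gamma: float = 100.0
    svm_rbf_class_weight: float = 0.86

    _DR = {"HT", "DFA", "LSLR"}
    _FSEL = {"none", "EHO", "CS"}
    _CLF = {"BLDC", "NBC", "RFC", "DTC", "SVM_linear", "SVM_poly", "SVM_rbf"}

    def __post_init__(self):
        if self.dr_method not in self._DR:
            raise ConfigError(f"unknown DR method {self.dr_method!r}")
        if self.fsel_method not in self._FSEL:
            raise ConfigError(f"unknown feature-selection method {self.fsel_method!r}")
        if self.classifier not in self._CLF:
            raise ConfigError(f"unknown classifier {self.classifier!r}")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.target_dim < 1:
            raise ConfigError("target_dim must be positive")
        if self.paper_scale:
            self.population = 1253
            self.iterations = 1000

    def rng(self) -> np.random.Generator:
        """The single generator all stage randomness flows from."""
        return np.random.default_rng(self.seed)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)


def _detect_delimiter(header: str) -> str:
    # LH2 distributions vary; accept tab or comma, decided from the header line
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_lh2_matrix(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read an LH2-dialect matrix; ADCA/MPM tokens map to Adeno/Meso."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: expected header, gene rows and a label row")
    delim = _detect_delimiter(lines[0])
    header = lines[0].split(delim)
    sample_ids = [c.strip() for c in header[1:]]
    n_samples = len(sample_ids)
    if n_samples < 1:
        raise FormatError(f"{path}: header row names no samples")

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for ridx, line in enumerate(lines[1:-1], start=2):
        cells = [c.strip() for c in line.split(delim)]
        if len(cells) != n_samples + 1:
            raise FormatError(
                f"{path}: row {ridx} has {len(cells) - 1} values, expected {n_samples}"
            )
        gene_ids.append(cells[0])
        vals = []
        for cidx, cell in enumerate(cells[1:], start=2):
            if cell == "":
                raise ParseError(f"{path}: empty cell at row {ridx}, column {cidx}")
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {ridx}, column {cidx}"
                ) from None
        rows.append(vals)

    label_cells = [c.strip() for c in lines[-1].split(delim)]
    if len(label_cells) != n_samples + 1:
        raise FormatError(f"{path}: label row has wrong width")
    labels = []
    for tok in label_cells[1:]:
        if tok not in LABEL_TOKENS:
            raise LabelError(f"{path}: unknown label token {tok!r}")
        labels.append(LABEL_TOKENS[tok])

    values = np.asarray(rows, dtype=float)
    if transpose:
        values = values.T
    logger.info("read %s: %d genes x %d samples", path, values.shape[0], values.shape[1])
    return ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids, labels=labels)


def write_lh2_matrix(matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write an ExpressionMatrix in the LH2 dialect (round-trips with read_lh2_matrix)."""
    out = []
    out.append(delimiter.join(["gene"] + list(matrix.sample_ids)))
    for gid, row in zip(matrix.gene_ids, matrix.values):
        out.append(delimiter.join([gid] + [repr(float(v)) for v in row]))
    out.append(delimiter.join(["class"] + [_WRITE_TOKENS[l] for l in matrix.labels]))
    Path(path).write_text("\n".join(out) + "\n")


def write_results(records: Sequence, path: str | Path) -> None:
    """Write one row per (dr_method, fsel_method, classifier) with Table-5-ordered metrics."""
    if not records:
        raise InputError("no metric records to write")
    rows = []
    for rec in records:
        row = {
            "dr_method": getattr(rec, "dr_method", ""),
            "fsel_method": getattr(rec, "fsel_method", ""),
            "classifier": getattr(rec, "classifier", ""),
        }
        for m in METRIC_COLUMNS:
            row[m] = getattr(rec, m)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["dr_method", "fsel_method", "classifier", *METRIC_COLUMNS])
    path = Path(path)
    if path.suffix == ".json":
        df.to_json(path, orient="records", indent=2, double_precision=15)
    else:
        df.to_csv(path, index=False, float_format="%.10f")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.read_json(path)
    return pd.read_csv(path)
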